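"""Accession passports joined to collection-site climate profiles.

A genebank *accession* is a uniquely identified seed sample tied to a
collection site; the site carries a long-term agro-climatic profile made of
eight variables: yearly precipitation (``precyr``, mm), yearly aridity index
(``ariyr``, dimensionless), yearly minimum/maximum temperature
(``tminyr``/``tmaxyr``, degC), temperature seasonality (``bio4``, SD x 100),
precipitation seasonality (``bio15``, CV %), and precipitation of the
wettest and coldest quarters (``bio16``/``bio19``, mm).

I/O is plain CSV (comma, decimal point, UTF-8, mandatory header); a schema
mapping translates foreign column names.  Rows violating the physical
invariants of a climate profile, or with missing climate values, are
rejected with row-level diagnostics rather than imputed — downstream set
selection presumes complete profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError

CLIMATE_VARS = ("precyr", "ariyr", "tminyr", "tmaxyr", "bio4", "bio15", "bio16", "bio19")

#: Canonical CSV column order.
COLLECTION_COLUMNS = ("accession_id", "site_id", "latitude", "longitude") + CLIMATE_VARS


@dataclass(frozen=True)
class ClimateProfile:
    """Eight long-term agro-climatic variables for one collection site."""

    precyr: float
    ariyr: float
    tminyr: float
    tmaxyr: float
    bio4: float
    bio15: float
    bio16: float
    bio19: float

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        out: list[str] = []
        for name in ("precyr", "ariyr", "bio15", "bio16", "bio19"):
            v = getattr(self, name)
            if not math.isfinite(v):
                out.append(f"{name} is not finite")
            elif v < 0:
                out.append(f"{name} < 0")
        for name in ("tminyr", "tmaxyr", "bio4"):
            if not math.isfinite(getattr(self, name)):
                out.append(f"{name} is not finite")
        if math.isfinite(self.tminyr) and math.isfinite(self.tmaxyr) and self.tmaxyr < self.tminyr:
            out.append("tmaxyr < tminyr")
        if math.isfinite(self.bio16) and math.isfinite(self.precyr) and self.bio16 > self.precyr:
            out.append("bio16 > precyr")
        return out

    @property
    def is_valid(self) -> bool:
        return not self.violations()


@dataclass(frozen=True)
class AccessionPassport:
    """One accession with its collection-site climate profile."""

    accession_id: str
    site_id: str
    climate: ClimateProfile
    latitude: float | None = None
    longitude: float | None = None


@dataclass(frozen=True)
class RowDiagnostic:
    """Why a row of an input file was rejected."""

    line: int  # 1-based physical line number in the file (header = line 1)
    accession_id: str
    reason: str


@dataclass
class Collection:
    """An ordered, duplicate-free set of accession passports.

    Records are kept sorted by ``accession_id`` so that every seeded
    downstream "random" step is reproducible.
    """

    records: list[AccessionPassport]
    provenance: str = ""
    skipped: list[RowDiagnostic] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.accession_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate accession_id: {', '.join(dupes)}")
        self.records = sorted(self.records, key=lambda r: r.accession_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AccessionPassport]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Collection):
            return NotImplemented
        return self.records == other.records

    def ids(self) -> list[str]:
        return [r.accession_id for r in self.records]

    def subset(self, keep: Iterable[str], provenance: str | None = None) -> "Collection":
        keep_set = set(keep)
        return Collection(
            [r for r in self.records if r.accession_id in keep_set],
            provenance if provenance is not None else self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the canonical column order."""
        rows = []
        for r in self.records:
            row = {
                "accession_id": r.accession_id,
                "site_id": r.site_id,
                "latitude": r.latitude,
                "longitude": r.longitude,
            }
            row.update({v: getattr(r.climate, v) for v in CLIMATE_VARS})
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COLLECTION_COLUMNS))


def _parse_optional(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_collection(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Collection:
    """Read a passport/climate CSV into a validated :class:`Collection`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping ``canonical name -> column name in the file`` for
        files with foreign headers.  Unmapped canonical names fall back to
        their own name.
    provenance
        Free-text source tag; defaults to the file name.

    Rows with missing or invariant-violating climate values are rejected and
    reported in ``Collection.skipped`` (line numbers are physical file
    lines).  Missing required columns raise :class:`SchemaError`; duplicate
    accession ids raise :class:`IntegrityError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in COLLECTION_COLUMNS}

    required = ["accession_id", "site_id", *CLIMATE_VARS]
    missing = [colmap[c] for c in required if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")

    have_lat = colmap["latitude"] in df.columns
    have_lon = colmap["longitude"] in df.columns

    records: list[AccessionPassport] = []
    skipped: list[RowDiagnostic] = []
    seen: dict[str, int] = {}
    for i, raw in enumerate(df.to_dict("records")):
        line = i + 2  # header occupies line 1
        acc = str(raw[colmap["accession_id"]]).strip()
        try:
            values = {v: float(raw[colmap[v]]) for v in CLIMATE_VARS}
        except (TypeError, ValueError) as exc:
            skipped.append(RowDiagnostic(line, acc, f"unparseable numeric value ({exc})"))
            continue
        if any(math.isnan(v) for v in values.values()):
            bad = sorted(k for k, v in values.items() if math.isnan(v))
            skipped.append(RowDiagnostic(line, acc, f"missing climate value(s): {', '.join(bad)}"))
            continue
        profile = ClimateProfile(**values)
        viol = profile.violations()
        if viol:
            skipped.append(RowDiagnostic(line, acc, "invariant violated: " + "; ".join(viol)))
            continue
        if acc in seen:
            raise IntegrityError(
                f"{path.name}: duplicate accession_id {acc!r} (lines {seen[acc]} and {line})"
            )
        seen[acc] = line
        records.append(
            AccessionPassport(
                accession_id=acc,
                site_id=str(raw[colmap["site_id"]]).strip(),
                climate=profile,
                latitude=_parse_optional(raw[colmap["latitude"]]) if have_lat else None,
                longitude=_parse_optional(raw[colmap["longitude"]]) if have_lon else None,
            )
        )

    coll = Collection(records, provenance if provenance is not None else path.name)
    coll.skipped = skipped
    return coll


def write_collection(collection: Collection, path: str | Path) -> Path:
    """Write a collection as canonical CSV (full float repr precision).

    ``read_collection(write_collection(c)) == c`` for every valid
    collection; absent latitude/longitude round-trip as empty cells.
    """
    path = Path(path)
    df = collection.to_frame()
    # 17 significant digits: every float64 round-trips bit-exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def collection_from_frame(df: pd.DataFrame, provenance: str = "") -> Collection:
    """Build a Collection from an in-memory table with canonical columns."""
    records = []
    for raw in df.to_dict("records"):
        records.append(
            AccessionPassport(
                accession_id=str(raw["accession_id"]),
                site_id=str(raw["site_id"]),
                climate=ClimateProfile(**{v: float(raw[v]) for v in CLIMATE_VARS}),
                latitude=_parse_optional(raw.get("latitude")),
                longitude=_parse_optional(raw.get("longitude")),
            )
        )
    return Collection(records, provenance)


def climate_matrix(collection: Collection) -> pd.DataFrame:
    """The n x 8 climate matrix indexed by accession_id (sorted order)."""
    df = collection.to_frame().set_index("accession_id")
    return df[list(CLIMATE_VARS)]
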