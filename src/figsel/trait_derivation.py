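"""Derived leaf morpho-physiological traits and accession-level aggregation.

Replicate-level (per-pot) raw measurements are turned into the 16 analysis
variables and averaged per accession:

* stomatal area ``SA = SL x SW`` (um^2), from stomatal length and width;
* stomatal area per unit leaflet area ``SAAL = SA x SD`` (um^2 mm^-2),
  reported on the conventional x10^-3 scale;
* relative water content ``RWC% = (FW - DW) / (TW - DW) x 100`` from fresh,
  turgid and dry leaf mass;
* intrinsic water-use efficiency ``WUE = A_net / g_s`` (umol CO2 per mol
  H2O of stomatal opening);
* leaflet and canopy temperature depression = tissue minus air temperature
  (negative values mean the tissue is cooler than the air, i.e. it is
  transpiring effectively);
* seed-size class (*minor* / *equina* / *major* botanical types) from seed
  mass with length as tie-breaker.

All ratio/product traits are computed at replicate level *before*
averaging: the mean of per-plant products is not the product of means, and
the published set means follow the former convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError
from .reference import ANALYSIS_VARIABLES

SEED_CLASSES = ("minor", "equina", "major")


@dataclass(frozen=True)
class SeedClassThresholds:
    """Seed-mass class bounds (g per seed), configurable.

    Defaults follow conventional *V. faba* botanical-variety mass ranges:
    minor < 0.5 g <= equina < 1.0 g <= major.  When mass sits exactly on a
    bound, seed length breaks the tie (longer seeds go to the larger
    class); the mass rule alone is decisive for the defaults.
    """

    minor_max: float = 0.5  # exclusive upper bound of minor
    major_min: float = 1.0  # inclusive lower bound of major
    length_tiebreak: float = 20.0  # mm; at a mass bound, length >= this bumps up


def stomatal_area(sl: float, sw: float) -> float:
    """Stomatal area SA = SL x SW (um^2)."""
    if sl < 0 or sw < 0:
        raise DomainError(f"stomatal dimensions must be non-negative (got {sl}, {sw})")
    return sl * sw


def stomatal_area_per_leaf_area(sa: float, sd: float) -> float:
    """Total stomatal pore-complex area per mm^2 of leaflet: SA x SD (um^2 mm^-2).

    The reporting layer divides by 1e3 for the conventional x10^-3 scale.
    """
    if sa < 0 or sd < 0:
        raise DomainError(f"SA and SD must be non-negative (got {sa}, {sd})")
    return sa * sd


def relative_water_content(fw: float, tw: float, dw: float) -> float:
    """RWC% = (FW - DW) / (TW - DW) x 100.

    Requires turgid > dry mass; values above 100 (fresh heavier than
    turgid, a weighing artifact) are returned as computed with a warning.
    """
    if tw <= dw:
        raise DomainError(f"degenerate sample: turgid mass {tw} <= dry mass {dw}")
    if fw < dw:
        raise DomainError(f"fresh mass {fw} below dry mass {dw}")
    rwc = (fw - dw) / (tw - dw) * 100.0
    if rwc > 100.0:
        warnings.warn(f"RWC {rwc:.1f}% > 100% (FW > TW)", stacklevel=2)
    return rwc


def intrinsic_wue(a_net: float, g_s: float) -> float:
    """Intrinsic water-use efficiency A_net / g_s (umol mol^-1)."""
    if g_s <= 0:
        raise DomainError(f"stomatal conductance must be positive (got {g_s})")
    return a_net / g_s


def temperature_depression(tissue_t: float, air_t: float) -> float:
    """Tissue (leaflet or canopy) minus air temperature, degC; negative = cooler."""
    return tissue_t - air_t


def classify_seed(
    seed_length: float,
    seed_mass: float,
    thresholds: SeedClassThresholds = SeedClassThresholds(),
) -> str:
    """Assign the traditional seed-size class from mass (length tie-break)."""
    if seed_length <= 0 or seed_mass <= 0:
        raise DomainError(
            f"seed length and mass must be positive (got {seed_length}, {seed_mass})"
        )
    if seed_mass >= thresholds.major_min:
        return "major"
    if seed_mass < thresholds.minor_max:
        return "minor"
    if seed_mass == thresholds.minor_max and seed_length < thresholds.length_tiebreak:
        return "minor"
    return "equina"


# Raw input columns that feed each derivable analysis variable.
_DERIVABLE = {
    "stomatal_area": ("stomatal_length", "stomatal_width"),
    "stomatal_area_per_leaflet_area": ("stomatal_area", "stomatal_density"),
    "relative_water_content": ("fresh_weight", "turgid_weight", "dry_weight"),
    "water_use_efficiency": ("photosynthetic_rate", "stomatal_conductance"),
    "leaflet_temp_depression": ("leaflet_temp", "air_temp"),
    "canopy_temp_depression": ("canopy_temp", "air_temp"),
}

_LEAFLET_COLS = tuple(f"leaflet_area_{i}" for i in range(1, 5))


def derive_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Fill in derivable analysis variables at replicate level.

    Columns already present are left untouched; otherwise they are computed
    from their raw inputs where available.  ``leaflet_area`` may be given
    directly or as up to four per-plant leaflet areas
    (``leaflet_area_1..4``), which are averaged per replicate.
    """
    df = replicates.copy()
    if "accession_id" not in df.columns:
        raise SchemaError("replicate table requires an accession_id column")

    if "leaflet_area" not in df.columns:
        present = [c for c in _LEAFLET_COLS if c in df.columns]
        if present:
            df["leaflet_area"] = df[present].mean(axis=1)

    if "stomatal_area" not in df.columns and all(
        c in df.columns for c in _DERIVABLE["stomatal_area"]
    ):
        df["stomatal_area"] = df["stomatal_length"] * df["stomatal_width"]
    if "stomatal_area_per_leaflet_area" not in df.columns and all(
        c in df.columns for c in _DERIVABLE["stomatal_area_per_leaflet_area"]
    ):
        # reported on the x10^-3 um^2 mm^-2 scale
        df["stomatal_area_per_leaflet_area"] = (
            df["stomatal_area"] * df["stomatal_density"] / 1e3
        )
    if "relative_water_content" not in df.columns and all(
        c in df.columns for c in _DERIVABLE["relative_water_content"]
    ):
        denom = df["turgid_weight"] - df["dry_weight"]
        if (denom <= 0).any():
            raise DomainError("turgid mass must exceed dry mass in every replicate")
        df["relative_water_content"] = (
            (df["fresh_weight"] - df["dry_weight"]) / denom * 100.0
        )
    if "water_use_efficiency" not in df.columns and all(
        c in df.columns for c in _DERIVABLE["water_use_efficiency"]
    ):
        if (df["stomatal_conductance"] <= 0).any():
            raise DomainError("stomatal conductance must be positive in every replicate")
        df["water_use_efficiency"] = df["photosynthetic_rate"] / df["stomatal_conductance"]
    for dep, (tissue, air) in (
        ("leaflet_temp_depression", _DERIVABLE["leaflet_temp_depression"]),
        ("canopy_temp_depression", _DERIVABLE["canopy_temp_depression"]),
    ):
        if dep not in df.columns and tissue in df.columns and air in df.columns:
            df[dep] = df[tissue] - df[air]
    return df


def aggregate_accession(
    replicates: pd.DataFrame,
    thresholds: SeedClassThresholds = SeedClassThresholds(),
) -> pd.DataFrame:
    """Replicate table -> one row per accession (mean over replicates).

    Analysis variables are averaged over available replicates (missing
    replicates tolerated; per-accession completeness recorded in the
    ``n_replicates`` column).  The seed-size class is carried per accession:
    taken from a ``seed_class`` column when present, otherwise classified
    from per-accession mean seed length and mass.
    """
    df = derive_replicates(replicates)
    if df.empty:
        raise DomainError("no replicate records to aggregate")
    present = [v for v in ANALYSIS_VARIABLES if v in df.columns]
    grouped = df.groupby("accession_id", sort=True)
    out = grouped[present].mean()
    out["n_replicates"] = grouped.size()

    if "seed_class" in df.columns:
        out["seed_class"] = grouped["seed_class"].agg(
            lambda s: s.mode().iloc[0] if not s.mode().empty else None
        )
    elif "seed_length" in df.columns and "seed_mass" in df.columns:
        means = grouped[["seed_length", "seed_mass"]].mean()
        out["seed_class"] = [
            classify_seed(l, m, thresholds)
            for l, m in zip(means["seed_length"], means["seed_mass"])
        ]
    return out.reset_index()


def read_replicates(path) -> pd.DataFrame:
    """Read a replicate-level trait CSV."""
    df = pd.read_csv(path, dtype={"accession_id": str})
    if "accession_id" not in df.columns:
        raise SchemaError(f"{path}: replicate table requires an accession_id column")
    return df


def write_traits(traits: pd.DataFrame, path) -> None:
    """Write an accession-level trait table as CSV."""
    traits.to_csv(path, index=False)
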