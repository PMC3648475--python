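"""Seeded synthetic genebank and trait data for exercising the pipeline.

No real passport or greenhouse data ship with this package, so two
generators emulate them:

* :func:`gen_collection` — a genebank-like passport/climate table spanning
  a dry rain-fed regime (300-550 mm/year sites whose precipitation
  seasonality straddles the bio15=50 cut and whose aridity straddles the
  0.1/0.6 pruning bounds), a wet regime (> 800 mm/year, high aridity
  index), and out-of-band noise sites, so that every branch of the set
  selection is reachable.

* :func:`gen_traits` — per-set accession-level latent trait values drawn
  from a multivariate normal with the reference per-set means and SDs of
  the 16 analysis variables (independent marginals by default; optional
  injected pairwise correlations), plus four replicate observations per
  accession (latent + within-accession noise), truncation at physical
  bounds with redraw, and a per-set seed-size class mixture.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .errors import ConfigError
from .passport_climate import (
    CLIMATE_VARS,
    AccessionPassport,
    ClimateProfile,
    Collection,
)
from .trait_derivation import aggregate_accession

_TRUNCATION_MAX_ROUNDS = 100


@dataclass(frozen=True)
class GeneratorConfig:
    """Distribution parameters of the synthetic genebank + trait generator.

    Trait defaults are the reference per-set summary statistics; the
    regime mix and climate spreads are chosen so that a 2,000-site
    collection comfortably supports a 201-accession dry set after all
    filters.
    """

    n_sites: int = 2000
    max_accessions_per_site: int = 3  # per-site count ~ Uniform{1..max}
    # regime mix: fractions of dry-band, wet-band and out-of-band sites
    dry_site_frac: float = 0.5
    wet_site_frac: float = 0.3
    # trait parameters: variable -> (mean, sd) per set; defaults = reference
    trait_params: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
    # optional injected correlations [(var_a, var_b, r), ...]
    correlations: Sequence[tuple[str, str, float]] = ()
    seed_class_probs: Mapping[str, Mapping[str, float]] | None = None
    n_replicates: int = 4
    within_sd_fraction: float = 0.5  # replicate noise SD as a fraction of the between-accession SD
    n_per_set: int = 201  # accessions per set in trait-only mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.max_accessions_per_site < 1:
            raise ConfigError("n_sites and max_accessions_per_site must be >= 1")
        if not 0 <= self.dry_site_frac + self.wet_site_frac <= 1:
            raise ConfigError("regime fractions must be probabilities summing to <= 1")
        if self.within_sd_fraction < 0:
            raise ConfigError("within_sd_fraction must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        for label, probs in (self.seed_class_probs or reference.SEED_CLASS_PROBS).items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"seed-class probabilities for {label!r} must sum to 1")

    def resolved_trait_params(self) -> dict[str, dict[str, tuple[float, float]]]:
        if self.trait_params is not None:
            return {k: dict(v) for k, v in self.trait_params.items()}
        return {
            "wet": {
                v: (s.wet_mean, s.wet_sd) for v, s in reference.TRAIT_SUMMARY.items()
            },
            "dry": {
                v: (s.dry_mean, s.dry_sd) for v, s in reference.TRAIT_SUMMARY.items()
            },
        }

    def resolved_seed_class_probs(self) -> dict[str, dict[str, float]]:
        return {
            k: dict(v)
            for k, v in (self.seed_class_probs or reference.SEED_CLASS_PROBS).items()
        }

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def ecophysiological_correlation_preset() -> list[tuple[str, str, float]]:
    """Optional documented correlation preset.

    Injects a moderate leaflet-area/RWC association (r = +0.54) and a
    strong RWC/canopy-temperature-depression association (r = +0.73),
    matching pooled R^2 values of about 0.29 and 0.54 reported for this
    system.  The pooled sign of the RWC-canopy association conflicts with
    the between-set mean structure (the dry set pairs higher RWC with
    cooler canopies), so independence remains the default.
    """
    return [
        ("leaflet_area", "relative_water_content", 0.54),
        ("relative_water_content", "canopy_temp_depression", 0.73),
    ]


def _draw_climate(rng: np.random.Generator, regime: str) -> ClimateProfile:
    """One site's climate profile for a regime, respecting the invariants."""
    if regime == "dry":
        precyr = rng.uniform(300.0, 550.0)
        ariyr = max(rng.normal(0.35, 0.14), 0.01)
        bio15 = max(rng.normal(62.0, 14.0), 0.0)
    elif regime == "wet":
        precyr = rng.uniform(801.0, 1500.0)
        ariyr = max(rng.normal(0.85, 0.25), 0.05)
        bio15 = max(rng.normal(45.0, 15.0), 0.0)
    elif regime == "arid":  # out-of-band, below the dry band
        precyr = rng.uniform(80.0, 299.0)
        ariyr = max(rng.normal(0.08, 0.05), 0.005)
        bio15 = max(rng.normal(70.0, 20.0), 0.0)
    else:  # "mid": out-of-band between the dry band and the wet threshold
        precyr = rng.uniform(551.0, 799.0)
        ariyr = max(rng.normal(0.55, 0.2), 0.02)
        bio15 = max(rng.normal(50.0, 15.0), 0.0)
    tminyr = rng.normal(7.0, 4.0)
    tmaxyr = tminyr + rng.uniform(8.0, 18.0)
    bio4 = max(rng.normal(750.0, 180.0), 1.0)
    bio16 = precyr * rng.uniform(0.30, 0.50)
    bio19 = precyr * rng.uniform(0.10, 0.45)
    return ClimateProfile(
        precyr=precyr,
        ariyr=ariyr,
        tminyr=tminyr,
        tmaxyr=tmaxyr,
        bio4=bio4,
        bio15=bio15,
        bio16=bio16,
        bio19=bio19,
    )


def gen_collection(cfg: GeneratorConfig, seed: int | None = None) -> Collection:
    """Generate a genebank-like passport/climate collection."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    regimes = ("dry", "wet", "arid", "mid")
    rest = max(1.0 - cfg.dry_site_frac - cfg.wet_site_frac, 0.0)
    probs = (cfg.dry_site_frac, cfg.wet_site_frac, rest / 2.0, rest / 2.0)
    records: list[AccessionPassport] = []
    acc_counter = 0
    for i in range(cfg.n_sites):
        site_id = f"S{i:05d}"
        regime = regimes[int(rng.choice(len(regimes), p=probs))]
        climate = _draw_climate(rng, regime)
        lat = rng.uniform(28.0, 48.0)
        lon = rng.uniform(-10.0, 48.0)
        for _ in range(int(rng.integers(1, cfg.max_accessions_per_site + 1))):
            acc_counter += 1
            records.append(
                AccessionPassport(
                    accession_id=f"ACC{acc_counter:06d}",
                    site_id=site_id,
                    climate=climate,
                    latitude=round(lat, 4),
                    longitude=round(lon, 4),
                )
            )
    return Collection(records, provenance=f"synthetic genebank (seed={cfg.seed}, n_sites={cfg.n_sites})")


def _set_covariance(
    variables: Sequence[str],
    params: Mapping[str, tuple[float, float]],
    correlations: Sequence[tuple[str, str, float]],
) -> np.ndarray:
    sds = np.array([params[v][1] for v in variables])
    corr = np.eye(len(variables))
    idx = {v: i for i, v in enumerate(variables)}
    for a, b, r in correlations:
        if a not in idx or b not in idx:
            raise ConfigError(f"correlation names unknown variable: ({a}, {b})")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ConfigError(
            "injected correlations do not form a positive semi-definite matrix: "
            + ", ".join(f"({a},{b},r={r})" for a, b, r in correlations)
        )
    return corr * np.outer(sds, sds)


_BOUNDS = {
    v: ((0.0, 100.0) if v == "relative_water_content" else (0.0, np.inf))
    for v in reference.NONNEGATIVE_VARIABLES
}


def _truncate_redraw(
    rng: np.random.Generator,
    values: np.ndarray,
    variables: Sequence[str],
    mean: np.ndarray,
    cov: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Redraw out-of-bound entries from their marginal until inside bounds.

    Marginal redraw slightly breaks injected correlations for the redrawn
    entries; redraw counts are returned for the generation log.
    """
    redraws = 0
    sd = np.sqrt(np.diag(cov))
    for j, var in enumerate(variables):
        lo, hi = _BOUNDS.get(var, (-np.inf, np.inf))
        bad = (values[:, j] < lo) | (values[:, j] > hi)
        rounds = 0
        while bad.any() and rounds < _TRUNCATION_MAX_ROUNDS:
            redraws += int(bad.sum())
            values[bad, j] = rng.normal(mean[j], sd[j], size=int(bad.sum()))
            bad = (values[:, j] < lo) | (values[:, j] > hi)
            rounds += 1
        if bad.any():  # pathological config: clip the stragglers
            values[:, j] = np.clip(values[:, j], lo, hi)
    return values, redraws


def gen_traits(
    cfg: GeneratorConfig,
    membership: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a replicate-level trait table for labelled accessions.

    ``membership`` needs columns ``accession_id`` and ``label``
    ("dry"/"wet").  Per accession a latent trait vector is drawn from its
    set's multivariate normal; each of the ``n_replicates`` observations is
    latent + independent noise with SD ``within_sd_fraction`` x the
    between-accession SD.  Fertile tillers are rounded to whole counts at
    replicate level; the seed-size class is drawn once per accession from
    the set's class mixture.

    Returns ``(replicate table, generation log)``.
    """
    if membership.empty:
        raise ConfigError("membership is empty")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    variables = list(reference.ANALYSIS_VARIABLES)
    params = cfg.resolved_trait_params()
    class_probs = cfg.resolved_seed_class_probs()
    log: dict = {"redraws": {}, "n_accessions": {}}

    frames = []
    for label in ("wet", "dry"):
        ids = sorted(membership.loc[membership["label"] == label, "accession_id"])
        if not ids:
            continue
        mean = np.array([params[label][v][0] for v in variables])
        cov = _set_covariance(variables, params[label], cfg.correlations)
        latent = rng.multivariate_normal(mean, cov, size=len(ids))
        latent, redraws = _truncate_redraw(rng, latent, variables, mean, cov)
        log["redraws"][label] = redraws
        log["n_accessions"][label] = len(ids)

        within_sd = cfg.within_sd_fraction * np.sqrt(np.diag(cov))
        classes = list(class_probs[label])
        seed_class = rng.choice(
            classes, size=len(ids), p=[class_probs[label][c] for c in classes]
        )
        for rep in range(1, cfg.n_replicates + 1):
            obs = latent + rng.normal(0.0, 1.0, latent.shape) * within_sd
            for j, var in enumerate(variables):
                lo, hi = _BOUNDS.get(var, (-np.inf, np.inf))
                obs[:, j] = np.clip(obs[:, j], lo, hi)
            df = pd.DataFrame(obs, columns=variables)
            df["fertile_tillers"] = np.maximum(np.rint(df["fertile_tillers"]), 0.0)
            df.insert(0, "accession_id", ids)
            df.insert(1, "replicate", rep)
            df["label"] = label
            df["seed_class"] = seed_class
            frames.append(df)

    table = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["accession_id", "replicate"], kind="mergesort")
        .reset_index(drop=True)
    )
    return table, log


@dataclass
class SyntheticBundle:
    """Everything one pipeline exercise needs, from a single seed."""

    collection: Collection | None
    membership: pd.DataFrame  # accession_id, label
    replicates: pd.DataFrame
    traits: pd.DataFrame  # accession-level
    log: dict = field(default_factory=dict)


def gen_bundle(cfg: GeneratorConfig, mode: str = "trait_only") -> SyntheticBundle:
    """Compose the generators into one labelled dataset.

    ``mode="trait_only"``: label ``n_per_set`` synthetic accessions per set
    directly and generate traits (no climate step) — the configuration used
    for classifier-harness experiments.  ``mode="full"``: generate a
    collection, run both set selections, then generate traits for the
    selected members.
    """
    if mode not in ("trait_only", "full"):
        raise ConfigError(f"unknown bundle mode {mode!r}")
    rng = np.random.default_rng(cfg.seed)
    log: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "mode": mode}
    collection: Collection | None = None

    if mode == "full":
        from .figs_selection import SelectionConfig, select_dry_set, select_wet_set

        collection = gen_collection(cfg, seed=int(rng.integers(2**31 - 1)))
        sel_cfg = SelectionConfig(seed=int(rng.integers(2**31 - 1)), set_size=cfg.n_per_set)
        dry = select_dry_set(collection, sel_cfg)
        wet = select_wet_set(collection, sel_cfg)
        membership = pd.DataFrame(
            {
                "accession_id": dry.members + wet.members,
                "label": ["dry"] * len(dry.members) + ["wet"] * len(wet.members),
            }
        )
        log["selection"] = {"dry": dry.dropped, "wet": wet.dropped}
    else:
        membership = pd.DataFrame(
            {
                "accession_id": [f"DRY{i:04d}" for i in range(1, cfg.n_per_set + 1)]
                + [f"WET{i:04d}" for i in range(1, cfg.n_per_set + 1)],
                "label": ["dry"] * cfg.n_per_set + ["wet"] * cfg.n_per_set,
            }
        )
    membership = membership.sort_values("accession_id", kind="mergesort").reset_index(drop=True)

    replicates, gen_log = gen_traits(cfg, membership, seed=int(rng.integers(2**31 - 1)))
    log["traits"] = gen_log
    traits = aggregate_accession(replicates.drop(columns=["label"]))
    traits = traits.merge(membership, on="accession_id", how="left")
    return SyntheticBundle(
        collection=collection,
        membership=membership,
        replicates=replicates,
        traits=traits,
        log=log,
    )
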