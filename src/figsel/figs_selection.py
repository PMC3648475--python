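"""Construction of climate-contrasted ("dry" / "wet") germplasm sets.

The dry set targets accessions from moisture-limited but rain-fed
environments: keep accessions whose site receives 300-550 mm/year, take one
accession per collection site at random, cluster sites on the eight climate
variables (average-linkage hierarchical clustering on squared Euclidean
distances, cut at 20 groups), drop clusters whose mean aridity index lies
above 0.6 or below 0.1 (the latter flags likely irrigated sites), discard
accessions with precipitation seasonality (bio15) of 50 or lower, rank the
remainder within each cluster by ascending yearly precipitation and pick
round-robin across clusters until the target set size (201) is reached.

The wet set is the control: sites receiving over 800 mm/year, one accession
per site, the 201 with the highest aridity indices.

Boundary conventions (documented, configurable): the dry rain band is the
closed interval [lo, hi] (the exclusion rule drops "below lo" and "greater
than hi"); the wet rule "over 800" is strict; aridity pruning uses strict
inequalities; ranking ties break by accession_id so the whole run is a pure
function of (collection, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ConfigError, EmptySelectionError
from .passport_climate import CLIMATE_VARS, AccessionPassport, Collection, climate_matrix


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of both set-construction algorithms."""

    dry_rain_min: float = 300.0  # mm/year, closed lower bound of the dry band
    dry_rain_max: float = 550.0  # mm/year, closed upper bound of the dry band
    n_clusters: int = 20
    aridity_hi: float = 0.6  # clusters with mean ariyr above this are dropped
    aridity_lo: float = 0.1  # ... or below this (likely irrigated sites)
    bio15_min_exclusive: float = 50.0  # accessions at or below are discarded
    set_size: int = 201
    wet_rain_min: float = 800.0  # mm/year, strict lower bound for the wet set
    seed: int = 0
    standardize_before_clustering: bool = True

    def __post_init__(self) -> None:
        if not self.dry_rain_min < self.dry_rain_max:
            raise ConfigError("dry_rain_min must be < dry_rain_max")
        if not self.aridity_lo < self.aridity_hi:
            raise ConfigError("aridity_lo must be < aridity_hi")
        if self.set_size < 1:
            raise ConfigError("set_size must be >= 1")
        if self.n_clusters < 2:
            raise ConfigError("n_clusters must be >= 2")


@dataclass
class FIGSSet:
    """A labelled accession subset with full selection provenance."""

    label: str  # "dry" | "wet"
    members: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)
    dropped: dict[str, dict] = field(default_factory=dict)
    cluster_summary: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _record_stage(dropped: dict, stage: str, before: int, after: int, reason: str) -> None:
    dropped[stage] = {"input": before, "kept": after, "dropped": before - after, "reason": reason}


def filter_rain_band(collection: Collection, lo: float, hi: float) -> Collection:
    """Keep accessions whose site precipitation lies in the closed band [lo, hi]."""
    if not lo < hi:
        raise ConfigError("rain band requires lo < hi")
    keep = [r.accession_id for r in collection if lo <= r.climate.precyr <= hi]
    return collection.subset(keep)


def one_per_site(collection: Collection, seed: int | np.random.Generator) -> Collection:
    """Choose one accession per collection site, uniformly at random.

    Sites are visited in sorted order and each site's accessions are sorted
    by id before drawing, so the result is a deterministic function of the
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_site: dict[str, list[AccessionPassport]] = {}
    for r in collection:
        by_site.setdefault(r.site_id, []).append(r)
    keep = []
    for site in sorted(by_site):
        group = sorted(by_site[site], key=lambda r: r.accession_id)
        keep.append(group[int(rng.integers(len(group)))].accession_id)
    return collection.subset(keep)


def cluster_sites(
    collection: Collection, k: int, standardize: bool = True
) -> tuple[dict[str, int], np.ndarray]:
    """Average-linkage hierarchical clustering of accessions on climate.

    Dissimilarity is squared Euclidean distance over the eight climate
    variables (z-scored first when ``standardize`` is on, since the
    variables differ by orders of magnitude).  "Between-groups" linkage is
    read in its standard sense: merge the pair of clusters with the
    smallest mean inter-cluster pairwise dissimilarity (UPGMA).  The
    dendrogram is cut into ``k`` groups.

    Returns ``(assignment, Z)`` where ``assignment`` maps accession_id to a
    1-based cluster id and ``Z`` is the linkage matrix (merge heights).
    """
    if len(collection) < k:
        raise ConfigError(f"cannot form {k} clusters from {len(collection)} accessions")
    X = climate_matrix(collection).to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = linkage(X, method="average", metric="sqeuclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    ids = climate_matrix(collection).index
    return dict(zip(ids, (int(l) for l in labels))), Z


def prune_clusters_by_aridity(
    assignment: Mapping[str, int],
    collection: Collection,
    lo: float,
    hi: float,
) -> tuple[set[int], list[dict]]:
    """Drop clusters whose mean aridity index is above ``hi`` or below ``lo``.

    Strict inequalities: a cluster mean exactly at a bound survives.
    Returns the surviving cluster ids and a per-cluster summary.
    """
    ariyr = {r.accession_id: r.climate.ariyr for r in collection}
    by_cluster: dict[int, list[float]] = {}
    for acc, cl in assignment.items():
        by_cluster.setdefault(cl, []).append(ariyr[acc])
    summary = []
    surviving: set[int] = set()
    for cl in sorted(by_cluster):
        mean = float(np.mean(by_cluster[cl]))
        kept = lo <= mean <= hi  # complement of strict "above hi or below lo"
        if kept:
            surviving.add(cl)
        summary.append(
            {"cluster": cl, "size": len(by_cluster[cl]), "mean_ariyr": mean, "kept": kept}
        )
    if not surviving:
        raise EmptySelectionError(
            f"all {len(by_cluster)} clusters pruned by aridity bounds ({lo}, {hi}); "
            "cluster means: " + ", ".join(f"{s['mean_ariyr']:.3f}" for s in summary)
        )
    return surviving, summary


def filter_bio15(collection: Collection, min_exclusive: float) -> Collection:
    """Discard accessions with precipitation seasonality at or below the cut."""
    keep = [r.accession_id for r in collection if r.climate.bio15 > min_exclusive]
    return collection.subset(keep)


def round_robin_select(
    clusters: Mapping[int, Sequence[AccessionPassport]], set_size: int
) -> FIGSSet:
    """Cycle clusters in ascending id order, taking each cluster's next
    lowest-precipitation accession, until ``set_size`` picks are made or
    every cluster is exhausted.

    Within a cluster, accessions are ranked by ascending ``precyr`` with
    ties broken by accession_id.
    """
    ranked = {
        cl: sorted(clusters[cl], key=lambda r: (r.climate.precyr, r.accession_id))
        for cl in sorted(clusters)
    }
    cursors = {cl: 0 for cl in ranked}
    members: list[str] = []
    provenance: dict[str, dict] = {}
    rnd = 0
    while len(members) < set_size:
        progressed = False
        rnd += 1
        for cl in sorted(ranked):
            if len(members) >= set_size:
                break
            i = cursors[cl]
            if i >= len(ranked[cl]):
                continue  # exhausted cluster: skip, keep cycling the rest
            rec = ranked[cl][i]
            cursors[cl] = i + 1
            members.append(rec.accession_id)
            provenance[rec.accession_id] = {
                "cluster": cl,
                "precyr_rank": i + 1,
                "round": rnd,
                "precyr": rec.climate.precyr,
                "bio15": rec.climate.bio15,
            }
            progressed = True
        if not progressed:
            break
    return FIGSSet(label="dry", members=members, provenance=provenance)


def select_dry_set(collection: Collection, cfg: SelectionConfig) -> FIGSSet:
    """Run the full dry-set pipeline with per-stage provenance."""
    dropped: dict[str, dict] = {}

    banded = filter_rain_band(collection, cfg.dry_rain_min, cfg.dry_rain_max)
    _record_stage(
        dropped, "rain_band", len(collection), len(banded),
        f"precyr outside [{cfg.dry_rain_min}, {cfg.dry_rain_max}] mm/year",
    )
    if not len(banded):
        raise EmptySelectionError("no accession inside the dry rain band")

    rng = np.random.default_rng(cfg.seed)
    per_site = one_per_site(banded, rng)
    _record_stage(dropped, "one_per_site", len(banded), len(per_site), "one accession per site")

    assignment, _ = cluster_sites(per_site, cfg.n_clusters, cfg.standardize_before_clustering)
    surviving, summary = prune_clusters_by_aridity(
        assignment, per_site, cfg.aridity_lo, cfg.aridity_hi
    )
    after_prune = per_site.subset(
        [acc for acc, cl in assignment.items() if cl in surviving]
    )
    _record_stage(
        dropped, "aridity_prune", len(per_site), len(after_prune),
        f"cluster mean ariyr above {cfg.aridity_hi} or below {cfg.aridity_lo}",
    )

    seasonal = filter_bio15(after_prune, cfg.bio15_min_exclusive)
    _record_stage(
        dropped, "bio15", len(after_prune), len(seasonal),
        f"bio15 <= {cfg.bio15_min_exclusive}",
    )
    if not len(seasonal):
        raise EmptySelectionError("no accession survives the bio15 filter")

    clusters: dict[int, list[AccessionPassport]] = {}
    for rec in seasonal:
        clusters.setdefault(assignment[rec.accession_id], []).append(rec)
    result = round_robin_select(clusters, cfg.set_size)
    _record_stage(
        dropped, "round_robin", len(seasonal), len(result.members),
        f"round-robin by ascending precyr to set size {cfg.set_size}",
    )
    result.dropped = dropped
    result.cluster_summary = summary
    if len(result.members) < cfg.set_size:
        result.warnings.append(
            f"only {len(result.members)} of the requested {cfg.set_size} accessions available"
        )
    return result


def select_wet_set(collection: Collection, cfg: SelectionConfig) -> FIGSSet:
    """Wet-set pipeline: precyr strictly over the wet threshold, one per
    site, then the ``set_size`` accessions with the highest aridity index
    (ties by accession_id)."""
    dropped: dict[str, dict] = {}
    eligible = collection.subset(
        [r.accession_id for r in collection if r.climate.precyr > cfg.wet_rain_min]
    )
    _record_stage(
        dropped, "rain_min", len(collection), len(eligible),
        f"precyr <= {cfg.wet_rain_min} mm/year",
    )
    if not len(eligible):
        raise EmptySelectionError("no accession above the wet rainfall threshold")

    per_site = one_per_site(eligible, np.random.default_rng(cfg.seed))
    _record_stage(dropped, "one_per_site", len(eligible), len(per_site), "one accession per site")

    ordered = sorted(per_site, key=lambda r: (-r.climate.ariyr, r.accession_id))
    chosen = ordered[: cfg.set_size]
    _record_stage(
        dropped, "top_aridity", len(per_site), len(chosen),
        f"top {cfg.set_size} by descending ariyr",
    )
    result = FIGSSet(
        label="wet",
        members=[r.accession_id for r in chosen],
        provenance={
            r.accession_id: {"ariyr_rank": i + 1, "ariyr": r.climate.ariyr}
            for i, r in enumerate(chosen)
        },
        dropped=dropped,
    )
    if len(result.members) < cfg.set_size:
        result.warnings.append(
            f"only {len(result.members)} of the requested {cfg.set_size} accessions available"
        )
    return result


def audit_set(figs_set: FIGSSet, collection: Collection, cfg: SelectionConfig) -> list[str]:
    """Independent post-hoc audit of a selected set against its filters.

    Returns a list of violations (empty = green).  Deliberately re-derives
    every predicate from the raw collection rather than trusting the
    provenance records.
    """
    by_id = {r.accession_id: r for r in collection}
    issues: list[str] = []
    if len(set(figs_set.members)) != len(figs_set.members):
        issues.append("duplicate members")
    if len(figs_set.members) > cfg.set_size:
        issues.append(f"set size {len(figs_set.members)} exceeds {cfg.set_size}")
    sites = [by_id[m].site_id for m in figs_set.members if m in by_id]
    if len(set(sites)) != len(sites):
        issues.append("more than one member from a single site")
    for m in figs_set.members:
        rec = by_id.get(m)
        if rec is None:
            issues.append(f"{m}: not in source collection")
            continue
        c = rec.climate
        if figs_set.label == "dry":
            if not cfg.dry_rain_min <= c.precyr <= cfg.dry_rain_max:
                issues.append(f"{m}: precyr {c.precyr} outside dry band")
            if not c.bio15 > cfg.bio15_min_exclusive:
                issues.append(f"{m}: bio15 {c.bio15} at or below cut")
        else:
            if not c.precyr > cfg.wet_rain_min:
                issues.append(f"{m}: precyr {c.precyr} not over wet threshold")
    if figs_set.label == "dry":
        for s in figs_set.cluster_summary:
            if s["kept"] and not (cfg.aridity_lo < s["mean_ariyr"] < cfg.aridity_hi):
                # equality at a bound is permitted by the strict-drop rule
                if not (cfg.aridity_lo <= s["mean_ariyr"] <= cfg.aridity_hi):
                    issues.append(
                        f"cluster {s['cluster']}: kept with mean ariyr {s['mean_ariyr']:.3f}"
                    )
    return issues
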