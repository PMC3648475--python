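import itertools

import numpy as np
import pytest

from figsel.errors import ConfigError, EmptySelectionError
from figsel.figs_selection import (
    FIGSSet,
    SelectionConfig,
    audit_set,
    cluster_sites,
    filter_bio15,
    filter_rain_band,
    one_per_site,
    prune_clusters_by_aridity,
    round_robin_select,
    select_dry_set,
    select_wet_set,
)
from figsel.passport_climate import Collection
from figsel.synthetic_data import GeneratorConfig, gen_collection

from conftest import make_passport


def collection_of(*passports):
    return Collection(list(passports))


# ------------------------------------------------------------ rain band


@pytest.mark.parametrize(
    "precyr,kept",
    [(250.0, False), (420.0, True), (300.0, True), (550.0, True), (550.1, False)],
)
def test_rain_band_closed_interval(precyr, kept):
    coll = collection_of(make_passport("A1", precyr=precyr))
    assert (len(filter_rain_band(coll, 300.0, 550.0)) == 1) is kept


# ---------------------------------------------------------- one per site


def test_one_per_site_keeps_one_per_site_deterministically():
    coll = collection_of(
        make_passport("a", site_id="S1"),
        make_passport("b", site_id="S1"),
        make_passport("c", site_id="S2"),
    )
    picks = one_per_site(coll, seed=3).ids()
    assert picks in (["a", "c"], ["b", "c"])
    assert one_per_site(coll, seed=3).ids() == picks


def test_one_per_site_identity_on_singleton_sites():
    coll = collection_of(
        make_passport("a", site_id="S1"), make_passport("b", site_id="S2")
    )
    assert one_per_site(coll, seed=0).ids() == ["a", "b"]


def test_one_per_site_choice_is_uniform():
    coll = collection_of(make_passport("a", site_id="S1"), make_passport("b", site_id="S1"))
    hits = sum(one_per_site(coll, seed=s).ids() == ["a"] for s in range(10_000))
    assert abs(hits / 10_000 - 0.5) < 0.02


# ------------------------------------------------------------ clustering


def _one_d_collection(values):
    return collection_of(
        *[
            make_passport(f"A{i}", site_id=f"S{i}", precyr=400.0, bio16=100.0, ariyr=v)
            for i, v in enumerate(values)
        ]
    )


def test_average_linkage_on_squared_distances_toy():
    # 1-D points {0, 1, 10} carried in a single varying variable:
    # d2(0,1)=1, d2(0,10)=100, d2(1,10)=81; first merge {0,1} at height 1,
    # then average linkage joins {0,1} to {10} at (100+81)/2 = 90.5.
    coll = _one_d_collection([0.0, 1.0, 10.0])
    assignment, Z = cluster_sites(coll, k=2, standardize=False)
    assert Z[0, 2] == pytest.approx(1.0)
    assert Z[1, 2] == pytest.approx(90.5)
    groups = {}
    for acc, cl in assignment.items():
        groups.setdefault(cl, set()).add(acc)
    assert sorted(map(sorted, groups.values())) == [["A0", "A1"], ["A2"]]


def test_every_accession_its_own_cluster_at_k_equals_n():
    coll = _one_d_collection([0.0, 1.0, 5.0, 9.0])
    assignment, _ = cluster_sites(coll, k=4, standardize=False)
    assert len(set(assignment.values())) == 4


def test_too_few_accessions_for_k_raises():
    with pytest.raises(ConfigError):
        cluster_sites(_one_d_collection([0.0, 1.0]), k=3)


def _brute_force_average_linkage(D):
    """O(n^3) agglomeration: merge the pair of clusters with the smallest
    mean inter-cluster dissimilarity; return merge heights and a function
    giving the partition at any k."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights, partitions = [], {n: [list(c) for c in clusters]}
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        partitions[len(clusters)] = [list(c) for c in clusters]
    return heights, partitions


def _co_membership(partition, n):
    m = np.zeros((n, n), dtype=bool)
    for group in partition:
        for a in group:
            for b in group:
                m[a, b] = True
    return m


@pytest.mark.parametrize("n,seed", [(8, 0), (14, 1), (20, 2)])
def test_clustering_matches_brute_force_oracle(n, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=n)
    coll = _one_d_collection(values)
    assignment, Z = cluster_sites(coll, k=3, standardize=False)
    D = (values[:, None] - values[None, :]) ** 2
    heights, partitions = _brute_force_average_linkage(D)
    assert np.allclose(np.sort(Z[:, 2]), np.sort(heights))
    got = {}
    for acc, cl in assignment.items():
        got.setdefault(cl, []).append(int(acc[1:]))
    assert np.array_equal(
        _co_membership(got.values(), n), _co_membership(partitions[3], n)
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_merge_heights_nondecreasing(seed):
    rng = np.random.default_rng(seed)
    coll = _one_d_collection(rng.normal(size=15))
    _, Z = cluster_sites(coll, k=2, standardize=False)
    assert np.all(np.diff(Z[:, 2]) >= -1e-12)


# -------------------------------------------------------- aridity pruning


def _assigned(means):
    """One singleton cluster per mean value."""
    coll = collection_of(
        *[make_passport(f"A{i}", site_id=f"S{i}", ariyr=m) for i, m in enumerate(means)]
    )
    assignment = {f"A{i}": i + 1 for i in range(len(means))}
    return assignment, coll


def test_prune_keeps_only_mid_aridity_clusters():
    assignment, coll = _assigned([0.05, 0.3, 0.7])
    surviving, summary = prune_clusters_by_aridity(assignment, coll, 0.1, 0.6)
    assert surviving == {2}
    assert [s["kept"] for s in summary] == [False, True, False]


def test_prune_boundary_mean_retained():
    assignment, coll = _assigned([0.6, 0.1, 0.7])
    surviving, _ = prune_clusters_by_aridity(assignment, coll, 0.1, 0.6)
    assert surviving == {1, 2}


def test_prune_six_of_twenty():
    means = [0.05] * 3 + [0.8] * 3 + [0.3] * 14
    assignment, coll = _assigned(means)
    surviving, _ = prune_clusters_by_aridity(assignment, coll, 0.1, 0.6)
    assert len(surviving) == 14


def test_prune_all_dropped_is_an_error():
    assignment, coll = _assigned([0.05, 0.9])
    with pytest.raises(EmptySelectionError):
        prune_clusters_by_aridity(assignment, coll, 0.1, 0.6)


# --------------------------------------------------------------- bio15


def test_bio15_cut_is_exclusive():
    coll = collection_of(
        *[make_passport(f"A{i}", bio15=b) for i, b in enumerate([10.0, 50.0, 51.0, 80.0])]
    )
    kept = filter_bio15(coll, 50.0)
    assert [r.climate.bio15 for r in kept] == [51.0, 80.0]


# ----------------------------------------------------------- round robin


def test_round_robin_cycles_clusters_by_ascending_precipitation():
    def p(name, cluster, precyr):
        return cluster, make_passport(name, site_id=name, precyr=precyr)

    groups = {}
    for cl, rec in [
        p("a1", 1, 310.0), p("a2", 1, 320.0),
        p("b1", 2, 305.0),
        p("c1", 3, 330.0), p("c2", 3, 340.0), p("c3", 3, 350.0),
    ]:
        groups.setdefault(cl, []).append(rec)
    result = round_robin_select(groups, set_size=5)
    assert result.members == ["a1", "b1", "c1", "a2", "c2"]
    assert result.provenance["c2"]["round"] == 2
    assert result.provenance["c2"]["precyr_rank"] == 2


def test_round_robin_exhaustion_returns_everything_once():
    groups = {
        1: [make_passport("a1", precyr=310.0), make_passport("a2", precyr=320.0)],
        2: [make_passport("b1", precyr=305.0)],
    }
    result = round_robin_select(groups, set_size=10)
    assert sorted(result.members) == ["a1", "a2", "b1"]
    assert len(set(result.members)) == 3


# --------------------------------------------------------- full pipelines


@pytest.fixture(scope="module")
def genebank():
    return gen_collection(GeneratorConfig(n_sites=2000, seed=11))


def test_dry_set_end_to_end(genebank):
    cfg = SelectionConfig(seed=11)
    dry = select_dry_set(genebank, cfg)
    assert len(dry.members) == 201
    assert audit_set(dry, genebank, cfg) == []
    # conservation at every stage: input = kept + dropped
    for stage in dry.dropped.values():
        assert stage["input"] == stage["kept"] + stage["dropped"]


def test_dry_set_deterministic_for_fixed_seed(genebank):
    cfg = SelectionConfig(seed=4)
    assert select_dry_set(genebank, cfg).members == select_dry_set(genebank, cfg).members


def test_dry_set_empty_rain_band_errors():
    coll = collection_of(make_passport("A1", precyr=900.0))
    with pytest.raises(EmptySelectionError):
        select_dry_set(coll, SelectionConfig(seed=0))


def test_wet_set_takes_highest_aridity_over_threshold(genebank):
    cfg = SelectionConfig(seed=11)
    wet = select_wet_set(genebank, cfg)
    assert len(wet.members) == 201
    assert audit_set(wet, genebank, cfg) == []
    by_id = {r.accession_id: r for r in genebank}
    chosen = sorted(
        (by_id[m].climate.ariyr, m) for m in wet.members
    )
    # sort oracle: no eligible non-member out-ranks the weakest member
    eligible = one_per_site(
        genebank.subset(
            [r.accession_id for r in genebank if r.climate.precyr > cfg.wet_rain_min]
        ),
        seed=cfg.seed,
    )
    outside = [r for r in eligible if r.accession_id not in set(wet.members)]
    weakest_ariyr = chosen[0][0]
    assert all(
        (r.climate.ariyr, r.accession_id) <= (weakest_ariyr, chosen[0][1])
        or r.climate.ariyr < weakest_ariyr
        for r in outside
    )


def test_wet_threshold_is_strict():
    coll = collection_of(
        make_passport("A1", precyr=800.0, ariyr=0.9),
        make_passport("A2", site_id="S2", precyr=800.5, ariyr=0.8),
    )
    wet = select_wet_set(coll, SelectionConfig(seed=0, set_size=5))
    assert wet.members == ["A2"]
    assert wet.warnings  # short set reported


def test_dry_and_wet_sets_disjoint(genebank):
    cfg = SelectionConfig(seed=11)
    dry = set(select_dry_set(genebank, cfg).members)
    wet = set(select_wet_set(genebank, cfg).members)
    assert not dry & wet


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SelectionConfig(dry_rain_min=600.0, dry_rain_max=500.0)
    with pytest.raises(ConfigError):
        SelectionConfig(n_clusters=1)
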