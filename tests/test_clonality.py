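import numpy as np
import pandas as pd
import pytest

from cnith.clonality import (
    INTER,
    INTRA,
    CloneThresholdModel,
    PairDistancePool,
    assign_clones,
    assign_clones_pairwise,
    classify_relapse_pattern,
    classify_topology,
    fit_clone_threshold,
    patient_evolution_report,
    pool_pair_distances,
)
from cnith.distance import Dendrogram, DistanceMatrix, cluster_complete_linkage
from cnith.errors import NoSignalError, ValidationError
from cnith.io import SampleRecord


def _meta(pairs):
    """pairs: (sample, patient[, timepoint])"""
    return [SampleRecord(s, p, t[0] if t else "primary")
            for s, p, *t in pairs]


def _dmat(ids, values):
    return DistanceMatrix(tuple(ids), np.asarray(values, dtype=float))


def _pool_from_draws(intra, inter):
    rows = [{"sample_a": f"i{k}", "sample_b": f"j{k}", "distance": d, "label": INTRA}
            for k, d in enumerate(intra)]
    rows += [{"sample_a": f"x{k}", "sample_b": f"y{k}", "distance": d, "label": INTER}
             for k, d in enumerate(inter)]
    return PairDistancePool(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def test_pool_combinatorics_two_patients():
    meta = _meta([("a", "P1"), ("b", "P1"), ("c", "P2"), ("d", "P2")])
    v = np.full((4, 4), 100.0)
    np.fill_diagonal(v, 0)
    pool = pool_pair_distances(_dmat("abcd", v), meta)
    assert pool.n_intra == 2 and pool.n_inter == 4
    assert len(pool.records) == 6  # C(4,2)


def test_pool_excludes_relapse_and_unknown_samples():
    meta = _meta([("a", "P1"), ("b", "P1", "relapse"), ("c", "P2")])
    v = np.full((4, 4), 10.0)
    np.fill_diagonal(v, 0)
    d = _dmat(["a", "b", "c", "germline"], v)
    pool = pool_pair_distances(d, meta)
    assert set(pool.records[["sample_a", "sample_b"]].to_numpy().ravel()) == {"a", "c"}
    pool_all = pool_pair_distances(d, meta, include_relapse=True)
    assert pool_all.n_intra == 1 and pool_all.n_inter == 2


def test_pool_single_patient_errors():
    meta = _meta([("a", "P1"), ("b", "P1")])
    with pytest.raises(ValidationError, match="single-patient"):
        pool_pair_distances(_dmat("ab", [[0, 5], [5, 0]]), meta)


# ---------------------------------------------------------------------------
# threshold fit
# ---------------------------------------------------------------------------


def test_threshold_lands_in_separation_gap():
    rng = np.random.default_rng(42)
    pool = _pool_from_draws(rng.uniform(0, 100, 200), rng.uniform(200, 300, 200))
    res = CloneThresholdModel(pool).fit()
    assert 100 < res.threshold < 200
    assert res.slope > 0
    # closed form of the 0.5 crossing
    assert res.threshold == pytest.approx(-res.intercept / res.slope)
    # probability is 0.5 at the threshold, monotone increasing in distance
    p = res.predict_inter_probability([res.threshold - 50, res.threshold,
                                       res.threshold + 50])
    assert p[0] < 0.5 == pytest.approx(p[1], abs=1e-6) and p[2] > 0.5


def test_threshold_no_signal_on_identical_pools():
    rng = np.random.default_rng(0)
    draws = rng.uniform(0, 100, 200)
    with pytest.raises(NoSignalError, match="discriminate"):
        fit_clone_threshold(_pool_from_draws(draws, draws.copy()))


def test_threshold_errors_on_reversed_signal():
    rng = np.random.default_rng(1)
    # inter-patient pairs CLOSER than intra: slope <= 0
    pool = _pool_from_draws(rng.uniform(200, 300, 100), rng.uniform(0, 100, 100))
    with pytest.raises(NoSignalError):
        fit_clone_threshold(pool)


def test_threshold_model_summary_and_diagnostics():
    rng = np.random.default_rng(2)
    pool = _pool_from_draws(rng.uniform(0, 100, 50), rng.uniform(150, 300, 80))
    res = CloneThresholdModel(pool).fit()
    text = res.summary()
    assert "threshold" in text and f"{res.threshold:.1f}" in text
    assert res.fit_diagnostics["n_intra"] == 50


def test_threshold_agrees_with_statsmodels_on_overlapping_pools():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(3)
    intra, inter = rng.normal(80, 30, 300), rng.normal(160, 30, 300)
    pool = _pool_from_draws(np.clip(intra, 0, None), np.clip(inter, 0, None))
    res = CloneThresholdModel(pool, ridge=1e-8, signal_alpha=None).fit()
    x = pool.records["distance"].to_numpy()
    y = (pool.records["label"] == INTER).astype(float).to_numpy()
    ref = sm.Logit(y, np.column_stack([np.ones_like(x), x])).fit(disp=0)
    assert res.intercept == pytest.approx(ref.params[0], rel=1e-3)
    assert res.slope == pytest.approx(ref.params[1], rel=1e-3)


# ---------------------------------------------------------------------------
# clone assignment
# ---------------------------------------------------------------------------


def _pairs_dend():
    v = np.array([[0, 10, 1000, 1000],
                  [10, 0, 1000, 1000],
                  [1000, 1000, 0, 10],
                  [1000, 1000, 10, 0]], dtype=float)
    return cluster_complete_linkage(DistanceMatrix(tuple("abcd"), v))


def test_assign_clones_cuts_between_merge_heights():
    # two tight pairs joined at 1000; any cut between 10 and 1000 (here a
    # cohort-scale threshold of 572.3 CN events) yields two clones
    clones = assign_clones(_pairs_dend(), 572.3)
    assert clones == {"a": 1, "b": 1, "c": 2, "d": 2}


def test_assign_clones_extremes():
    dend = _pairs_dend()
    assert len(set(assign_clones(dend, 2000).values())) == 1
    assert len(set(assign_clones(dend, 5).values())) == 4
    assert len(set(assign_clones(dend, 0).values())) == 4  # warning path


def test_clone_count_monotone_in_threshold():
    rng = np.random.default_rng(9)
    v = rng.integers(1, 500, (8, 8)).astype(float)
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    dend = cluster_complete_linkage(DistanceMatrix(tuple("abcdefgh"), v))
    counts = [len(set(assign_clones(dend, t).values())) for t in range(0, 600, 10)]
    assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))


def test_pairwise_assignment_agrees_on_clean_separation():
    d = DistanceMatrix(tuple("abcd"),
                       np.array([[0, 10, 900, 900], [10, 0, 900, 900],
                                 [900, 900, 0, 10], [900, 900, 10, 0]], float))
    dend = cluster_complete_linkage(d)
    a1 = assign_clones(dend, 500)
    a2 = assign_clones_pairwise(d, 500)
    groups = lambda a: set(frozenset(s for s in a if a[s] == c) for c in set(a.values()))
    assert groups(a1) == groups(a2)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


def _dend_from_merges(leaves, merges):
    return Dendrogram(tuple(leaves), np.array(merges, dtype=float))


def test_topology_balanced_is_dichotomous():
    # ((a,b),(c,d))
    dend = _dend_from_merges("abcd", [[0, 1, 10, 2], [2, 3, 12, 2], [4, 5, 50, 4]])
    assert classify_topology(dend) == "dichotomous"


def test_topology_caterpillar_is_sympodial():
    # (((a,b),c),d)
    dend = _dend_from_merges("abcd", [[0, 1, 10, 2], [4, 2, 20, 3], [5, 3, 30, 4]])
    assert classify_topology(dend) == "sympodial"


def test_topology_small_or_degenerate_is_indeterminate():
    three = _dend_from_merges("abc", [[0, 1, 5, 2], [3, 2, 9, 3]])
    assert classify_topology(three) == "indeterminate"
    tied = _dend_from_merges("abcd", [[0, 1, 10, 2], [2, 3, 10, 2], [4, 5, 10, 4]])
    assert classify_topology(tied) == "indeterminate"


# ---------------------------------------------------------------------------
# relapse patterns
# ---------------------------------------------------------------------------


def _assignment_case(primary_clones, relapse_clones):
    assignment, meta = {}, []
    for i, c in enumerate(primary_clones):
        assignment[f"p{i}"] = c
        meta.append(SampleRecord(f"p{i}", "P", "primary"))
    for i, c in enumerate(relapse_clones):
        assignment[f"r{i}"] = c
        meta.append(SampleRecord(f"r{i}", "P", "relapse"))
    return assignment, meta


@pytest.mark.parametrize("primary,relapse,expected", [
    ([1, 1, 1], [1, 1], "type1"),
    ([1, 2, 2], [2], "type2"),
    ([1, 1], [2], "type3"),
    ([1, 2], [1, 3], "type3"),  # polyclonal primary + novel relapse clone
])
def test_relapse_pattern_definitions(primary, relapse, expected):
    assignment, meta = _assignment_case(primary, relapse)
    assert classify_relapse_pattern(assignment, meta) == expected


def test_relapse_pattern_invariant_to_relabelling():
    assignment, meta = _assignment_case([1, 2, 2], [2])
    relabelled = {s: {1: 7, 2: 3}[c] for s, c in assignment.items()}
    assert classify_relapse_pattern(relabelled, meta) == "type2"


def test_relapse_pattern_requires_both_timepoints():
    assignment, meta = _assignment_case([1, 1], [])
    with pytest.raises(ValidationError, match="undefined"):
        classify_relapse_pattern(assignment, meta)


# ---------------------------------------------------------------------------
# patient report
# ---------------------------------------------------------------------------


def test_patient_evolution_report_smoke():
    meta = _meta([("a", "P"), ("b", "P"), ("c", "P"), ("d", "P", "relapse")])
    v = np.array([[0, 10, 600, 700], [10, 0, 600, 700],
                  [600, 600, 0, 650], [700, 700, 650, 0]], dtype=float)
    rep = patient_evolution_report("P", _dmat("abcd", v), meta, 572.3)
    assert rep.n_clones == 3 and rep.relapse_pattern == "type3"
    assert "clone1" in rep.newick and rep.to_dict()["patient"] == "P"
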