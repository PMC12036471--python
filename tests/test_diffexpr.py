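import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurescence import diffexpr
from neurescence.diffexpr import DEConfig
from neurescence.labeling import NON_SENESCENT, SENESCENT


def _labels(y):
    return np.where(np.asarray(y, dtype=bool), SENESCENT, NON_SENESCENT).astype(object)


# ---------------------------------------------------------------------------
# filtering and normalization


def test_filter_boundary(toy_counts_factory):
    n = 250
    X = np.zeros((n, 3), dtype=int)
    X[:199, 0] = 1  # 199 detected cells: removed at min_cells=200
    X[:200, 1] = 1  # exactly 200: kept
    X[:, 2] = 2
    cm = toy_counts_factory(X)
    kept = diffexpr.filter_genes(cm, min_count=1, min_cells=200)
    assert kept.genes.tolist() == ["g1", "g2"]
    assert diffexpr.filter_genes(cm, min_cells=0).genes.tolist() == ["g0", "g1", "g2"]


def test_filter_all_removed_errors(toy_counts_factory):
    cm = toy_counts_factory(np.zeros((5, 2), dtype=int))
    with pytest.raises(ValueError):
        diffexpr.filter_genes(cm, min_cells=1)


def test_normalize_arithmetic(toy_counts_factory):
    cm = toy_counts_factory([[1, 1, 2]])
    expr = diffexpr.normalize(cm)
    vals = np.asarray(expr.X.todense()).ravel()
    assert np.allclose(vals, [np.log2(250001), np.log2(250001), np.log2(500001)])
    assert vals[0] == pytest.approx(17.9316, abs=1e-4)


def test_normalize_cpm_invariance_and_zero_library(toy_counts_factory):
    cm1 = toy_counts_factory([[1, 3], [2, 2]])
    cm2 = toy_counts_factory([[2, 6], [2, 2]])  # first cell doubled
    a = np.asarray(diffexpr.normalize(cm1).X.todense())
    b = np.asarray(diffexpr.normalize(cm2).X.todense())
    assert np.allclose(a, b)
    cm0 = toy_counts_factory([[0, 0], [1, 1]])
    with pytest.raises(ValueError, match="zero library"):
        diffexpr.normalize(cm0)


def test_all_zero_gene_normalizes_to_zero(toy_counts_factory):
    cm = toy_counts_factory([[1, 0], [2, 0]])
    expr = diffexpr.normalize(cm)
    assert np.asarray(expr.X.todense())[:, 1].max() == 0.0


# ---------------------------------------------------------------------------
# upsampling


@pytest.mark.parametrize(
    "n_minor,n_major,factor",
    [(475, 16871, 36), (10, 10, 1), (3, 10, 3), (2, 5, 3)],
)
def test_upsample_factor(n_minor, n_major, factor):
    lab = np.array(["a"] * n_minor + ["b"] * n_major, dtype=object)
    f, idx = diffexpr.upsample_minority(lab)
    assert f == factor
    assert idx.size == n_major + factor * n_minor  # conservation
    # majority untouched, minority repeated factor times
    counts = np.bincount(idx, minlength=lab.size)
    assert set(counts[:n_minor]) == {factor}
    assert set(counts[n_minor:]) == {1}


def test_upsample_requires_two_classes():
    with pytest.raises(ValueError):
        diffexpr.upsample_minority(np.array(["a", "a"], dtype=object))


# ---------------------------------------------------------------------------
# hurdle test


def test_hurdle_identical_groups_is_null():
    v = np.array([0, 0, 1.5, 2.0, 0, 0, 1.5, 2.0])
    g = np.array([True] * 4 + [False] * 4)
    stat, p, lfc, df = diffexpr.hurdle_test(v, g)
    assert stat == 0.0 and p == 1.0 and lfc == 0.0


def test_hurdle_strong_separation():
    rng = np.random.default_rng(4)
    v = np.concatenate([np.zeros(200), rng.normal(8, 1, 200)])
    g = np.array([False] * 200 + [True] * 200)
    stat, p, lfc, df = diffexpr.hurdle_test(v, g)
    assert p < 1e-6
    assert lfc == pytest.approx(v[200:].mean(), abs=0.01)


def test_hurdle_constant_gene_degenerate():
    v = np.zeros(20)
    g = np.array([True] * 10 + [False] * 10)
    stat, p, lfc, df = diffexpr.hurdle_test(v, g)
    assert (stat, p, df) == (0.0, 1.0, 0)


def test_hurdle_weights_equal_literal_replication():
    rng = np.random.default_rng(6)
    v = np.concatenate([rng.exponential(1, 8), np.zeros(4), rng.exponential(2, 30)])
    g = np.array([True] * 12 + [False] * 30)
    w = np.where(g, 3.0, 1.0)
    expanded_v = np.concatenate([np.repeat(v[g], 3), v[~g]])
    expanded_g = np.array([True] * (12 * 3) + [False] * 30)
    a = diffexpr.hurdle_test(v, g, weights=w)
    b = diffexpr.hurdle_test(expanded_v, expanded_g)
    assert np.allclose(a[:3], b[:3], rtol=1e-10)


def test_hurdle_type1_calibration_small():
    """Null false-positive rate near nominal (reduced-scale check; the
    full-scale calibration lives in the acceptance suite)."""
    from neurescence._random import substream

    rng = substream(5, "null")
    n, g = 300, 400
    X = rng.poisson(rng.gamma(10, 0.15, size=(n, g)) * 10)
    import scipy.sparse as sp

    from neurescence.io import CountMatrix

    cm = CountMatrix(
        [f"c{i}" for i in range(n)], [f"g{j}" for j in range(g)], sp.csr_matrix(X)
    )
    expr = diffexpr.normalize(cm)
    group = np.zeros(n, dtype=bool)
    group[:150] = True
    _, p, _, df = diffexpr._hurdle_all(expr, group)
    assert 0.02 <= (p[df > 0] < 0.05).mean() <= 0.09


# ---------------------------------------------------------------------------
# EMD


def test_emd_trivial_cases():
    assert diffexpr.emd_1d([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert diffexpr.emd_1d([0.0], [1.0]) == 1.0
    with pytest.raises(ValueError):
        diffexpr.emd_1d([], [1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    b=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    c=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    delta=st.floats(-5, 5),
)
def test_emd_metric_properties(a, b, c, delta):
    ab = diffexpr.emd_1d(a, b)
    assert ab >= 0
    assert ab == pytest.approx(diffexpr.emd_1d(b, a), abs=1e-12)
    assert ab <= diffexpr.emd_1d(a, c) + diffexpr.emd_1d(c, b) + 1e-9
    shifted = diffexpr.emd_1d(np.asarray(a) + delta, b)
    assert abs(shifted - ab) <= abs(delta) + 1e-9
    # identical shapes translate exactly
    assert diffexpr.emd_1d(np.asarray(a) + delta, a) == pytest.approx(abs(delta), abs=1e-9)


def test_emd_test_identical_groups():
    v = np.tile([0.0, 1.0, 2.0], 20)
    g = np.arange(60) % 2 == 0
    score, p = diffexpr.emd_test(v, g, n_permutations=200, seed=1)
    assert score == 0.0 and p == 1.0


def test_emd_test_planted_shift_hits_floor():
    rng = np.random.default_rng(2)
    v = np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1, 200)])
    g = np.array([False] * 200 + [True] * 200)
    score, p = diffexpr.emd_test(v, g, n_permutations=200, seed=1)
    assert score > 5
    assert p == pytest.approx(1 / 201)


def test_emd_null_pvalues_uniform_on_grid():
    """Permutation p-values under the null are uniform over the achievable
    grid (vectorized path, shared permutations)."""
    from neurescence._random import substream
    from scipy.stats import kstest

    rng = substream(9, "emd_null_data")
    n, g = 80, 1000
    X = rng.poisson(3.0, size=(n, g))
    import scipy.sparse as sp

    from neurescence.io import CountMatrix, ExpressionMatrix

    expr = diffexpr.normalize(
        CountMatrix([f"c{i}" for i in range(n)], [f"g{j}" for j in range(g)], sp.csr_matrix(X))
    )
    group = np.zeros(n, dtype=bool)
    group[:40] = True
    scores, pvals = diffexpr._emd_all(expr, group, 199, substream(9, "perms"))
    # compare against the uniform distribution on the p-value grid
    assert kstest(pvals, "uniform").statistic < 0.08


def test_emd_all_matches_single_gene_observed(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    group = ds.true_senescent
    from neurescence._random import substream

    scores, _ = diffexpr._emd_all(expr, group, 100, substream(0, "x"))
    for j in [0, 50, 399]:
        v = np.asarray(expr.X[:, j].todense()).ravel()
        assert scores[j] == pytest.approx(diffexpr.emd_1d(v[group], v[~group]), abs=1e-10)


# ---------------------------------------------------------------------------
# run_de


def test_run_de_impossible_thresholds_calls_nothing(small_dataset):
    ds = small_dataset
    cfg = DEConfig(min_cells=40, hurdle_abs_lfc_min=1e9, emd_score_min=1e9, n_permutations=100)
    res = diffexpr.run_de(ds.counts, _labels(ds.true_senescent), cfg)
    assert res.summary["n_called_both"] == 0
    assert res.summary["overlap_p"] == 1.0


def test_run_de_recovers_planted_genes(small_dataset):
    ds = small_dataset
    cfg = DEConfig(min_cells=40, n_permutations=300, seed=2)
    res = diffexpr.run_de(ds.counts, _labels(ds.true_senescent), cfg)
    called = set(res.called_both)
    de = set(ds.truth["de_genes"])
    assert called, "no genes called"
    precision = len(called & de) / len(called)
    recall = len(called & de) / len(de)
    assert precision >= 0.9 and recall >= 0.8
    t = res.table
    assert (t["hurdle_adj_p"] >= t["hurdle_p"] - 1e-15).all()
    assert (t["emd_adj_p"] >= t["emd_p"] - 1e-15).all()
    assert (t["called_both"] == (t["called_hurdle"] & t["called_emd"])).all()


def test_run_de_requires_both_classes(small_dataset):
    ds = small_dataset
    with pytest.raises(ValueError):
        diffexpr.run_de(ds.counts, _labels(np.zeros(ds.counts.shape[0])), DEConfig(min_cells=40))


def test_config_validation():
    with pytest.raises(ValueError):
        DEConfig(n_permutations=50)
    assert DEConfig.published_profile().emd_score_min == 30.0
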