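import numpy as np
import pytest

from neurescence import trees
from neurescence.labeling import NON_SENESCENT, SENESCENT
from neurescence.trees import TreeConfig


def _labels(y):
    return np.where(np.asarray(y, dtype=bool), SENESCENT, NON_SENESCENT).astype(object)


def brute_force_best_error(X, y, mc):
    """Naive enumeration of every tree in the <=2-gene family honoring the
    leaf-size constraint; returns the minimal training error."""
    n, G = X.shape
    P = int(y.sum())
    Nn = n - P

    def werr(p, q):
        return min(p, q)

    best = werr(P, Nn)  # majority stump
    splits = []
    for j in range(G):
        for t in np.unique(X[:, j])[:-1]:
            splits.append(X[:, j] <= t)
    for m in splits:
        nl = int(m.sum())
        pl = int(y[m].sum())
        nr, pr = n - nl, P - pl
        if nl >= mc and nr >= mc:
            best = min(best, werr(pl, nl - pl) + werr(pr, nr - pr))
        for m2 in splits:
            for child, cp, cn, lp, ln in (
                (m, pl, nl, pr, nr - pr),
                (~m, pr, nr, pl, nl - pl),
            ):
                a = child & m2
                na, pa = int(a.sum()), int(y[a].sum())
                nb, pb = cn - na, cp - pa
                if na >= mc and nb >= mc and (lp + ln) >= mc:
                    best = min(best, werr(pa, na - pa) + werr(pb, nb - pb) + werr(lp, ln))
    return best


def test_binarize_maps_positives_to_one(toy_counts_factory):
    cm = toy_counts_factory([[0, 1, 5], [2, 0, 0]])
    b = trees.binarize(cm)
    assert b.to_dense().tolist() == [[0, 1, 1], [1, 0, 0]]
    bb = trees.binarize(b)
    assert (bb.X != b.X).nnz == 0  # idempotent
    assert b.X.nnz == cm.X.nnz  # sparsity pattern preserved


def test_perfect_separator_single_split(toy_counts_factory):
    y = np.array([1] * 6 + [0] * 10, dtype=bool)
    X = np.zeros((16, 3), dtype=int)
    X[y, 1] = 1
    cm = toy_counts_factory(X)
    tree = trees.fit_marker_tree(cm, _labels(y), TreeConfig(min_cases=1, binarize=True))
    assert tree.genes == ["g1"]
    assert tree.threshold == 0
    assert tree.training_metrics.accuracy == 1.0


def test_tie_break_prefers_lexicographic_gene(toy_counts_factory):
    y = np.array([1] * 6 + [0] * 10, dtype=bool)
    col = np.where(y, 1, 0)
    X = np.column_stack([col, col])
    cm = toy_counts_factory(X, genes=["zeta", "alpha"])
    tree = trees.fit_marker_tree(cm, _labels(y), TreeConfig(min_cases=1))
    assert tree.genes == ["alpha"]


def test_binarized_thresholds_are_zero(small_dataset):
    ds = small_dataset
    y = ds.true_senescent
    pool = ds.truth["marker_genes"] + ds.panels[0].genes[:10]
    tree = trees.fit_marker_tree(
        ds.counts, _labels(y), TreeConfig(binarize=True, gene_pool=pool)
    )
    assert tree.threshold == 0
    if tree.second_gene is not None:
        assert tree.second_threshold == 0


def test_single_class_and_empty_pool_errors(toy_counts_factory):
    cm = toy_counts_factory(np.ones((6, 2), dtype=int))
    with pytest.raises(ValueError, match="both classes"):
        trees.fit_marker_tree(cm, _labels(np.ones(6)), TreeConfig())
    y = np.array([1, 1, 0, 0, 0, 0], dtype=bool)
    with pytest.raises(ValueError, match="pool"):
        trees.fit_marker_tree(cm, _labels(y), TreeConfig(gene_pool=["absent"]))


def test_fit_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(77)
    import scipy.sparse as sp

    from neurescence.io import CountMatrix

    for rep in range(8):
        n = int(rng.integers(40, 201))
        G = int(rng.integers(3, 16))
        X = rng.negative_binomial(2, 0.5, size=(n, G))
        y = rng.random(n) < 0.3
        if rep % 2:
            X[y, 0] += rng.poisson(1.5, int(y.sum()))
        if y.sum() in (0, n):
            continue
        cm = CountMatrix(
            [f"c{i}" for i in range(n)], [f"g{j}" for j in range(G)], sp.csr_matrix(X)
        )
        mc = int(rng.integers(1, 6))
        tree = trees.fit_marker_tree(cm, _labels(y), TreeConfig(min_cases=mc))
        err = tree.training_metrics.fp + tree.training_metrics.fn
        assert err == brute_force_best_error(X, y, mc)


def test_predict_self_consistency_and_missing_gene(toy_counts_factory):
    y = np.array([1] * 5 + [0] * 12, dtype=bool)
    X = np.column_stack([np.where(y, 2, 0), np.zeros(17, dtype=int)])
    cm = toy_counts_factory(X)
    tree = trees.fit_marker_tree(cm, _labels(y), TreeConfig(min_cases=1))
    pred = trees.predict(tree, cm)
    m = trees.evaluate(pred, _labels(y))
    assert m.to_dict() == tree.training_metrics.to_dict()
    cm2 = toy_counts_factory(np.zeros((3, 1), dtype=int), genes=["other"])
    with pytest.raises(KeyError, match=tree.gene):
        trees.predict(tree, cm2)


def test_all_zero_cell_gets_negative_class_under_and_tree():
    tree = trees.MarkerTree(
        gene="g0",
        threshold=0,
        left=NON_SENESCENT,
        right=None,
        second_side="right",
        second_gene="g1",
        second_threshold=0,
        second_left=NON_SENESCENT,
        second_right=SENESCENT,
        binarized=True,
    )
    import scipy.sparse as sp

    from neurescence.io import CountMatrix

    cm = CountMatrix(["c0"], ["g0", "g1"], sp.csr_matrix(np.zeros((1, 2), dtype=int)))
    assert trees.predict(tree, cm)[0] == NON_SENESCENT


@pytest.mark.parametrize(
    "tp,tn,fp,fn,sens,spec,acc",
    [
        (3, 5, 0, 2, 0.6, 1.0, 0.8),
        (10, 90, 0, 0, 1.0, 1.0, 1.0),
        (0, 9, 0, 1, 0.0, 1.0, 0.9),
    ],
)
def test_evaluate_rates(tp, tn, fp, fn, sens, spec, acc):
    pred = np.array(
        [SENESCENT] * (tp + fp) + [NON_SENESCENT] * (tn + fn), dtype=object
    )
    truth = np.array(
        [SENESCENT] * tp + [NON_SENESCENT] * fp + [NON_SENESCENT] * tn + [SENESCENT] * fn,
        dtype=object,
    )
    m = trees.evaluate(pred, truth)
    assert (m.sensitivity, m.specificity, m.accuracy) == (sens, spec, acc)
    assert m.tp_rate_of_total == pytest.approx(tp / (tp + tn + fp + fn))


def test_evaluate_undefined_rates_are_nan():
    pred = np.array([NON_SENESCENT, NON_SENESCENT], dtype=object)
    truth = np.array([NON_SENESCENT, NON_SENESCENT], dtype=object)
    m = trees.evaluate(pred, truth)
    assert np.isnan(m.sensitivity) and m.specificity == 1.0


def test_elimination_orders_planted_pairs(toy_counts_factory):
    rng = np.random.default_rng(3)
    n = 400
    y = np.zeros(n, dtype=bool)
    y[:40] = True
    # strong pair: each fires in 85% of positives, never in negatives;
    # weak pair: 60% of positives, 2% of negatives
    def marker(p_on, p_leak):
        return np.where(y, rng.random(n) < p_on, rng.random(n) < p_leak).astype(int)

    X = np.column_stack(
        [marker(0.85, 0.0), marker(0.85, 0.0), marker(0.6, 0.02), marker(0.6, 0.02),
         rng.integers(0, 2, n)]
    )
    cm = toy_counts_factory(X, genes=["s1", "s2", "w1", "w2", "noise"])
    ledger = trees.elimination_analysis(
        cm, _labels(y), TreeConfig(binarize=True, min_cases=2), n_rounds=2
    )
    assert sorted(ledger[0]["tree"].genes) == ["s1", "s2"]
    assert sorted(ledger[1]["tree"].genes) == ["w1", "w2"]
    assert ledger[0]["metrics"].accuracy >= ledger[1]["metrics"].accuracy


def test_elimination_truncates_when_pool_exhausted(toy_counts_factory):
    y = np.array([1] * 8 + [0] * 12, dtype=bool)
    X = np.column_stack([np.where(y, 1, 0), np.where(y, 1, 0)])
    cm = toy_counts_factory(X)
    ledger = trees.elimination_analysis(
        cm, _labels(y), TreeConfig(min_cases=1), n_rounds=5
    )
    assert len(ledger) < 5


def test_exhausted_pool_falls_back_to_majority(toy_counts_factory):
    rng = np.random.default_rng(8)
    y = np.array([1] * 10 + [0] * 30, dtype=bool)
    X = rng.integers(0, 2, size=(40, 2))  # uninformative
    cm = toy_counts_factory(X)
    tree = trees.fit_marker_tree(cm, _labels(y), TreeConfig(min_cases=15, binarize=True))
    assert tree.gene is None
    assert tree.training_metrics.sensitivity == 0.0


def test_tree_round_trip(tmp_path, toy_counts_factory):
    y = np.array([1] * 6 + [0] * 10, dtype=bool)
    X = np.column_stack([np.where(y, 1, 0), np.zeros(16, dtype=int)])
    cm = toy_counts_factory(X)
    tree = trees.fit_marker_tree(cm, _labels(y), TreeConfig(min_cases=1))
    tree.save(tmp_path / "t.json")
    back = trees.MarkerTree.load(tmp_path / "t.json")
    assert np.array_equal(trees.predict(back, cm), trees.predict(tree, cm))
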