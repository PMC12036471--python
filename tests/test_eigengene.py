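import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from neurescence import diffexpr, eigengene, simulate
from neurescence.io import ExpressionMatrix, GenePanel


def _expr(Z, genes=None):
    n, g = np.asarray(Z).shape
    return ExpressionMatrix(
        np.array([f"c{i}" for i in range(n)], dtype=object),
        np.array(genes or [f"g{j}" for j in range(g)], dtype=object),
        sp.csr_matrix(np.asarray(Z, dtype=float)),
    )


@pytest.mark.parametrize(
    "types,expected",
    [
        (["A", "A", "B", "B"], [2, 2, 2, 2]),
        (["A", "A", "A", "B"], [4 / 3, 4 / 3, 4 / 3, 4]),
        (["A", "A"], [1, 1]),
    ],
)
def test_cell_weights_formula(types, expected):
    meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(types))], "cell_type": types})
    w = eigengene.compute_cell_weights(meta)
    assert np.allclose(w, expected)
    # each type contributes total weight N
    for t in set(types):
        assert np.isclose(w[np.asarray(types) == t].sum(), len(types))


def test_cell_weights_empty_meta_error():
    with pytest.raises(ValueError):
        eigengene.compute_cell_weights(pd.DataFrame({"cell_id": [], "cell_type": []}))


def test_single_gene_requires_flag():
    e = _expr(np.linspace(0, 5, 30)[:, None])
    panel = GenePanel("p", ["g0"])
    with pytest.raises(ValueError):
        eigengene.fit_eigengene(e, panel, np.ones(30))
    model, scores = eigengene.fit_eigengene(e, panel, np.ones(30), allow_single_gene=True)
    assert np.allclose(model.loadings, [1.0])
    z = (np.linspace(0, 5, 30) - model.gene_centers[0]) / model.gene_scales[0]
    assert np.allclose(scores.score, z)


def test_perfectly_correlated_pair_is_rank_one():
    x = np.linspace(0, 5, 40)
    e = _expr(np.column_stack([x, 2 * x]))
    model, scores = eigengene.fit_eigengene(e, GenePanel("p", ["g0", "g1"]), np.ones(40))
    assert abs(np.corrcoef(scores.score, x)[0, 1]) == pytest.approx(1.0)
    assert np.isclose(np.linalg.norm(model.loadings), 1.0)


def test_orientation_score_correlates_with_panel_mean(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    for panel in ds.panels:
        model, scores = eigengene.fit_eigengene(expr, panel, w)
        B = expr.dense_genes(list(model.used_genes))
        Z = (B - model.gene_centers) / model.gene_scales
        assert np.corrcoef(scores.score, Z.mean(axis=1))[0, 1] >= 0


def test_duplicating_a_cell_type_leaves_loadings_unchanged(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    panel = ds.panels[1]
    model, scores = eigengene.fit_eigengene(expr, panel, w)

    dup = (ds.cell_meta["cell_type"] == "inhibitory").to_numpy()
    idx = np.concatenate([np.arange(dup.size), np.flatnonzero(dup)])
    expr2 = ExpressionMatrix(
        np.array([f"d{i}" for i in range(idx.size)], dtype=object), expr.genes, expr.X[idx]
    )
    meta2 = pd.DataFrame(
        {"cell_id": expr2.cells, "cell_type": ds.cell_meta["cell_type"].to_numpy()[idx]}
    )
    model2, scores2 = eigengene.fit_eigengene(expr2, panel, eigengene.compute_cell_weights(meta2))
    sign = np.sign(np.dot(model.loadings, model2.loadings))
    assert np.max(np.abs(model.loadings - sign * model2.loadings)) < 1e-8
    assert np.max(np.abs(scores.score - sign * scores2.score[: scores.score.size])) < 1e-8


def test_gene_scale_equivariance(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    panel = ds.panels[0]
    _, scores = eigengene.fit_eigengene(expr, panel, w)
    X = expr.X.tocsc(copy=True)
    j = int(np.flatnonzero(expr.genes == panel.genes[0])[0])
    X[:, j] = X[:, j] * 9.0
    expr2 = ExpressionMatrix(expr.cells, expr.genes, X.tocsr())
    _, scores2 = eigengene.fit_eigengene(expr2, panel, w)
    assert np.max(np.abs(scores.score - scores2.score)) < 1e-8


def test_self_projection_identity(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    for panel in ds.panels:
        model, scores = eigengene.fit_eigengene(expr, panel, w)
        for mode in ("rms", "euclidean"):
            proj = eigengene.project_eigengene(model, expr, mode)
            assert np.max(np.abs(proj.score - scores.score)) < 1e-8


def test_projection_permutation_equivariance(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    model, _ = eigengene.fit_eigengene(expr, ds.panels[0], w)
    rng = np.random.default_rng(0)
    perm = rng.permutation(expr.shape[0])
    expr_p = ExpressionMatrix(expr.cells[perm], expr.genes, expr.X[perm])
    a = eigengene.project_eigengene(model, expr)
    b = eigengene.project_eigengene(model, expr_p)
    assert np.allclose(a.score[perm], b.score)


def test_projection_on_gene_subset_matches_oracle(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    model, _ = eigengene.fit_eigengene(expr, ds.panels[2], w)
    half = list(model.used_genes[: len(model.used_genes) // 2])
    keep = np.isin(expr.genes, half)
    expr_half = ExpressionMatrix(expr.cells, expr.genes[keep], expr.X[:, keep])
    proj = eigengene.project_eigengene(model, expr_half, "none")
    # independent recomputation: re-normalized loadings on the subset
    sel = np.isin(model.used_genes, half)
    l = model.loadings[sel] / np.linalg.norm(model.loadings[sel])
    B = expr.dense_genes([g for g in model.used_genes if g in set(half)])
    Z = (B - model.gene_centers[sel]) / model.gene_scales[sel]
    assert np.max(np.abs(proj.score - Z @ l)) < 1e-10


def test_projection_with_too_few_shared_genes_errors(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    model, _ = eigengene.fit_eigengene(expr, ds.panels[0], w)
    keep = np.isin(expr.genes, [model.used_genes[0]])
    expr_one = ExpressionMatrix(expr.cells, expr.genes[keep], expr.X[:, keep])
    with pytest.raises(ValueError, match="missing"):
        eigengene.project_eigengene(model, expr_one)


def test_compare_loadings_identity_and_sign_flip(small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    model, _ = eigengene.fit_eigengene(expr, ds.panels[1], w)
    assert eigengene.compare_loadings(model, model) == pytest.approx(1.0)
    import dataclasses

    flipped = dataclasses.replace(model, loadings=-model.loadings)
    assert eigengene.compare_loadings(model, flipped) == pytest.approx(1.0)


def test_replicate_fits_agree_on_loadings():
    """Two independent draws of the same planted structure recover
    correlated panel weights (the reciprocal-validation property)."""
    models = []
    for seed in (21, 22):
        cfg = simulate.SimulationConfig(
            n_cells_by_type={"excitatory": 4200, "inhibitory": 800},
            n_genes=600,
            n_de_genes=40,
            senescent_fraction=0.02,
            seed=seed,
            structure_seed=21,
        )
        ds = simulate.generate_dataset(cfg)
        expr = diffexpr.normalize(ds.counts)
        w = eigengene.compute_cell_weights(ds.cell_meta)
        model, _ = eigengene.fit_eigengene(expr, ds.panels[2], w)
        models.append(model)
    assert eigengene.compare_loadings(*models) >= 0.8


def test_model_round_trip(tmp_path, small_dataset):
    ds = small_dataset
    expr = diffexpr.normalize(ds.counts)
    w = eigengene.compute_cell_weights(ds.cell_meta)
    model, scores = eigengene.fit_eigengene(expr, ds.panels[0], w)
    model.save(tmp_path / "m")
    back = eigengene.EigengeneModel.load(tmp_path / "m")
    proj = eigengene.project_eigengene(back, expr)
    assert np.max(np.abs(proj.score - scores.score)) < 1e-8
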