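import numpy as np
import pytest
import scipy.sparse as sp

from neurescence import diffexpr, eigengene, labeling, simulate
from neurescence.io import CountMatrix, GenePanel


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced-scale simulation for unit tests."""
    return simulate.SimulationConfig(
        n_cells_by_type={"excitatory": 1400, "inhibitory": 400, "astrocyte": 200},
        n_genes=400,
        n_de_genes=30,
        senescent_fraction=0.03,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale study conditions (10,000 cells, ~1% senescent
    excitatory neurons); session-scoped because generation is the costly
    part of the acceptance checks."""
    return simulate.generate_dataset(simulate.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_labels(default_dataset):
    """Eigengene scores and consensus labels for the default dataset."""
    ds = default_dataset
    expr = diffexpr.normalize(ds.counts)
    weights = eigengene.compute_cell_weights(ds.cell_meta)
    scores = {}
    models = {}
    for panel in ds.panels:
        model, sc = eigengene.fit_eigengene(expr, panel, weights)
        models[panel.name] = model
        scores[panel.name] = sc
    thresholds = labeling.derive_thresholds(scores)
    labels = labeling.label_cells(scores, thresholds)
    return {"expr": expr, "models": models, "scores": scores,
            "thresholds": thresholds, "labels": labels}


def toy_counts(X, cells=None, genes=None) -> CountMatrix:
    X = np.asarray(X)
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    return CountMatrix(np.asarray(cells, dtype=object),
                       np.asarray(genes, dtype=object),
                       sp.csr_matrix(X))


@pytest.fixture
def toy_counts_factory():
    return toy_counts


@pytest.fixture
def tiny_panel():
    return GenePanel("toy", ["g0", "g1", "g2"])
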