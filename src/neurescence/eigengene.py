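"""Panel eigengenes: weighted-PCA summary scores for senescence gene panels.

An eigengene of a gene panel is the first principal component of the
panel's standardized expression across cells — a weighted average of the
panel genes' expression, one value per cell. To keep abundant cell types
from dominating the component, every cell is weighted by the total number
of cells divided by the size of its own cell type, so each type contributes
equal total weight.

Expression fed to the PCA is expected to be on a variance-stabilized scale
(log2(CPM+1) from :func:`neurescence.diffexpr.normalize`); raw counts would
let a handful of high-mean genes dominate the component.

A fitted model can be projected onto a second (validation) matrix using the
gene loadings, centers and scales learned on the discovery matrix. The
projected score vector is rescaled to match the discovery scores' scale:
by default their root-mean-square (invariant to the number of cells), or,
in ``euclidean`` mode, their Euclidean norm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePanel

__all__ = [
    "EigengeneModel",
    "EigengeneScores",
    "compute_cell_weights",
    "fit_eigengene",
    "project_eigengene",
    "compare_loadings",
]

_VAR_TOL = 1e-12


@dataclass
class EigengeneScores:
    panel: str
    cells: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        self.score = np.asarray(self.score, dtype=float)
        if len(self.cells) != len(self.score):
            raise ValueError("scores and cell ids differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cells, "score": self.score})


@dataclass
class EigengeneModel:
    """Per-gene loadings and standardization statistics for one panel."""

    panel: str
    used_genes: np.ndarray
    loadings: np.ndarray      # unit Euclidean norm, oriented
    gene_centers: np.ndarray  # weighted means on the discovery matrix
    gene_scales: np.ndarray   # weighted standard deviations, strictly positive
    reference_norm: float     # Euclidean norm of the discovery score vector
    reference_rms: float      # root-mean-square of the discovery score vector
    sign_anchor: int          # +1/-1: orientation applied to the raw eigenvector
    norm_mode: str = "rms"

    def __post_init__(self) -> None:
        self.used_genes = np.asarray(self.used_genes, dtype=object)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.gene_centers = np.asarray(self.gene_centers, dtype=float)
        self.gene_scales = np.asarray(self.gene_scales, dtype=float)

    def save(self, prefix) -> None:
        """TSV of per-gene quantities plus a JSON header."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "gene": self.used_genes,
                "loading": self.loadings,
                "center": self.gene_centers,
                "scale": self.gene_scales,
            }
        ).to_csv(f"{prefix}.tsv", sep="\t", index=False)
        header = {
            "panel": self.panel,
            "reference_norm": self.reference_norm,
            "reference_rms": self.reference_rms,
            "sign_anchor": self.sign_anchor,
            "norm_mode": self.norm_mode,
        }
        Path(f"{prefix}.json").write_text(json.dumps(header, indent=2) + "\n")

    @classmethod
    def load(cls, prefix) -> "EigengeneModel":
        df = pd.read_csv(f"{prefix}.tsv", sep="\t")
        header = json.loads(Path(f"{prefix}.json").read_text())
        return cls(
            panel=header["panel"],
            used_genes=df["gene"].to_numpy(dtype=object),
            loadings=df["loading"].to_numpy(),
            gene_centers=df["center"].to_numpy(),
            gene_scales=df["scale"].to_numpy(),
            reference_norm=header["reference_norm"],
            reference_rms=header["reference_rms"],
            sign_anchor=header["sign_anchor"],
            norm_mode=header["norm_mode"],
        )


def compute_cell_weights(cell_meta: pd.DataFrame) -> np.ndarray:
    """Weight of a cell = total cells / size of its cell type.

    Each cell type then contributes total weight equal to the number of
    cells, i.e. all types have equal influence on the weighted PCA.
    """
    if cell_meta is None or len(cell_meta) == 0:
        raise ValueError("empty cell metadata")
    if "cell_type" not in cell_meta.columns:
        raise ValueError("cell metadata lacks a cell_type column")
    ct = cell_meta["cell_type"].astype(str)
    if (ct == "").any():
        raise ValueError("empty cell_type values")
    counts = ct.value_counts()
    return (len(cell_meta) / ct.map(counts)).to_numpy(dtype=float)


def _weighted_moments(B: np.ndarray, p: np.ndarray):
    mu = p @ B
    var = p @ (B - mu) ** 2
    return mu, var


def fit_eigengene(
    expr: ExpressionMatrix,
    panel: GenePanel,
    weights: np.ndarray,
    allow_single_gene: bool = False,
) -> tuple[EigengeneModel, EigengeneScores]:
    """Fit the panel eigengene on a discovery matrix.

    Panel genes present in the matrix are standardized with their weighted
    mean and standard deviation (constant genes are dropped); the loadings
    are the leading eigenvector of the weighted correlation matrix, with
    the sign chosen so that the score correlates non-negatively with the
    mean standardized panel expression (high score = high panel
    expression).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != expr.shape[0]:
        raise ValueError("one weight per cell required")
    if np.any(weights <= 0):
        raise ValueError("cell weights must be positive")
    present = [g for g in panel.genes if g in set(expr.genes.tolist())]
    min_genes = 1 if allow_single_gene else 2
    if len(present) < min_genes:
        raise ValueError(
            f"panel {panel.name!r}: only {len(present)} genes present in the matrix"
        )
    B = expr.dense_genes(present)
    p = weights / weights.sum()
    mu, var = _weighted_moments(B, p)
    usable = var > _VAR_TOL
    if int(usable.sum()) < min_genes:
        raise ValueError(
            f"panel {panel.name!r}: fewer than {min_genes} genes with nonzero "
            "weighted variance"
        )
    used = [g for g, u in zip(present, usable) if u]
    B, mu, var = B[:, usable], mu[usable], var[usable]
    sd = np.sqrt(var)
    Z = (B - mu) / sd

    if Z.shape[1] == 1:
        v = np.array([1.0])
    else:
        C = (Z * p[:, None]).T @ Z
        C = (C + C.T) / 2.0
        evals, evecs = np.linalg.eigh(C)
        top = np.flatnonzero(evals >= evals[-1] - 1e-12)
        if top.size == 1:
            v = evecs[:, -1]
        else:
            # exact eigenvalue tie: pick the eigenvector whose largest
            # |loading| sits on the lowest gene index
            best = min(top, key=lambda j: int(np.argmax(np.abs(evecs[:, j]))))
            v = evecs[:, best]
    v = v / np.linalg.norm(v)

    score = Z @ v
    anchor = 1
    mean_z = Z.mean(axis=1)
    c = float(np.dot(score - score.mean(), mean_z - mean_z.mean()))
    if c < 0:
        anchor, v, score = -1, -v, -score

    model = EigengeneModel(
        panel=panel.name,
        used_genes=np.asarray(used, dtype=object),
        loadings=v,
        gene_centers=mu,
        gene_scales=sd,
        reference_norm=float(np.linalg.norm(score)),
        reference_rms=float(np.sqrt(np.mean(score**2))),
        sign_anchor=anchor,
    )
    return model, EigengeneScores(panel.name, expr.cells, score)


def project_eigengene(
    model: EigengeneModel,
    expr: ExpressionMatrix,
    norm_mode: str | None = None,
) -> EigengeneScores:
    """Score a new matrix with a fitted model.

    Loadings are restricted to the genes shared with the new matrix and
    re-normalized to unit norm; standardization uses the discovery centers
    and scales; the score vector is then rescaled so its RMS (default) or
    Euclidean norm matches the discovery scores.
    """
    mode = norm_mode or model.norm_mode
    if mode not in ("rms", "euclidean", "none"):
        raise ValueError(f"unknown norm mode {mode!r}")
    have = set(expr.genes.tolist())
    keep = np.asarray([g in have for g in model.used_genes], dtype=bool)
    if int(keep.sum()) < 2:
        missing = [g for g in model.used_genes if g not in have]
        raise ValueError(
            f"panel {model.panel!r}: fewer than 2 model genes present; "
            f"missing {missing[:10]!r}"
        )
    genes = model.used_genes[keep]
    l = model.loadings[keep]
    l = l / np.linalg.norm(l)
    B = expr.dense_genes(list(genes))
    Z = (B - model.gene_centers[keep]) / model.gene_scales[keep]
    raw = Z @ l
    if mode == "rms":
        denom = float(np.sqrt(np.mean(raw**2)))
        scale = model.reference_rms / denom if denom > 0 else 1.0
    elif mode == "euclidean":
        denom = float(np.linalg.norm(raw))
        scale = model.reference_norm / denom if denom > 0 else 1.0
    else:
        scale = 1.0
    return EigengeneScores(model.panel, expr.cells, raw * scale)


def _oriented(model: EigengeneModel) -> np.ndarray:
    """Loadings oriented so their sum is non-negative (comparison contract)."""
    l = model.loadings
    return -l if float(l.sum()) < 0 else l


def compare_loadings(model_a: EigengeneModel, model_b: EigengeneModel) -> float:
    """Pearson correlation of the two models' loadings over shared genes,
    after orienting both models."""
    shared = [g for g in model_a.used_genes if g in set(model_b.used_genes.tolist())]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    ia = {g: i for i, g in enumerate(model_a.used_genes)}
    ib = {g: i for i, g in enumerate(model_b.used_genes)}
    la = _oriented(model_a)[[ia[g] for g in shared]]
    lb = _oriented(model_b)[[ib[g] for g in shared]]
    return float(np.corrcoef(la, lb)[0, 1])
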