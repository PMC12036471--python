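"""Dual differential expression between senescent and non-senescent cells.

The pipeline mirrors the two-pronged design used for senescent-neuron DE
calling: genes are filtered for minimal detection, counts are normalized to
log2(CPM+1), the rare senescent class is upsampled by an integer
replication factor so the two groups are roughly balanced, and every gene
is tested twice —

* a two-part *hurdle* test: a likelihood-ratio test of the group effect on
  the detection rate (logistic part, equivalent to a 2x2 G-test) plus a
  likelihood-ratio test on the positive expression values (Gaussian part),
  combined as a chi-square with up to 2 degrees of freedom;
* a nonparametric *Earth Mover's Distance* (first-order Wasserstein) score
  with a label-permutation p-value.

Both p-value sets are Benjamini-Hochberg adjusted; genes passing the
hurdle FDR + |log2FC| thresholds and the EMD FDR + score thresholds are
intersected, and the overlap is scored with an upper-tail hypergeometric
test over the tested genes.

Replicating cells changes no empirical distribution function, so the EMD
score and its permutation null are computed on the original cells (labels
are permuted before any re-expansion); the hurdle test sees the upsampled
data through per-cell replication weights, exactly equivalent to literal
row duplication.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2

from ._random import substream
from .enrichment import bh_adjust, hypergeom_tail
from .io import CountMatrix, ExpressionMatrix
from .labeling import NON_SENESCENT, SENESCENT, ConsensusLabels

__all__ = [
    "DEConfig",
    "DEResult",
    "filter_genes",
    "normalize",
    "upsample_minority",
    "hurdle_test",
    "emd_1d",
    "emd_test",
    "run_de",
]


@dataclass
class DEConfig:
    min_count: int = 1
    min_cells: int = 200
    cpm_scale: float = 1e6
    log_base: float = 2.0
    pseudocount: float = 1.0
    hurdle_fdr_max: float = 0.01
    hurdle_abs_lfc_min: float = 6.0
    emd_fdr_max: float = 0.01
    emd_score_min: float = 3.0
    emd_score_scale: float = 1.0
    n_permutations: int = 1000
    upsample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hurdle_fdr_max", "hurdle_abs_lfc_min", "emd_fdr_max", "emd_score_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")

    @classmethod
    def published_profile(cls, **overrides) -> "DEConfig":
        """Literal published thresholds, including the EMD score cutoff of
        30 that is tied to the original script's internal scaling."""
        base = dict(emd_score_min=30.0)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DEResult:
    table: pd.DataFrame  # one row per tested gene
    summary: dict

    @property
    def called_both(self) -> list:
        return self.table.loc[self.table["called_both"], "gene"].tolist()


# ---------------------------------------------------------------------------
# preprocessing


def filter_genes(counts: CountMatrix, min_count: int = 1, min_cells: int = 200) -> CountMatrix:
    """Keep genes with counts >= min_count in at least min_cells cells."""
    Xc = counts.X.tocsc()
    det = np.asarray((Xc >= min_count).sum(axis=0)).ravel() if min_count > 0 else np.full(
        counts.shape[1], counts.shape[0]
    )
    keep = det >= min_cells
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return CountMatrix(counts.cells.copy(), counts.genes[keep], counts.X[:, keep])


def normalize(
    counts: CountMatrix, cpm_scale: float = 1e6, pseudocount: float = 1.0, log_base: float = 2.0
) -> ExpressionMatrix:
    """log(CPM + pseudocount) in the configured base; zeros stay zero when
    pseudocount = 1, so sparsity is preserved."""
    totals = np.asarray(counts.X.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"{zero.size} cells have zero library size, e.g. "
            f"{counts.cells[zero[:5]].tolist()!r}"
        )
    X = counts.X.tocsr().astype(np.float64)
    scale = cpm_scale / totals
    row_rep = np.repeat(scale, np.diff(X.indptr))
    X.data = np.log(X.data * row_rep + pseudocount) / np.log(log_base)
    return ExpressionMatrix(counts.cells.copy(), counts.genes.copy(), X)


def upsample_minority(labels) -> tuple[int, np.ndarray]:
    """Half-up-rounded replication factor for the minority class and the
    expanded cell index (majority untouched, minority repeated factor
    times, original order preserved)."""
    lab = np.asarray(labels, dtype=object)
    classes, counts = np.unique(lab, return_counts=True)
    if classes.size != 2 or counts.min() == 0:
        raise ValueError("exactly two non-empty classes required")
    minority = classes[np.argmin(counts)]
    n_minor, n_major = counts.min(), counts.max()
    factor = int(np.floor(n_major / n_minor + 0.5))
    factor = max(factor, 1)
    reps = np.where(lab == minority, factor, 1)
    return factor, np.repeat(np.arange(lab.size), reps)


# ---------------------------------------------------------------------------
# hurdle test


def _hurdle_core(N1, D1, S1, Q1, N0, D0, S0, Q0, pos1, pos0):
    """Vectorized two-part statistic from per-group sufficient statistics.

    N = (weighted) cells, D = (weighted) detected cells, S/Q = (weighted)
    sum and sum of squares of positive values; pos1/pos0 = raw detected
    cell counts (for the <2-positive degeneracy rule).
    """
    N1, D1, S1, Q1, N0, D0, S0, Q0 = (
        np.asarray(a, dtype=float) for a in (N1, D1, S1, Q1, N0, D0, S0, Q0)
    )
    N, D = N1 + N0, D1 + D0

    # discrete part: G-statistic of the 2x2 detection table
    with np.errstate(divide="ignore", invalid="ignore"):
        def xlogx(x):
            return np.where(x > 0, x * np.log(np.maximum(x, 1e-300)), 0.0)

        G = 2.0 * (
            xlogx(D1) + xlogx(N1 - D1) + xlogx(D0) + xlogx(N0 - D0)
            - xlogx(N1) - xlogx(N0)
            - xlogx(D) - xlogx(N - D)
            + xlogx(N)
        )
    disc_ok = (D > 0) & (D < N)
    G = np.where(disc_ok, np.maximum(G, 0.0), 0.0)

    # continuous part: Gaussian LRT on positive values
    cont_ok = (np.asarray(pos1) >= 2) & (np.asarray(pos0) >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ss1 = np.maximum(Q1 - S1**2 / np.maximum(D1, 1e-300), 0.0)
        ss0 = np.maximum(Q0 - S0**2 / np.maximum(D0, 1e-300), 0.0)
        ss_within = ss1 + ss0
        S, Q = S1 + S0, Q1 + Q0
        ss_total = np.maximum(Q - S**2 / np.maximum(D, 1e-300), 0.0)
        L = np.where(
            ss_within > 0,
            D * np.log(np.maximum(ss_total, 1e-300) / np.maximum(ss_within, 1e-300)),
            np.where(ss_total > 0, np.inf, 0.0),
        )
    L = np.where(cont_ok, np.maximum(L, 0.0), 0.0)

    stat = G + L
    df = disc_ok.astype(int) + cont_ok.astype(int)
    p = np.where(df > 0, chi2.sf(stat, np.maximum(df, 1)), 1.0)
    with np.errstate(invalid="ignore"):
        lfc = S1 / N1 - S0 / N0
    return stat, p, lfc, df


def hurdle_test(values, groups, weights=None):
    """Two-part hurdle test for one gene.

    *values* are normalized expression levels; *groups* a boolean or
    two-level array (True / the second level = the senescent group);
    *weights* optional per-cell replication counts. Returns
    ``(statistic, p, log2FC, df)``; a fully degenerate gene gets
    statistic 0, p 1, df 0.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if g.dtype != bool:
        levels = np.unique(g)
        if levels.size != 2:
            raise ValueError("groups must have exactly two levels")
        g = g == levels[1]
    if v.shape != g.shape:
        raise ValueError("values and groups differ in length")
    if int(g.sum()) < 2 or int((~g).sum()) < 2:
        raise ValueError("each group needs at least 2 cells")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    pos = v > 0
    stats = []
    for grp in (g, ~g):
        stats.append(
            (
                w[grp].sum(),
                w[grp & pos].sum(),
                (w * v)[grp & pos].sum(),
                (w * v**2)[grp & pos].sum(),
            )
        )
    (N1, D1, S1, Q1), (N0, D0, S0, Q0) = stats
    stat, p, lfc, df = _hurdle_core(
        N1, D1, S1, Q1, N0, D0, S0, Q0, int((g & pos).sum()), int((~g & pos).sum())
    )
    return float(stat), float(p), float(lfc), int(df)


def _hurdle_all(expr: ExpressionMatrix, group: np.ndarray, cell_weights=None):
    """Vectorized hurdle test across all genes of a matrix."""
    w = np.ones(expr.shape[0]) if cell_weights is None else np.asarray(cell_weights, float)
    Xc = expr.X.tocsc()
    pos = Xc.copy()
    pos.data = np.ones_like(pos.data)

    def group_sums(mask):
        wm = w * mask
        N = wm.sum()
        D = pos.T @ wm
        S = Xc.T @ wm
        Q = (Xc.multiply(Xc)).T @ wm
        rawD = pos.T @ mask.astype(float)
        return N, np.asarray(D).ravel(), np.asarray(S).ravel(), np.asarray(Q).ravel(), rawD

    N1, D1, S1, Q1, raw1 = group_sums(group)
    N0, D0, S0, Q0, raw0 = group_sums(~group)
    return _hurdle_core(
        np.full_like(D1, N1), D1, S1, Q1, np.full_like(D0, N0), D0, S0, Q0,
        np.asarray(raw1).ravel(), np.asarray(raw0).ravel(),
    )


# ---------------------------------------------------------------------------
# Earth Mover's Distance


def emd_1d(a, b) -> float:
    """Exact first-order Wasserstein distance between two empirical 1-D
    distributions: the integral of |ECDF_a - ECDF_b|."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    v = np.union1d(a, b)
    if v.size == 1:
        return 0.0
    Fa = np.searchsorted(a, v, side="right") / a.size
    Fb = np.searchsorted(b, v, side="right") / b.size
    return float(np.sum(np.abs(Fa[:-1] - Fb[:-1]) * np.diff(v)))


def emd_test(values, groups, n_permutations: int = 1000, seed: int = 0, score_scale: float = 1.0):
    """EMD score for one gene with a label-permutation p-value.

    p = (1 + #{permuted scores >= observed}) / (1 + n_permutations).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if g.dtype != bool:
        levels = np.unique(g)
        if levels.size != 2:
            raise ValueError("groups must have exactly two levels")
        g = g == levels[1]
    if v.shape != g.shape:
        raise ValueError("values and groups differ in length")
    obs = emd_1d(v[g], v[~g]) * score_scale
    rng = substream(seed, "emd_permutations")
    hits = 0
    for _ in range(int(n_permutations)):
        gp = rng.permutation(g)
        if emd_1d(v[gp], v[~gp]) * score_scale >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + int(n_permutations))
    return float(obs), float(p)


def _emd_all(expr: ExpressionMatrix, group: np.ndarray, n_permutations: int, rng, score_scale=1.0):
    """Vectorized EMD scores and permutation p-values for all genes.

    One shared set of label permutations is used for every gene (the
    standard choice for permutation testing across many features). For a
    group and its complement, |ECDF_A - ECDF_B| = n/(n - nA) |ECDF_A - F|,
    which lets the permuted statistics be computed with one cumulative sum
    per gene over a permutation matrix.
    """
    n = expr.shape[0]
    nA = int(group.sum())
    nB = n - nA
    if nA == 0 or nB == 0:
        raise ValueError("both groups must be non-empty")
    P = np.empty((n_permutations, n), dtype=bool)
    for i in range(n_permutations):
        P[i] = rng.permutation(group)
    Xd = np.asarray(expr.X.todense())
    n_genes = expr.shape[1]
    scores = np.zeros(n_genes)
    pvals = np.ones(n_genes)
    idx_all = np.arange(1, n + 1)
    for j in range(n_genes):
        v = Xd[:, j]
        order = np.argsort(v, kind="stable")
        d = np.diff(v[order])
        if not d.any():
            scores[j] = 0.0
            pvals[j] = 1.0
            continue
        cumA = np.cumsum(group[order])
        obs = float(
            np.sum(np.abs(cumA[:-1] / nA - (idx_all[:-1] - cumA[:-1]) / nB) * d)
        ) * score_scale
        CA = np.cumsum(P[:, order], axis=1, dtype=np.float64)
        D = np.abs(CA[:, :-1] / nA - (idx_all[:-1] - CA[:, :-1]) / nB)
        perm = (D @ d) * score_scale
        scores[j] = obs
        pvals[j] = (1 + int((perm >= obs - 1e-12).sum())) / (1 + n_permutations)
    return scores, pvals


# ---------------------------------------------------------------------------
# pipeline


def run_de(counts: CountMatrix, labels, config: DEConfig | None = None) -> DEResult:
    """Filter, normalize, upsample, run both tests, adjust and intersect."""
    config = config or DEConfig()
    if isinstance(labels, ConsensusLabels):
        keep = np.isin(labels.labels, [SENESCENT, NON_SENESCENT])
        cells = labels.cells[keep]
        lab = labels.labels[keep]
        pos = {c: i for i, c in enumerate(counts.cells)}
        idx = np.array([pos[c] for c in cells], dtype=int)
        counts = counts.subset_cells(idx)
    else:
        lab = np.asarray(labels, dtype=object)
        if len(lab) != counts.shape[0]:
            raise ValueError("labels must align with the matrix cells")
    group = lab == SENESCENT
    if int(group.sum()) == 0 or int((~group).sum()) == 0:
        raise ValueError("both senescent and non-senescent cells are required")

    filtered = filter_genes(counts, config.min_count, config.min_cells)
    expr = normalize(filtered, config.cpm_scale, config.pseudocount, config.log_base)

    if config.upsample:
        factor, _ = upsample_minority(lab)
        minority = SENESCENT if group.sum() <= (~group).sum() else NON_SENESCENT
        weights = np.where(lab == minority, float(factor), 1.0)
    else:
        factor, weights = 1, None

    h_stat, h_p, lfc, h_df = _hurdle_all(expr, group, weights)
    h_adj = bh_adjust(np.clip(h_p, np.nextafter(0, 1), 1.0))

    rng = substream(config.seed, "emd_permutations")
    e_score, e_p = _emd_all(
        expr, group, config.n_permutations, rng, config.emd_score_scale
    )
    e_adj = bh_adjust(np.clip(e_p, np.nextafter(0, 1), 1.0))

    called_h = (h_adj < config.hurdle_fdr_max) & (np.abs(lfc) > config.hurdle_abs_lfc_min)
    called_e = (e_adj < config.emd_fdr_max) & (e_score > config.emd_score_min)
    called_both = called_h & called_e

    n_tested = expr.shape[1]
    overlap_p = hypergeom_tail(
        int(called_both.sum()), int(called_h.sum()), int(called_e.sum()), n_tested
    )
    overlap_log_p = hypergeom_tail(
        int(called_both.sum()), int(called_h.sum()), int(called_e.sum()), n_tested, log=True
    )

    table = pd.DataFrame(
        {
            "gene": expr.genes,
            "mean_log_sen": np.asarray(
                expr.X[group].mean(axis=0)
            ).ravel(),
            "mean_log_nonsen": np.asarray(expr.X[~group].mean(axis=0)).ravel(),
            "log2_fc": lfc,
            "hurdle_stat": h_stat,
            "hurdle_df": h_df,
            "hurdle_p": h_p,
            "hurdle_adj_p": h_adj,
            "emd_score": e_score,
            "emd_p": e_p,
            "emd_adj_p": e_adj,
            "called_hurdle": called_h,
            "called_emd": called_e,
            "called_both": called_both,
        }
    )
    summary = {
        "n_cells": int(counts.shape[0]),
        "n_senescent": int(group.sum()),
        "n_non_senescent": int((~group).sum()),
        "n_tested_genes": int(n_tested),
        "upsample_factor": int(factor),
        "n_called_hurdle": int(called_h.sum()),
        "n_called_emd": int(called_e.sum()),
        "n_called_both": int(called_both.sum()),
        "overlap_p": overlap_p,
        "overlap_log10_p": overlap_log_p / np.log(10.0),
        "config": config.to_dict(),
    }
    return DEResult(table=table, summary=summary)
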