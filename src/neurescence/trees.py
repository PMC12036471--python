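"""Depth-limited decision trees over at most two genes for marker selection.

The searched family is small enough (root split on one gene at an integer
threshold, optionally one further split on one of the two children, at most
two distinct genes in the tree) that the learner can enumerate it
exhaustively and return the tree with minimal (optionally class-weighted)
training misclassification, subject to a minimum leaf size that mirrors
the minCases-style control used to keep marker trees small. Ties are broken
deterministically: higher information gain, then larger minimum leaf, then
lexicographic gene name, then smaller threshold.

On binarized expression (any count above zero becomes 1) every threshold is
0, so a split reads "detected vs not detected" — the regime relevant for
histology-style markers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix
from .labeling import NON_SENESCENT, SENESCENT, ConsensusLabels

logger = logging.getLogger(__name__)

__all__ = [
    "TreeConfig",
    "MarkerTree",
    "EvalMetrics",
    "binarize",
    "fit_marker_tree",
    "predict",
    "evaluate",
    "elimination_analysis",
]


@dataclass
class TreeConfig:
    max_genes: int = 2
    min_cases: int | None = None  # None: max(5, ceil(1% of the minority class))
    binarize: bool = False
    gene_pool: list | None = None  # None: every gene in the matrix
    excluded_genes: tuple = ()
    class_weighting: str = "none"  # "none" | "balanced"
    max_thresholds_per_gene: int | None = None

    def __post_init__(self) -> None:
        if self.max_genes not in (1, 2):
            raise ValueError("max_genes must be 1 or 2")
        if self.min_cases is not None and self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")

    def resolved_min_cases(self, n_minority: int) -> int:
        if self.min_cases is not None:
            return int(self.min_cases)
        return max(5, math.ceil(0.01 * n_minority))


@dataclass
class EvalMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    tp_rate_of_total: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MarkerTree:
    """Root split, optional one child split, and leaf classes.

    ``left``/``right`` are class names; when ``second`` is set, the child
    on ``second_side`` is replaced by a sub-split on ``second_gene`` with
    leaf classes ``second_left``/``second_right``. A tree with
    ``gene is None`` is the majority-class stump.
    """

    gene: str | None = None
    threshold: int | None = None
    left: str | None = None
    right: str | None = None
    second_side: str | None = None  # "left" | "right" | None
    second_gene: str | None = None
    second_threshold: int | None = None
    second_left: str | None = None
    second_right: str | None = None
    majority: str | None = None  # class of the stump when gene is None
    binarized: bool = False
    min_cases: int = 1
    training_metrics: EvalMetrics | None = None

    @property
    def genes(self) -> list:
        out = []
        for g in (self.gene, self.second_gene):
            if g is not None and g not in out:
                out.append(g)
        return out

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "training_metrics"}
        if self.training_metrics is not None:
            d["training_metrics"] = self.training_metrics.to_dict()
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "MarkerTree":
        d = json.loads(Path(path).read_text())
        tm = d.pop("training_metrics", None)
        tree = cls(**d)
        if tm is not None:
            tree.training_metrics = EvalMetrics(**tm)
        return tree


def binarize(counts: CountMatrix) -> CountMatrix:
    """Any expression level above zero becomes 1; sparsity preserved."""
    X = counts.X.copy()
    X.data = np.ones_like(X.data)
    return CountMatrix(counts.cells.copy(), counts.genes.copy(), X)


# ---------------------------------------------------------------------------
# fitting


def _h2(a: float, b: float) -> float:
    """Shannon entropy (bits) of a two-class mass pair."""
    tot = a + b
    if tot <= 0 or a <= 0 or b <= 0:
        return 0.0
    pa, pb = a / tot, b / tot
    return -(pa * math.log2(pa) + pb * math.log2(pb))


def _resolve_labels(counts: CountMatrix, labels):
    """Accept a ConsensusLabels (restricted to the two classes) or an
    aligned label array; return (counts, y) with y True = senescent."""
    if isinstance(labels, ConsensusLabels):
        keep = np.isin(labels.labels, [SENESCENT, NON_SENESCENT])
        lab_cells = labels.cells[keep]
        lab = labels.labels[keep]
        pos = {c: i for i, c in enumerate(counts.cells)}
        missing = [c for c in lab_cells if c not in pos]
        if missing:
            raise ValueError(f"labeled cells missing from matrix: {missing[:5]!r}")
        idx = np.array([pos[c] for c in lab_cells], dtype=int)
        counts = counts.subset_cells(idx)
        y = lab == SENESCENT
    else:
        lab = np.asarray(labels, dtype=object)
        if len(lab) != counts.shape[0]:
            raise ValueError("labels must align with the matrix cells")
        bad = set(np.unique(lab).tolist()) - {SENESCENT, NON_SENESCENT}
        if bad:
            raise ValueError(f"unexpected labels {sorted(map(str, bad))!r}")
        y = lab == SENESCENT
    return counts, np.asarray(y, dtype=bool)


def _thin(thresholds: np.ndarray, max_keep: int | None) -> np.ndarray:
    if max_keep is None or thresholds.size <= max_keep:
        return thresholds
    idx = np.unique(np.round(np.linspace(0, thresholds.size - 1, max_keep)).astype(int))
    return thresholds[idx]


class _Best:
    """Running best tree under the deterministic tie-break order."""

    def __init__(self) -> None:
        self.key = None
        self.payload = None

    def offer(self, key: tuple, payload) -> None:
        if self.key is None or key < self.key:
            self.key = key
            self.payload = payload


def fit_marker_tree(counts: CountMatrix, labels, config: TreeConfig) -> MarkerTree:
    """Exhaustively fit the best tree over at most two genes.

    Both classes must be present; pool genes absent from the matrix are
    dropped with a warning. The returned tree minimizes (class-weighted)
    training misclassification over all trees in the family whose leaves
    each hold at least ``min_cases`` training cells, with the documented
    deterministic tie-breaking.
    """
    counts, y = _resolve_labels(counts, labels)
    n = counts.shape[0]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit a tree")

    pool = list(config.gene_pool) if config.gene_pool is not None else list(counts.genes)
    have = set(counts.genes.tolist())
    missing = [g for g in pool if g not in have]
    if missing:
        logger.warning("dropping %d pool genes absent from the matrix", len(missing))
    excluded = set(config.excluded_genes)
    pool = [g for g in pool if g in have and g not in excluded]
    if not pool:
        raise ValueError("empty gene pool")
    pool = sorted(set(pool))

    X = np.asarray(counts.subset_genes(pool).X.todense())
    if config.binarize:
        X = (X > 0).astype(np.int64)

    mc = config.resolved_min_cases(min(n_pos, n_neg))
    if config.class_weighting == "balanced":
        w1, w0 = n / (2.0 * n_pos), n / (2.0 * n_neg)
    else:
        w1 = w0 = 1.0

    yb = y
    P, Nn = n_pos, n_neg
    mass_tot = w1 * P + w0 * Nn
    H_root = _h2(w1 * P, w0 * Nn)

    def werr(pos, neg):
        return np.minimum(w1 * np.asarray(pos, dtype=float), w0 * np.asarray(neg, dtype=float))

    def leaf_class(pos, neg) -> str:
        return SENESCENT if w1 * pos > w0 * neg else NON_SENESCENT

    # per-gene sort structure
    genes_info = []
    for j, g in enumerate(pool):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sv = col[order]
        uniq = np.unique(col)
        thr = _thin(uniq[:-1], config.max_thresholds_per_gene)
        cnt = np.searchsorted(sv, thr, side="right") if thr.size else np.array([], dtype=int)
        ys = yb[order]
        genes_info.append(
            {
                "gene": g,
                "order": order,
                "thr": thr,
                "cnt": cnt,
                "cumpos": np.cumsum(ys),
                "ys": ys,
            }
        )

    best = _Best()
    stump_class = leaf_class(P, Nn)
    stump_err = float(werr(P, Nn))
    best.offer(
        (stump_err, -0.0, -n, "", -1, -1, "", -1),
        MarkerTree(majority=stump_class),
    )

    def tree_ig(leaf_masses) -> float:
        h = 0.0
        for a, b in leaf_masses:
            m = a + b
            if m > 0:
                h += (m / mass_tot) * _h2(a, b)
        return H_root - h

    # phase 1: all single-split trees. Candidates with error above the
    # running best can never win (error is the leading key), so the
    # information gain is only evaluated for potential winners.
    root_records = []  # (lower bound, gene info, ti) for phase 2
    for gi in genes_info:
        g, thr = gi["gene"], gi["thr"]
        if not thr.size:
            continue
        cumpos = gi["cumpos"]
        nL = gi["cnt"]
        posL = cumpos[nL - 1]
        negL = nL - posL
        nR = n - nL
        posR = P - posL
        negR = nR - posR
        werrL = werr(posL, negL)
        werrR = werr(posR, negR)

        valid = (nL >= mc) & (nR >= mc)
        if valid.any():
            err = np.where(valid, werrL + werrR, np.inf)
            for ti in np.flatnonzero(err <= best.key[0]):
                e = float(err[ti])
                ig = tree_ig([(w1 * posL[ti], w0 * negL[ti]), (w1 * posR[ti], w0 * negR[ti])])
                ml = int(min(nL[ti], nR[ti]))
                best.offer(
                    (e, -ig, -ml, g, int(thr[ti]), -1, "", -1),
                    MarkerTree(
                        gene=g,
                        threshold=int(thr[ti]),
                        left=leaf_class(posL[ti], negL[ti]),
                        right=leaf_class(posR[ti], negR[ti]),
                    ),
                )

        if config.max_genes < 2:
            continue
        for ti in range(thr.size):
            nl = int(nL[ti])
            nr = n - nl
            split_left = nl >= 2 * mc and nr >= mc
            split_right = nr >= 2 * mc and nl >= mc
            if not (split_left or split_right):
                continue
            # any two-split tree with this root keeps one child as a leaf
            lb = min(
                float(werrR[ti]) if split_left else np.inf,
                float(werrL[ti]) if split_right else np.inf,
            )
            root_records.append((lb, gi, ti, split_left, split_right))

    # phase 2: second splits, roots in order of their error lower bound so
    # the scan can stop once no remaining root can beat the running best.
    root_records.sort(key=lambda r: r[0])
    for lb, gi, ti, split_left, split_right in root_records:
        if lb > best.key[0]:
            break
        g, thr = gi["gene"], gi["thr"]
        nl = int(gi["cnt"][ti])
        pl = int(gi["cumpos"][nl - 1])
        nr, pr = n - nl, P - pl
        mask = np.zeros(n, dtype=bool)
        mask[gi["order"][:nl]] = True

        for gj in genes_info:
            g2, thr2, cnt2 = gj["gene"], gj["thr"], gj["cnt"]
            if not thr2.size:
                continue
            mo = mask[gj["order"]]
            cumS = np.cumsum(mo)
            cumSpos = np.cumsum(mo & gj["ys"])
            c = cnt2 - 1
            nS_le = cumS[c]
            posS_le = cumSpos[c]
            allpos_le = gj["cumpos"][c]

            for side in ("left", "right"):
                if side == "left":
                    if not split_left:
                        continue
                    tot_n, tot_p = nl, pl
                    n_le, p_le = nS_le, posS_le
                    leaf_p, leaf_n = pr, nr - pr
                else:
                    if not split_right:
                        continue
                    tot_n, tot_p = nr, pr
                    n_le = cnt2 - nS_le
                    p_le = allpos_le - posS_le
                    leaf_p, leaf_n = pl, nl - pl
                n_gt = tot_n - n_le
                p_gt = tot_p - p_le
                ok = (n_le >= mc) & (n_gt >= mc)
                if not ok.any():
                    continue
                err = (
                    werr(p_le, n_le - p_le)
                    + werr(p_gt, n_gt - p_gt)
                    + float(werr(leaf_p, leaf_n))
                )
                err = np.where(ok, err, np.inf)
                for t2 in np.flatnonzero(err <= best.key[0]):
                    ig = tree_ig(
                        [
                            (w1 * p_le[t2], w0 * (n_le[t2] - p_le[t2])),
                            (w1 * p_gt[t2], w0 * (n_gt[t2] - p_gt[t2])),
                            (w1 * leaf_p, w0 * leaf_n),
                        ]
                    )
                    ml = int(min(n_le[t2], n_gt[t2], leaf_p + leaf_n))
                    side_code = 0 if side == "left" else 1
                    key = (
                        float(err[t2]),
                        -ig,
                        -ml,
                        g,
                        int(thr[ti]),
                        side_code,
                        g2,
                        int(thr2[t2]),
                    )
                    sub_left = leaf_class(p_le[t2], n_le[t2] - p_le[t2])
                    sub_right = leaf_class(p_gt[t2], n_gt[t2] - p_gt[t2])
                    other = leaf_class(leaf_p, leaf_n)
                    best.offer(
                        key,
                        MarkerTree(
                            gene=g,
                            threshold=int(thr[ti]),
                            left=None if side == "left" else other,
                            right=None if side == "right" else other,
                            second_side=side,
                            second_gene=g2,
                            second_threshold=int(thr2[t2]),
                            second_left=sub_left,
                            second_right=sub_right,
                        ),
                    )

    tree = best.payload
    tree.binarized = bool(config.binarize)
    tree.min_cases = mc
    pred = predict(tree, counts)
    truth = np.where(y, SENESCENT, NON_SENESCENT)
    tree.training_metrics = evaluate(pred, truth)
    return tree


# ---------------------------------------------------------------------------
# prediction and evaluation


def _column(counts: CountMatrix, gene: str) -> np.ndarray:
    if gene not in set(counts.genes.tolist()):
        raise KeyError(f"tree gene {gene!r} not present in the matrix")
    j = int(np.flatnonzero(counts.genes == gene)[0])
    col = np.asarray(counts.X[:, j].todense()).ravel()
    return col


def predict(tree: MarkerTree, counts: CountMatrix) -> np.ndarray:
    """Route every cell through the tree; returns a class label per cell."""
    n = counts.shape[0]
    if tree.gene is None:
        return np.full(n, tree.majority, dtype=object)
    col = _column(counts, tree.gene)
    if tree.binarized:
        col = (col > 0).astype(int)
    left_mask = col <= tree.threshold
    out = np.empty(n, dtype=object)
    for side, mask in (("left", left_mask), ("right", ~left_mask)):
        leaf = tree.left if side == "left" else tree.right
        if tree.second_side == side:
            col2 = _column(counts, tree.second_gene)
            if tree.binarized:
                col2 = (col2 > 0).astype(int)
            le2 = col2 <= tree.second_threshold
            out[mask & le2] = tree.second_left
            out[mask & ~le2] = tree.second_right
        else:
            out[mask] = leaf
    return out


def evaluate(pred, truth, positive: str = SENESCENT) -> EvalMetrics:
    """Confusion counts and rates; undefined rates are NaN, not 0.

    ``tp_rate_of_total`` (true positives over all cells) is reported in
    addition to standard accuracy because some marker studies quote that
    ratio under the name accuracy.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    pp = pred == positive
    tt = truth == positive
    tp = int((pp & tt).sum())
    tn = int((~pp & ~tt).sum())
    fp = int((pp & ~tt).sum())
    fn = int((~pp & tt).sum())
    n = tp + tn + fp + fn
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / n if n else float("nan")
    tp_rate = tp / n if n else float("nan")
    return EvalMetrics(tp, tn, fp, fn, sens, spec, acc, tp_rate)


def elimination_analysis(
    counts: CountMatrix, labels, config: TreeConfig, n_rounds: int
) -> list:
    """Iteratively exclude each round's selected genes and refit.

    Returns an ordered ledger of dicts (round, excluded set before the
    fit, fitted tree, training metrics); truncated with a warning when the
    pool is exhausted.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    ledger = []
    excluded = list(config.excluded_genes)
    for rnd in range(1, n_rounds + 1):
        cfg = TreeConfig(
            max_genes=config.max_genes,
            min_cases=config.min_cases,
            binarize=config.binarize,
            gene_pool=config.gene_pool,
            excluded_genes=tuple(excluded),
            class_weighting=config.class_weighting,
            max_thresholds_per_gene=config.max_thresholds_per_gene,
        )
        try:
            tree = fit_marker_tree(counts, labels, cfg)
        except ValueError as exc:
            logger.warning("elimination stopped at round %d: %s", rnd, exc)
            break
        ledger.append(
            {
                "round": rnd,
                "excluded": tuple(excluded),
                "tree": tree,
                "metrics": tree.training_metrics,
            }
        )
        if not tree.genes:
            logger.warning("elimination stopped at round %d: no informative split", rnd)
            break
        excluded.extend(tree.genes)
    return ledger
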