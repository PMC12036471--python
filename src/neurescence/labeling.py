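"""Consensus senescence labels from three panel eigengene score vectors.

A cell is *senescent* when it exceeds mean + k_sd * s.d. on all three panel
eigengenes (k_sd = 3 by default), *non-senescent* when it lies below the
mean on all three, and *borderline* otherwise. Borderline cells are
excluded from downstream marker and differential-expression work.
Thresholds come from the empirical score distribution of the dataset being
labeled (unweighted mean and population standard deviation over all scored
cells). Both boundary comparisons are strict, so a cell exactly at a
boundary is borderline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import hypergeom_tail

__all__ = [
    "SENESCENT",
    "NON_SENESCENT",
    "BORDERLINE",
    "LabelingThresholds",
    "ConsensusLabels",
    "derive_thresholds",
    "label_cells",
    "celltype_enrichment",
]

SENESCENT = "senescent"
NON_SENESCENT = "non_senescent"
BORDERLINE = "borderline"


@dataclass
class LabelingThresholds:
    means: dict       # panel -> mean score
    sds: dict         # panel -> population s.d.
    k_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        for panel, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"negative s.d. for panel {panel!r}")

    def upper(self, panel: str) -> float:
        return self.means[panel] + self.k_sd * self.sds[panel]

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps({"means": self.means, "sds": self.sds, "k_sd": self.k_sd}, indent=2)
            + "\n"
        )

    @classmethod
    def load(cls, path) -> "LabelingThresholds":
        d = json.loads(Path(path).read_text())
        return cls(means=d["means"], sds=d["sds"], k_sd=d["k_sd"])


@dataclass
class ConsensusLabels:
    cells: np.ndarray
    labels: np.ndarray           # senescent / non_senescent / borderline
    flags: pd.DataFrame          # one +/-/mid column per panel, indexed like cells

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.cells) != len(self.labels):
            raise ValueError("cells and labels differ in length")

    def counts(self) -> dict:
        vals, cnt = np.unique(self.labels, return_counts=True)
        out = {SENESCENT: 0, NON_SENESCENT: 0, BORDERLINE: 0}
        out.update(dict(zip(vals.tolist(), cnt.tolist())))
        return out

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cells, "label": self.labels})
        for col in self.flags.columns:
            df[f"flag_{col}"] = self.flags[col].to_numpy()
        return df


def _as_dict(scores3) -> dict:
    if isinstance(scores3, dict):
        d = dict(scores3)
    else:
        d = {s.panel: s for s in scores3}
    if len(d) != 3:
        raise ValueError(f"expected three score vectors, got {len(d)}")
    return d


def derive_thresholds(scores3, k_sd: float = 3.0) -> LabelingThresholds:
    """Mean and population s.d. of each panel's empirical score
    distribution."""
    d = _as_dict(scores3)
    means, sds = {}, {}
    for panel, s in d.items():
        x = np.asarray(s.score, dtype=float)
        if x.size < 2:
            raise ValueError(f"panel {panel!r}: need at least 2 cells")
        means[panel] = float(x.mean())
        sds[panel] = float(x.std(ddof=0))
    return LabelingThresholds(means=means, sds=sds, k_sd=k_sd)


def label_cells(scores3, thresholds: LabelingThresholds) -> ConsensusLabels:
    """Apply the consensus rule to three aligned score vectors."""
    d = _as_dict(scores3)
    panels = list(d)
    ref = d[panels[0]].cells
    ref_set = set(ref.tolist())
    aligned = {}
    for panel in panels:
        s = d[panel]
        if set(s.cells.tolist()) != ref_set:
            raise ValueError(f"panel {panel!r} scores cover a different cell set")
        if np.array_equal(s.cells, ref):
            aligned[panel] = s.score
        else:
            pos = {c: i for i, c in enumerate(s.cells)}
            aligned[panel] = s.score[[pos[c] for c in ref]]

    above = np.ones(len(ref), dtype=bool)
    below = np.ones(len(ref), dtype=bool)
    flags = {}
    for panel in panels:
        x = aligned[panel]
        hi = x > thresholds.upper(panel)
        lo = x < thresholds.means[panel]
        above &= hi
        below &= lo
        flags[panel] = np.where(hi, "+", np.where(lo, "-", "mid"))
    labels = np.full(len(ref), BORDERLINE, dtype=object)
    labels[above] = SENESCENT
    labels[below] = NON_SENESCENT
    return ConsensusLabels(ref, labels, pd.DataFrame(flags))


def celltype_enrichment(labels: ConsensusLabels, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type upper-tail hypergeometric test for an excess of
    senescent cells.

    Population = all labeled cells, successes = all senescent cells,
    draws = the cells of the type; p = P(X >= observed senescent in type).
    """
    meta = cell_meta.set_index("cell_id")
    types = meta.loc[labels.cells, "cell_type"].to_numpy()
    sen = labels.mask(SENESCENT)
    K = int(sen.sum())
    if K < 1:
        raise ValueError("no senescent cells; enrichment test undefined")
    N = len(labels.cells)
    rows = []
    for t in pd.unique(types):
        in_type = types == t
        n, k = int(in_type.sum()), int((sen & in_type).sum())
        rows.append(
            {
                "cell_type": t,
                "n_cells": n,
                "n_senescent": k,
                "p": hypergeom_tail(k, K, n, N),
                "log_p": hypergeom_tail(k, K, n, N, log=True),
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
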