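"""Synthetic single-nucleus count data with a planted senescent subpopulation.

The generator emulates the statistical structure the downstream analysis
assumes: several cell types with very unequal abundances, sparse
overdispersed (gamma-Poisson) counts with variable library sizes, a rare
senescent subpopulation of excitatory neurons whose three senescence gene
panels are coherently upregulated, a handful of near-binary marker genes,
and a set of strongly induced differentially expressed (DE) genes.

Ground truth (which cells are senescent, which genes are planted markers or
DE genes, which panel genes respond) is returned alongside the counts so
that every downstream stage can be scored against it.

Randomness is organized as named substreams of one global seed, with one
substream per gene for the count draws, so that changing one planted
component (e.g. the marker mechanism) does not perturb the counts of
unrelated genes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._random import substream
from .io import (
    CountMatrix,
    GenePanel,
    read_cell_meta,
    read_counts,
    read_panel,
    write_cell_meta,
    write_counts,
    write_panel,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "synthetic_gene_sets",
]

PANEL_NAMES = ("CSP", "SIP", "SenMayo")


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a 10,000-cell dataset with three cell types of very
    unequal abundance and ~1% senescent excitatory neurons, panel sizes
    matching the three senescence panels (22, 48 and 125 genes), four
    near-binary marker genes and 120 strongly induced DE genes.

    Baseline per-gene mean counts are gamma distributed. Panel genes draw
    their baselines from a separate, higher-mean gamma: curated senescence
    panels consist of well-characterized, detectably expressed genes, and a
    22-gene panel sampled from the sparse tail of the transcriptome would
    carry no usable eigengene signal. Planted DE genes get a fixed low
    baseline: they model senescence-induced genes that are near-silent in
    normal neurons, which also keeps the senescent cells' library-size
    inflation (and hence the compositional distortion of CPM values) small.
    """

    n_cells_by_type: dict = field(
        default_factory=lambda: {"excitatory": 7000, "inhibitory": 2000, "astrocyte": 1000}
    )
    n_genes: int = 1500
    senescent_type: str = "excitatory"
    senescent_fraction: float = 0.01
    panel_sizes: tuple = (22, 48, 125)
    panel_names: tuple = PANEL_NAMES
    panel_response_prob: float = 0.7
    panel_log2_effect: float = 2.0
    n_marker_genes: int = 4
    marker_on_prob: float = 0.9
    marker_leak_prob: float = 0.001
    marker_extra_mean: float = 0.7
    n_de_genes: int = 120
    de_log2_effect: float = 6.5
    de_baseline_mean: float = 0.25
    baseline_mean_shape: float = 0.4
    baseline_mean_scale: float = 25.0
    panel_mean_shape: float = 2.0
    panel_mean_scale: float = 5.0
    dispersion: float = 10.0
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.15
    seed: int = 0
    # gene-level structure (baseline means, panel means, responder subsets)
    # is drawn from this seed; None ties it to `seed`. Two runs sharing a
    # structure_seed but differing in seed are replicates of the same
    # planted structure with independent cells and counts.
    structure_seed: int | None = None

    def validate(self) -> None:
        if not self.n_cells_by_type:
            raise ConfigurationError("n_cells_by_type is empty")
        for t, n in self.n_cells_by_type.items():
            if int(n) <= 0:
                raise ConfigurationError(f"cell type {t!r} has non-positive count {n}")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        for name, frac in (
            ("senescent_fraction", self.senescent_fraction),
            ("panel_response_prob", self.panel_response_prob),
            ("marker_on_prob", self.marker_on_prob),
            ("marker_leak_prob", self.marker_leak_prob),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name}={frac} outside [0, 1]")
        if not 0.0 <= self.senescent_fraction < 1.0:
            raise ConfigurationError("senescent_fraction must be in [0, 1)")
        if len(self.panel_sizes) != 3 or any(s <= 0 for s in self.panel_sizes):
            raise ConfigurationError("panel_sizes must be three positive integers")
        if self.n_marker_genes < 0 or self.n_de_genes < 0:
            raise ConfigurationError("gene counts must be non-negative")
        budget = sum(self.panel_sizes) + self.n_marker_genes + self.n_de_genes
        if budget > self.n_genes:
            raise ConfigurationError(
                f"gene budget infeasible: panels+markers+DE = {budget} > n_genes = {self.n_genes}"
            )
        if self.senescent_fraction > 0 and self.n_cells_by_type.get(self.senescent_type, 0) == 0:
            raise ConfigurationError(
                f"senescent_fraction > 0 but no {self.senescent_type!r} cells configured"
            )
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel_sizes"] = list(self.panel_sizes)
        d["panel_names"] = list(self.panel_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "panel_sizes" in d:
            d["panel_sizes"] = tuple(d["panel_sizes"])
        if "panel_names" in d:
            d["panel_names"] = tuple(d["panel_names"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    cell_meta: pd.DataFrame  # cell_id, cell_type, true_senescent
    panels: list  # three GenePanel
    truth: dict  # marker_genes, de_genes, panel_response
    config: SimulationConfig

    @property
    def true_senescent(self) -> np.ndarray:
        return self.cell_meta["true_senescent"].to_numpy(dtype=bool)


def _gene_roles(config: SimulationConfig) -> dict:
    """Deterministic role layout over gene indices: panels, markers, DE, rest."""
    roles: dict = {}
    start = 0
    panels = []
    for size in config.panel_sizes:
        panels.append(np.arange(start, start + size))
        start += size
    roles["panels"] = panels
    roles["markers"] = np.arange(start, start + config.n_marker_genes)
    start += config.n_marker_genes
    roles["de"] = np.arange(start, start + config.n_de_genes)
    start += config.n_de_genes
    roles["background"] = np.arange(start, config.n_genes)
    return roles


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset under *config*; identical config+seed gives
    identical counts."""
    config.validate()
    seed = config.seed
    sseed = config.seed if config.structure_seed is None else config.structure_seed
    n_genes = config.n_genes

    # cells, grouped by type in declaration order
    types, cell_ids = [], []
    for t, n in config.n_cells_by_type.items():
        types.extend([t] * int(n))
        cell_ids.extend(f"{t}_{i:05d}" for i in range(int(n)))
    types = np.asarray(types, dtype=object)
    cell_ids = np.asarray(cell_ids, dtype=object)
    n_cells = len(cell_ids)

    # senescence flags, only within the configured type
    sen = np.zeros(n_cells, dtype=bool)
    in_type = types == config.senescent_type
    if config.senescent_fraction > 0 and in_type.any():
        rng = substream(seed, "senescent")
        sen[in_type] = rng.random(int(in_type.sum())) < config.senescent_fraction

    # per-gene baseline means; role-specific overrides
    roles = _gene_roles(config)
    rng = substream(sseed, "baseline")
    means = rng.gamma(config.baseline_mean_shape, config.baseline_mean_scale, n_genes)
    panel_idx = np.concatenate(roles["panels"]) if roles["panels"] else np.array([], dtype=int)
    rng = substream(sseed, "panel_means")
    means[panel_idx] = rng.gamma(config.panel_mean_shape, config.panel_mean_scale, panel_idx.size)
    means[roles["de"]] = config.de_baseline_mean

    # responding subset per panel, drawn once per simulation
    rng = substream(sseed, "panel_response")
    responders = np.zeros(n_genes, dtype=bool)
    panel_response: dict = {}
    gene_names = np.asarray([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    for name, idx in zip(config.panel_names, roles["panels"]):
        resp = idx[rng.random(idx.size) < config.panel_response_prob]
        responders[resp] = True
        panel_response[name] = [gene_names[i] for i in resp]

    # library-size factors
    rng = substream(seed, "libsize")
    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n_cells)

    panel_mult = 2.0 ** config.panel_log2_effect
    de_mult = 2.0 ** config.de_log2_effect
    de_set = set(roles["de"].tolist())
    marker_set = set(roles["markers"].tolist())

    r = config.dispersion
    indptr = np.zeros(n_genes + 1, dtype=np.int64)
    col_rows, col_data = [], []
    for g in range(n_genes):
        if g in marker_set:
            rng = substream(seed, f"markers.g{g}")
            p_on = np.where(sen, config.marker_on_prob, config.marker_leak_prob)
            on = rng.random(n_cells) < p_on
            counts = np.zeros(n_cells, dtype=np.int64)
            n_on = int(on.sum())
            if n_on:
                counts[on] = 1 + rng.poisson(config.marker_extra_mean, n_on)
        else:
            mu = means[g] * libsize
            if responders[g]:
                mu = np.where(sen, mu * panel_mult, mu)
            elif g in de_set:
                mu = np.where(sen, mu * de_mult, mu)
            rng = substream(seed, f"counts.g{g}")
            lam = rng.gamma(r, mu / r)
            counts = rng.poisson(lam)
        nz = np.flatnonzero(counts)
        col_rows.append(nz.astype(np.int32))
        col_data.append(counts[nz])
        indptr[g + 1] = indptr[g] + nz.size

    X = sp.csc_matrix(
        (np.concatenate(col_data), np.concatenate(col_rows), indptr),
        shape=(n_cells, n_genes),
    ).tocsr()

    counts_cm = CountMatrix(cell_ids, gene_names, X)
    cell_meta = pd.DataFrame(
        {"cell_id": cell_ids, "cell_type": types, "true_senescent": sen}
    )
    panels = [
        GenePanel(name, [gene_names[i] for i in idx])
        for name, idx in zip(config.panel_names, roles["panels"])
    ]
    truth = {
        "marker_genes": [gene_names[i] for i in roles["markers"]],
        "de_genes": [gene_names[i] for i in roles["de"]],
        "panel_response": panel_response,
    }
    return SyntheticDataset(counts_cm, cell_meta, panels, truth, config)


def synthetic_gene_sets(
    ds: SyntheticDataset,
    n_random_sets: int = 35,
    n_enriched_sets: int = 5,
    enriched_de_fraction: float = 0.35,
    shared_core_size: int = 16,
    set_size_range: tuple = (20, 100),
    seed: int | None = None,
) -> "GeneSetCollection":
    """A synthetic pathway collection to exercise over-representation tests.

    Most sets are uniform draws from all genes; ``n_enriched_sets`` sets
    additionally contain a sizeable fraction of the planted DE genes —
    including a common core of ``shared_core_size`` DE genes present in
    every enriched set — so they behave like the disease pathways a real
    collection would flag, with a significant shared overlap across the
    top sets.
    """
    from .io import GeneSetCollection

    seed = ds.config.seed if seed is None else seed
    rng = substream(seed, "gene_sets")
    genes = ds.counts.genes
    de = np.asarray(ds.truth["de_genes"], dtype=object)
    lo, hi = set_size_range
    sets: dict = {}
    descriptions: dict = {}
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        name = f"pw_random_{i:02d}"
        sets[name] = sorted(members.tolist())
        descriptions[name] = "background pathway"
    core = set(rng.choice(de, size=min(shared_core_size, de.size), replace=False).tolist())
    for i in range(n_enriched_sets):
        size = max(int(rng.integers(lo, hi + 1)), len(core) + 4)
        n_de = min(int(round(enriched_de_fraction * size)), de.size)
        members = set(core)
        extra_de = [g for g in de if g not in members]
        if n_de > len(members) and extra_de:
            take = min(n_de - len(members), len(extra_de))
            members |= set(rng.choice(np.asarray(extra_de, dtype=object), size=take, replace=False).tolist())
        filler = np.asarray([g for g in genes if g not in members], dtype=object)
        need = size - len(members)
        if need > 0:
            members |= set(rng.choice(filler, size=need, replace=False).tolist())
        name = f"pw_enriched_{i:02d}"
        sets[name] = sorted(members)
        descriptions[name] = "senescence-responsive pathway"
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# persistence


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write the dataset in the package's on-disk formats; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_counts(ds.counts, directory)
    meta = ds.cell_meta.copy()
    meta["true_senescent"] = meta["true_senescent"].astype(bool).astype(int)
    write_cell_meta(meta, directory / "cells.tsv")
    paths["cells_meta"] = directory / "cells.tsv"
    paths["panels"] = []
    for panel in ds.panels:
        p = directory / f"panel_{panel.name}.txt"
        write_panel(panel, p)
        paths["panels"].append(p)
    rows = [("marker", g) for g in ds.truth["marker_genes"]]
    rows += [("de", g) for g in ds.truth["de_genes"]]
    for pname, genes in ds.truth["panel_response"].items():
        rows += [(f"panel_response:{pname}", g) for g in genes]
    pd.DataFrame(rows, columns=["kind", "gene"]).to_csv(
        directory / "truth.tsv", sep="\t", index=False
    )
    paths["truth"] = directory / "truth.tsv"
    (directory / "config.json").write_text(json.dumps(ds.config.to_dict(), indent=2) + "\n")
    paths["config"] = directory / "config.json"
    return paths


def read_dataset(directory) -> SyntheticDataset:
    directory = Path(directory)
    config = SimulationConfig.from_dict(json.loads((directory / "config.json").read_text()))
    counts = read_counts(
        directory / "matrix.mtx", directory / "genes.tsv", directory / "barcodes.tsv"
    )
    meta = read_cell_meta(directory / "cells.tsv")
    meta["true_senescent"] = meta["true_senescent"].astype(int).astype(bool)
    panels = [
        read_panel(directory / f"panel_{name}.txt", name=name) for name in config.panel_names
    ]
    truth_df = pd.read_csv(directory / "truth.tsv", sep="\t")
    truth = {
        "marker_genes": truth_df.loc[truth_df["kind"] == "marker", "gene"].tolist(),
        "de_genes": truth_df.loc[truth_df["kind"] == "de", "gene"].tolist(),
        "panel_response": {
            name: truth_df.loc[truth_df["kind"] == f"panel_response:{name}", "gene"].tolist()
            for name in config.panel_names
        },
    }
    return SyntheticDataset(counts, meta, panels, truth, config)
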