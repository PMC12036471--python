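"""End-to-end orchestration of the analysis stages with one manifest.

The full run mirrors the analysis order of the study design: simulate (or
load) a count matrix, fit the three panel eigengenes with cell-type
weights, derive consensus senescence labels, restrict marker and DE work
to the senescent-prone cell type, fit marker trees (raw and binarized),
run the dual DE procedure, and score pathway enrichment of the DE
intersection. Every run writes a ``manifest.json`` with the config echo,
seed, input checksums, stage timings and output list; rerunning with the
same inputs and seed reproduces identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, eigengene, enrichment, labeling, simulate, trees
from .io import write_run_metadata, write_table

logger = logging.getLogger(__name__)

__all__ = ["run_all", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(
    outdir,
    sim_config: simulate.SimulationConfig | None = None,
    seed: int = 0,
    k_sd: float = 3.0,
    norm_mode: str = "rms",
    tree_config: trees.TreeConfig | None = None,
    de_config: diffexpr.DEConfig | None = None,
    raw_tree_max_thresholds: int = 16,
    elimination_rounds: int = 3,
) -> dict:
    """Run every stage on one synthetic dataset and write all outputs.

    Returns the manifest dict. The marker-gene candidate pool is the union
    of the three panels and the planted marker genes — the synthetic
    analogue of a curated senescence-associated gene pool.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": [], "outputs": []}
    t_all = time.time()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    (outdir / f"{name}.failed").write_text(str(exc) + "\n")
                    raise StageError(name, exc) from exc
                manifest["stages"].append(
                    {"name": name, "seconds": round(time.time() - self.t0, 3)}
                )
                return False

        return _Ctx()

    def record(*paths):
        for p in paths:
            manifest["outputs"].append(str(Path(p).relative_to(outdir)))

    # ---- simulate -------------------------------------------------------
    with stage("simulate"):
        cfg = sim_config or simulate.SimulationConfig()
        cfg = simulate.SimulationConfig.from_dict({**cfg.to_dict(), "seed": seed})
        ds = simulate.generate_dataset(cfg)
        paths = simulate.write_dataset(ds, outdir / "dataset")
        record(*(p for k, p in paths.items() if k != "panels"), *paths["panels"])
        manifest["config"] = cfg.to_dict()

    # ---- eigengenes -----------------------------------------------------
    with stage("eigengene"):
        totals = np.asarray(ds.counts.X.sum(axis=1)).ravel()
        if (totals == 0).any():
            keep = totals > 0
            logger.warning("dropping %d zero-library cells", int((~keep).sum()))
            ds.counts = ds.counts.subset_cells(keep)
            ds.cell_meta = ds.cell_meta.loc[keep].reset_index(drop=True)
        expr = diffexpr.normalize(ds.counts)
        weights = eigengene.compute_cell_weights(ds.cell_meta)
        models, scores = {}, {}
        for panel in ds.panels:
            model, sc = eigengene.fit_eigengene(expr, panel, weights)
            model.norm_mode = norm_mode
            models[panel.name] = model
            scores[panel.name] = sc
            model.save(outdir / f"eigengene_{panel.name}")
            write_table(sc.to_frame(), outdir / f"scores_{panel.name}.tsv")
            record(
                outdir / f"eigengene_{panel.name}.tsv",
                outdir / f"eigengene_{panel.name}.json",
                outdir / f"scores_{panel.name}.tsv",
            )

    # ---- labeling -------------------------------------------------------
    with stage("label"):
        thresholds = labeling.derive_thresholds(scores, k_sd=k_sd)
        labels = labeling.label_cells(scores, thresholds)
        thresholds.save(outdir / "thresholds.json")
        write_table(labels.to_frame(), outdir / "labels.tsv")
        ct = labeling.celltype_enrichment(labels, ds.cell_meta)
        write_table(ct, outdir / "celltype_enrichment.tsv")
        record(outdir / "thresholds.json", outdir / "labels.tsv", outdir / "celltype_enrichment.tsv")

    # restrict marker/DE work to the senescent-prone cell type
    sen_type = cfg.senescent_type
    is_type = (ds.cell_meta["cell_type"] == sen_type).to_numpy()
    labeled = np.isin(labels.labels, [labeling.SENESCENT, labeling.NON_SENESCENT])
    use = is_type & labeled
    counts_use = ds.counts.subset_cells(use)
    labels_use = labels.labels[use]

    # ---- marker trees ---------------------------------------------------
    with stage("markers"):
        pool = sorted(
            set(g for p in ds.panels for g in p.genes) | set(ds.truth["marker_genes"])
        )
        base = tree_config or trees.TreeConfig()
        raw_cfg = trees.TreeConfig(
            max_genes=base.max_genes,
            min_cases=base.min_cases,
            binarize=False,
            gene_pool=pool,
            class_weighting=base.class_weighting,
            max_thresholds_per_gene=raw_tree_max_thresholds,
        )
        bin_cfg = trees.TreeConfig(
            max_genes=base.max_genes,
            min_cases=base.min_cases,
            binarize=True,
            gene_pool=pool,
            class_weighting=base.class_weighting,
        )
        raw_tree = trees.fit_marker_tree(counts_use, labels_use, raw_cfg)
        bin_tree = trees.fit_marker_tree(counts_use, labels_use, bin_cfg)
        raw_tree.save(outdir / "tree_raw.json")
        bin_tree.save(outdir / "tree_binary.json")
        rows = []
        for name, tree in (("raw", raw_tree), ("binary", bin_tree)):
            m = tree.training_metrics
            rows.append(
                {
                    "tree": name,
                    "genes": ",".join(tree.genes),
                    "accuracy": m.accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "tp_rate_of_total": m.tp_rate_of_total,
                }
            )
        write_table(pd.DataFrame(rows), outdir / "tree_metrics.tsv")
        ledger = trees.elimination_analysis(counts_use, labels_use, bin_cfg, elimination_rounds)
        lrows = [
            {
                "round": rec["round"],
                "excluded": ",".join(rec["excluded"]),
                "genes": ",".join(rec["tree"].genes),
                "accuracy": rec["metrics"].accuracy,
                "sensitivity": rec["metrics"].sensitivity,
                "specificity": rec["metrics"].specificity,
            }
            for rec in ledger
        ]
        write_table(pd.DataFrame(lrows), outdir / "elimination.tsv")
        record(
            outdir / "tree_raw.json",
            outdir / "tree_binary.json",
            outdir / "tree_metrics.tsv",
            outdir / "elimination.tsv",
        )

    # ---- differential expression ---------------------------------------
    with stage("de"):
        de_cfg = de_config or diffexpr.DEConfig()
        de_cfg = diffexpr.DEConfig(**{**de_cfg.to_dict(), "seed": seed})
        de_res = diffexpr.run_de(counts_use, labels_use, de_cfg)
        write_table(de_res.table, outdir / "de_results.tsv")
        (outdir / "de_summary.json").write_text(
            json.dumps(de_res.summary, indent=2, default=float) + "\n"
        )
        record(outdir / "de_results.tsv", outdir / "de_summary.json")

    # ---- enrichment -----------------------------------------------------
    with stage("enrich"):
        collection = simulate.synthetic_gene_sets(ds, seed=seed)
        query = de_res.called_both
        universe = de_res.table["gene"].tolist()
        if query:
            enr = enrichment.pathway_enrichment(query, collection, universe)
            write_table(enr, outdir / "enrichment.tsv")
            bubble = enr[["set", "overlap", "adj_p"]]
            write_table(bubble, outdir / "enrichment_bubble.tsv")
            top = enr.head(5)
            top_sets = [
                set(collection.sets[s]) & set(query) for s in top["set"]
            ]
            shared = set.intersection(*top_sets) if top_sets else set()
            multi_p = enrichment.multiset_intersection_test(
                [sorted(s) for s in top_sets],
                universe_size=len(query),
                observed_intersection=len(shared),
            )
            summary = {
                "n_query": len(query),
                "n_significant_sets": int((enr["adj_p"] < 0.05).sum()),
                "top5_shared_genes": sorted(shared),
                "top5_shared_p": multi_p,
            }
            (outdir / "enrichment_summary.json").write_text(
                json.dumps(summary, indent=2, default=float) + "\n"
            )
            record(
                outdir / "enrichment.tsv",
                outdir / "enrichment_bubble.tsv",
                outdir / "enrichment_summary.json",
            )
        else:
            logger.warning("no DE intersection genes; skipping enrichment")

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    manifest["input_checksums"] = {
        name: _sha256(outdir / "dataset" / name)
        for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "cells.tsv")
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    write_run_metadata(
        outdir / "run_metadata.json", config=manifest.get("config", {}), seed=seed
    )
    return manifest
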