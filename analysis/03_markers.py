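"""Marker-pair decision trees on the labeled excitatory neurons.

Fits the best <=2-gene tree over the senescence-associated candidate pool
(panel genes plus planted marker candidates), on raw counts and on
binarized expression, then runs the iterative elimination analysis that
ranks successive next-best marker pairs.

Run after 02_eigengenes_label.py:  python analysis/03_markers.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neurescence import labeling, simulate, trees
from neurescence.io import write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--rounds", type=int, default=3)
    args = ap.parse_args()

    ds = simulate.read_dataset(args.out / "dataset")
    lab_df = pd.read_csv(args.out / "labels.tsv", sep="\t")
    is_exc = ds.cell_meta["cell_type"].to_numpy() == ds.config.senescent_type
    labeled = lab_df["label"].isin([labeling.SENESCENT, labeling.NON_SENESCENT]).to_numpy()
    use = is_exc & labeled
    cm = ds.counts.subset_cells(use)
    y = lab_df["label"].to_numpy(dtype=object)[use]
    print(f"labeled excitatory neurons: {use.sum()} "
          f"({int((y == labeling.SENESCENT).sum())} senescent)")

    pool = sorted(set(g for p in ds.panels for g in p.genes) | set(ds.truth["marker_genes"]))
    rows = []
    for name, cfg in (
        ("raw", trees.TreeConfig(binarize=False, gene_pool=pool, max_thresholds_per_gene=16)),
        ("binary", trees.TreeConfig(binarize=True, gene_pool=pool)),
    ):
        tree = trees.fit_marker_tree(cm, y, cfg)
        tree.save(args.out / f"tree_{name}.json")
        m = tree.training_metrics
        rows.append({"tree": name, "genes": ",".join(tree.genes),
                     "threshold": tree.threshold, "second_threshold": tree.second_threshold,
                     "accuracy": m.accuracy, "sensitivity": m.sensitivity,
                     "specificity": m.specificity, "tp_rate_of_total": m.tp_rate_of_total})
        planted = set(tree.genes) & set(ds.truth["marker_genes"])
        print(f"{name} tree: genes {tree.genes} (planted markers among them: "
              f"{sorted(planted)}), accuracy {m.accuracy:.4f}, "
              f"sensitivity {m.sensitivity:.3f}, specificity {m.specificity:.5f}")
    write_table(pd.DataFrame(rows), args.out / "tree_metrics.tsv")

    ledger = trees.elimination_analysis(
        cm, y, trees.TreeConfig(binarize=True, gene_pool=pool), args.rounds
    )
    lrows = [{"round": r["round"], "excluded": ",".join(r["excluded"]),
              "genes": ",".join(r["tree"].genes),
              "accuracy": r["metrics"].accuracy,
              "sensitivity": r["metrics"].sensitivity,
              "specificity": r["metrics"].specificity} for r in ledger]
    write_table(pd.DataFrame(lrows), args.out / "elimination.tsv")
    print("elimination ledger:")
    print(pd.DataFrame(lrows).to_string(index=False))


if __name__ == "__main__":
    main()
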