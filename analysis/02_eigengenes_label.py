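"""Fit the three panel eigengenes and derive consensus senescence labels.

For each of the three senescence panels the weighted-PCA eigengene is
fitted on log2(CPM+1) expression with cell-type-balancing weights; cells
above mean + 3 s.d. on all three eigengenes are labeled senescent, cells
below all three means non-senescent, everything else borderline. The
script reports label counts, recovery of the planted truth, and the
cell-type enrichment of senescent cells.

Run after 01_simulate.py:  python analysis/02_eigengenes_label.py
"""

import argparse
from pathlib import Path

from neurescence import diffexpr, eigengene, labeling, simulate
from neurescence.io import write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--k-sd", type=float, default=3.0)
    args = ap.parse_args()

    ds = simulate.read_dataset(args.out / "dataset")
    expr = diffexpr.normalize(ds.counts)
    weights = eigengene.compute_cell_weights(ds.cell_meta)

    scores = {}
    for panel in ds.panels:
        model, sc = eigengene.fit_eigengene(expr, panel, weights)
        scores[panel.name] = sc
        model.save(args.out / f"eigengene_{panel.name}")
        write_table(sc.to_frame(), args.out / f"scores_{panel.name}.tsv")
        print(f"{panel.name}: {len(model.used_genes)} genes used")

    thresholds = labeling.derive_thresholds(scores, k_sd=args.k_sd)
    labels = labeling.label_cells(scores, thresholds)
    thresholds.save(args.out / "thresholds.json")
    write_table(labels.to_frame(), args.out / "labels.tsv")
    print(f"label counts: {labels.counts()}")

    truth = ds.true_senescent
    called = labels.labels == labeling.SENESCENT
    print(f"labeling vs planted truth: sensitivity {called[truth].mean():.3f}, "
          f"specificity {1 - called[~truth].mean():.5f}")

    ct = labeling.celltype_enrichment(labels, ds.cell_meta)
    write_table(ct, args.out / "celltype_enrichment.tsv")
    print("cell-type enrichment of senescent cells:")
    print(ct.to_string(index=False))


if __name__ == "__main__":
    main()
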