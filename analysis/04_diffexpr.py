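"""Dual differential expression: hurdle model and EMD permutation test.

Runs both DE procedures on the labeled excitatory neurons (gene filter,
log2(CPM+1) normalization, minority-class upsampling), adjusts both
p-value sets with Benjamini-Hochberg, intersects the calls and scores the
overlap with a hypergeometric test, then measures recovery of the planted
DE genes.

Run after 02_eigengenes_label.py:  python analysis/04_diffexpr.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from neurescence import diffexpr, labeling, simulate
from neurescence.io import write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--profile", choices=["default", "published"], default="default")
    args = ap.parse_args()

    ds = simulate.read_dataset(args.out / "dataset")
    lab_df = pd.read_csv(args.out / "labels.tsv", sep="\t")
    is_exc = ds.cell_meta["cell_type"].to_numpy() == ds.config.senescent_type
    labeled = lab_df["label"].isin([labeling.SENESCENT, labeling.NON_SENESCENT]).to_numpy()
    use = is_exc & labeled
    cm = ds.counts.subset_cells(use)
    y = lab_df["label"].to_numpy(dtype=object)[use]

    base = diffexpr.DEConfig.published_profile() if args.profile == "published" else diffexpr.DEConfig()
    cfg = diffexpr.DEConfig(**{**base.to_dict(), "seed": args.seed})
    res = diffexpr.run_de(cm, y, cfg)
    write_table(res.table, args.out / "de_results.tsv")
    (args.out / "de_summary.json").write_text(
        json.dumps(res.summary, indent=2, default=float) + "\n"
    )

    s = res.summary
    print(f"tested genes: {s['n_tested_genes']} "
          f"(upsampling factor {s['upsample_factor']}x)")
    print(f"hurdle calls: {s['n_called_hurdle']}, EMD calls: {s['n_called_emd']}, "
          f"intersection: {s['n_called_both']}")
    print(f"overlap hypergeometric log10 p: {s['overlap_log10_p']:.1f}")

    called = set(res.called_both)
    de = set(ds.truth["de_genes"])
    if called:
        print(f"recovery of planted DE genes: precision "
              f"{len(called & de) / len(called):.3f}, recall {len(called & de) / len(de):.3f}")


if __name__ == "__main__":
    main()
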