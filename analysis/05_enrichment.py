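"""Pathway over-representation of the DE intersection genes.

Builds the synthetic pathway collection that accompanies the simulated
dataset (background sets plus five senescence-responsive sets seeded with
planted DE genes), tests each set with the upper-tail hypergeometric
statistic against the tested-gene universe, and scores the shared core of
DE genes across the top five sets with the multi-set intersection test.

Run after 04_diffexpr.py:  python analysis/05_enrichment.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from neurescence import enrichment, simulate
from neurescence.io import write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    ds = simulate.read_dataset(args.out / "dataset")
    de_table = pd.read_csv(args.out / "de_results.tsv", sep="\t")
    query = de_table.loc[de_table["called_both"], "gene"].tolist()
    universe = de_table["gene"].tolist()
    if not query:
        raise SystemExit("no DE intersection genes; run 04_diffexpr.py first")

    collection = simulate.synthetic_gene_sets(ds, seed=args.seed)
    enr = enrichment.pathway_enrichment(query, collection, universe)
    write_table(enr, args.out / "enrichment.tsv")
    write_table(enr[["set", "overlap", "adj_p"]], args.out / "enrichment_bubble.tsv")

    n_sig = int((enr["adj_p"] < 0.05).sum())
    print(f"{n_sig} of {len(enr)} sets enriched at adjusted p < 0.05")
    print(enr.head(8).drop(columns="overlap_genes").to_string(index=False))

    top = enr.head(5)
    top_sets = [sorted(set(collection.sets[s]) & set(query)) for s in top["set"]]
    shared = set(top_sets[0])
    for s in top_sets[1:]:
        shared &= set(s)
    p = enrichment.multiset_intersection_test(
        top_sets, universe_size=len(query), observed_intersection=len(shared)
    )
    print(f"top-5 sets share {len(shared)} DE genes "
          f"(multi-set intersection p = {p:.3g})")
    (args.out / "enrichment_summary.json").write_text(json.dumps({
        "n_significant_sets": n_sig,
        "top5_shared_genes": sorted(shared),
        "top5_shared_p": p,
    }, indent=2, default=float) + "\n")


if __name__ == "__main__":
    main()
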