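"""Generate the synthetic discovery dataset.

Draws the default study conditions — 10,000 cells in three cell types of
very unequal abundance, ~1% senescent excitatory neurons, three senescence
gene panels (22/48/125 genes) with coherent upregulation in senescent
cells, four near-binary marker genes and 120 strongly induced DE genes —
and writes the dataset plus ground truth under results/analysis/dataset.

Run:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
from pathlib import Path

from neurescence import simulate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = simulate.SimulationConfig(seed=args.seed)
    ds = simulate.generate_dataset(cfg)
    simulate.write_dataset(ds, args.out / "dataset")

    n_sen = int(ds.true_senescent.sum())
    print(f"dataset: {ds.counts.shape[0]} cells x {ds.counts.shape[1]} genes")
    print(f"cell types: {dict(ds.cell_meta['cell_type'].value_counts())}")
    print(f"planted senescent excitatory neurons: {n_sen}")
    print(f"planted markers: {ds.truth['marker_genes']}")
    print(f"planted DE genes: {len(ds.truth['de_genes'])}")
    print(f"written to {args.out / 'dataset'}")


if __name__ == "__main__":
    main()
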