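#!/usr/bin/env python
"""Consensus differential expression on each training split.

For every dataset: moderated t, NB Wald and NB LRT with age/sex/batch
covariates, intersected at p < 0.05 and |log2FC| > 0.  Prints recovery of
the planted DE genes and the false-discovery proportion.
"""

import argparse
from pathlib import Path

import pandas as pd

from dreg import io
from dreg.de import CountDataset, run_all_de


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/de"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    planted = set(pd.read_csv(args.data / "truth.de_genes.txt")["gene_id"])
    for counts_path in sorted(args.data.glob("DS*.counts.tsv")):
        name = counts_path.name.split(".")[0]
        ds = io.read_dataset(counts_path, args.data / f"{name}.meta.tsv", name)
        split = pd.read_csv(args.data / f"{name}.split.tsv", sep="\t", index_col=0)
        train_cols = split.index[~split["is_test"]]
        train = CountDataset(ds.counts[train_cols], ds.covariates.loc[train_cols], name)
        results, cons = run_all_de(train)
        for r in results:
            r.table.to_csv(args.out / f"{name}.{r.method}.tsv", sep="\t",
                           index_label="gene_id", float_format="%.6g")
        pd.Series(cons.genes).to_csv(args.out / f"{name}.consensus.txt",
                                     index=False, header=["gene_id"])
        got = set(cons.genes)
        print(f"{name}: {len(got)} consensus DEGs | "
              f"recall {len(got & planted) / len(planted):.2f}, "
              f"FDP {len(got - planted) / max(len(got), 1):.2f}")


if __name__ == "__main__":
    main()
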