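#!/usr/bin/env python
"""Hypergeometric enrichment per dataset, shared pathways, candidate pool.

Pathways significant (p < 0.05) in every dataset are intersected; their
members that are consensus DEGs anywhere form the candidate gene pool for
recursive feature elimination.
"""

import argparse
from pathlib import Path

import pandas as pd

from dreg.enrich import GeneSetCollection, candidate_pool, hypergeom_enrich, shared_pathways


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--de", type=Path, default=Path("results/de"))
    ap.add_argument("--out", type=Path, default=Path("results/pool"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    collection = GeneSetCollection.read_gmt(args.data / "pathways.gmt")
    consensus = {
        p.name.split(".")[0]: set(pd.read_csv(p)["gene_id"])
        for p in sorted(args.de.glob("DS*.consensus.txt"))
    }
    results = [
        hypergeom_enrich(genes, collection, set(collection.universe), name)
        for name, genes in consensus.items()
    ]
    for r in results:
        r.table.to_csv(args.out / f"{r.dataset}.enrichment.tsv", sep="\t",
                       float_format="%.6g")
    shared = shared_pathways(results, alpha=0.05)
    pool = candidate_pool(shared, collection, consensus)
    pd.Series(sorted(shared)).to_csv(args.out / "shared_pathways.txt",
                                     index=False, header=["pathway"])
    pd.Series(pool.genes).to_csv(args.out / "pool_genes.txt",
                                 index=False, header=["gene_id"])
    pool.provenance.to_csv(args.out / "pool_provenance.tsv", sep="\t", index=False)

    truth_pw = set(pd.read_csv(args.data / "truth.pathways.txt")["pathway"])
    print(f"{len(shared)} shared pathways "
          f"({len(shared & truth_pw)}/{len(truth_pw)} planted recovered); "
          f"pool of {len(pool.genes)} genes")


if __name__ == "__main__":
    main()
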