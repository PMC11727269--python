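#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes four case/control count datasets (three from the first tissue, one
from the second), the pathway collection, the interactome edge list, the
GWAS panel, per-dataset 7:3 train/test splits, and the planted-truth files
that later steps score themselves against.
"""

import argparse
from pathlib import Path

import pandas as pd

from dreg import io
from dreg.pipeline import stage_seed, stratified_split
from dreg.simulate import SimulationConfig, simulate_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    data = simulate_all(cfg)
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    for ds in data.datasets:
        io.write_dataset(ds, out)
        _, _, mask = stratified_split(ds, 0.3, stage_seed(args.seed, 1))
        pd.Series(mask, index=ds.samples, name="is_test").to_csv(
            out / f"{ds.name}.split.tsv", sep="\t"
        )
    data.collection.write_gmt(out / "pathways.gmt")
    io.write_edges(data.interactome, out / "interactome.tsv")
    io.write_panel(data.panel, out)

    truth = data.truth
    pd.Series(sorted(truth.planted_genes)).to_csv(
        out / "truth.de_genes.txt", index=False, header=["gene_id"])
    pd.Series(sorted(truth.enriched_pathways)).to_csv(
        out / "truth.pathways.txt", index=False, header=["pathway"])
    pd.Series(sorted(truth.module_genes)).to_csv(
        out / "truth.module_genes.txt", index=False, header=["gene_id"])
    pd.Series(truth.causal_snps, name="beta").to_csv(
        out / "truth.causal_snps.tsv", sep="\t", index_label="SNP")

    print(f"{len(data.datasets)} datasets x {cfg.n_genes} genes "
          f"({cfg.n_planted_de} planted DE), {len(data.collection)} pathways "
          f"({len(truth.enriched_pathways)} enriched), "
          f"{data.interactome.number_of_edges()} interactome edges, "
          f"{cfg.n_snps} SNPs ({len(truth.causal_snps)} causal) -> {out}")


if __name__ == "__main__":
    main()
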