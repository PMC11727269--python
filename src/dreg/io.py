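"""Plain-text readers and writers for every pipeline interchange format.

Counts TSV (genes as rows, samples as header), sample-metadata TSV, GMT
(via GeneSetCollection), PPI edge TSV, BED (0-based half-open), GWAS summary
TSV, dosage TSV (SNPs x samples).  Floating-point output uses fixed formats
so identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from dreg.de import CountDataset
from dreg.prs import GwasPanel

__all__ = [
    "write_counts",
    "read_counts",
    "write_metadata",
    "write_dataset",
    "read_dataset",
    "write_edges",
    "write_bed",
    "read_bed",
    "write_summary",
    "read_summary",
    "write_dosages",
    "read_dosages",
]


def write_counts(dataset: CountDataset, path: str | Path) -> None:
    dataset.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_metadata(dataset: CountDataset, path: str | Path) -> None:
    dataset.covariates.to_csv(path, sep="\t", index_label="sample_id")


def write_dataset(dataset: CountDataset, outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cpath = outdir / f"{dataset.name}.counts.tsv"
    mpath = outdir / f"{dataset.name}.meta.tsv"
    write_counts(dataset, cpath)
    write_metadata(dataset, mpath)
    return cpath, mpath


def read_dataset(counts_path: str | Path, meta_path: str | Path, name: str | None = None) -> CountDataset:
    counts = read_counts(counts_path)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    if name is None:
        name = Path(counts_path).name.split(".")[0]
    return CountDataset(counts, meta, name)


def write_edges(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def write_bed(bed: pd.DataFrame, path: str | Path) -> None:
    bed[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str},
    )


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    out = summary.copy()
    for col, fmt in (("BETA", "%.6g"), ("P", "%.6g"), ("MAF", "%.6g"), ("INFO", "%.6g")):
        out[col] = [fmt % v for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", dtype={"CHR": str})


def write_dosages(dosages: pd.DataFrame, path: str | Path) -> None:
    # stored SNPs x samples per convention; in memory samples x SNPs
    dosages.T.to_csv(path, sep="\t", index_label="SNP")


def read_dosages(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="SNP").T


def write_panel(panel: GwasPanel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_summary(panel.summary, outdir / "gwas.summary.tsv")
    write_dosages(panel.dosages, outdir / "gwas.dosages.tsv")
    write_bed(panel.bed, outdir / "genes.bed")
    pheno = pd.DataFrame({"phenotype": panel.phenotype})
    pheno.join(panel.covariates).to_csv(outdir / "gwas.pheno.tsv", sep="\t", index_label="sample_id")
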