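"""Synthetic pipeline inputs with planted ground truth.

Emulates the study design the pipeline is built for: several case/control
RNA-seq count datasets from two tissues sharing a planted set of
differentially expressed genes (negative-binomial counts, age/sex/batch
covariates), a pathway collection whose enriched pathways are seeded with the
planted genes, an interactome with a planted dense subgraph, and a genetics
panel (LD-blocked dosages, liability-threshold phenotype, summary statistics
from an independent training cohort) whose causal SNPs sit near planted
genes.  Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from dreg.de import CountDataset
from dreg.enrich import GeneSetCollection
from dreg.prs import GwasPanel

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedData",
    "generate_counts",
    "generate_gene_sets",
    "generate_interactome",
    "generate_genetics",
    "simulate_all",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Counts: ``n_datasets`` case/control datasets of ``2 * n_samples_per_group``
    samples over ``n_genes`` genes; ``n_planted_de`` genes carry a log2
    fold-change of magnitude ``planted_lfc``.  NB dispersion alpha
    (var = mu + alpha*mu^2) is gene-wise log-uniform in [0.01, 0.5] unless
    ``nb_dispersion`` fixes it.  All but the last dataset belong to the first
    tissue; under the default ``de_sign_mode='tissue'`` the second tissue
    flips the sign of a ``tissue_flip_fraction`` of planted genes.
    """

    n_datasets: int = 4
    n_genes: int = 2000
    n_samples_per_group: int = 50
    n_planted_de: int = 400
    planted_lfc: float = 0.5
    nb_dispersion: float | None = None
    batch_effect_sd: float = 0.15
    # pathways
    n_pathways: int = 60
    pathway_size_range: tuple[int, int] = (10, 60)
    planted_pathway_fraction: float = 0.6
    n_enriched_pathways: int = 12
    # interactome
    interactome_n_edges: int = 16000
    planted_subgraph_density: float = 0.1
    planted_module_density: float = 0.7
    n_module_genes: int = 25
    # genetics
    n_snps: int = 1000
    n_causal_snps: int = 20
    causal_beta_sd: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    seed: int = 0
    # secondary knobs
    de_sign_mode: str = "tissue"  # tissue | shared | independent
    tissue_flip_fraction: float = 0.3
    coexpression_sd: float = 0.2
    age_effect_sd: float = 0.002
    sex_effect_sd: float = 0.05
    depth_sd: float = 0.25
    n_gwas_train: int = 2000
    n_gwas_target: int = 1000
    ld_flip_prob: float = 0.03
    liability_noise_sd: float = 1.0
    prevalence: float = 0.5
    causal_gene_fraction: float = 0.9

    def __post_init__(self) -> None:
        counts = {
            "n_datasets": self.n_datasets,
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_planted_de": self.n_planted_de,
            "n_pathways": self.n_pathways,
            "n_enriched_pathways": self.n_enriched_pathways,
            "interactome_n_edges": self.interactome_n_edges,
            "n_module_genes": self.n_module_genes,
            "n_snps": self.n_snps,
            "ld_block_size": self.ld_block_size,
            "n_gwas_train": self.n_gwas_train,
            "n_gwas_target": self.n_gwas_target,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, value in (
            ("planted_pathway_fraction", self.planted_pathway_fraction),
            ("planted_module_density", self.planted_module_density),
            ("planted_subgraph_density", self.planted_subgraph_density),
        ):
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_planted_de > self.n_genes:
            raise ValueError("n_planted_de exceeds n_genes")
        if not 0 <= self.n_causal_snps <= self.n_snps:
            raise ValueError("n_causal_snps must lie in [0, n_snps]")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway_size_range max exceeds n_genes")
        if self.de_sign_mode not in ("tissue", "shared", "independent"):
            raise ValueError(f"unknown de_sign_mode {self.de_sign_mode!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:06d}" for i in range(self.n_genes)]


@dataclass
class PlantedTruth:
    """What was planted, for downstream recovery checks."""

    de_genes: dict[str, set[str]] = field(default_factory=dict)  # per dataset
    de_signs: dict[str, dict[str, int]] = field(default_factory=dict)
    enriched_pathways: set[str] = field(default_factory=set)
    module_genes: set[str] = field(default_factory=set)
    causal_snps: dict[str, float] = field(default_factory=dict)  # SNP -> beta

    @property
    def planted_genes(self) -> set[str]:
        return set.union(*self.de_genes.values()) if self.de_genes else set()


@dataclass
class SimulatedData:
    config: SimulationConfig
    datasets: list[CountDataset]
    truth: PlantedTruth
    collection: GeneSetCollection
    interactome: nx.Graph
    panel: GwasPanel


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one independent child stream per component, derived from the master seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# --------------------------------------------------------------------------
# Counts
# --------------------------------------------------------------------------

def generate_counts(
    config: SimulationConfig,
) -> tuple[list[CountDataset], PlantedTruth]:
    """NB count datasets with planted DE genes and age/sex/batch covariates.

    Planted genes shift the group log2 mean by ``planted_lfc`` (sign policy
    per ``de_sign_mode``); batch B2 shifts log-means by N(0, batch_effect_sd^2)
    per gene; ages and sexes act through small gene-wise coefficients.
    """
    rng = _rng(config, 1)
    genes = config.gene_ids
    g = config.n_genes
    planted_idx = np.sort(rng.choice(g, size=config.n_planted_de, replace=False))
    planted = [genes[i] for i in planted_idx]

    log_base = rng.normal(np.log(50.0), 1.5, size=g)
    # planted "essential" genes are solidly expressed so the low-expression
    # filter cannot silently remove the signal the benchmark measures
    log_base[planted_idx] = np.maximum(log_base[planted_idx], np.log(20.0))
    if config.nb_dispersion is None:
        alpha = np.exp(rng.uniform(np.log(0.01), np.log(0.5), size=g))
    else:
        alpha = np.full(g, float(config.nb_dispersion))
    age_coef = rng.normal(0.0, config.age_effect_sd, size=g)
    sex_coef = rng.normal(0.0, config.sex_effect_sd, size=g)

    base_sign = rng.choice([-1.0, 1.0], size=config.n_planted_de)
    flip_mask = rng.random(config.n_planted_de) < config.tissue_flip_fraction

    datasets: list[CountDataset] = []
    truth = PlantedTruth()
    n = 2 * config.n_samples_per_group
    for d in range(config.n_datasets):
        name = f"DS{d + 1}"
        tissue = "tissueA" if d < config.n_datasets - 1 else "tissueB"
        if config.de_sign_mode == "shared":
            sign = base_sign
        elif config.de_sign_mode == "independent":
            sign = rng.choice([-1.0, 1.0], size=config.n_planted_de)
        else:  # tissue-consistent, partial flip in the second tissue
            sign = np.where(flip_mask, -base_sign, base_sign) if tissue == "tissueB" else base_sign

        pheno = np.repeat([1.0, 0.0], config.n_samples_per_group)
        age = rng.uniform(20.0, 70.0, size=n)
        male = rng.random(n) < 0.5
        batch2 = rng.random(n) < 0.5
        depth = rng.normal(0.0, config.depth_sd, size=n)
        batch_coef = rng.normal(0.0, config.batch_effect_sd, size=g)
        # planted genes form one co-expressed program: a per-sample latent
        # activity loading on each gene with the same sign as its disease
        # effect (up-genes co-rise, down-genes co-fall).  Shared noise
        # collinear with the signal caps how separable any classifier built
        # on these genes can be, as in real transcriptomes.
        latent = rng.normal(0.0, config.coexpression_sd, size=n)

        log_mu = (
            log_base[:, None]
            + depth[None, :]
            + age_coef[:, None] * (age - 45.0)[None, :]
            + sex_coef[:, None] * male[None, :]
            + batch_coef[:, None] * batch2[None, :]
        )
        log_mu[planted_idx, :] += sign[:, None] * latent[None, :]
        effect = np.zeros(g)
        effect[planted_idx] = sign * config.planted_lfc * np.log(2.0)
        log_mu = log_mu + effect[:, None] * pheno[None, :]
        mu = np.exp(log_mu)
        size = 1.0 / alpha
        counts = rng.negative_binomial(size[:, None], size[:, None] / (size[:, None] + mu))

        samples = [f"{name}_S{j:03d}" for j in range(n)]
        covars = pd.DataFrame(
            {
                "phenotype": np.where(pheno == 1.0, "case", "control"),
                "age": np.round(age, 1),
                "sex": np.where(male, "M", "F"),
                "batch": np.where(batch2, "B2", "B1"),
                "dataset": name,
                "tissue": tissue,
            },
            index=samples,
        )
        datasets.append(
            CountDataset(pd.DataFrame(counts, index=genes, columns=samples), covars, name)
        )
        truth.de_genes[name] = set(planted)
        truth.de_signs[name] = {genes[i]: int(s) for i, s in zip(planted_idx, sign)}
    return datasets, truth


# --------------------------------------------------------------------------
# Gene sets
# --------------------------------------------------------------------------

def generate_gene_sets(
    config: SimulationConfig, truth: PlantedTruth
) -> GeneSetCollection:
    """Pathway collection whose enriched pathways carry the planted genes.

    The planted genes are distributed round-robin over the enriched pathways
    (every planted gene is covered), topped up with random non-planted genes
    so that the planted fraction equals ``planted_pathway_fraction``; the
    remaining pathways sample member genes uniformly.
    """
    rng = _rng(config, 2)
    genes = np.array(config.gene_ids)
    planted = sorted(truth.planted_genes)
    if not planted:
        raise ValueError("truth has no planted DE genes")
    others = np.array(sorted(set(genes) - set(planted)))
    lo, hi = config.pathway_size_range
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    n_enr = min(config.n_enriched_pathways, config.n_pathways)
    for i in range(n_enr):
        chunk = planted[i::n_enr]
        size = max(lo, math.ceil(len(chunk) / config.planted_pathway_fraction))
        n_fill = min(size - len(chunk), len(others))
        fill = rng.choice(others, size=n_fill, replace=False) if n_fill else []
        name = f"PW{i:04d}"
        sets[name] = ("planted-enriched pathway", frozenset(chunk) | frozenset(fill))
        truth.enriched_pathways.add(name)
    for i in range(n_enr, config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"PW{i:04d}"] = ("background pathway", frozenset(members))
    return GeneSetCollection(sets, frozenset(genes))


# --------------------------------------------------------------------------
# Interactome
# --------------------------------------------------------------------------

def generate_interactome(config: SimulationConfig, truth: PlantedTruth) -> nx.Graph:
    """Erdos-Renyi background plus a planted dense subgraph.

    All planted DE genes are wired with edge probability
    ``planted_subgraph_density`` (the disease genes interact more than
    chance); a smaller module core (``n_module_genes`` of them) is wired at
    the higher ``planted_module_density``.  Uniform background edges are then
    added until ``interactome_n_edges`` is reached.  Simple, undirected,
    loop-free.
    """
    rng = _rng(config, 3)
    genes = config.gene_ids
    g = config.n_genes
    max_edges = g * (g - 1) // 2
    if config.interactome_n_edges > max_edges:
        raise ValueError(
            f"requested {config.interactome_n_edges} edges exceeds simple-graph "
            f"maximum {max_edges}"
        )
    planted = sorted(truth.planted_genes)
    k = min(config.n_module_genes, len(planted))
    module = sorted(rng.choice(np.array(planted), size=k, replace=False))
    truth.module_genes = set(module)

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    module_set = set(module)
    # heavy-tailed connectivity propensities give the planted subgraph the
    # hub structure typical of protein-interaction networks
    w = rng.pareto(2.5, size=len(planted)) + 0.5
    w = w / w.mean()
    for i in range(len(planted)):
        for j in range(i + 1, len(planted)):
            in_core = planted[i] in module_set and planted[j] in module_set
            p_edge = (
                config.planted_module_density if in_core
                else min(1.0, config.planted_subgraph_density * w[i] * w[j])
            )
            if rng.random() < p_edge:
                graph.add_edge(planted[i], planted[j])
    if graph.number_of_edges() > config.interactome_n_edges:
        raise ValueError(
            "planted subgraph alone exceeds interactome_n_edges; "
            "raise the edge budget or lower the planted densities"
        )
    while graph.number_of_edges() < config.interactome_n_edges:
        need = config.interactome_n_edges - graph.number_of_edges()
        a = rng.integers(0, g, size=2 * need + 16)
        b = rng.integers(0, g, size=2 * need + 16)
        for x, y in zip(a, b):
            if x == y:
                continue
            graph.add_edge(genes[x], genes[y])
            if graph.number_of_edges() >= config.interactome_n_edges:
                break
    return graph


# --------------------------------------------------------------------------
# Genetics
# --------------------------------------------------------------------------

_SAFE_ALLELES = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_ALLELES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _gene_bed(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic gene coordinates: genes tiled over 22 chromosomes,
    200 kb apart, 5 kb long (0-based half-open)."""
    per_chrom = math.ceil(config.n_genes / 22)
    rows = []
    for i, gene in enumerate(config.gene_ids):
        chrom = i // per_chrom + 1
        start = 50_000 + (i % per_chrom) * 200_000
        rows.append((str(chrom), start, start + 5_000, gene))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def _block_dosages(
    rng: np.random.Generator, n: int, size: int, f: float, flip: float
) -> np.ndarray:
    """LD block: a latent haplotype copied to each SNP with small flip
    probability, two haplotypes per sample; dosage in {0, 1, 2}."""
    latent = rng.random((n, 2)) < f
    out = np.empty((n, size), dtype=np.int8)
    for s in range(size):
        flips = rng.random((n, 2)) < flip
        out[:, s] = (latent ^ flips).sum(axis=1)
    return out


def _per_snp_logistic(d: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP logistic regression (intercept + dosage).

    Returns (beta, p) Wald statistics for every SNP column at once.
    """
    n, s = d.shape
    a = np.zeros(s)
    b = np.zeros(s)
    yc = y[:, None]
    for _ in range(25):
        eta = np.clip(a[None, :] + d * b[None, :], -30, 30)
        mu = special.expit(eta)
        w = mu * (1 - mu) + 1e-12
        r = yc - mu
        g1 = r.sum(axis=0)
        g2 = (d * r).sum(axis=0)
        h11 = w.sum(axis=0)
        h12 = (w * d).sum(axis=0)
        h22 = (w * d * d).sum(axis=0)
        det = h11 * h22 - h12 * h12
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-10:
            break
    eta = np.clip(a[None, :] + d * b[None, :], -30, 30)
    mu = special.expit(eta)
    w = mu * (1 - mu) + 1e-12
    h11 = w.sum(axis=0)
    h12 = (w * d).sum(axis=0)
    h22 = (w * d * d).sum(axis=0)
    det = np.maximum(h11 * h22 - h12 * h12, 1e-12)
    se = np.sqrt(h11 / det)
    p = 2.0 * stats.norm.sf(np.abs(b / se))
    return b, p


def generate_genetics(config: SimulationConfig, truth: PlantedTruth) -> GwasPanel:
    """LD-blocked dosages, liability-threshold phenotype, summary statistics.

    SNPs come in blocks of ``ld_block_size`` correlated dosages anchored at
    gene positions; ``causal_gene_fraction`` of the causal SNPs sit inside a
    planted gene (the rest are intergenic).  Summary statistics (per-SNP
    logistic regression) come from an independent training cohort, so there
    is no sample overlap with the target cohort.  Causal SNPs are generated
    non-palindromic and well-imputed so the planted signal survives standard
    QC.
    """
    rng = _rng(config, 4)
    bed = _gene_bed(config)
    gene_pos = bed.set_index("gene_id")
    planted = sorted(truth.planted_genes)
    n_blocks = math.ceil(config.n_snps / config.ld_block_size)
    n_causal = config.n_causal_snps
    if n_causal > n_blocks:
        raise ValueError("need at least one LD block per causal SNP")
    n_near = int(round(config.causal_gene_fraction * n_causal))
    causal_genes = list(rng.choice(np.array(planted), size=min(n_near, len(planted)), replace=False))

    lo, hi = config.maf_range
    snp_rows = []  # (snp, chrom, bp, block, causal)
    block_specs = []  # (chrom, center, f, causal_flag)
    all_genes = bed["gene_id"].to_numpy()
    for blk in range(n_blocks):
        if blk < len(causal_genes):
            row = gene_pos.loc[causal_genes[blk]]
            chrom, center = row["chrom"], (int(row["start"]) + int(row["end"])) // 2
            causal_flag = True
            f = rng.uniform(max(lo, 0.1), hi)
        elif blk < n_causal:
            # intergenic causal block, midway between two gene slots
            chrom = str(int(rng.integers(1, 23)))
            center = int(rng.integers(150_000, 10_000_000))
            causal_flag = True
            f = rng.uniform(max(lo, 0.1), hi)
        else:
            anchor = gene_pos.loc[all_genes[int(rng.integers(0, len(all_genes)))]]
            chrom, center = anchor["chrom"], (int(anchor["start"]) + int(anchor["end"])) // 2
            causal_flag = False
            f = rng.uniform(lo, hi)
        block_specs.append((chrom, center, f, causal_flag))

    spacing = 1_500
    snp_id = 0
    block_of: list[int] = []
    causal_snp_ids: list[str] = []
    for blk, (chrom, center, f, causal_flag) in enumerate(block_specs):
        size = min(config.ld_block_size, config.n_snps - blk * config.ld_block_size)
        if size <= 0:
            break
        start = center - (size // 2) * spacing
        mid = size // 2
        for s in range(size):
            name = f"rsS{snp_id:06d}"
            snp_rows.append((name, chrom, max(start + s * spacing, 1), blk))
            if causal_flag and s == mid:
                causal_snp_ids.append(name)
            block_of.append(blk)
            snp_id += 1
    snp_df = pd.DataFrame(snp_rows, columns=["SNP", "CHR", "BP", "block"])
    n_snps = len(snp_df)

    def cohort(n: int) -> np.ndarray:
        d = np.empty((n, n_snps), dtype=np.int8)
        for blk, (chrom, center, f, _) in enumerate(block_specs):
            cols = np.flatnonzero(snp_df["block"].to_numpy() == blk)
            if cols.size == 0:
                continue
            d[:, cols] = _block_dosages(rng, n, cols.size, f, config.ld_flip_prob)
        return d

    d_train = cohort(config.n_gwas_train)
    d_target = cohort(config.n_gwas_target)

    betas = rng.normal(0.0, config.causal_beta_sd, size=len(causal_snp_ids))
    causal_cols = [snp_df.index[snp_df["SNP"] == s][0] for s in causal_snp_ids]
    truth.causal_snps = dict(zip(causal_snp_ids, betas.tolist()))

    def liability_pheno(d: np.ndarray) -> np.ndarray:
        gcomp = (d[:, causal_cols] - d[:, causal_cols].mean(axis=0)) @ betas
        liab = gcomp + rng.normal(0.0, config.liability_noise_sd, size=d.shape[0])
        thresh = np.quantile(liab, 1.0 - config.prevalence)
        return (liab > thresh).astype(int)

    y_train = liability_pheno(d_train)
    y_target = liability_pheno(d_target)

    beta_hat, pvals = _per_snp_logistic(d_train.astype(float), y_train.astype(float))
    maf = d_train.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1.0 - maf)

    is_causal = snp_df["SNP"].isin(causal_snp_ids).to_numpy()
    a_idx = rng.integers(0, len(_SAFE_ALLELES), size=n_snps)
    pal = (~is_causal) & (rng.random(n_snps) < 0.15)
    p_idx = rng.integers(0, len(_PALINDROMIC_ALLELES), size=n_snps)
    a1 = np.where(pal, [ _PALINDROMIC_ALLELES[i][0] for i in p_idx],
                  [_SAFE_ALLELES[i][0] for i in a_idx])
    a2 = np.where(pal, [ _PALINDROMIC_ALLELES[i][1] for i in p_idx],
                  [_SAFE_ALLELES[i][1] for i in a_idx])
    info = np.where(is_causal, rng.uniform(0.6, 1.0, n_snps), rng.uniform(0.3, 1.0, n_snps))

    summary = pd.DataFrame(
        {
            "SNP": snp_df["SNP"],
            "CHR": snp_df["CHR"],
            "BP": snp_df["BP"],
            "A1": a1,
            "A2": a2,
            "BETA": beta_hat,
            "P": pvals,
            "MAF": maf,
            "INFO": info,
        }
    )
    samples = [f"T{j:05d}" for j in range(config.n_gwas_target)]
    dosages = pd.DataFrame(d_target, index=samples, columns=snp_df["SNP"].tolist())
    covars = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=config.n_gwas_target),
            "PC1": rng.normal(size=config.n_gwas_target),
            "PC2": rng.normal(size=config.n_gwas_target),
            "PC3": rng.normal(size=config.n_gwas_target),
        },
        index=samples,
    )
    return GwasPanel(
        summary=summary,
        dosages=dosages,
        phenotype=pd.Series(y_target, index=samples),
        covariates=covars,
        bed=bed,
        geno_alleles=summary.set_index("SNP")[["A1", "A2"]].copy(),
    )


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Generate every pipeline input under a single master seed."""
    datasets, truth = generate_counts(config)
    collection = generate_gene_sets(config, truth)
    graph = generate_interactome(config, truth)
    panel = generate_genetics(config, truth)
    return SimulatedData(config, datasets, truth, collection, graph, panel)
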