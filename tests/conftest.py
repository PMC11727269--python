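import numpy as np
import pandas as pd
import pytest

from dreg.de import CountDataset
from dreg.simulate import SimulationConfig


def make_dataset(
    counts: np.ndarray,
    phenotype: list[str] | None = None,
    seed: int = 0,
    name: str = "toy",
    **covars,
) -> CountDataset:
    """Wrap a raw count array into a CountDataset with simple covariates."""
    rng = np.random.default_rng(seed)
    g, n = counts.shape
    if phenotype is None:
        phenotype = ["case"] * (n // 2) + ["control"] * (n - n // 2)
    samples = [f"{name}_S{j:03d}" for j in range(n)]
    meta = pd.DataFrame(
        {
            "phenotype": phenotype,
            "age": covars.get("age", rng.uniform(20, 70, n).round(1)),
            "sex": covars.get("sex", np.where(rng.random(n) < 0.5, "M", "F")),
            "batch": covars.get("batch", np.where(rng.random(n) < 0.5, "B1", "B2")),
        },
        index=samples,
    )
    genes = [f"G{i:06d}" for i in range(g)]
    return CountDataset(pd.DataFrame(counts, index=genes, columns=samples), meta, name)


def simulate_counts(
    g: int, n: int, mu: float = 100.0, alpha: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Plain NB counts, no covariate structure."""
    rng = np.random.default_rng(seed)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu), size=(g, n))


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A fast, small-but-complete simulation configuration."""
    return SimulationConfig(
        n_datasets=2,
        n_genes=300,
        n_samples_per_group=25,
        n_planted_de=60,
        n_pathways=15,
        n_enriched_pathways=4,
        pathway_size_range=(8, 40),
        interactome_n_edges=2500,
        n_module_genes=10,
        n_snps=200,
        n_causal_snps=6,
        n_gwas_train=500,
        n_gwas_target=300,
        seed=7,
    )
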