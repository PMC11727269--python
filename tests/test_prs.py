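"""C+T polygenic scoring: QC, clumping, gene-set restriction, association."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from dreg.prs import (
    DEFAULT_THRESHOLDS,
    GwasPanel,
    clump,
    logit_irls,
    qc_filter,
    raw_scores,
    restrict_to_gene_set,
    score_and_associate,
)
from dreg.simulate import SimulationConfig, generate_counts, generate_genetics


def _summary(rows: list[dict]) -> pd.DataFrame:
    base = {"CHR": "1", "BP": 1000, "A1": "A", "A2": "G",
            "BETA": 0.1, "P": 0.01, "MAF": 0.3, "INFO": 0.9}
    return pd.DataFrame([{**base, **r} for r in rows])


# -- QC --------------------------------------------------------------------

def test_qc_filter_rules():
    s = _summary([
        {"SNP": "s1", "MAF": 0.04},             # rare -> out
        {"SNP": "s2", "A1": "A", "A2": "T"},    # palindromic -> out
        {"SNP": "s3", "INFO": 0.4},             # poorly imputed -> out
        {"SNP": "s4", "MAF": 0.30, "INFO": 0.9, "A1": "A", "A2": "G"},  # keeps
    ])
    out = qc_filter(s)
    assert list(out["SNP"]) == ["s4"]
    assert out.attrs["excluded"] == {"maf": 1, "info": 1, "palindromic": 1}
    with pytest.raises(ValueError, match="INFO"):
        qc_filter(s.drop(columns=["INFO"]))


# -- clumping --------------------------------------------------------------

def _panel_dosages(r2: float, n: int = 400, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    a = rng.binomial(2, 0.4, n).astype(float)
    noise = rng.binomial(2, 0.4, n).astype(float)
    w = np.sqrt(r2)
    b = w * a + (1 - w) * noise  # correlated companion
    return pd.DataFrame({"s1": a, "s2": b})


def test_clump_keeps_best_of_correlated_pair_and_all_independent():
    s = _summary([
        {"SNP": "s1", "BP": 1000, "P": 1e-8},
        {"SNP": "s2", "BP": 11000, "P": 1e-6},
    ])
    high_ld = _panel_dosages(0.95)
    assert clump(s, high_ld) == ["s1"]
    rng = np.random.default_rng(1)
    no_ld = pd.DataFrame({
        "s1": rng.binomial(2, 0.4, 500).astype(float),
        "s2": rng.binomial(2, 0.4, 500).astype(float),
    })
    assert clump(s, no_ld) == ["s1", "s2"]


def test_clump_twenty_snp_fixture_posthoc_verification():
    """No retained pair violates (window, r2) and every removed SNP is
    explained by a better retained index within the window."""
    rng = np.random.default_rng(2)
    n, m = 500, 20
    blocks = rng.binomial(2, 0.35, size=(n, 5)).astype(float)
    dos = {}
    rows = []
    for j in range(m):
        blk = j // 4
        noise = rng.binomial(2, 0.35, n)
        d = np.where(rng.random(n) < 0.8, blocks[:, blk], noise).astype(float)
        dos[f"s{j}"] = d
        rows.append({"SNP": f"s{j}", "BP": 1000 + j * 50_000,
                     "P": float(rng.uniform(1e-8, 0.5))})
    dosages = pd.DataFrame(dos)
    summary = _summary(rows)
    window_kb, r2_max = 250.0, 0.1
    kept = clump(summary, dosages, window_kb, r2_max)

    bp = summary.set_index("SNP")["BP"]
    pv = summary.set_index("SNP")["P"]
    corr = dosages.corr() ** 2
    for a in kept:
        for b in kept:
            if a != b and abs(bp[a] - bp[b]) <= window_kb * 1000:
                assert corr.loc[a, b] <= r2_max
    for snp in set(summary["SNP"]) - set(kept):
        explained = any(
            pv[idx] <= pv[snp]
            and abs(bp[idx] - bp[snp]) <= window_kb * 1000
            and corr.loc[idx, snp] > r2_max
            for idx in kept
        )
        assert explained, f"{snp} removed without a qualifying index SNP"


# -- gene-set restriction --------------------------------------------------

def test_restrict_interval_arithmetic():
    bed = pd.DataFrame({"chrom": ["1"], "start": [1000], "end": [2000], "gene_id": ["G1"]})
    s = _summary([{"SNP": "edge", "BP": 990}, {"SNP": "inside", "BP": 1500}])
    assert list(restrict_to_gene_set(s, bed, flank_bp=10)["SNP"]) == ["inside"]
    assert list(restrict_to_gene_set(s, bed, flank_bp=11)["SNP"]) == ["edge", "inside"]
    # a SNP in the gene body is kept at any flank
    assert "inside" in set(restrict_to_gene_set(s, bed, flank_bp=0)["SNP"])
    with pytest.raises(ValueError, match="empty gene annotation"):
        restrict_to_gene_set(s, bed, genes={"not_there"})


def test_restrict_normalizes_chromosome_names():
    bed = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5000], "gene_id": ["G1"]})
    s = _summary([{"SNP": "x", "BP": 100, "CHR": "1"}])
    assert list(restrict_to_gene_set(s, bed)["SNP"]) == ["x"]


# -- scoring and association ----------------------------------------------

def _toy_panel(seed: int = 0, n: int = 300, n_snps: int = 30) -> GwasPanel:
    rng = np.random.default_rng(seed)
    snps = [f"s{j}" for j in range(n_snps)]
    dosages = pd.DataFrame(
        rng.binomial(2, 0.3, size=(n, n_snps)).astype(float),
        columns=snps, index=[f"i{k}" for k in range(n)],
    )
    beta = rng.normal(0, 0.3, n_snps)
    liab = (dosages - dosages.mean()) @ beta + rng.normal(0, 1, n)
    y = (liab > liab.median()).astype(int)
    summary = _summary([
        {"SNP": s, "BP": 1000 + j * 1000, "BETA": beta[j],
         "P": float(rng.uniform(1e-6, 0.5))}
        for j, s in enumerate(snps)
    ])
    covars = pd.DataFrame({"sex": rng.integers(0, 2, n)}, index=dosages.index)
    bed = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10_000], "gene_id": ["G1"]})
    return GwasPanel(summary, dosages, pd.Series(y.to_numpy(), index=dosages.index),
                     covars, bed, summary.set_index("SNP")[["A1", "A2"]].copy())


def test_raw_score_arithmetic():
    panel = _toy_panel()
    s = panel.summary.iloc[:1].copy()
    s.loc[:, "BETA"] = 0.5
    s.loc[:, "P"] = 0.001
    dosages = panel.dosages[["s0"]].copy()
    dosages.iloc[0, 0] = 2.0
    dosages.iloc[1, 0] = 0.0
    panel2 = GwasPanel(s, dosages, panel.phenotype,
                       panel.covariates, panel.bed,
                       s.set_index("SNP")[["A1", "A2"]])
    raw, counts = raw_scores(panel2, ["s0"], [0.01])
    assert raw.iloc[0, 0] == pytest.approx(1.0)
    assert raw.iloc[1, 0] == pytest.approx(0.0)
    assert counts == [1]


def test_snp_counts_monotone_in_threshold():
    panel = _toy_panel(3)
    res = score_and_associate(panel, list(panel.summary["SNP"]),
                              DEFAULT_THRESHOLDS, n_permutations=20, seed=0)
    counts = res.per_threshold["n_snps"].to_numpy()
    assert (np.diff(counts) >= 0).all()


def test_allele_flip_with_negated_beta_is_invariant():
    panel = _toy_panel(4)
    res1 = score_and_associate(panel, list(panel.summary["SNP"]),
                               [0.5, 1.0], n_permutations=50, seed=1)
    flipped = panel.summary.copy()
    flip_rows = flipped.index[::2]
    flipped.loc[flip_rows, ["A1", "A2"]] = flipped.loc[flip_rows, ["A2", "A1"]].to_numpy()
    flipped.loc[flip_rows, "BETA"] = -flipped.loc[flip_rows, "BETA"]
    panel2 = GwasPanel(flipped, panel.dosages, panel.phenotype,
                       panel.covariates, panel.bed, panel.geno_alleles)
    res2 = score_and_associate(panel2, list(panel.summary["SNP"]),
                               [0.5, 1.0], n_permutations=50, seed=1)
    pd.testing.assert_series_equal(res1.best_scores, res2.best_scores, atol=1e-10)
    assert res1.best_pvalue == pytest.approx(res2.best_pvalue, rel=1e-8)
    assert res1.empirical_pvalue == res2.empirical_pvalue


def test_logit_irls_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(5)
    n = 400
    x = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    y = (special.expit(x @ [0.2, 0.8, -0.5]) > rng.random(n)).astype(float)
    beta, cov, ll, converged = logit_irls(x, y)
    ref = sm.Logit(y, x).fit(disp=0)
    assert converged
    assert np.allclose(beta, ref.params, atol=1e-6)
    assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, atol=1e-5)
    assert ll == pytest.approx(ref.llf, abs=1e-6)


def test_geneset_snps_subset_of_genomewide_and_empirical_formula():
    cfg = SimulationConfig(
        n_genes=300, n_planted_de=60, n_samples_per_group=20, n_datasets=2,
        n_snps=200, n_causal_snps=6, n_gwas_train=500, n_gwas_target=300, seed=3,
    )
    _, truth = generate_counts(cfg)
    panel = generate_genetics(cfg, truth)
    qcd = qc_filter(panel.summary)
    index_snps = clump(qcd, panel.dosages)
    restricted = restrict_to_gene_set(qcd[qcd["SNP"].isin(index_snps)], panel.bed,
                                      genes=truth.planted_genes)
    assert set(restricted["SNP"]) <= set(index_snps)
    res = score_and_associate(panel, restricted["SNP"].tolist(),
                              n_permutations=99, seed=2)
    # the empirical p always uses the add-one estimator
    assert res.empirical_pvalue * 100 == pytest.approx(round(res.empirical_pvalue * 100))
    assert 1 / 100 <= res.empirical_pvalue <= 1.0
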