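"""Differential-expression statistics against closed forms and oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dreg.de import (
    CountDataset,
    DEResult,
    consensus_degs,
    design_matrix,
    filter_low_expression,
    median_ratio_size_factors,
    moderated_t_test,
    nb_lrt_test,
    nb_wald_test,
    normalized_cpm,
    run_all_de,
    tmm_factors,
)
from dreg.simulate import SimulationConfig, generate_counts

from conftest import make_dataset, simulate_counts


# -- size factors ----------------------------------------------------------

def test_size_factors_constant_ratio_closed_form():
    """Sample2 = 2 x sample1 exactly -> factors (1/sqrt(2), sqrt(2))."""
    c1 = np.array([10, 20, 30, 40, 50])
    counts = np.column_stack([c1, 2 * c1])
    f = median_ratio_size_factors(counts)
    assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)


def test_size_factors_identity_and_brute_force():
    counts = np.tile(np.arange(1, 31)[:, None], (1, 4))
    assert np.allclose(median_ratio_size_factors(counts), 1.0)

    rng = np.random.default_rng(3)
    y = rng.integers(0, 400, size=(50, 4)).astype(float)
    y[0] += 1  # guarantee one all-nonzero gene
    # independent median-of-ratios re-implementation
    nz = np.all(y > 0, axis=1)
    ref = np.exp(np.mean(np.log(y[nz]), axis=1))
    expected = np.array([np.median(y[nz, j] / ref) for j in range(4)])
    expected /= np.exp(np.mean(np.log(expected)))
    assert np.allclose(median_ratio_size_factors(y), expected, atol=1e-12)


def test_size_factors_require_an_all_nonzero_gene():
    y = np.array([[0, 5], [5, 0]], dtype=float)
    with pytest.raises(ValueError, match="nonzero"):
        median_ratio_size_factors(y)


def test_tmm_identity_on_identical_samples():
    counts = np.tile(simulate_counts(200, 1, seed=5), (1, 6))
    assert np.allclose(tmm_factors(counts), 1.0)


# -- moderated t -----------------------------------------------------------

def test_moderated_t_zero_prior_equals_ordinary_t():
    ds = make_dataset(simulate_counts(60, 40, seed=1))
    res = moderated_t_test(ds, prior_df=0.0)
    # ordinary OLS t computed independently
    x, _ = design_matrix(ds.covariates)
    counts = filter_low_expression(ds.counts)
    e = np.log2(normalized_cpm(counts) + 0.5)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = e @ x @ xtx_inv
    resid = e - beta @ x.T
    df = x.shape[0] - x.shape[1]
    s2 = (resid**2).sum(axis=1) / df
    t_ord = beta[:, 1] / np.sqrt(xtx_inv[1, 1] * s2)
    assert np.allclose(res.table["stat"].to_numpy(), t_ord, atol=1e-10)
    p_ord = 2 * stats.t.sf(np.abs(t_ord), df)
    assert np.allclose(res.table["pvalue"].to_numpy(), p_ord, atol=1e-10)


def test_moderated_t_all_zero_gene_excluded():
    counts = simulate_counts(30, 30, seed=2)
    counts[4] = 0
    ds = make_dataset(counts)
    res = moderated_t_test(ds)
    assert "G000004" not in res.table.index  # filtered before testing


def test_rank_deficient_design_names_columns():
    ds = make_dataset(simulate_counts(20, 20, seed=3), sex=["M"] * 20, batch=["B1"] * 10 + ["B2"] * 10)
    cov = ds.covariates.copy()
    cov["batch"] = np.where(cov["phenotype"] == "case", "B1", "B2")  # batch == phenotype
    with pytest.raises(ValueError, match="batch"):
        design_matrix(cov)


# -- NB GLM tests ----------------------------------------------------------

def test_nb_wald_poisson_limit_matches_statsmodels():
    """With dispersion forced to ~0 the Wald statistic is the Poisson GLM one."""
    sm = pytest.importorskip("statsmodels.api")
    ds = make_dataset(simulate_counts(10, 60, mu=80, alpha=0.0001, seed=4))
    res = nb_wald_test(ds, dispersion=1e-8)
    x, _ = design_matrix(ds.covariates)
    counts = filter_low_expression(ds.counts)
    sf = median_ratio_size_factors(counts)
    offset = np.log(sf)
    for gene in counts.index:
        y = counts.loc[gene].to_numpy(dtype=float)
        fit = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
        z_ref = fit.params[1] / fit.bse[1]
        assert res.table.loc[gene, "stat"] == pytest.approx(z_ref, abs=1e-6)


def test_nb_wald_group_swap_symmetry():
    ds = make_dataset(simulate_counts(40, 40, seed=5))
    swapped_pheno = ["control" if p == "case" else "case" for p in ds.covariates["phenotype"]]
    cov2 = ds.covariates.copy()
    cov2["phenotype"] = swapped_pheno
    ds2 = CountDataset(ds.counts, cov2, "swapped")
    r1, r2 = nb_wald_test(ds), nb_wald_test(ds2)
    assert np.allclose(r1.table["log2fc"], -r2.table["log2fc"], atol=1e-8)
    assert np.allclose(r1.table["pvalue"], r2.table["pvalue"], atol=1e-10, equal_nan=True)


def test_nb_wald_lfc_matches_plugin_estimator():
    """Balanced two-group, large n: log2FC ~ log2 of normalized group means."""
    rng = np.random.default_rng(6)
    n = 600
    mu = np.where(np.arange(n) < n // 2, 160.0, 100.0)
    counts = rng.negative_binomial(10, 10 / (10 + mu), size=(25, n))
    ds = make_dataset(counts)
    ds = CountDataset(ds.counts, ds.covariates[["phenotype"]], "plain")
    res = nb_wald_test(ds)
    sf = median_ratio_size_factors(filter_low_expression(ds.counts))
    norm = filter_low_expression(ds.counts).to_numpy() / sf
    plugin = np.log2(norm[:, : n // 2].mean(axis=1) / norm[:, n // 2 :].mean(axis=1))
    assert np.abs(res.table["log2fc"].to_numpy() - plugin).max() < 0.05


def test_nb_lrt_close_to_wald_and_nested_identity():
    ds = make_dataset(simulate_counts(50, 50, seed=7))
    rw = nb_wald_test(ds)
    rl = nb_lrt_test(ds)
    ok = rw.table["pvalue"].notna() & rl.table["pvalue"].notna()
    ratio = np.log10(rw.table.loc[ok, "pvalue"] / rl.table.loc[ok, "pvalue"])
    # asymptotic equivalence: agree within an order of magnitude
    assert np.abs(ratio).max() < 1.0


# -- consensus -------------------------------------------------------------

def _fake_result(sig: dict[str, float], universe: list[str], method: str) -> DEResult:
    table = pd.DataFrame(
        {
            "log2fc": [sig.get(g, (0.0, 0.0))[0] if g in sig else 0.0 for g in universe],
            "stat": 0.0,
            "pvalue": [sig[g][1] if g in sig else 0.9 for g in universe],
            "base_mean": 1.0,
        },
        index=universe,
    )
    return DEResult(table, method, "toy")


def test_consensus_is_set_intersection():
    uni = list("abcde")
    mk = lambda genes: _fake_result({g: (1.0, 0.01) for g in genes}, uni, "m")
    cons = consensus_degs([mk("abc"), mk("bcd"), mk("bc")])
    assert cons.genes == ["b", "c"]
    empty = consensus_degs([mk("abc"), mk(""), mk("bc")])
    assert empty.genes == []


def test_consensus_requires_shared_universe():
    a = _fake_result({}, list("abc"), "m1")
    b = _fake_result({}, list("abd"), "m2")
    c = _fake_result({}, list("abc"), "m3")
    with pytest.raises(ValueError, match="symmetric difference"):
        consensus_degs([a, b, c])


def test_statistics_invariant_to_row_and_column_order():
    ds = make_dataset(simulate_counts(30, 30, seed=8))
    rng = np.random.default_rng(0)
    rows = rng.permutation(ds.counts.index)
    cols = rng.permutation(ds.counts.columns)
    shuffled = CountDataset(ds.counts.loc[rows, cols], ds.covariates.loc[cols], "shuf")
    for fn in (moderated_t_test, nb_wald_test, nb_lrt_test):
        r1 = fn(ds).table.sort_index()
        r2 = fn(shuffled).table.sort_index()
        assert np.allclose(r1["pvalue"], r2["pvalue"], atol=1e-9, equal_nan=True)


def test_label_permutation_kills_consensus_signal():
    """Permuting phenotype labels shrinks the consensus far below observed."""
    cfg = SimulationConfig(
        n_datasets=2, n_genes=250, n_samples_per_group=25, n_planted_de=50,
        planted_lfc=0.8, seed=11,
    )
    datasets, _ = generate_counts(cfg)
    ds = datasets[0]
    observed = len(run_all_de(ds)[1].genes)
    rng = np.random.default_rng(1)
    null_sizes = []
    for _ in range(15):
        cov = ds.covariates.copy()
        cov["phenotype"] = rng.permutation(cov["phenotype"].to_numpy())
        null_sizes.append(len(run_all_de(CountDataset(ds.counts, cov, "perm"))[1].genes))
    assert np.quantile(null_sizes, 0.95) < observed
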