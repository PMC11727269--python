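"""Consensus differential expression over count datasets.

Three distinct per-gene statistics — a moderated t on log2-CPM with empirical
Bayes variance shrinkage, a negative-binomial GLM Wald test with
median-of-ratios size factors, and a negative-binomial likelihood-ratio test
with TMM effective library sizes — are computed per dataset with explicit
covariates (phenotype, age, sex, batch) and intersected into a consensus DEG
set: genes with p < alpha and |log2FC| > lfc_min in *all three* methods.
The direction of change is deliberately not required to agree, accommodating
tissue-dependent effect directions.

All NB fits use iteratively reweighted least squares batched over genes
(shared design matrix), with gene-wise method-of-moments dispersion under the
parameterization var = mu + alpha * mu**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CountDataset",
    "DEResult",
    "ConsensusDEGSet",
    "median_ratio_size_factors",
    "tmm_factors",
    "filter_low_expression",
    "design_matrix",
    "moderated_t_test",
    "nb_wald_test",
    "nb_lrt_test",
    "consensus_degs",
    "run_all_de",
]

LN2 = float(np.log(2.0))
_DISP_FLOOR = 1e-8


@dataclass
class CountDataset:
    """One study's gene x sample integer counts plus per-sample covariates.

    ``counts`` has genes as rows and samples as columns; ``covariates`` is
    indexed by sample ID and carries at least ``phenotype`` (case/control),
    ``age``, ``sex`` (M/F) and ``batch``.
    """

    counts: pd.DataFrame
    covariates: pd.DataFrame
    name: str = "dataset"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.covariates.index):
            raise ValueError(
                f"{self.name}: covariate rows must align 1:1 with sample columns"
            )
        pheno = self.covariates["phenotype"]
        n_case = int((pheno == "case").sum())
        n_ctrl = int((pheno == "control").sum())
        if min(n_case, n_ctrl) < 2:
            raise ValueError(
                f"{self.name}: need >=2 samples per phenotype group, "
                f"got {n_case} case / {n_ctrl} control"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DEResult:
    """Per-gene differential-expression table for one method.

    ``table`` is indexed by gene with columns ``log2fc``, ``stat``, ``pvalue``
    and ``base_mean`` (normalized mean expression).  Untestable genes carry
    NaN p-values.
    """

    table: pd.DataFrame
    method: str
    dataset: str = "dataset"

    def significant(self, alpha: float = 0.05, lfc_min: float = 0.0) -> set[str]:
        t = self.table
        mask = (t["pvalue"] < alpha) & (t["log2fc"].abs() > lfc_min)
        return set(t.index[mask.fillna(False)])

    def tested(self) -> set[str]:
        return set(self.table.index[self.table["pvalue"].notna()])


@dataclass
class ConsensusDEGSet:
    """Genes significant under all three DE methods for one dataset."""

    dataset: str
    genes: list[str]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)  # max_p, min_abs_log2fc


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def median_ratio_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    For genes with nonzero count in every sample, each sample's factor is the
    median over genes of count / (gene geometric mean).
    """
    y = np.asarray(counts, dtype=float)
    all_nonzero = (y > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "median-of-ratios undefined (consider a pseudo-reference fallback)"
        )
    ref = y[all_nonzero]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: int | None = None,
) -> np.ndarray:
    """Trimmed-mean-of-M normalization factors (geometric mean 1).

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper quartile, unless ``ref_sample`` is given.
    """
    y = np.asarray(counts, dtype=float)
    lib = y.sum(axis=0)
    frac = y / lib
    if ref_sample is None:
        uq = np.quantile(frac, 0.75, axis=0)
        ref_sample = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_sample:
            continue
        ok = (y[:, j] > 0) & (y[:, ref_sample] > 0)
        if not ok.any():
            continue
        pj, pr = frac[ok, j], frac[ok, ref_sample]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # asymptotic delta-method weights
        w = (lib[j] - y[ok, j]) / (lib[j] * y[ok, j]) + (
            lib[ref_sample] - y[ok, ref_sample]
        ) / (lib[ref_sample] * y[ok, ref_sample])
        n = m.size
        m_rank = stats.rankdata(m)
        a_rank = stats.rankdata(a)
        keep = (
            (m_rank > trim_m * n)
            & (m_rank <= (1 - trim_m) * n)
            & (a_rank > trim_a * n)
            & (a_rank <= (1 - trim_a) * n)
        )
        if not keep.any():
            keep = np.ones(n, bool)
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def cpm(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    y = np.asarray(counts, dtype=float)
    return y / y.sum(axis=0) * 1e6


def normalized_cpm(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """CPM on median-of-ratios-normalized counts.

    Total-count CPM is biased when a sizable fraction of genes is
    differentially expressed (library composition tracks the phenotype and
    leaks into every gene); dividing by robust size factors instead keeps
    non-DE genes comparable across samples.  The per-million scale uses the
    geometric-mean library size, a constant across samples.
    """
    y = np.asarray(counts, dtype=float)
    sf = median_ratio_size_factors(y)
    lib = np.exp(np.mean(np.log(y.sum(axis=0))))
    return y / sf / lib * 1e6


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Drop genes with CPM < min_cpm in more than ``min_fraction`` of samples."""
    frac_low = (cpm(counts) < min_cpm).mean(axis=1)
    return counts.loc[frac_low <= min_fraction]


# --------------------------------------------------------------------------
# Design
# --------------------------------------------------------------------------

def design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Build (intercept, phenotype, age, sex, batch dummies) design.

    Raises if the design is rank-deficient, naming the collinear columns.
    """
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cols.append((covariates["phenotype"].to_numpy() == "case").astype(float))
    names.append("phenotype")
    if "age" in covariates:
        age = covariates["age"].astype(float).to_numpy()
        cols.append(age - age.mean())
        names.append("age")
    if "sex" in covariates:
        cols.append((covariates["sex"].to_numpy() == "M").astype(float))
        names.append("sex")
    if "batch" in covariates:
        batches = pd.unique(covariates["batch"])
        for b in batches[1:]:
            cols.append((covariates["batch"].to_numpy() == b).astype(float))
            names.append(f"batch_{b}")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = []
        rank = 0
        for j in range(x.shape[1]):
            r = np.linalg.matrix_rank(x[:, : j + 1])
            if r == rank:
                bad.append(names[j])
            rank = r
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    return x, names


# --------------------------------------------------------------------------
# Moderated t (log2-CPM, empirical Bayes variance shrinkage)
# --------------------------------------------------------------------------

def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist_moments(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2) on log s^2.

    Models s^2 ~ s0^2 * F(df, d0); returns (d0, s0sq) with d0 possibly inf.
    """
    z = np.log(s2[s2 > 0])
    e_z = float(np.mean(z))
    var_z = float(np.var(z, ddof=1)) if z.size > 1 else 0.0
    resid = var_z - float(special.polygamma(1, df / 2.0))
    if resid > 1e-8:
        d0 = 2.0 * _inv_trigamma(resid)
        log_s0 = (
            e_z
            - (special.digamma(df / 2.0) - np.log(df / 2.0))
            + (special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        log_s0 = e_z - (special.digamma(df / 2.0) - np.log(df / 2.0))
    return float(d0), float(np.exp(log_s0))


def moderated_t_test(
    dataset: CountDataset,
    prior_df: float | None = None,
    min_cpm: float = 1.0,
) -> DEResult:
    """Empirical-Bayes moderated t on log2(CPM + 0.5), per gene.

    OLS residual variances are shrunk toward a common prior,
    s2_tilde = (d0*s0^2 + d*s^2) / (d0 + d), and the phenotype t statistic is
    referred to t with d0 + d degrees of freedom.  ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary t test).
    """
    counts = filter_low_expression(dataset.counts, min_cpm=min_cpm)
    x, _ = design_matrix(dataset.covariates)
    n, p = x.shape
    expr = np.log2(normalized_cpm(counts) + 0.5)  # genes x samples
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = expr @ x @ xtx_inv  # genes x p
    resid = expr - beta @ x.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    c11 = xtx_inv[1, 1]

    testable = s2 > 0
    if prior_df is not None:
        d0 = float(prior_df)
        s0sq = float(np.median(s2[testable])) if np.isfinite(d0) and d0 > 0 else 1.0
    else:
        d0, s0sq = fit_f_dist_moments(s2[testable], df)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2.copy()
        df_total = float(df)
    else:
        s2_tilde = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[:, 1] / np.sqrt(c11 * s2_tilde)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pval[~testable] = np.nan
    tstat = np.where(testable, tstat, np.nan)

    table = pd.DataFrame(
        {
            "log2fc": beta[:, 1],
            "stat": tstat,
            "pvalue": pval,
            "base_mean": normalized_cpm(counts).mean(axis=1),
        },
        index=counts.index,
    )
    return DEResult(table, "moderated_t", dataset.name)


# --------------------------------------------------------------------------
# NB GLM machinery (batched IRLS, shared design)
# --------------------------------------------------------------------------

def _nb_irls(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB GLMs with log link for all genes at once.

    y: (G, n) counts; x: (n, p) shared design; offset: (n,) log-scale;
    alpha: (G,) dispersions (0 -> Poisson).  Returns (beta (G,p), mu (G,n),
    cov (G,p,p) of beta at convergence, converged (G,) bool).
    """
    g, n = y.shape
    p = x.shape[1]
    mu = np.maximum(y, 0.5) * 1.0
    eta = np.log(mu) - offset
    beta = np.zeros((g, p))
    converged = np.zeros(g, dtype=bool)
    a = alpha[:, None]
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        w = mu / (1.0 + a * mu)  # IRLS working weights
        z = eta + (y - mu) / mu
        xtwx = np.einsum("np,gn,nq->gpq", x, w, x) + ridge
        xtwz = np.einsum("np,gn->gp", x, w * z)
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        step = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        eta = beta @ x.T
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta + offset)
        mu = np.maximum(mu, 1e-10)
        converged |= step < tol
        if converged.all():
            break
    w = mu / (1.0 + a * mu)
    xtwx = np.einsum("np,gn,nq->gpq", x, w, x) + ridge
    cov = np.linalg.inv(xtwx)
    return beta, mu, cov, converged


def _mom_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> np.ndarray:
    """Gene-wise method-of-moments dispersion, floored at 1e-8."""
    n = y.shape[1]
    scale = n / max(n - n_params, 1)
    num = ((y - mu) ** 2 - mu).sum(axis=1) * scale
    den = (mu**2).sum(axis=1)
    return np.clip(num / den, _DISP_FLOOR, 50.0)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; Poisson limit for tiny dispersion."""
    a = alpha[:, None]
    ll = np.where(
        a > 1e-6,
        special.gammaln(y + 1.0 / np.maximum(a, 1e-12))
        - special.gammaln(1.0 / np.maximum(a, 1e-12))
        - special.gammaln(y + 1.0)
        + y * np.log(a * mu / (1.0 + a * mu))
        - (1.0 / np.maximum(a, 1e-12)) * np.log1p(a * mu),
        y * np.log(mu) - mu - special.gammaln(y + 1.0),
    )
    return ll.sum(axis=1)


def _prepare_nb(
    dataset: CountDataset, min_cpm: float
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    counts = filter_low_expression(dataset.counts, min_cpm=min_cpm)
    x, _ = design_matrix(dataset.covariates)
    return counts, x, counts.to_numpy(dtype=float)


def nb_wald_test(
    dataset: CountDataset,
    dispersion: float | np.ndarray | None = None,
    min_cpm: float = 1.0,
) -> DEResult:
    """NB GLM Wald test with median-of-ratios size-factor offsets.

    Per gene: IRLS fit with gene-wise method-of-moments dispersion (floored at
    1e-8), Wald z = beta_phenotype / SE against the standard normal, and
    log2FC = beta_phenotype / ln 2.  ``dispersion`` overrides the estimate.
    """
    counts, x, y = _prepare_nb(dataset, min_cpm)
    sf = median_ratio_size_factors(counts)
    offset = np.log(sf)
    g = y.shape[0]
    if dispersion is None:
        beta0, mu0, _, _ = _nb_irls(y, x, offset, np.zeros(g), max_iter=30)
        alpha = _mom_dispersion(y, mu0, x.shape[1])
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (g,)).copy()
        alpha = np.maximum(alpha, _DISP_FLOOR)
    beta, mu, cov, ok = _nb_irls(y, x, offset, alpha)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
    z = beta[:, 1] / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval[~ok] = np.nan
    table = pd.DataFrame(
        {
            "log2fc": beta[:, 1] / LN2,
            "stat": np.where(ok, z, np.nan),
            "pvalue": pval,
            "base_mean": (y / sf).mean(axis=1),
        },
        index=counts.index,
    )
    return DEResult(table, "nb_wald", dataset.name)


def nb_lrt_test(
    dataset: CountDataset,
    min_cpm: float = 1.0,
    ref_sample: int | None = None,
) -> DEResult:
    """NB likelihood-ratio test with TMM effective library sizes.

    Fits the full design and the reduced design with phenotype dropped, shares
    the full-model dispersion, and refers 2*(llf - llr) to chi2 with 1 df.
    """
    counts, x, y = _prepare_nb(dataset, min_cpm)
    lib = np.asarray(dataset.counts.sum(axis=0), dtype=float)
    eff = lib * tmm_factors(counts, ref_sample=ref_sample)
    offset = np.log(eff / np.exp(np.mean(np.log(eff))))
    g = y.shape[0]
    x_red = np.delete(x, 1, axis=1)

    beta0, mu0, _, _ = _nb_irls(y, x, offset, np.zeros(g), max_iter=30)
    alpha = _mom_dispersion(y, mu0, x.shape[1])
    beta_f, mu_f, _, ok_f = _nb_irls(y, x, offset, alpha)
    beta_r, mu_r, _, ok_r = _nb_irls(y, x_red, offset, alpha)
    lrt = 2.0 * (_nb_loglik(y, mu_f, alpha) - _nb_loglik(y, mu_r, alpha))
    lrt = np.maximum(lrt, 0.0)
    ok = ok_f & ok_r
    pval = stats.chi2.sf(lrt, df=1)
    pval[~ok] = np.nan
    table = pd.DataFrame(
        {
            "log2fc": beta_f[:, 1] / LN2,
            "stat": np.where(ok, lrt, np.nan),
            "pvalue": pval,
            "base_mean": (y / (eff / eff.mean())).mean(axis=1),
        },
        index=counts.index,
    )
    return DEResult(table, "nb_lrt", dataset.name)


# --------------------------------------------------------------------------
# Consensus
# --------------------------------------------------------------------------

def consensus_degs(
    results: list[DEResult],
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> ConsensusDEGSet:
    """Intersect the significant sets of the three DE methods.

    Genes untestable (NaN p) in any method are excluded.  Raises if the
    methods' gene universes differ.
    """
    if len(results) != 3:
        raise ValueError(f"expected three DE results, got {len(results)}")
    universes = [set(r.table.index) for r in results]
    sym = (universes[0] ^ universes[1]) | (universes[0] ^ universes[2])
    if sym:
        raise ValueError(
            f"mismatched gene universes across methods: symmetric difference "
            f"of size {len(sym)}"
        )
    testable = set.intersection(*[r.tested() for r in results])
    sig = set.intersection(*[r.significant(alpha, lfc_min) for r in results])
    genes = sorted(sig & testable)
    max_p = pd.concat([r.table.loc[genes, "pvalue"] for r in results], axis=1).max(axis=1)
    min_lfc = pd.concat(
        [r.table.loc[genes, "log2fc"].abs() for r in results], axis=1
    ).min(axis=1)
    table = pd.DataFrame({"max_pvalue": max_p, "min_abs_log2fc": min_lfc})
    dataset = results[0].dataset
    out = ConsensusDEGSet(dataset, genes, table)
    # intersection semantics must hold on every run
    for r in results:
        assert set(genes) <= r.significant(alpha, lfc_min)
    return out


def run_all_de(
    dataset: CountDataset,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    min_cpm: float = 1.0,
) -> tuple[list[DEResult], ConsensusDEGSet]:
    """Convenience: all three DE methods plus their consensus for one dataset."""
    results = [
        moderated_t_test(dataset, min_cpm=min_cpm),
        nb_wald_test(dataset, min_cpm=min_cpm),
        nb_lrt_test(dataset, min_cpm=min_cpm),
    ]
    return results, consensus_degs(results, alpha=alpha, lfc_min=lfc_min)
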