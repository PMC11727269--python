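"""Clumping + thresholding polygenic risk scores, genome-wide or gene-set-restricted.

The workflow mirrors standard C+T practice: QC (common, well-imputed,
non-palindromic SNPs), greedy LD clumping on dosage r^2, optional restriction
to SNPs within gene bodies +/- 10 kb of a gene set, then per-threshold scores
sum(dosage * BETA), z-standardized and associated with case/control status by
logistic regression adjusting for sex and principal components.  The best
threshold (minimum association p) is corrected for the threshold search by a
phenotype-permutation empirical p, (exceedances + 1) / (B + 1), repeating the
full search in every permutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "GwasPanel",
    "PrsResult",
    "DEFAULT_THRESHOLDS",
    "qc_filter",
    "clump",
    "restrict_to_gene_set",
    "score_and_associate",
]

# P-value grid used for threshold optimisation
DEFAULT_THRESHOLDS = (
    5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0,
)

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GwasPanel:
    """Summary statistics + target-cohort genotypes for C+T scoring.

    ``summary``: columns SNP, CHR, BP, A1 (effect allele), A2, BETA, P, MAF,
    INFO.  ``dosages``: samples x SNPs in [0, 2]; ``geno_alleles`` states per
    SNP which allele the dosage counts (columns A1, A2); when omitted the
    summary's alleles are assumed.  ``phenotype`` is 0/1 per sample;
    ``covariates`` carries sex and principal components.  ``bed`` gives gene
    coordinates (0-based half-open).
    """

    summary: pd.DataFrame
    dosages: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame
    bed: pd.DataFrame
    geno_alleles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.summary["BP"] <= 0).any():
            raise ValueError("BP must be positive")


@dataclass
class PrsResult:
    per_threshold: pd.DataFrame  # threshold, n_snps, or_per_sd, pvalue, r2_nagelkerke
    best_threshold: float
    best_pvalue: float
    best_or_per_sd: float
    empirical_pvalue: float
    n_permutations: int
    seed: int
    best_scores: pd.Series = field(default_factory=pd.Series)
    separation_flagged: bool = False


# --------------------------------------------------------------------------
# QC / clumping / gene-set restriction
# --------------------------------------------------------------------------

def qc_filter(
    summary: pd.DataFrame, maf_min: float = 0.05, info_min: float = 0.5
) -> pd.DataFrame:
    """Keep common (MAF > maf_min), well-imputed (INFO >= info_min),
    non-palindromic SNPs.  Exclusion counts are logged and stored in attrs."""
    for col in ("SNP", "A1", "A2", "BETA", "P", "MAF", "INFO"):
        if col not in summary.columns:
            raise ValueError(f"summary statistics missing required column {col!r}")
    maf_bad = summary["MAF"] <= maf_min
    info_bad = summary["INFO"] < info_min
    pal = [
        (a1, a2) in _PALINDROMIC
        for a1, a2 in zip(summary["A1"].str.upper(), summary["A2"].str.upper())
    ]
    pal = pd.Series(pal, index=summary.index)
    keep = ~(maf_bad | info_bad | pal)
    out = summary[keep].copy()
    out.attrs["excluded"] = {
        "maf": int(maf_bad.sum()),
        "info": int(info_bad.sum()),
        "palindromic": int(pal.sum()),
    }
    logger.info("qc_filter: %s", out.attrs["excluded"])
    return out


def clump(
    summary: pd.DataFrame,
    dosages: pd.DataFrame,
    window_kb: float = 250.0,
    r2_max: float = 0.1,
) -> list[str]:
    """Greedy LD clumping: lowest-P unclaimed SNP becomes an index; SNPs on
    the same chromosome within the window with dosage r^2 > r2_max are
    removed.  Deterministic (P, then SNP ID order)."""
    present = summary["SNP"].isin(dosages.columns)
    if (~present).any():
        logger.warning("clump: %d summary SNPs missing from dosages", int((~present).sum()))
    s = summary[present].sort_values(["P", "SNP"], kind="mergesort")
    snps = s["SNP"].to_numpy()
    chrom = s["CHR"].astype(str).to_numpy()
    bp = s["BP"].to_numpy(dtype=float)
    geno = dosages[snps].to_numpy(dtype=float)
    sd = geno.std(axis=0)
    window = window_kb * 1000.0
    claimed = np.zeros(len(snps), dtype=bool)
    index_snps: list[str] = []
    for i in range(len(snps)):
        if claimed[i]:
            continue
        index_snps.append(snps[i])
        claimed[i] = True
        near = (~claimed) & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window)
        idx = np.flatnonzero(near)
        if idx.size == 0:
            continue
        gi = geno[:, i] - geno[:, i].mean()
        gj = geno[:, idx] - geno[:, idx].mean(axis=0)
        denom = sd[i] * sd[idx] * len(gi)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, gi @ gj / denom, 0.0)
        claimed[idx[r**2 > r2_max]] = True
    return index_snps


def _norm_chrom(c: pd.Series | np.ndarray) -> np.ndarray:
    out = pd.Series(c).astype(str).str.replace("^chr", "", regex=True)
    return out.to_numpy()


def restrict_to_gene_set(
    summary: pd.DataFrame,
    bed: pd.DataFrame,
    flank_bp: int = 10_000,
    genes: set[str] | list[str] | None = None,
) -> pd.DataFrame:
    """Keep SNPs within a gene body +/- flank of the (optionally restricted)
    gene annotation.  BED is 0-based half-open; the summary's 1-based BP is
    converted before the interval check."""
    b = bed if genes is None else bed[bed["gene_id"].isin(set(genes))]
    if len(b) == 0:
        raise ValueError("empty gene annotation after restriction")
    bchrom = _norm_chrom(b["chrom"])
    schrom = _norm_chrom(summary["CHR"])
    pos0 = summary["BP"].to_numpy(dtype=np.int64) - 1  # 1-based BP -> 0-based
    keep = np.zeros(len(summary), dtype=bool)
    for c in np.unique(bchrom):
        rows = bchrom == c
        starts = b.loc[rows, "start"].to_numpy(dtype=np.int64) - flank_bp
        ends = b.loc[rows, "end"].to_numpy(dtype=np.int64) + flank_bp
        sel = schrom == c
        if not sel.any():
            continue
        p = pos0[sel]
        hit = ((p[:, None] >= starts[None, :]) & (p[:, None] < ends[None, :])).any(axis=1)
        keep[np.flatnonzero(sel)] = hit
    return summary[keep].copy()


# --------------------------------------------------------------------------
# Logistic fits
# --------------------------------------------------------------------------

def logit_irls(
    x: np.ndarray, y: np.ndarray, ridge: float = 1e-8, max_iter: int = 40
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-Raphson logistic regression.

    Returns (beta, cov, loglik, converged).  A small ridge keeps the Hessian
    invertible under (near-)separation.
    """
    n, p = x.shape
    beta = np.zeros(p)
    eye = np.eye(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = special.expit(eta)
        w = mu * (1 - mu) + 1e-12
        grad = x.T @ (y - mu) - ridge * beta
        hess = (x.T * w) @ x + ridge * eye
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            converged = True
            break
    eta = np.clip(x @ beta, -30, 30)
    mu = special.expit(eta)
    w = mu * (1 - mu) + 1e-12
    cov = np.linalg.inv((x.T * w) @ x + ridge * eye)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, cov, ll, converged


def _assoc_pvalue(score: np.ndarray, covar: np.ndarray, y: np.ndarray) -> float:
    """Wald p for the score coefficient in y ~ score + covariates."""
    x = np.column_stack([np.ones_like(score), score, covar])
    beta, cov, _, _ = logit_irls(x, y)
    z = beta[1] / np.sqrt(cov[1, 1])
    return float(2.0 * stats.norm.sf(abs(z)))


def _full_report(
    score: np.ndarray, covar: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, bool]:
    """(OR per SD, p, Nagelkerke R2, separation flag) via statsmodels,
    falling back to the ridge-penalized Newton fit under separation."""
    import statsmodels.api as sm

    x = np.column_stack([np.ones_like(score), score, covar])
    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        beta, bse = fit.params, fit.bse
        llf, lln = fit.llf, fit.llnull
        if not np.isfinite(bse[1]):
            raise np.linalg.LinAlgError
        p = float(2.0 * stats.norm.sf(abs(beta[1] / bse[1])))
    except Exception:  # perfect separation or singular fit
        flagged = True
        beta, cov, llf, _ = logit_irls(x, y, ridge=1e-3)
        x0 = np.column_stack([np.ones_like(score), covar])
        _, _, lln, _ = logit_irls(x0, y, ridge=1e-3)
        p = float(2.0 * stats.norm.sf(abs(beta[1] / np.sqrt(cov[1, 1]))))
    n = len(y)
    denom = 1.0 - np.exp(2.0 * lln / n)
    r2 = float((1.0 - np.exp(-2.0 * (llf - lln) / n)) / denom) if denom > 0 else np.nan
    return float(np.exp(beta[1])), p, r2, flagged


# --------------------------------------------------------------------------
# Scoring + association
# --------------------------------------------------------------------------

def _reconciled_betas(
    summary: pd.DataFrame, geno_alleles: pd.DataFrame | None
) -> tuple[pd.Series, pd.Series]:
    """Per-SNP (beta, flipped) with beta applied to the *genotyped* allele.

    If the summary's effect allele is the genotype panel's other allele, the
    dosage is counted on 2 - d, equivalently beta is negated and 2*beta added
    to a constant that standardization removes.
    """
    beta = summary.set_index("SNP")["BETA"].astype(float)
    if geno_alleles is None:
        return beta, pd.Series(False, index=beta.index)
    s = summary.set_index("SNP")
    g = geno_alleles.loc[s.index]
    same = (s["A1"].str.upper() == g["A1"].str.upper()) & (
        s["A2"].str.upper() == g["A2"].str.upper()
    )
    flip = (s["A1"].str.upper() == g["A2"].str.upper()) & (
        s["A2"].str.upper() == g["A1"].str.upper()
    )
    bad = ~(same | flip)
    if bad.any():
        logger.warning("dropping %d SNPs with irreconcilable alleles", int(bad.sum()))
        beta = beta[~bad]
        flip = flip[~bad]
    return beta, flip


def raw_scores(
    panel: GwasPanel,
    index_snps: list[str],
    thresholds: tuple[float, ...] | list[float] = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, list[int]]:
    """Unstandardized per-threshold scores sum_j dosage_ij * BETA_j.

    Returns (samples x thresholds DataFrame, SNP count per threshold);
    alleles are reconciled against the genotype panel first.
    """
    thresholds = sorted(thresholds)
    s = panel.summary[panel.summary["SNP"].isin(set(index_snps))]
    beta, flip = _reconciled_betas(s, panel.geno_alleles)
    snps = [x for x in beta.index if x in panel.dosages.columns]
    beta = beta.loc[snps]
    flip = flip.loc[snps]
    pvals = s.set_index("SNP").loc[snps, "P"].astype(float)
    d = panel.dosages[snps].to_numpy(dtype=float)
    d = np.where(flip.to_numpy(), 2.0 - d, d)
    cols = {}
    counts = []
    for t in thresholds:
        sel = (pvals <= t).to_numpy()
        counts.append(int(sel.sum()))
        cols[t] = d[:, sel] @ beta.to_numpy()[sel] if sel.any() else np.zeros(len(d))
    return pd.DataFrame(cols, index=panel.dosages.index), counts


def score_and_associate(
    panel: GwasPanel,
    index_snps: list[str],
    thresholds: tuple[float, ...] | list[float] = DEFAULT_THRESHOLDS,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PrsResult:
    """Per-threshold C+T scores with permutation-corrected best-threshold p.

    For every threshold t: score_i = sum_j dosage_ij * BETA_j over index SNPs
    with P <= t; scores are z-standardized and associated by logistic
    regression (phenotype ~ score + sex + PCs).  The best threshold minimizes
    the association p; its empirical significance permutes phenotype labels
    (covariates stay attached to samples) and repeats the whole search.
    """
    thresholds = sorted(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    y = panel.phenotype.to_numpy(dtype=float)
    covar = panel.covariates.to_numpy(dtype=float)
    raw, n_snps = raw_scores(panel, index_snps, thresholds)

    # per-threshold standardized score columns
    score_cols: list[np.ndarray | None] = []
    for i, t in enumerate(thresholds):
        col = raw[t].to_numpy()
        sd = col.std()
        if n_snps[i] == 0 or sd == 0:
            score_cols.append(None)
        else:
            score_cols.append((col - col.mean()) / sd)

    rows = []
    best_p, best_i = np.inf, None
    flagged = False
    for i, t in enumerate(thresholds):
        col = score_cols[i]
        if col is None:
            rows.append((t, n_snps[i], np.nan, np.nan, np.nan))
            continue
        or_sd, p, r2, flag = _full_report(col, covar, y)
        flagged |= flag
        rows.append((t, n_snps[i], or_sd, p, r2))
        if p < best_p:
            best_p, best_i = p, i
    per_threshold = pd.DataFrame(
        rows, columns=["threshold", "n_snps", "or_per_sd", "pvalue", "r2_nagelkerke"]
    )
    if best_i is None:
        raise ValueError("no threshold yielded a nonempty, non-degenerate score")

    # the permutation comparison uses the same (Newton/Wald) fit on observed
    # and permuted data so observed and null p-values are exchangeable
    usable = [c for c in score_cols if c is not None]
    obs_best = min(_assoc_pvalue(c, covar, y) for c in usable)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        perm_best = min(_assoc_pvalue(c, covar, yp) for c in usable)
        if perm_best <= obs_best:
            exceed += 1
    emp_p = (exceed + 1) / (n_permutations + 1)

    return PrsResult(
        per_threshold=per_threshold,
        best_threshold=float(thresholds[best_i]),
        best_pvalue=float(best_p),
        best_or_per_sd=float(per_threshold.loc[best_i, "or_per_sd"]),
        empirical_pvalue=float(emp_p),
        n_permutations=n_permutations,
        seed=seed,
        best_scores=pd.Series(score_cols[best_i], index=panel.dosages.index),
        separation_flagged=flagged,
    )
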