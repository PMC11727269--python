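"""SVM recursive feature elimination with cross-validated performance.

A linear-kernel SVM is fit on all current features; features are ranked by
squared weight and the lowest-ranked ``step`` features are discarded, until a
single feature remains.  At each set size the stratified k-fold
cross-validated ROC-AUC (or accuracy) is recorded with a t-based 95% CI, and
the selected gene set is the one at the maximum mean score, ties resolved in
favour of the smaller set.  Standardization inside cross-validation uses
training-fold statistics only; the ranking model uses full-data statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from dreg.de import CountDataset, normalized_cpm

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "RFETrace", "expression_features", "standardize", "svm_rfe"]


@dataclass
class FeatureMatrix:
    """Samples x genes expression features with labels and dataset tags."""

    x: pd.DataFrame
    labels: pd.Series  # 1 = case, 0 = control
    datasets: pd.Series

    def __post_init__(self) -> None:
        if self.x.isna().any().any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class RFETrace:
    """Elimination trace: one record per evaluated feature-set size."""

    records: pd.DataFrame  # n_discarded, n_remaining, mean_score, ci_halfwidth
    fold_scores: list[np.ndarray]
    elimination_order: list[str]
    selected: list[str]
    metric: str = "auc"

    def __post_init__(self) -> None:
        nd = self.records["n_discarded"].to_numpy()
        assert (np.diff(nd) > 0).all(), "n_discarded must be strictly increasing"


def expression_features(
    datasets: list[CountDataset], genes: list[str] | None = None
) -> FeatureMatrix:
    """Pool datasets into a samples x genes log2(CPM + 0.5) matrix.

    Columns are restricted to ``genes`` (e.g. the candidate pool) when given;
    genes absent from any dataset are dropped.
    """
    frames, labels, tags = [], [], []
    common: set[str] | None = None
    for ds in datasets:
        common = set(ds.genes) if common is None else common & set(ds.genes)
    keep = sorted(common & set(genes)) if genes is not None else sorted(common)
    for ds in datasets:
        expr = pd.DataFrame(
            np.log2(normalized_cpm(ds.counts) + 0.5),
            index=ds.counts.index,
            columns=ds.samples,
        )
        frames.append(expr.loc[keep].T)
        labels.append((ds.covariates["phenotype"] == "case").astype(int))
        tags.append(pd.Series(ds.name, index=ds.covariates.index))
    return FeatureMatrix(pd.concat(frames), pd.concat(labels), pd.concat(tags))


def standardize(
    features: FeatureMatrix,
    stats_: tuple[pd.Series, pd.Series] | None = None,
) -> tuple[FeatureMatrix, tuple[pd.Series, pd.Series]]:
    """Gene-wise z-scores.  ``stats_`` (mean, sd) reuses training statistics;
    otherwise they are computed from the data.  Zero-variance genes are
    dropped (with a log entry) when computing fresh statistics."""
    x = features.x
    if stats_ is None:
        mean, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
        dead = sd[sd == 0].index
        if len(dead):
            logger.info("standardize: dropping %d zero-variance genes", len(dead))
            x = x.drop(columns=dead)
            mean, sd = mean.drop(dead), sd.drop(dead)
    else:
        mean, sd = stats_
        x = x[mean.index]
    z = (x - mean) / sd
    return FeatureMatrix(z, features.labels, features.datasets), (mean, sd)


def fold_standardize(
    x: np.ndarray, tr: np.ndarray, te: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scale both fold halves with training-fold statistics only."""
    mu = x[tr].mean(axis=0)
    sd = x[tr].std(axis=0)
    sd[sd == 0] = 1.0
    return (x[tr] - mu) / sd, (x[te] - mu) / sd


def _cv_score(
    x: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    folds: int,
    seed: int,
    metric: str,
    c: float,
) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(folds)
    for i, (tr, te) in enumerate(skf.split(x, strata)):
        xtr, xte = fold_standardize(x, tr, te)
        clf = SVC(kernel="linear", C=c)
        clf.fit(xtr, y[tr])
        if metric == "auc":
            scores[i] = roc_auc_score(y[te], clf.decision_function(xte))
        else:
            scores[i] = accuracy_score(y[te], clf.predict(xte))
    return scores


def svm_rfe(
    features: FeatureMatrix,
    step: int = 1,
    folds: int = 10,
    seed: int = 0,
    metric: str = "auc",
    c: float = 1.0,
) -> RFETrace:
    """Recursive feature elimination with a linear SVM.

    At each iteration the cross-validated score of the current feature set is
    recorded, a linear SVM is fit on the full (fold-independently
    standardized) data, and the ``step`` features with the smallest squared
    weights are discarded (ties by gene ID).  The selected set maximizes the
    mean CV score; among ties the smaller set wins.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if metric not in ("auc", "accuracy"):
        raise ValueError(f"unknown metric {metric!r}")
    y = features.labels.to_numpy()
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds; "
            "use fewer folds"
        )
    # stratify by label x dataset when every stratum can fill the folds
    combo = features.labels.astype(str) + "|" + features.datasets.astype(str)
    strata = combo.to_numpy() if combo.value_counts().min() >= folds else y

    current = sorted(features.x.columns)
    order: list[str] = []
    recs, fold_scores = [], []
    t_crit = stats.t.ppf(0.975, folds - 1)
    n_total = len(current)
    while current:
        x = features.x[current].to_numpy()
        scores = _cv_score(x, y, strata, folds, seed, metric, c)
        recs.append(
            (
                n_total - len(current),
                len(current),
                scores.mean(),
                t_crit * scores.std(ddof=1) / np.sqrt(folds),
            )
        )
        fold_scores.append(scores)
        if len(current) == 1:
            order.extend(current)
            break
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=c)
        clf.fit((x - mu) / sd, y)
        w2 = np.ravel(np.asarray(clf.coef_)) ** 2
        ranked = sorted(zip(w2, current))  # ascending weight, ties by gene ID
        n_drop = min(step, len(current) - 1)
        dropped = [g for _, g in ranked[:n_drop]]
        order.extend(dropped)
        current = [g for g in current if g not in set(dropped)]

    records = pd.DataFrame(
        recs, columns=["n_discarded", "n_remaining", "mean_score", "ci_halfwidth"]
    )
    # argmax of mean score; ties -> larger n_discarded (smaller set)
    best = records.sort_values(
        ["mean_score", "n_discarded"], ascending=[False, False], kind="mergesort"
    ).index[0]
    n_disc = int(records.loc[best, "n_discarded"])
    selected = sorted(set(features.x.columns) - set(order[:n_disc]))
    assert sorted(order) == sorted(features.x.columns)  # permutation, no loss
    return RFETrace(records, fold_scores, order, selected, metric)


def plot_trace(trace: RFETrace, path: str) -> None:
    """AUC-versus-discarded curve with its 95% CI band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = trace.records
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(r["n_discarded"], r["mean_score"], lw=1)
    ax.fill_between(
        r["n_discarded"],
        r["mean_score"] - r["ci_halfwidth"],
        r["mean_score"] + r["ci_halfwidth"],
        alpha=0.3,
    )
    best_disc = r.loc[r["n_remaining"] == len(trace.selected), "n_discarded"]
    if len(best_disc):
        ax.axvline(float(best_disc.iloc[0]), ls=":", color="gray")
    ax.set_xlabel("number of discarded genes")
    ax.set_ylabel(f"mean CV {trace.metric.upper()}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
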