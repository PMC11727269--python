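"""Classifier harness: eight model families, tenfold CV, held-out evaluation.

The candidate model families are logistic regression (LR), decision tree
(DT), random forest (RF), extra trees (ET), gradient boosting (GBDT),
XGBoost, a support vector machine (SVM) and a multilayer perceptron (MLP).
Each family is tuned over a small documented grid by stratified k-fold
cross-validated accuracy on the combined training data; the winner (ties go
to the simpler family in a fixed order) is refit on all training samples and
evaluated on named held-out test sets with ROC curves, trapezoidal AUC,
accuracy at the 0.5 decision threshold and confusion counts.  Test sets are
standardized with training-set statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = ["ModelReport", "EvalReport", "MODEL_ORDER", "crossval_models", "fit_final", "evaluate"]

# fixed simplicity order for tie-breaking
MODEL_ORDER = ["LR", "DT", "RF", "ET", "GBDT", "XGBoost", "SVM", "MLP"]


def _grids(seed: int) -> dict[str, list[tuple[dict, object]]]:
    """Small documented hyperparameter grids per family."""

    def lr(c):
        return LogisticRegression(C=c, max_iter=2000)

    def svm(c):
        return SVC(kernel="rbf", C=c, gamma="scale")

    return {
        "LR": [({"C": c}, lr(c)) for c in (0.1, 1.0)],
        "DT": [
            ({"max_depth": d}, DecisionTreeClassifier(max_depth=d, random_state=seed))
            for d in (3, None)
        ],
        "RF": [
            (
                {"n_estimators": 200},
                RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1),
            )
        ],
        "ET": [
            (
                {"n_estimators": 200},
                ExtraTreesClassifier(n_estimators=200, random_state=seed, n_jobs=1),
            )
        ],
        "GBDT": [
            (
                {"n_estimators": 100, "max_depth": 3},
                GradientBoostingClassifier(
                    n_estimators=100, max_depth=3, random_state=seed
                ),
            )
        ],
        "XGBoost": [
            (
                {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
                XGBClassifier(
                    n_estimators=100,
                    max_depth=3,
                    learning_rate=0.1,
                    random_state=seed,
                    n_jobs=1,
                    verbosity=0,
                ),
            )
        ],
        "SVM": [({"C": c, "kernel": "rbf"}, svm(c)) for c in (1.0, 10.0)],
        "MLP": [
            (
                {"hidden_layer_sizes": (32,)},
                MLPClassifier(
                    hidden_layer_sizes=(32,), max_iter=500, random_state=seed
                ),
            )
        ],
    }


@dataclass
class ModelReport:
    name: str
    fold_accuracies: np.ndarray
    mean_accuracy: float
    sem_accuracy: float
    params: dict = field(default_factory=dict)


@dataclass
class EvalReport:
    """Per test set: ROC points, AUC, accuracy and confusion counts."""

    per_set: dict[str, dict] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = [
            (name, d.get("auc"), d["accuracy"], d["n"])
            for name, d in self.per_set.items()
        ]
        return pd.DataFrame(rows, columns=["test_set", "auc", "accuracy", "n"]).set_index(
            "test_set"
        )


def _pipe(model) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", model)])


def crossval_models(
    x: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    folds: int = 10,
    seed: int = 0,
    families: list[str] | None = None,
) -> tuple[list[ModelReport], str]:
    """Stratified k-fold accuracy for each family over its grid.

    Returns per-family reports (at each family's best grid point) and the
    winning family name.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    grids = _grids(seed)
    names = families if families is not None else MODEL_ORDER
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    reports: list[ModelReport] = []
    for name in names:
        best: ModelReport | None = None
        for params, model in grids[name]:
            accs = np.empty(folds)
            for i, (tr, te) in enumerate(splits):
                pipe = _pipe(model)
                pipe.fit(x[tr], y[tr])
                accs[i] = accuracy_score(y[te], pipe.predict(x[te]))
            rep = ModelReport(
                name,
                accs,
                float(accs.mean()),
                float(accs.std(ddof=1) / np.sqrt(folds)),
                params,
            )
            if best is None or rep.mean_accuracy > best.mean_accuracy:
                best = rep
        reports.append(best)
    winner = max(
        reports, key=lambda r: (r.mean_accuracy, -MODEL_ORDER.index(r.name))
    ).name
    return reports, winner


def fit_final(
    name: str,
    params: dict,
    x: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    seed: int = 0,
) -> Pipeline:
    """Refit the chosen family at its tuned grid point on the full training data."""
    for p, model in _grids(seed)[name]:
        if p == params:
            pipe = _pipe(model)
            pipe.fit(np.asarray(x, dtype=float), np.asarray(y, dtype=int))
            return pipe
    raise ValueError(f"params {params!r} not in the documented grid for {name}")


def _scores(pipe: Pipeline, x: np.ndarray) -> np.ndarray:
    clf = pipe.named_steps["clf"]
    if hasattr(clf, "predict_proba") and getattr(clf, "probability", True):
        return pipe.predict_proba(x)[:, 1]
    return pipe.decision_function(x)


def evaluate(
    pipe: Pipeline,
    test_sets: dict[str, tuple[pd.DataFrame | np.ndarray, np.ndarray | pd.Series]],
) -> EvalReport:
    """ROC/AUC/accuracy/confusion per named test set.

    Single-class sets get a missing AUC with an explanation rather than an
    error.
    """
    report = EvalReport()
    for name, (x, y) in test_sets.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        pred = pipe.predict(x)
        acc = float(accuracy_score(y, pred))
        cm = confusion_matrix(y, pred, labels=[0, 1])
        entry: dict = {"accuracy": acc, "confusion": cm, "n": int(len(y))}
        if len(np.unique(y)) < 2:
            entry["auc"] = None
            entry["note"] = "AUC undefined: test set contains a single class"
        else:
            s = _scores(pipe, x)
            fpr, tpr, thr = roc_curve(y, s)
            entry["roc"] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
            entry["auc"] = float(roc_auc_score(y, s))
        report.per_set[name] = entry
    return report
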