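#!/usr/bin/env python
"""Select and evaluate the DREG-based characterization model.

Eight model families are compared by tenfold cross-validated accuracy on
the combined training splits (features = selected DREGs); the winner is
refit and evaluated on the pooled and per-dataset held-out splits with
ROC/AUC and accuracy.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from dreg import classify, io, rfe
from dreg.de import CountDataset
from dreg.pipeline import stage_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--rfe", type=Path, default=Path("results/rfe"))
    ap.add_argument("--out", type=Path, default=Path("results/classifier"))
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    trains, tests = [], []
    for counts_path in sorted(args.data.glob("DS*.counts.tsv")):
        name = counts_path.name.split(".")[0]
        ds = io.read_dataset(counts_path, args.data / f"{name}.meta.tsv", name)
        split = pd.read_csv(args.data / f"{name}.split.tsv", sep="\t", index_col=0)
        tr = split.index[~split["is_test"]]
        te = split.index[split["is_test"]]
        trains.append(CountDataset(ds.counts[tr], ds.covariates.loc[tr], name))
        tests.append(CountDataset(ds.counts[te], ds.covariates.loc[te], name))

    dregs = list(pd.read_csv(args.rfe / "dregs.txt")["gene_id"])
    train_fm = rfe.expression_features(trains, genes=dregs)
    seed = stage_seed(args.seed, 5)
    reports, best = classify.crossval_models(train_fm.x, train_fm.labels,
                                             folds=10, seed=seed)
    rows = [(r.name, r.mean_accuracy, r.sem_accuracy, json.dumps(r.params))
            for r in reports]
    pd.DataFrame(rows, columns=["model", "mean_accuracy", "sem", "params"]).to_csv(
        args.out / "model_cv.tsv", sep="\t", index=False, float_format="%.6g")

    best_rep = next(r for r in reports if r.name == best)
    pipe = classify.fit_final(best, best_rep.params, train_fm.x, train_fm.labels, seed)
    test_fm = rfe.expression_features(tests, genes=list(train_fm.x.columns))
    named = {"internal_test": (test_fm.x, test_fm.labels)}
    for ds in tests:
        sel = (test_fm.datasets == ds.name).to_numpy()
        named[f"internal_test_{ds.name}"] = (test_fm.x[sel], test_fm.labels[sel])
    report = classify.evaluate(pipe, named)
    report.table().to_csv(args.out / "evaluation.tsv", sep="\t", float_format="%.6g")
    for name, entry in report.per_set.items():
        if "roc" in entry:
            entry["roc"].to_csv(args.out / f"roc_{name}.csv", index=False,
                                float_format="%.6g")

    print(f"best model: {best} "
          f"(CV accuracy {best_rep.mean_accuracy:.3f} +/- {best_rep.sem_accuracy:.3f})")
    print(report.table().to_string())


if __name__ == "__main__":
    main()
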