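"""End-to-end orchestration: simulate -> DE -> enrich -> RFE -> network -> PRS -> classify.

``run_pipeline`` executes the stages in dependency order on synthetic data
(or on caller-provided inputs), records every applied threshold, derives one
seed per stage from the master seed, and writes a JSON manifest with
parameters, seeds, wall-clock and output hashes.  Stage outputs are written
as plain-text tables before the next stage starts; a failing stage stops the
run with a partial manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dreg import classify as _classify
from dreg import enrich as _enrich
from dreg import io as _io
from dreg import network as _network
from dreg import prs as _prs
from dreg import rfe as _rfe
from dreg.de import CountDataset, run_all_de
from dreg.simulate import SimulatedData, SimulationConfig, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "stratified_split", "stage_seed"]


@dataclass
class RunConfig:
    """All stage parameters plus toggles for the optional stages."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    # DE / enrichment
    alpha: float = 0.05
    lfc_min: float = 0.0
    min_cpm: float = 1.0
    # split
    test_fraction: float = 0.3
    # RFE
    rfe_step: int = 5
    rfe_folds: int = 10
    # network
    network_permutations: int = 1000
    hub_k_min: int = 20
    module_penalty: float = 2.0
    module_min_size: int = 3
    module_overlap_merge: float = 0.8
    # PRS
    prs_window_kb: float = 250.0
    prs_r2_max: float = 0.1
    prs_flank_bp: int = 10_000
    prs_permutations: int = 1000
    prs_thresholds: tuple[float, ...] = _prs.DEFAULT_THRESHOLDS
    # classifier
    cv_folds: int = 10
    model_families: tuple[str, ...] = tuple(_classify.MODEL_ORDER)
    # stage toggles
    do_network: bool = True
    do_prs: bool = True
    do_classify: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("simulation", {}) or {}).items()
        })
        for key in ("prs_thresholds", "model_families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


@dataclass
class RunResult:
    config: RunConfig
    data: SimulatedData
    train_sets: list[CountDataset]
    test_sets: list[CountDataset]
    consensus: dict[str, set[str]]
    enrichments: list[_enrich.EnrichmentResult]
    shared_pathways: set[str]
    pool: _enrich.CandidatePool
    trace: _rfe.RFETrace
    dregs: list[str]
    network: dict = field(default_factory=dict)
    prs: dict = field(default_factory=dict)
    model_reports: list = field(default_factory=list)
    best_model: str = ""
    eval_report: _classify.EvalReport | None = None
    manifest: dict = field(default_factory=dict)


def stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage integer seed (< 2**31) from the master seed."""
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31 - 1))


def stratified_split(
    dataset: CountDataset, test_fraction: float = 0.3, seed: int = 0
) -> tuple[CountDataset, CountDataset, np.ndarray]:
    """Per-dataset stratified train/test split (no overlap); returns the test mask."""
    rng = np.random.default_rng(seed)
    pheno = dataset.covariates["phenotype"].to_numpy()
    test_mask = np.zeros(len(pheno), dtype=bool)
    for grp in ("case", "control"):
        idx = np.flatnonzero(pheno == grp)
        n_test = int(round(test_fraction * idx.size))
        test_mask[rng.choice(idx, size=n_test, replace=False)] = True
    cols = np.array(dataset.samples)
    train = CountDataset(
        dataset.counts[cols[~test_mask]],
        dataset.covariates.loc[cols[~test_mask]],
        dataset.name,
    )
    test = CountDataset(
        dataset.counts[cols[test_mask]],
        dataset.covariates.loc[cols[test_mask]],
        dataset.name,
    )
    return train, test, test_mask


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full synthetic-data pipeline and collect all stage outputs."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "simulation"
        },
        "simulation": asdict(config.simulation),
        "seeds": {},
        "stages": {},
        "outputs": {},
    }

    def _finish_stage(name: str, t0: float, files: list[Path] | None = None) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        for f in files or []:
            manifest["outputs"][str(f.name)] = _hash_file(f)

    def _write_manifest() -> None:
        if out is not None:
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1, default=str)

    try:
        # -- simulate ------------------------------------------------------
        t0 = time.time()
        data = simulate_all(config.simulation)
        files: list[Path] = []
        if out is not None:
            for ds in data.datasets:
                files.extend(_io.write_dataset(ds, out))
            data.collection.write_gmt(out / "pathways.gmt")
            _io.write_edges(data.interactome, out / "interactome.tsv")
            _io.write_panel(data.panel, out)
            files += [out / "pathways.gmt", out / "interactome.tsv"]
        _finish_stage("simulate", t0, files)

        # -- split + DE ----------------------------------------------------
        t0 = time.time()
        split_seed = stage_seed(config.seed, 1)
        manifest["seeds"]["split"] = split_seed
        train_sets, test_sets = [], []
        for ds in data.datasets:
            tr, te, mask = stratified_split(ds, config.test_fraction, split_seed)
            train_sets.append(tr)
            test_sets.append(te)
            if out is not None:
                pd.Series(mask, index=ds.samples, name="is_test").to_csv(
                    out / f"{ds.name}.split.tsv", sep="\t"
                )
        consensus: dict[str, set[str]] = {}
        de_files = []
        for ds in train_sets:
            results, cons = run_all_de(
                ds, alpha=config.alpha, lfc_min=config.lfc_min, min_cpm=config.min_cpm
            )
            consensus[ds.name] = set(cons.genes)
            if out is not None:
                for r in results:
                    f = out / f"{ds.name}.{r.method}.tsv"
                    r.table.to_csv(f, sep="\t", index_label="gene_id", float_format="%.6g")
                    de_files.append(f)
                f = out / f"{ds.name}.consensus.tsv"
                cons.table.to_csv(f, sep="\t", index_label="gene_id", float_format="%.6g")
                de_files.append(f)
        logger.info(
            "consensus DEGs per dataset: %s (alpha=%g, lfc>%g)",
            {k: len(v) for k, v in consensus.items()}, config.alpha, config.lfc_min,
        )
        _finish_stage("consensus_de", t0, de_files)
        _write_manifest()

        # -- enrichment + pool --------------------------------------------
        t0 = time.time()
        universe = set(data.collection.universe) & set(data.datasets[0].genes)
        enrichments = [
            _enrich.hypergeom_enrich(consensus[ds.name], data.collection, universe, ds.name)
            for ds in train_sets
        ]
        shared = _enrich.shared_pathways(enrichments, alpha=config.alpha)
        pool = _enrich.candidate_pool(shared, data.collection, consensus)
        if out is not None:
            for e in enrichments:
                e.table.to_csv(out / f"{e.dataset}.enrichment.tsv", sep="\t", float_format="%.6g")
            pd.Series(sorted(shared)).to_csv(out / "shared_pathways.tsv", sep="\t", index=False, header=["pathway"])
            pool.provenance.to_csv(out / "candidate_pool.tsv", sep="\t", index=False)
        logger.info("%d shared pathways, %d pooled genes", len(shared), len(pool.genes))
        _finish_stage("enrichment", t0)
        _write_manifest()

        # -- RFE -----------------------------------------------------------
        t0 = time.time()
        rfe_seed = stage_seed(config.seed, 2)
        manifest["seeds"]["rfe"] = rfe_seed
        features = _rfe.expression_features(train_sets, genes=pool.genes)
        trace = _rfe.svm_rfe(
            features, step=config.rfe_step, folds=config.rfe_folds, seed=rfe_seed
        )
        dregs = trace.selected
        if out is not None:
            trace.records.to_csv(out / "rfe_trace.tsv", sep="\t", index=False, float_format="%.6g")
            pd.Series(dregs).to_csv(out / "dregs.txt", index=False, header=["gene_id"])
        logger.info("RFE selected %d DREGs from pool of %d", len(dregs), len(pool.genes))
        _finish_stage("rfe", t0)
        _write_manifest()

        result = RunResult(
            config, data, train_sets, test_sets, consensus, enrichments,
            shared, pool, trace, dregs, manifest=manifest,
        )

        # -- network -------------------------------------------------------
        if config.do_network:
            t0 = time.time()
            net_seed = stage_seed(config.seed, 3)
            manifest["seeds"]["network"] = net_seed
            graph = data.interactome
            betw = None  # full-graph betweenness is costly; computed on demand
            stats_ = _network.induced_stats(graph, dregs, betweenness=betw)
            perm = _network.connectivity_permutation_test(
                graph, dregs, config.network_permutations, net_seed
            )
            comparison = _network.centrality_comparison(graph, dregs)
            hubs = _network.find_hubs(stats_, config.hub_k_min)
            sub = graph.subgraph(stats_.members)
            modules = _network.detect_modules(
                sub,
                penalty=config.module_penalty,
                min_size=config.module_min_size,
                overlap_merge=config.module_overlap_merge,
                seed=net_seed,
            )
            result.network = {
                "stats": stats_,
                "permutation": perm,
                "centrality": comparison,
                "hubs": hubs,
                "modules": modules,
            }
            if out is not None:
                stats_.per_node.to_csv(out / "subnetwork_nodes.tsv", sep="\t", float_format="%.6g")
                comparison.to_csv(out / "centrality_tests.tsv", sep="\t", float_format="%.6g")
            _finish_stage("network", t0)
            _write_manifest()

        # -- PRS -----------------------------------------------------------
        if config.do_prs:
            t0 = time.time()
            prs_seed = stage_seed(config.seed, 4)
            manifest["seeds"]["prs"] = prs_seed
            panel = data.panel
            qcd = _prs.qc_filter(panel.summary)
            index_snps = _prs.clump(qcd, panel.dosages, config.prs_window_kb, config.prs_r2_max)
            qcd_idx = qcd[qcd["SNP"].isin(index_snps)]
            genomewide = _prs.score_and_associate(
                panel, index_snps, config.prs_thresholds, config.prs_permutations, prs_seed
            )
            restricted = _prs.restrict_to_gene_set(
                qcd_idx, panel.bed, config.prs_flank_bp, genes=set(dregs)
            )
            geneset = _prs.score_and_associate(
                panel, restricted["SNP"].tolist(), config.prs_thresholds,
                config.prs_permutations, prs_seed,
            )
            result.prs = {"genomewide": genomewide, "geneset": geneset}
            if out is not None:
                genomewide.per_threshold.to_csv(out / "prs_genomewide.tsv", sep="\t", index=False, float_format="%.6g")
                geneset.per_threshold.to_csv(out / "prs_geneset.tsv", sep="\t", index=False, float_format="%.6g")
            _finish_stage("prs", t0)
            _write_manifest()

        # -- classifier ----------------------------------------------------
        if config.do_classify:
            t0 = time.time()
            clf_seed = stage_seed(config.seed, 5)
            manifest["seeds"]["classifier"] = clf_seed
            train_fm = _rfe.expression_features(train_sets, genes=dregs)
            reports, best = _classify.crossval_models(
                train_fm.x, train_fm.labels, config.cv_folds, clf_seed,
                families=list(config.model_families),
            )
            best_rep = next(r for r in reports if r.name == best)
            pipe = _classify.fit_final(best, best_rep.params, train_fm.x, train_fm.labels, clf_seed)
            test_fm = _rfe.expression_features(test_sets, genes=list(train_fm.x.columns))
            named = {"internal_test": (test_fm.x, test_fm.labels)}
            for ds in test_sets:
                sel = test_fm.datasets == ds.name
                named[f"internal_test_{ds.name}"] = (test_fm.x[sel.to_numpy()], test_fm.labels[sel.to_numpy()])
            ev = _classify.evaluate(pipe, named)
            result.model_reports = reports
            result.best_model = best
            result.eval_report = ev
            if out is not None:
                rows = [(r.name, r.mean_accuracy, r.sem_accuracy, json.dumps(r.params)) for r in reports]
                pd.DataFrame(rows, columns=["model", "mean_accuracy", "sem", "params"]).to_csv(
                    out / "model_cv.tsv", sep="\t", index=False, float_format="%.6g"
                )
                ev.table().to_csv(out / "evaluation.tsv", sep="\t", float_format="%.6g")
            _finish_stage("classifier", t0)
        _write_manifest()
        return result
    except Exception:
        manifest["failed"] = True
        _write_manifest()
        raise
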