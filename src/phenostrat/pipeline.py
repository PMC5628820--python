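"""End-to-end orchestration of the stratification workflow.

A :class:`RunConfig` fully determines a run: cohort simulation (or input
paths), preprocessing, forest dissimilarity, cluster selection, the
permutation null, the three supervised models with a shared fixed 90/10
split, optional cross-cohort validation, and the two-stage
extreme-vs-mixture model.  Every stage writes its artifact (TSV for
matrices, JSON for reports) and the manifest records the configuration,
seeds and output hashes so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import CohortModel, CohortSpec, inject_missing
from .clustering import classical_mds, cluster_label_agreement, savannah, select_k
from .matrix import PhenotypeMatrix
from .preprocess import preprocess_pipeline
from .proximity import ForestConfig, fit_unsupervised_forest
from .supervised import (
    cross_cohort_validate,
    evaluate,
    fit_method,
    split_train_test,
)
from .two_stage import two_stage_analysis

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("phenostrat")

ALL_STAGES = (
    "simulate", "preprocess", "dissimilarity", "cluster", "savannah",
    "train", "evaluate", "crossvalidate", "two_stage",
)


@dataclass
class RunConfig:
    """Everything a full run needs; YAML-serializable."""

    out_dir: str = "phenostrat_run"
    stages: tuple = ALL_STAGES
    # simulation (ignored when input paths are given)
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    extreme_path: str | None = None
    nonextreme_path: str | None = None
    second_cohort_path: str | None = None
    shared_features: int = 106
    second_n_per_class: tuple = (32, 32, 32)
    # preprocessing
    missing_threshold: float = 0.05
    # clustering
    ntree: int = 10_000
    savannah_ntree: int = 2_000
    n_permutations: int = 20
    kmin: int = 2
    kmax: int = 20
    # modelling
    methods: tuple = ("lasso", "enet", "rf")
    train_fraction: float = 0.9
    n_folds: int = 10
    boruta_runs: int = 100
    forest_tuning: dict = field(default_factory=dict)  # tune_forest overrides
    two_stage_candidates: int = 10
    seed: int = 1
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["methods"] = list(self.methods)
        d["second_n_per_class"] = list(self.second_n_per_class)
        cohort = dict(self.cohort)
        if "n_nonextreme" in cohort:  # tuple pair keys are not JSON/YAML keys
            cohort["n_nonextreme"] = {
                ("+".join(k) if isinstance(k, tuple) else str(k)): v
                for k, v in cohort["n_nonextreme"].items()}
        for key, val in cohort.items():
            if isinstance(val, tuple):
                cohort[key] = list(val)
        d["cohort"] = cohort
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dictionary.

    Any stage error aborts the run with the stage named in the exception;
    artifacts written so far are kept and a ``MANIFEST.partial`` marker is
    left beside them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="[phenostrat %(levelname)s] %(message)s",
        force=True,
    )
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "outputs": {},
        "results": {},
    }
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)
        return path

    try:
        spec = CohortSpec(**{"seed": config.seed, **config.cohort})
        model = CohortModel(spec)

        stage = "simulate"
        if config.extreme_path:
            raw = PhenotypeMatrix.from_tsv(config.extreme_path)
        else:
            raw = inject_missing(model.generate_extreme(), spec.missing_rate, spec.seed)
        nonextreme = None
        if config.nonextreme_path:
            nonextreme = PhenotypeMatrix.from_tsv(config.nonextreme_path)
        elif "simulate" in config.stages:
            nonextreme = model.generate_nonextreme()
        if "simulate" in config.stages:
            log.info("simulate: %d extreme / %s mixture samples", raw.n_samples,
                     "no" if nonextreme is None else nonextreme.n_samples)
            emit("extreme_raw.tsv", raw.to_tsv)
            if nonextreme is not None:
                emit("nonextreme.tsv", nonextreme.to_tsv)

        stage = "preprocess"
        if "preprocess" in config.stages:
            clean, report = preprocess_pipeline(raw, config.missing_threshold)
            log.info("preprocess: %d -> %d features", raw.n_features, clean.n_features)
            emit("extreme_clean.tsv", clean.to_tsv)
            emit("preprocess_report.json", report.to_json)
            manifest["results"]["n_features_clean"] = clean.n_features
        else:
            clean = raw

        D = None
        stage = "dissimilarity"
        if "dissimilarity" in config.stages:
            D = fit_unsupervised_forest(clean, ForestConfig(ntree=config.ntree, seed=config.seed))
            emit("dissimilarity.tsv", D.to_tsv)
            mds = classical_mds(D, dims=2)
            emit("mds_coords.tsv", mds.to_tsv)

        stage = "cluster"
        if "cluster" in config.stages and D is not None:
            k_star, sols = select_k(D, config.kmin, config.kmax, config.seed)
            agreement = cluster_label_agreement(sols[k_star].assignment, clean.labels)
            log.info("cluster: k*=%d agreement=%.3f", k_star, agreement)
            manifest["results"]["k_star"] = k_star
            manifest["results"]["agreement"] = agreement
            emit("clusters.json", lambda p: Path(p).write_text(json.dumps({
                "k_star": k_star,
                "agreement": agreement,
                "avg_silhouette": {k: s.avg_silhouette for k, s in sols.items()},
                "assignment": sols[k_star].assignment.to_dict(),
                "medoids": sols[k_star].medoids,
            }, indent=2)))

        stage = "savannah"
        if "savannah" in config.stages:
            sav = savannah(clean, ForestConfig(ntree=config.savannah_ntree, seed=config.seed),
                           n_permutations=config.n_permutations,
                           kmin=config.kmin, kmax=config.kmax, seed=config.seed)
            emit("savannah.tsv", sav.to_long_tsv)
            manifest["results"]["savannah_max_original"] = float(sav.original_widths.max())
            manifest["results"]["savannah_max_permuted"] = float(sav.permuted_widths.max())

        models = {}
        stage = "train"
        if "train" in config.stages:
            train, test = split_train_test(clean, config.train_fraction, config.seed)
            for method in config.methods:
                log.info("train: %s", method)
                kw = config.forest_tuning if method == "rf" else {}
                models[method] = fit_method(train, method, seed=config.seed,
                                            n_folds=config.n_folds,
                                            boruta_runs=config.boruta_runs, **kw)
            emit("selected_features.json", lambda p: Path(p).write_text(json.dumps(
                {m: list(mod.selected_features) for m, mod in models.items()}, indent=2)))

            stage = "evaluate"
            if "evaluate" in config.stages:
                holdout = {m: evaluate(mod, test).as_percent() for m, mod in models.items()}
                emit("holdout_eval.json", lambda p: Path(p).write_text(
                    json.dumps(holdout, indent=2)))
                manifest["results"]["holdout_accuracy_pct"] = {
                    m: holdout[m]["overall_accuracy_pct"] for m in holdout}

        stage = "crossvalidate"
        if "crossvalidate" in config.stages:
            if config.second_cohort_path:
                cohort_b = PhenotypeMatrix.from_tsv(config.second_cohort_path)
            else:
                cohort_b = model.generate_second_cohort(
                    config.shared_features, config.second_n_per_class)
                emit("cohortB.tsv", cohort_b.to_tsv)
            xval = {}
            for method in config.methods:
                log.info("crossvalidate: %s", method)
                kw = config.forest_tuning if method == "rf" else {}
                report, _ = cross_cohort_validate(clean, cohort_b, method,
                                                  seed=config.seed,
                                                  fraction=config.train_fraction,
                                                  boruta_runs=config.boruta_runs, **kw)
                xval[method] = report.as_percent()
            emit("crossvalidation.json", lambda p: Path(p).write_text(json.dumps(xval, indent=2)))
            manifest["results"]["crossvalidation"] = {
                m: xval[m]["overall_accuracy_pct"] for m in xval}

        stage = "two_stage"
        if "two_stage" in config.stages and models and nonextreme is not None:
            extreme_clean = clean
            mixture = nonextreme.select_features(
                [f for f in clean.feature_ids if f in set(nonextreme.feature_ids)])
            results = two_stage_analysis(models, extreme_clean, mixture,
                                         n_candidates=config.two_stage_candidates,
                                         seed=config.seed)
            emit("two_stage_scores.tsv", lambda p: pd_concat_scores(results).to_csv(
                p, sep="\t"))
            emit("two_stage.json", lambda p: Path(p).write_text(json.dumps(
                {m: r["report"] for m, r in results.items()}, indent=2)))
            manifest["results"]["two_stage_auc"] = {
                m: results[m]["report"]["auc"] for m in results}

        stage = "manifest"
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        partial = out / "MANIFEST.partial"
        if partial.exists():
            partial.unlink()
        return manifest
    except Exception as exc:
        (out / "MANIFEST.partial").write_text(json.dumps(
            {"failed_stage": stage, "error": str(exc), "manifest": manifest}, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def pd_concat_scores(results: dict):
    import pandas as pd

    return pd.concat([r["scores"].to_frame() for r in results.values()])
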