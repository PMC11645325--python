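"""Configuration-driven end-to-end run of the LAMA prediction framework.

Stages: generate (or load) raw visits -> optional missingness degradation ->
KNN imputation (+ MAPE validation report) -> encoding -> stratified 80/20
split -> optional SFS/SBS feature selection -> per data group x sampling mode:
annealer-tuned gradient boosting with k-fold CV -> test-set evaluation ->
attribution of the best model.  Every stage seed derives deterministically
from the run seed and is recorded in a JSON manifest, so a rerun of the same
config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .atsa import AtsaConfig, AtsaResult, optimize, trace_to_csv
from .datagen import LABEL_COLUMN, GeneratorConfig, degrade, generate_visits
from .explain import attribute, interactions, summarize
from .impute import encode_features, knn_impute, validate_imputation
from .objective import (
    CVObjective,
    VisitTable,
    audit_leakage,
    metric_suite,
    rebalance,
    split_train_test,
    train_learner,
)
from .select import run_selectors, selection_frequency
from .space import SearchSpace, Solution, default_xgb_space

__all__ = ["RunConfig", "PipelineResult", "ModelRecord", "run_pipeline"]

log = logging.getLogger("edlama")

_STAGES = ("generate", "degrade", "impute", "encode", "select", "optimize", "evaluate", "explain")


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    ss = np.random.SeedSequence([seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    out_dir: str = "edlama_run"
    input_csv: Optional[str] = None  # if given, skip generation and load this
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    degrade_rates: Optional[Mapping[str, float]] = None
    impute_k: int = 5
    validate_fraction: Optional[float] = None  # e.g. 0.1 to emit a MAPE report
    run_selection: bool = True
    selection_tolerance: float = 1e-4
    selection_rf_trees: int = 100
    selection_estimators: Sequence[str] = ("DT", "RF")
    groups: Optional[Sequence[str]] = None  # None = all five from selection
    modes: Sequence[str] = ("oversample", "undersample")
    split_ratio: float = 0.8
    k: int = 4
    threshold: float = 0.5
    atsa: AtsaConfig = field(default_factory=AtsaConfig)
    space: SearchSpace = field(default_factory=default_xgb_space)
    explain_interactions: bool = True

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "input_csv": self.input_csv,
            "generator": {
                "n": self.generator.n,
                "prevalence": self.generator.prevalence,
                "effect_weights": dict(self.generator.effect_weights),
                "correlations": [list(c) for c in self.generator.correlations],
                "seed": self.generator.seed,
            },
            "degrade_rates": dict(self.degrade_rates) if self.degrade_rates else None,
            "impute_k": self.impute_k,
            "validate_fraction": self.validate_fraction,
            "run_selection": self.run_selection,
            "selection_tolerance": self.selection_tolerance,
            "selection_rf_trees": self.selection_rf_trees,
            "selection_estimators": list(self.selection_estimators),
            "groups": list(self.groups) if self.groups else None,
            "modes": list(self.modes),
            "split_ratio": self.split_ratio,
            "k": self.k,
            "threshold": self.threshold,
            "atsa": self.atsa.to_dict(),
            "space": self.space.to_dict(),
            "explain_interactions": self.explain_interactions,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], Mapping):
            g = dict(d["generator"])
            if "correlations" in g:
                g["correlations"] = [tuple(c) for c in g["correlations"]]
            d["generator"] = GeneratorConfig(**g)
        if "atsa" in d and isinstance(d["atsa"], Mapping):
            d["atsa"] = AtsaConfig(**d["atsa"])
        if "space" in d and isinstance(d["space"], Mapping):
            d["space"] = SearchSpace.from_dict(d["space"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ModelRecord:
    """One tuned model: a data group under one sampling mode."""

    group: str
    mode: str
    features: tuple[str, ...]
    best_solution: Solution
    cv_mean: dict[str, float]
    cv_sd: dict[str, float]
    test: dict[str, float]
    atsa_result: AtsaResult

    @property
    def name(self) -> str:
        return f"{self.group}/{self.mode}"


@dataclass
class PipelineResult:
    run_dir: Path
    table: VisitTable
    models: list[ModelRecord]
    best_by_cv: ModelRecord
    best_by_test: ModelRecord
    manifest: dict
    imputation_report: Optional[pd.DataFrame] = None
    selection_report: Optional[pd.DataFrame] = None
    metrics_report: Optional[pd.DataFrame] = None
    params_report: Optional[pd.DataFrame] = None
    attribution_summary: Optional[pd.DataFrame] = None
    leakage_report: Optional[dict] = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _metrics_row(rec: ModelRecord) -> dict:
    row = {"model": rec.group, "mode": rec.mode}
    for m in ("accuracy", "auc", "sensitivity", "specificity"):
        row[f"cv_{m}_mean"] = rec.cv_mean[m]
        row[f"cv_{m}_sd"] = rec.cv_sd[m]
    for m in ("accuracy", "auc", "sensitivity", "specificity"):
        row[f"test_{m}"] = rec.test[m]
    return row


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the framework end to end and write all reports under ``out_dir``."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"config": config.to_dict(), "stage_seeds": {}, "timings": timings}
    try:
        import sklearn
        import xgboost

        manifest["versions"] = {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        }
    except Exception:  # pragma: no cover
        pass

    def stage(name: str):
        manifest["stage_seeds"][name] = _stage_seed(config.seed, name)
        log.info("stage %s starting", name)
        return time.perf_counter()

    def done(name: str, t0: float) -> None:
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])

    # generate ---------------------------------------------------------------
    t0 = stage("generate")
    try:
        if config.input_csv:
            raw = pd.read_csv(config.input_csv)
            truth = None
        else:
            raw, truth = generate_visits(config.generator)
            with open(run_dir / "ground_truth.json", "w") as fh:
                json.dump(truth, fh, indent=2, default=float)
    except Exception as exc:
        raise StageError("generate", exc) from exc
    done("generate", t0)

    # degrade ----------------------------------------------------------------
    if config.degrade_rates:
        t0 = stage("degrade")
        try:
            raw = degrade(
                raw, config.degrade_rates, seed=manifest["stage_seeds"]["degrade"]
            )
        except Exception as exc:
            raise StageError("degrade", exc) from exc
        done("degrade", t0)

    # impute -----------------------------------------------------------------
    t0 = stage("impute")
    imputation_report = None
    try:
        if raw.drop(columns=[LABEL_COLUMN], errors="ignore").isna().any().any():
            raw = knn_impute(raw, k=config.impute_k, label_col=LABEL_COLUMN)
        if config.validate_fraction:
            report = validate_imputation(
                raw,
                fraction=config.validate_fraction,
                k=config.impute_k,
                seed=manifest["stage_seeds"]["impute"],
                label_col=LABEL_COLUMN,
            )
            imputation_report = report.to_frame()
            imputation_report.to_csv(run_dir / "imputation_mape.csv", index=False)
    except Exception as exc:
        raise StageError("impute", exc) from exc
    done("impute", t0)

    # encode -----------------------------------------------------------------
    t0 = stage("encode")
    try:
        table = encode_features(raw, label_col=LABEL_COLUMN)
    except Exception as exc:
        raise StageError("encode", exc) from exc
    done("encode", t0)

    # split ------------------------------------------------------------------
    split = split_train_test(
        table, ratio=config.split_ratio, seed=_stage_seed(config.seed, "optimize"), k=config.k
    )
    train_df = table.df.loc[split.train_ids]
    test_df = table.df.loc[split.test_ids]

    # select -----------------------------------------------------------------
    selection_report = None
    t0 = stage("select")
    try:
        if config.run_selection:
            from .select import default_estimators

            train_table = VisitTable(train_df, table.label_col, table.schema)
            estimators = {
                name: est
                for name, est in default_estimators(
                    manifest["stage_seeds"]["select"], rf_trees=config.selection_rf_trees
                ).items()
                if name in config.selection_estimators
            }
            subsets = run_selectors(
                train_table,
                seed=manifest["stage_seeds"]["select"],
                estimators=estimators,
                k=config.k,
                tolerance=config.selection_tolerance,
            )
            summary = selection_frequency(subsets)
            selection_report = summary.to_frame()
            selection_report.to_csv(run_dir / "feature_selection.csv")
            group_features = {name: list(sub.features) for name, sub in subsets.items()}
        else:
            group_features = {"X_all": table.features}
    except Exception as exc:
        raise StageError("select", exc) from exc
    done("select", t0)

    if config.groups:
        group_features = {g: group_features[g] for g in config.groups}
    group_features = {g: f for g, f in group_features.items() if f}

    # optimize + evaluate ----------------------------------------------------
    models: list[ModelRecord] = []
    leakage_report: dict = {}
    y_test = test_df[table.label_col].to_numpy(dtype=int)
    t0 = stage("optimize")
    try:
        opt_seed = manifest["stage_seeds"]["optimize"]
        for group, feats in group_features.items():
            for mode in config.modes:
                cv = CVObjective(
                    train_df,
                    table.label_col,
                    k=config.k,
                    mode=mode,
                    seed=opt_seed,
                    feature_cols=feats,
                    threshold=config.threshold,
                )
                leakage_report[f"{group}/{mode}"] = audit_leakage(cv, split.test_ids)
                atsa_cfg = AtsaConfig(
                    **{**config.atsa.to_dict(), "seed": opt_seed}
                )
                result = optimize(cv, config.space, atsa_cfg)
                trace_to_csv(result.trace, run_dir / f"trace_{group}_{mode}.csv")
                cv_best = cv.evaluate(result.best)
                fit_df = rebalance(train_df, table.label_col, mode, seed=opt_seed)
                model = train_learner(
                    result.best, fit_df, table.label_col, seed=opt_seed, feature_cols=feats
                )
                test_metrics = metric_suite(
                    model.predict_proba(test_df), y_test, threshold=config.threshold
                )
                models.append(
                    ModelRecord(
                        group=group,
                        mode=mode,
                        features=tuple(feats),
                        best_solution=result.best,
                        cv_mean={
                            m: cv_best.mean(m)
                            for m in ("accuracy", "auc", "sensitivity", "specificity")
                        },
                        cv_sd={
                            m: cv_best.sd(m)
                            for m in ("accuracy", "auc", "sensitivity", "specificity")
                        },
                        test=test_metrics.as_dict(),
                        atsa_result=result,
                    )
                )
                log.info(
                    "model %s/%s: cv mean AUC %.3f, test AUC %.3f",
                    group,
                    mode,
                    models[-1].cv_mean["auc"],
                    models[-1].test["auc"],
                )
    except Exception as exc:
        raise StageError("optimize", exc) from exc
    done("optimize", t0)

    # reports ----------------------------------------------------------------
    t0 = stage("evaluate")
    try:
        metrics_report = pd.DataFrame([_metrics_row(r) for r in models])
        metrics_report.to_csv(run_dir / "model_metrics.csv", index=False)
        params_report = pd.DataFrame(
            [
                {"model": r.group, "mode": r.mode, **r.best_solution.values}
                for r in models
            ]
        )
        params_report.to_csv(run_dir / "tuned_parameters.csv", index=False)
        best_by_cv = max(models, key=lambda r: r.cv_mean["auc"])
        best_by_test = max(models, key=lambda r: r.test["auc"])
        manifest["best_by_cv"] = best_by_cv.name
        manifest["best_by_test"] = best_by_test.name
        manifest["leakage_clean"] = all(v["clean"] for v in leakage_report.values())
    except Exception as exc:
        raise StageError("evaluate", exc) from exc
    done("evaluate", t0)

    # explain ----------------------------------------------------------------
    t0 = stage("explain")
    try:
        rec = best_by_cv
        fit_df = rebalance(
            train_df, table.label_col, rec.mode, seed=manifest["stage_seeds"]["optimize"]
        )
        model = train_learner(
            rec.best_solution,
            fit_df,
            table.label_col,
            seed=manifest["stage_seeds"]["optimize"],
            feature_cols=list(rec.features),
        )
        attr = attribute(model, test_df)
        summary = summarize(attr)
        attribution_summary = summary.table
        attribution_summary.to_csv(run_dir / "attribution_summary.csv", index=False)
        manifest["attribution_max_residual"] = attr.max_residual
        if config.explain_interactions:
            grid = interactions(model, test_df)
            grid.matrix.to_csv(run_dir / "attribution_interactions.csv")
    except Exception as exc:
        raise StageError("explain", exc) from exc
    done("explain", t0)

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    config.to_yaml(run_dir / "config.yaml")

    return PipelineResult(
        run_dir=run_dir,
        table=table,
        models=models,
        best_by_cv=best_by_cv,
        best_by_test=best_by_test,
        manifest=manifest,
        imputation_report=imputation_report,
        selection_report=selection_report,
        metrics_report=metrics_report,
        params_report=params_report,
        attribution_summary=attribution_summary,
        leakage_report=leakage_report,
    )
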