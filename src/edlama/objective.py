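"""From a labeled visit table to the black-box objective the annealer tunes.

The pipeline splits visits 80/20 stratified by disposition, rebalances the
training side of each cross-validation fold by random over- or undersampling
(the held-out validation fold and the test set are never resampled), fits a
gradient-boosted tree classifier under a candidate hyperparameter solution,
and scores rank-based AUC plus the accuracy/sensitivity/specificity suite.
The scalar handed to the optimizer is the mean validation-fold AUC across
k folds with fold assignment fixed for the whole optimization run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .space import Solution

__all__ = [
    "VisitTable",
    "SplitIndices",
    "Metrics",
    "CVResult",
    "FittedModel",
    "split_train_test",
    "rebalance",
    "train_learner",
    "auc",
    "metric_suite",
    "CVObjective",
    "cv_objective",
    "audit_leakage",
]

#: Fixed (non-tuned) learner settings; everything else is library default.
_BASE_PARAMS = {
    "objective": "binary:logistic",
    "tree_method": "hist",
    "max_bin": 64,
    "nthread": 1,
}

#: Tuned axis name -> xgboost parameter name ("n_estimators" is the number of
#: boosting rounds and is handled separately).
_PARAM_MAP = {
    "max_depth": "max_depth",
    "max_delta_step": "max_delta_step",
    "num_parallel_tree": "num_parallel_tree",
    "learning_rate": "eta",
    "reg_alpha": "alpha",
    "reg_lambda": "lambda",
    "gamma": "gamma",
}
_INT_PARAMS = {"max_depth", "max_delta_step", "num_parallel_tree"}


@dataclass
class VisitTable:
    """Rectangular visit dataset plus schema metadata shared by all stages.

    ``schema`` maps every feature column to its kind (``"numeric"`` or
    ``"binary"``); the label column is coded LAMA = 1, SAT = 0.
    """

    df: pd.DataFrame
    label_col: str
    schema: dict[str, str]

    def __post_init__(self) -> None:
        if self.label_col not in self.df.columns:
            raise ValueError(f"label column {self.label_col!r} missing")
        y = self.df[self.label_col]
        if not y.isin([0, 1]).all():
            raise ValueError("label must be binary 0/1")
        feature_cols = [c for c in self.df.columns if c != self.label_col]
        uncovered = set(feature_cols) - set(self.schema)
        if uncovered:
            raise ValueError(f"schema does not cover columns {sorted(uncovered)}")
        if self.df[feature_cols].isna().any().any():
            raise ValueError("visit table must have no missing values")

    @property
    def features(self) -> list[str]:
        return [c for c in self.df.columns if c != self.label_col]

    @property
    def labels(self) -> np.ndarray:
        return self.df[self.label_col].to_numpy(dtype=int)

    def subset(self, ids: Sequence) -> pd.DataFrame:
        return self.df.loc[list(ids)]


@dataclass(frozen=True)
class SplitIndices:
    """Stratified train/test row ids plus a k-fold assignment of train rows."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    fold_of: pd.Series  # index = train row id, value = fold number

    def __post_init__(self) -> None:
        train, test = set(self.train_ids.tolist()), set(self.test_ids.tolist())
        if train & test:
            raise ValueError("train and test overlap")
        if set(self.fold_of.index.tolist()) != train:
            raise ValueError("fold assignment must cover exactly the train rows")

    @property
    def k(self) -> int:
        return int(self.fold_of.nunique())


def split_train_test(
    table: VisitTable, ratio: float = 0.8, seed: int = 0, k: int = 4
) -> SplitIndices:
    """Stratified train/test split plus stratified k-fold assignment.

    ``ratio`` is the training fraction; the test rows are never touched by
    rebalancing downstream.  Stratification keeps both disposition classes in
    every partition and fold, which is essential at a 0.66% prevalence.
    """
    y = table.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 rows to stratify")
    ids = table.df.index.to_numpy()
    train_ids, test_ids = train_test_split(
        ids, train_size=ratio, random_state=seed, stratify=y, shuffle=True
    )
    y_train = table.df.loc[train_ids, table.label_col].to_numpy(dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(train_ids), dtype=int)
    for f, (_, val_idx) in enumerate(skf.split(np.zeros(len(train_ids)), y_train)):
        fold[val_idx] = f
    return SplitIndices(
        train_ids=np.asarray(train_ids),
        test_ids=np.asarray(test_ids),
        fold_of=pd.Series(fold, index=pd.Index(train_ids)),
    )


def rebalance(
    df: pd.DataFrame, label_col: str, mode: str, seed: int = 0
) -> pd.DataFrame:
    """Equalize class counts by random over- or undersampling.

    ``oversample`` keeps every row and duplicates randomly chosen minority
    rows (no synthetic interpolation) until the counts match, so every
    minority row is present at least once.  ``undersample`` keeps the minority
    and a uniform random subset of the majority.  Row ids (the index) are
    preserved, with duplicates, so resampled sets remain auditable.
    """
    if mode not in ("oversample", "undersample"):
        raise ValueError(f"unknown mode {mode!r}")
    y = df[label_col].to_numpy(dtype=int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    if n0 == n1:
        return df.copy()
    rng = np.random.default_rng(seed)
    minority, majority = (1, 0) if n1 < n0 else (0, 1)
    min_pos = np.flatnonzero(y == minority)
    maj_pos = np.flatnonzero(y == majority)
    if mode == "oversample":
        extra = rng.choice(min_pos, size=maj_pos.size - min_pos.size, replace=True)
        keep = np.concatenate([np.arange(len(df)), extra])
    else:
        kept_maj = rng.choice(maj_pos, size=min_pos.size, replace=False)
        keep = np.sort(np.concatenate([min_pos, kept_maj]))
    return df.iloc[keep]


@dataclass
class FittedModel:
    """A trained gradient-boosted classifier plus its feature contract."""

    booster: xgb.Booster
    feature_names: list[str]
    params: dict
    n_rounds: int

    def _dmatrix(self, df: pd.DataFrame) -> xgb.DMatrix:
        missing = [c for c in self.feature_names if c not in df.columns]
        if missing:
            raise ValueError(f"table lacks model features {missing}")
        return xgb.DMatrix(
            df[self.feature_names].to_numpy(dtype=float),
            feature_names=self.feature_names,
            nthread=1,
        )

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """Class-1 (LAMA) probability per row."""
        return self.booster.predict(self._dmatrix(df)).astype(float)

    def predict_margin(self, df: pd.DataFrame) -> np.ndarray:
        """Raw additive margin (log-odds) per row."""
        return self.booster.predict(self._dmatrix(df), output_margin=True).astype(float)

    @property
    def base_margin(self) -> float:
        """The constant margin of the intercept-only ensemble."""
        import json

        cfg = json.loads(self.booster.save_config())
        base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
        from scipy.special import logit

        return float(logit(base_score))


def _solution_params(solution: Union[Solution, Mapping[str, float]]) -> dict:
    vals = dict(solution.values) if isinstance(solution, Solution) else dict(solution)
    params = dict(_BASE_PARAMS)
    for axis, xgb_name in _PARAM_MAP.items():
        if axis in vals:
            v = vals[axis]
            params[xgb_name] = int(v) if axis in _INT_PARAMS else float(v)
    n_rounds = int(vals.get("n_estimators", 1))
    return params, n_rounds


def train_learner(
    solution: Union[Solution, Mapping[str, float]],
    df: pd.DataFrame,
    label_col: str,
    seed: int = 0,
    feature_cols: Optional[Sequence[str]] = None,
) -> FittedModel:
    """Fit the boosted-tree classifier under a hyperparameter solution.

    The learner is an additive ensemble of trees minimizing logistic loss plus
    the complexity penalty ``gamma * T + (lambda/2) * ||w||^2`` (plus an L1
    term ``alpha * ||w||_1``); the eight tuned axes map onto the corresponding
    library parameters, all others stay at library defaults.  Deterministic for
    a fixed seed and parameter set (single-threaded histogram tree method).
    """
    y = df[label_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    feats = list(feature_cols) if feature_cols is not None else [
        c for c in df.columns if c != label_col
    ]
    params, n_rounds = _solution_params(solution)
    params["seed"] = int(seed)
    dtrain = xgb.DMatrix(
        df[feats].to_numpy(dtype=float), label=y, feature_names=feats, nthread=1
    )
    booster = xgb.train(params, dtrain, num_boost_round=n_rounds)
    return FittedModel(booster=booster, feature_names=feats, params=params, n_rounds=n_rounds)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def metric_suite(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> Metrics:
    """Accuracy, AUC, sensitivity (TPR on LAMA) and specificity (TNR on SAT)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    return Metrics(
        accuracy=(tp + tn) / len(labels),
        auc=auc(scores, labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
    )


@dataclass
class CVResult:
    """Per-fold metric suite with mean/sd summaries."""

    folds: list[Metrics]

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.folds])

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def sd(self, name: str) -> float:
        return float(self._values(name).std(ddof=0))

    @property
    def mean_auc(self) -> float:
        return self.mean("auc")


class CVObjective:
    """Mean k-fold validation AUC of a visit table, as a function of a solution.

    Fold assignment and the per-fold rebalanced fitting sets are fixed at
    construction: every candidate solution is scored against the same folds
    and the same resampled data, so the objective is a deterministic function
    of the solution.  Only the k-1 fitting folds are rebalanced; the
    validation fold is scored untouched.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        label_col: str,
        k: int = 4,
        mode: str = "oversample",
        seed: int = 0,
        feature_cols: Optional[Sequence[str]] = None,
        threshold: float = 0.5,
    ):
        y = df[label_col].to_numpy(dtype=int)
        if k < 2:
            raise ValueError("k must be >= 2")
        self.label_col = label_col
        self.mode = mode
        self.seed = int(seed)
        self.threshold = threshold
        self.feature_cols = list(feature_cols) if feature_cols is not None else [
            c for c in df.columns if c != label_col
        ]
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        self._folds: list[dict] = []
        for f, (fit_idx, val_idx) in enumerate(skf.split(np.zeros(len(df)), y)):
            fit_df = df.iloc[fit_idx]
            val_df = df.iloc[val_idx]
            if len(np.unique(val_df[label_col])) < 2 or len(np.unique(fit_df[label_col])) < 2:
                raise ValueError(f"fold {f} lacks both classes; reduce k or stratify input")
            fit_bal = rebalance(fit_df, label_col, mode, seed=seed + f)
            dtrain = xgb.DMatrix(
                fit_bal[self.feature_cols].to_numpy(dtype=float),
                label=fit_bal[label_col].to_numpy(dtype=int),
                feature_names=self.feature_cols,
                nthread=1,
            )
            dval = xgb.DMatrix(
                val_df[self.feature_cols].to_numpy(dtype=float),
                feature_names=self.feature_cols,
                nthread=1,
            )
            self._folds.append(
                {
                    "dtrain": dtrain,
                    "dval": dval,
                    "y_val": val_df[label_col].to_numpy(dtype=int),
                    "fit_ids": fit_bal.index.to_numpy(),
                    "val_ids": val_df.index.to_numpy(),
                }
            )

    @property
    def k(self) -> int:
        return len(self._folds)

    def audit(self) -> list[dict]:
        """Row ids of each fold's rebalanced fitting set and validation set."""
        return [
            {"fit_ids": f["fit_ids"].copy(), "val_ids": f["val_ids"].copy()}
            for f in self._folds
        ]

    def evaluate(self, solution: Union[Solution, Mapping[str, float]]) -> CVResult:
        params, n_rounds = _solution_params(solution)
        params["seed"] = self.seed
        metrics = []
        for f in self._folds:
            booster = xgb.train(params, f["dtrain"], num_boost_round=n_rounds)
            scores = booster.predict(f["dval"]).astype(float)
            metrics.append(metric_suite(scores, f["y_val"], threshold=self.threshold))
        return CVResult(folds=metrics)

    def __call__(self, solution: Union[Solution, Mapping[str, float]]) -> float:
        return self.evaluate(solution).mean_auc


def cv_objective(
    solution: Union[Solution, Mapping[str, float]],
    df: pd.DataFrame,
    label_col: str,
    k: int = 4,
    mode: str = "oversample",
    seed: int = 0,
) -> CVResult:
    """One-shot convenience wrapper around :class:`CVObjective`."""
    return CVObjective(df, label_col, k=k, mode=mode, seed=seed).evaluate(solution)


def audit_leakage(cv: CVObjective, test_ids: Sequence) -> dict:
    """Prove no test or validation-fold row entered a rebalanced fitting set.

    Returns a report with per-fold overlap counts; raises ``AssertionError``
    on any leakage.
    """
    test = set(np.asarray(test_ids).tolist())
    report = {"folds": [], "clean": True}
    for i, f in enumerate(cv.audit()):
        fit = set(f["fit_ids"].tolist())
        val = set(f["val_ids"].tolist())
        overlap_val = fit & val
        overlap_test = fit & test
        report["folds"].append(
            {"fold": i, "fit_val_overlap": len(overlap_val), "fit_test_overlap": len(overlap_test)}
        )
        if overlap_val or overlap_test:
            report["clean"] = False
    assert report["clean"], f"leakage detected: {report}"
    return report
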