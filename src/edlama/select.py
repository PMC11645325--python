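"""Sequential forward/backward wrapper feature selection.

Greedy search over feature subsets around a pluggable criterion.  Forward
selection (SFS) starts from the empty set and at each step adds the single
feature whose addition most improves the criterion, stopping when the best
addition improves by no more than the tolerance.  Backward selection (SBS)
starts from the full set and removes the feature whose removal leaves the
criterion highest; a removal is accepted on strict improvement, or when it
costs at most the tolerance while at least one feature remains.  Ties among
equally good candidates break to the lowest column index for determinism.

``run_selectors`` wraps decision-tree and random-forest estimators with both
searches using k-fold AUC as the criterion, yielding the four selected groups
plus the all-features group, and ``selection_frequency`` summarizes how often
each feature was selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .objective import VisitTable, auc

__all__ = [
    "FeatureSubset",
    "SelectionSummary",
    "sfs",
    "sbs",
    "run_selectors",
    "selection_frequency",
    "cv_auc_evaluator",
]


@dataclass
class FeatureSubset:
    """Result of one greedy search: the selected features and its step trace."""

    selector_id: str
    features: tuple[str, ...]
    trace: list[tuple[str, str, float]] = field(default_factory=list)  # (action, feature, score)
    score: float = float("nan")
    n_evaluations: int = 0


class _CachedEvaluator:
    """Memoizes the criterion so each distinct subset is scored at most once."""

    def __init__(self, evaluator: Callable[[tuple[str, ...]], float]):
        self._evaluator = evaluator
        self._cache: dict[frozenset, float] = {}
        self.n_calls = 0

    def __call__(self, subset: Sequence[str]) -> float:
        key = frozenset(subset)
        if key not in self._cache:
            self._cache[key] = float(self._evaluator(tuple(subset)))
            self.n_calls += 1
        return self._cache[key]


def sfs(
    evaluator: Callable[[tuple[str, ...]], float],
    features: Sequence[str],
    tolerance: float = 1e-4,
    max_features: Optional[int] = None,
) -> FeatureSubset:
    """Sequential forward selection starting from the empty set."""
    if not features:
        raise ValueError("need at least one candidate feature")
    features = list(features)
    ev = _CachedEvaluator(evaluator)
    selected: list[str] = []
    current = ev(selected)
    trace: list[tuple[str, str, float]] = []
    while len(selected) < len(features):
        if max_features is not None and len(selected) >= max_features:
            break
        best_feat, best_score = None, -np.inf
        for f in features:  # candidate order = column order; first best wins ties
            if f in selected:
                continue
            score = ev(selected + [f])
            if score > best_score:
                best_feat, best_score = f, score
        if best_feat is None or best_score <= current + tolerance:
            break
        selected.append(best_feat)
        current = best_score
        trace.append(("add", best_feat, best_score))
    return FeatureSubset(
        selector_id="SFS",
        features=tuple(selected),
        trace=trace,
        score=current,
        n_evaluations=ev.n_calls,
    )


def sbs(
    evaluator: Callable[[tuple[str, ...]], float],
    features: Sequence[str],
    tolerance: float = 1e-4,
    min_features: int = 0,
) -> FeatureSubset:
    """Sequential backward selection starting from the full set.

    A removal is accepted when it strictly improves the criterion (the set may
    empty itself), or when it worsens it by at most ``tolerance`` while at
    least one feature would remain.
    """
    if not features:
        raise ValueError("need at least one candidate feature")
    selected = list(features)
    ev = _CachedEvaluator(evaluator)
    current = ev(selected)
    trace: list[tuple[str, str, float]] = []
    while len(selected) > min_features:
        best_feat, best_score = None, -np.inf
        for f in selected:
            remaining = [g for g in selected if g != f]
            score = ev(remaining)
            if score > best_score:
                best_feat, best_score = f, score
        if best_feat is None:
            break
        strictly_better = best_score > current
        tolerable = best_score >= current - tolerance and len(selected) > 1
        if not (strictly_better or tolerable):
            break
        selected.remove(best_feat)
        current = best_score
        trace.append(("remove", best_feat, best_score))
    return FeatureSubset(
        selector_id="SBS",
        features=tuple(selected),
        trace=trace,
        score=current,
        n_evaluations=ev.n_calls,
    )


def cv_auc_evaluator(
    df: pd.DataFrame,
    label_col: str,
    estimator,
    k: int = 4,
    seed: int = 0,
) -> Callable[[tuple[str, ...]], float]:
    """k-fold AUC of a wrapped estimator on a candidate subset.

    The empty subset scores 0.5 (a featureless classifier is chance).  Fold
    assignment is fixed across all subsets within one selection run.
    """
    y = df[label_col].to_numpy(dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(df)), y))

    def evaluate(subset: tuple[str, ...]) -> float:
        if not subset:
            return 0.5
        X = df[list(subset)].to_numpy(dtype=float)
        aucs = []
        for fit_idx, val_idx in folds:
            est = clone(estimator)
            est.fit(X[fit_idx], y[fit_idx])
            scores = est.predict_proba(X[val_idx])[:, 1]
            aucs.append(auc(scores, y[val_idx]))
        return float(np.mean(aucs))

    return evaluate


def default_estimators(seed: int = 0, rf_trees: int = 100) -> dict:
    return {
        "DT": DecisionTreeClassifier(random_state=seed),
        "RF": RandomForestClassifier(n_estimators=rf_trees, random_state=seed, n_jobs=1),
    }


def run_selectors(
    table: VisitTable,
    seed: int = 0,
    estimators: Optional[Mapping[str, object]] = None,
    k: int = 4,
    tolerance: float = 1e-4,
    max_features: Optional[int] = None,
) -> dict[str, FeatureSubset]:
    """Run SFS and SBS around each wrapped estimator; add the all-features group.

    Returns ``{"DT_SFS": ..., "DT_SBS": ..., "RF_SFS": ..., "RF_SBS": ...,
    "X_all": ...}`` (keyed by estimator label x search direction).  Each
    estimator shares one evaluation cache between its two searches.
    """
    if estimators is None:
        estimators = default_estimators(seed)
    feats = table.features
    groups: dict[str, FeatureSubset] = {}
    for name, est in estimators.items():
        evaluator = _CachedEvaluator(
            cv_auc_evaluator(table.df, table.label_col, est, k=k, seed=seed)
        )
        fwd = sfs(evaluator, feats, tolerance=tolerance, max_features=max_features)
        bwd = sbs(evaluator, feats, tolerance=tolerance)
        groups[f"{name}_SFS"] = FeatureSubset(
            f"{name}_SFS", fwd.features, fwd.trace, fwd.score, evaluator.n_calls
        )
        groups[f"{name}_SBS"] = FeatureSubset(
            f"{name}_SBS", bwd.features, bwd.trace, bwd.score, evaluator.n_calls
        )
    groups["X_all"] = FeatureSubset("X_all", tuple(feats), [], float("nan"), 0)
    return groups


@dataclass
class SelectionSummary:
    """Per-feature selection counts across selectors, plus subset sizes."""

    counts: pd.Series  # feature -> number of selectors choosing it
    sizes: pd.Series  # selector -> subset size
    membership: pd.DataFrame  # feature x selector boolean

    def to_frame(self) -> pd.DataFrame:
        """Checkmark-style layout: feature rows, selector columns, Total column
        and a bottom totals row."""
        frame = self.membership.astype(int).copy()
        frame["Total"] = self.counts
        totals = frame.sum(axis=0)
        totals.name = "Total"
        return pd.concat([frame, totals.to_frame().T])


def selection_frequency(
    subsets: Mapping[str, Iterable[str]] | Mapping[str, FeatureSubset],
    features: Optional[Sequence[str]] = None,
    exclude: Sequence[str] = ("X_all",),
) -> SelectionSummary:
    """Count how many selectors chose each feature (all-features group excluded)."""
    sel: dict[str, set[str]] = {}
    for name, sub in subsets.items():
        if name in exclude:
            continue
        feats = sub.features if isinstance(sub, FeatureSubset) else tuple(sub)
        sel[name] = set(feats)
    if not sel:
        raise ValueError("need at least one selector subset")
    if features is None:
        if "X_all" in subsets:
            allsub = subsets["X_all"]
            features = list(
                allsub.features if isinstance(allsub, FeatureSubset) else allsub
            )
        else:
            features = sorted(set().union(*sel.values()))
    membership = pd.DataFrame(
        {name: [f in chosen for f in features] for name, chosen in sel.items()},
        index=pd.Index(features, name="Feature"),
    )
    return SelectionSummary(
        counts=membership.sum(axis=1),
        sizes=membership.sum(axis=0),
        membership=membership,
    )
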