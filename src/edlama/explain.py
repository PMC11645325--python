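"""Attribution-based interpretation of a fitted boosted-tree model.

Per-instance additive feature scores (Shapley values computed by the exact
tree-path algorithm built into xgboost), global mean-|score| summaries with a
direction indicator, and a main-plus-interaction grid.  Scores are reported in
log-odds margin units — the tree output space — because probability-space
attributions are not additive.  Local accuracy (base value plus all feature
scores equals the model's margin output) is measured and stored on every
matrix; see docs/methods.md for the backend's float32 precision envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import xgboost as xgb

from .objective import FittedModel

__all__ = ["AttributionMatrix", "AttributionSummary", "InteractionGrid", "attribute", "summarize", "interactions"]


@dataclass
class AttributionMatrix:
    """Per-instance per-feature additive scores in margin (log-odds) units."""

    values: np.ndarray  # (n, d)
    base: float  # expected model output (margin units)
    feature_names: list[str]
    feature_values: np.ndarray  # (n, d) the explained instances
    model_output: np.ndarray  # (n,) margin per instance

    @property
    def residuals(self) -> np.ndarray:
        """Local-accuracy residual |base + sum(scores) - output| per instance."""
        return np.abs(self.base + self.values.sum(axis=1) - self.model_output)

    @property
    def max_residual(self) -> float:
        return float(self.residuals.max())


@dataclass
class AttributionSummary:
    """Global importance ranking: mean |score| and a direction indicator."""

    table: pd.DataFrame  # columns: feature, mean_abs_score, direction, rank

    @property
    def ranking(self) -> list[str]:
        return self.table["feature"].tolist()


@dataclass
class InteractionGrid:
    """Feature x feature mean |interaction| with main effects on the diagonal."""

    matrix: pd.DataFrame

    @property
    def is_symmetric(self) -> bool:
        m = self.matrix.to_numpy()
        return bool(np.allclose(m, m.T, atol=1e-8))


def attribute(model: FittedModel, df: pd.DataFrame) -> AttributionMatrix:
    """Exact additive attributions of every row's prediction.

    Uses the tree-path-dependent Shapley decomposition for tree ensembles.
    The bias column returned by the backend (the cover-weighted expected
    margin) becomes the base value.
    """
    dm = model._dmatrix(df)
    contribs = model.booster.predict(dm, pred_contribs=True).astype(np.float64)
    margin = model.booster.predict(dm, output_margin=True).astype(np.float64)
    return AttributionMatrix(
        values=contribs[:, :-1],
        base=float(contribs[0, -1]),
        feature_names=list(model.feature_names),
        feature_values=df[model.feature_names].to_numpy(dtype=float),
        model_output=margin,
    )


def summarize(attr: AttributionMatrix) -> AttributionSummary:
    """Rank features by mean |score|; direction = corr(score, feature value).

    The direction statistic compresses the red-high/blue-low reading of a
    beeswarm summary into one number: positive when high feature values push
    the prediction toward LAMA.
    """
    if attr.values.size == 0:
        raise ValueError("empty attribution matrix")
    mean_abs = np.abs(attr.values).mean(axis=0)
    direction = np.zeros(len(attr.feature_names))
    for j in range(len(attr.feature_names)):
        s, v = attr.values[:, j], attr.feature_values[:, j]
        if np.std(s) > 0 and np.std(v) > 0:
            direction[j] = float(np.corrcoef(v, s)[0, 1])
    table = (
        pd.DataFrame(
            {
                "feature": attr.feature_names,
                "mean_abs_score": mean_abs,
                "direction": direction,
            }
        )
        .sort_values("mean_abs_score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return AttributionSummary(table=table)


def interactions(model: FittedModel, df: pd.DataFrame) -> InteractionGrid:
    """Mean |Shapley interaction| grid with main effects on the diagonal.

    The per-instance interaction tensor is symmetric and its rows sum (with
    the main effects) to the instance's total attribution; the grid averages
    absolute values over instances and is symmetrized against residual
    float32 asymmetry.
    """
    dm = model._dmatrix(df)
    inter = model.booster.predict(dm, pred_interactions=True).astype(np.float64)
    grid = np.abs(inter[:, :-1, :-1]).mean(axis=0)
    grid = 0.5 * (grid + grid.T)
    names = list(model.feature_names)
    return InteractionGrid(matrix=pd.DataFrame(grid, index=names, columns=names))
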