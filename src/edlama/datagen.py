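"""Synthetic emergency-department visit generator.

Emulates the published summary schema of the study hospital's triage data: one
row per ED visit with demographics, vital signs, an Emergency Severity Index
(ESI) score, temporal features, front-end waiting time and four facility
location identifiers, plus a binary disposition label (LAMA = left against
medical advice = 1, SAT = seen and treated = 0) at a configurable prevalence
(0.66% by default, matching the printed class balance).

Numeric features are drawn from truncated normals matching the printed
mean +/- sd and clipped to the printed range; a Gaussian copula imposes a
configurable correlation block (by default a modest positive correlation
between pulse and respiratory rate) so that nearest-neighbor imputation has
cross-feature structure to exploit.  The outcome is generated from a logistic
model on standardized features with configurable log-odds weights; the
intercept is calibrated numerically so the realized prevalence matches the
configured one.  The generator returns a ground-truth record (weights,
intercept, a Monte-Carlo estimate of the Bayes-optimal AUC) so tests can bound
what any fitted model may achieve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import stats
from scipy.special import expit, logit

__all__ = ["GeneratorConfig", "generate_visits", "degrade", "NUMERIC_MARGINALS", "CATEGORICAL_LEVELS"]

# name -> (mean, sd, low, high) as printed in the study's raw-data summary.
NUMERIC_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "age": (42.46, 24.83, 0.0, 107.0),
    "bmi": (28.56, 7.804, 7.38, 50.68),
    "systolic_bp": (121.01, 15.016, 69.0, 168.0),
    "diastolic_bp": (72.99, 10.802, 35.0, 107.0),
    "pulse_rate": (82.71, 16.051, 34.0, 130.0),
    "temperature_f": (97.87, 0.8, 94.4, 100.6),
    "o2_saturation": (97.54, 1.968, 92.0, 100.0),
    "respiratory_rate": (16.92, 2.122, 12.0, 23.0),
    "waiting_time": (9.31, 11.579, 0.0, 51.0),
}

# ESI is an integer acuity score; generated by rounding a latent normal.
ESI_MARGINAL = (3.23, 0.633, 2, 5)

CATEGORICAL_LEVELS: dict[str, dict[str, float]] = {
    "location_id": {"10001": 0.2761, "10025": 0.1622, "10026": 0.2032, "15001": 0.3586},
    "sex": {"Male": 0.5352, "Female": 0.4648},
    "ethnicity": {"Hispanic or Latino": 0.9522, "Not Hispanic or Latino": 0.0478},
    "smoking_status": {
        "Current Smoker": 0.2363,
        "Former Smoker": 0.0107,
        "Never Smoker": 0.0529,
        "Unknown": 0.7000,
    },
}

# Small fixed pool inside the printed zip range, standing in for the
# socio-economic proxy role of the real feature.
ZIP_POOL: tuple[int, ...] = tuple(int(z) for z in np.linspace(10016, 99750, 24).round())

LABEL_COLUMN = "disposition"

#: Default planted outcome mechanism: higher ESI (lower acuity) strongly raises
#: LAMA odds; longer front-end waits lower them.  Weights are log-odds per
#: standard deviation of the feature.
DEFAULT_EFFECT_WEIGHTS: dict[str, float] = {"esi": 2.5, "waiting_time": -2.5}


@dataclass
class GeneratorConfig:
    """Settings of the synthetic cohort.

    ``effect_weights`` maps feature names to log-odds coefficients per standard
    deviation of the feature; an empty mapping produces a signal-free cohort.
    ``correlations`` lists ``(col_a, col_b, rho)`` latent-normal correlations.
    ``missing_rates`` optionally drives :func:`degrade` from the pipeline.
    """

    n: int = 10_000
    prevalence: float = 0.0066
    effect_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS)
    )
    correlations: Sequence[tuple[str, str, float]] = field(
        default_factory=lambda: [("pulse_rate", "respiratory_rate", 0.3)]
    )
    missing_rates: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


def _truncnorm(mean: float, sd: float, low: float, high: float) -> stats.rv_continuous:
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def truncated_moments(name: str) -> tuple[float, float]:
    """Theoretical mean and sd of a named numeric marginal after truncation."""
    mean, sd, low, high = NUMERIC_MARGINALS[name]
    m, v = _truncnorm(mean, sd, low, high).stats(moments="mv")
    return float(m), float(np.sqrt(v))


def _correlated_uniforms(
    cols: Sequence[str],
    correlations: Sequence[tuple[str, str, float]],
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Gaussian-copula uniforms with the configured correlation block."""
    idx = {c: i for i, c in enumerate(cols)}
    corr = np.eye(len(cols))
    for a, b, rho in correlations:
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(cols))) @ chol.T
    u = stats.norm.cdf(z)
    # keep ppf away from exact 0/1
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return {c: u[:, i] for c, i in idx.items()}


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept a solving mean(expit(a + eta)) = prevalence."""
    if np.allclose(eta, 0.0):
        return float(logit(prevalence))

    def gap(a: float) -> float:
        return float(np.mean(expit(a + eta)) - prevalence)

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("infeasible prevalence/effect combination")
    return float(sp_optimize.brentq(gap, lo, hi, xtol=1e-10))


def generate_visits(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a raw visit table and its ground-truth record.

    Returns ``(table, truth)`` where ``truth`` holds the standardized log-odds
    weights, the calibrated intercept, the per-feature standardization
    constants and a Monte-Carlo estimate of the Bayes-optimal AUC of the
    planted mechanism on this sample.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    numeric_cols = list(NUMERIC_MARGINALS)
    u = _correlated_uniforms(numeric_cols, config.correlations, n, rng)
    data: dict[str, np.ndarray] = {}
    for name in numeric_cols:
        mean, sd, low, high = NUMERIC_MARGINALS[name]
        vals = _truncnorm(mean, sd, low, high).ppf(u[name])
        if name == "waiting_time":  # recorded in whole minutes
            vals = np.rint(vals)
        data[name] = np.clip(vals, low, high)

    mean, sd, low, high = ESI_MARGINAL
    esi = np.clip(np.rint(rng.normal(mean, sd, size=n)), low, high).astype(int)
    data["esi"] = esi.astype(float)

    for col, levels in CATEGORICAL_LEVELS.items():
        names = list(levels)
        p = np.array([levels[k] for k in names], dtype=float)
        data[col] = rng.choice(names, size=n, p=p / p.sum())

    data["zip_code"] = rng.choice(np.array(ZIP_POOL, dtype=float), size=n)
    data["day_of_month"] = rng.integers(1, 32, size=n).astype(float)
    data["month_of_year"] = rng.integers(1, 13, size=n).astype(float)
    data["hour_of_day"] = rng.integers(0, 24, size=n).astype(float)

    table = pd.DataFrame(data)

    # planted logistic outcome on standardized features
    eta = np.zeros(n)
    standardization: dict[str, tuple[float, float]] = {}
    for feat, w in config.effect_weights.items():
        if feat not in table.columns:
            raise KeyError(f"effect weight on unknown feature {feat!r}")
        x = table[feat].to_numpy(dtype=float)
        mu, sigma = float(x.mean()), float(x.std())
        if sigma == 0:
            raise ValueError(f"feature {feat!r} is constant; cannot plant an effect")
        standardization[feat] = (mu, sigma)
        eta = eta + w * (x - mu) / sigma

    intercept = _calibrate_intercept(eta, config.prevalence)
    p1 = expit(intercept + eta)
    y = (rng.random(n) < p1).astype(int)

    if y.sum() in (0, n):
        bayes_auc = 0.5
    elif np.allclose(eta, 0.0):
        bayes_auc = 0.5
    else:
        from sklearn.metrics import roc_auc_score

        bayes_auc = float(roc_auc_score(y, eta))

    table[LABEL_COLUMN] = np.where(y == 1, "LAMA", "SAT")

    truth = {
        "effect_weights": dict(config.effect_weights),
        "intercept": intercept,
        "standardization": standardization,
        "prevalence_target": config.prevalence,
        "prevalence_realized": float(y.mean()),
        "bayes_auc": bayes_auc,
        "seed": config.seed,
        "n": n,
    }
    return table, truth


def degrade(
    table: pd.DataFrame,
    rates: Mapping[str, float] | float,
    seed: int = 0,
    class_rates: Optional[Mapping[str, Mapping[str, float]]] = None,
    label_col: str = LABEL_COLUMN,
) -> pd.DataFrame:
    """Inject missing cells column-by-column; never touches the label.

    ``rates`` is either one fraction applied to every feature column or a
    mapping ``column -> fraction``.  ``class_rates`` optionally overrides a
    column's rate per disposition class (``{"bmi": {"LAMA": 0.3, "SAT": 0.1}}``)
    to emulate class-dependent missingness patterns.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    feature_cols = [c for c in table.columns if c != label_col]
    if isinstance(rates, Mapping):
        col_rates = dict(rates)
    else:
        col_rates = {c: float(rates) for c in feature_cols}
    for col, rate in col_rates.items():
        if col == label_col:
            raise ValueError("cannot degrade the label column")
        if not 0 <= rate <= 1:
            raise ValueError(f"rate for {col!r} outside [0, 1]")
        if col not in out.columns:
            raise KeyError(col)
        if class_rates and col in class_rates:
            mask = np.zeros(len(out), dtype=bool)
            for cls, r in class_rates[col].items():
                in_cls = (out[label_col] == cls).to_numpy()
                mask |= in_cls & (rng.random(len(out)) < r)
        else:
            if rate == 0:
                continue
            mask = rng.random(len(out)) < rate
        if out[col].dtype.kind in "fiu":
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
        else:
            out[col] = out[col].astype(object)
            out.loc[mask, col] = np.nan
    return out
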