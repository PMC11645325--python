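"""KNN imputation, the artificial-missingness MAPE validation protocol, and
one-hot/derived-feature preprocessing.

Missing numeric cells are replaced by the mean of the K nearest rows' values,
with distances computed nan-aware on standardized numeric features; binary
dummy columns enter the distance unscaled and are thresholded back to {0, 1}
after imputation; categorical (string) cells are filled with the modal value
among the K nearest donors.  The validation protocol withholds a fraction of
observed cells at random, imputes them, and scores the per-feature mean
absolute percentage error (MAPE) over the withheld cells only.

Preprocessing follows the study's encoding rules: a feature with c categories
becomes c-1 dummies with a documented reference level, timestamps reduce to
month and hour, repeated vital-sign readings are averaged, and waiting time
passes through in minutes.  Imputation of numerics runs on the raw table and
encoding afterwards (the package's documented order; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.metrics.pairwise import nan_euclidean_distances

from .datagen import LABEL_COLUMN
from .objective import VisitTable

__all__ = [
    "MissingnessMask",
    "ImputationReport",
    "encode_features",
    "knn_impute",
    "inject_missingness",
    "validate_imputation",
]

# Vital-sign base names whose repeated readings (suffix _1, _2, ...) average.
VITAL_COLUMNS = (
    "systolic_bp",
    "diastolic_bp",
    "pulse_rate",
    "temperature_f",
    "o2_saturation",
    "respiratory_rate",
)

TIMESTAMP_COLUMNS = ("arrival_time", "physician_assessment_time")

LABEL_CODES = {"SAT": 0, "LAMA": 1}


@dataclass(frozen=True)
class MissingnessMask:
    """Cell positions withheld by :func:`inject_missingness`."""

    positions: tuple[tuple[int, str], ...]  # (positional row index, column)
    fraction: float
    seed: int

    def rows_for(self, column: str) -> np.ndarray:
        return np.array([r for r, c in self.positions if c == column], dtype=int)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ImputationReport:
    """Per-feature MAPE (%) of KNN imputation on artificially withheld cells."""

    k: int
    fraction: float
    mape: dict[str, float]
    n_masked: dict[str, int]
    n_zero_excluded: dict[str, int]
    categorical_mismatch: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Two-column report layout: Feature, MAPE (%)."""
        return pd.DataFrame(
            {"Feature": list(self.mape), "MAPE (%)": [self.mape[f] for f in self.mape]}
        )


def _average_repeated_vitals(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for base in VITAL_COLUMNS:
        reps = [c for c in out.columns if c.startswith(base + "_") and c[len(base) + 1 :].isdigit()]
        if reps:
            stacked = out[reps].astype(float)
            if base in out.columns:
                stacked = pd.concat([stacked, out[[base]].astype(float)], axis=1)
            out[base] = stacked.mean(axis=1, skipna=True)
            out = out.drop(columns=reps)
    return out


def _reference_level(levels: Sequence[str]) -> str:
    # "Unknown"-style levels are natural references; otherwise sorted-first.
    if "Unknown" in levels:
        return "Unknown"
    return sorted(levels)[0]


def encode_features(
    raw: pd.DataFrame,
    label_col: str = LABEL_COLUMN,
    categories: Optional[Mapping[str, Sequence[str]]] = None,
) -> VisitTable:
    """Encode a raw visit table into the numeric modeling table.

    Every c-category feature becomes c-1 binary dummies named
    ``"{column}={level}"`` with the reference level dropped ("Unknown" when
    present, else the lexicographically first level).  Timestamp columns reduce
    to month and hour; repeated vital-sign readings are averaged; the label is
    coded LAMA=1, SAT=0.  Raises on category values outside the declared (or
    observed) level sets.
    """
    table = _average_repeated_vitals(raw)

    for ts in TIMESTAMP_COLUMNS:
        if ts in table.columns:
            col = pd.to_datetime(table[ts])
            if ts == "arrival_time":
                if "month_of_year" not in table.columns:
                    table["month_of_year"] = col.dt.month.astype(float)
                if "hour_of_day" not in table.columns:
                    table["hour_of_day"] = col.dt.hour.astype(float)
            table = table.drop(columns=[ts])

    if label_col not in table.columns:
        raise KeyError(f"label column {label_col!r} not present")
    label = table[label_col]
    if label.dtype == object:
        unknown = set(label.dropna().unique()) - set(LABEL_CODES)
        if unknown:
            raise ValueError(f"unknown disposition values {sorted(unknown)}")
        y = label.map(LABEL_CODES).astype(int)
    else:
        y = label.astype(int)
        if not y.isin([0, 1]).all():
            raise ValueError("numeric label must be binary 0/1")
    table = table.drop(columns=[label_col])

    schema: dict[str, str] = {}
    pieces: dict[str, pd.Series] = {}
    for col in table.columns:
        s = table[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            observed = [str(v) for v in s.dropna().unique()]
            levels = [str(v) for v in (categories[col] if categories and col in categories else sorted(observed))]
            bad = set(observed) - set(levels)
            if bad:
                raise ValueError(f"unknown category values in {col!r}: {sorted(bad)}")
            ref = _reference_level(levels)
            for level in levels:
                if level == ref:
                    continue
                name = f"{col}={level}"
                pieces[name] = (s.astype(str) == level).astype(float).where(s.notna())
                schema[name] = "binary"
        else:
            pieces[col] = s.astype(float)
            schema[col] = "numeric"

    encoded = pd.DataFrame(pieces, index=table.index)
    encoded[label_col] = y.to_numpy()
    return VisitTable(df=encoded, label_col=label_col, schema=schema)


def _standardized_numeric_block(
    df: pd.DataFrame, numeric_cols: Sequence[str], binary_cols: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columns stacked for distance/imputation: scaled numerics + raw dummies."""
    X = df[list(numeric_cols) + list(binary_cols)].to_numpy(dtype=float)
    k = len(numeric_cols)
    mu = np.nanmean(X[:, :k], axis=0) if k else np.empty(0)
    sd = np.nanstd(X[:, :k], axis=0) if k else np.empty(0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = X.copy()
    if k:
        Xs[:, :k] = (X[:, :k] - mu) / sd
    return Xs, mu, sd


def _infer_binary(df: pd.DataFrame, cols: Iterable[str]) -> list[str]:
    binary = []
    for c in cols:
        vals = df[c].dropna().unique()
        if len(vals) and np.isin(vals, [0.0, 1.0]).all():
            binary.append(c)
    return binary


def knn_impute(
    table: pd.DataFrame,
    k: int = 5,
    binary_cols: Optional[Sequence[str]] = None,
    label_col: Optional[str] = None,
) -> pd.DataFrame:
    """Complete a table by K-nearest-neighbor imputation.

    Numeric cells are filled with the mean of the K nearest rows' values in
    that column; distances are nan-aware Euclidean over standardized numeric
    columns with dummy columns included unscaled.  Dummy columns are
    thresholded at 0.5 back to {0, 1}; categorical (string) cells take the
    modal value of the K nearest donors.  Observed cells are returned
    unchanged, and an already-complete table is returned as an identical copy.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = table.copy()
    num_like = [c for c in out.columns if out[c].dtype.kind in "fiu" and c != label_col]
    cat_cols = [c for c in out.columns if out[c].dtype == object and c != label_col]

    for c in num_like + cat_cols:
        n_obs = out[c].notna().sum()
        if n_obs == 0:
            raise ValueError(f"column {c!r} is entirely missing")
        if n_obs < k:
            raise ValueError(f"column {c!r} has fewer than k={k} observed rows")

    if not out.isna().any().any():
        return out

    if binary_cols is None:
        binary_cols = _infer_binary(out, num_like)
    binary_cols = [c for c in binary_cols if c in num_like]
    numeric_cols = [c for c in num_like if c not in binary_cols]

    if num_like:
        Xs, mu, sd = _standardized_numeric_block(out, numeric_cols, binary_cols)
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        filled = imputer.fit_transform(Xs)
        if filled.shape[1] != Xs.shape[1]:  # pragma: no cover - guarded above
            raise RuntimeError("imputer dropped a column")
        nk = len(numeric_cols)
        if nk:
            filled[:, :nk] = filled[:, :nk] * sd + mu
        for j, c in enumerate(numeric_cols):
            missing = out[c].isna().to_numpy()
            vals = out[c].to_numpy(dtype=float)
            vals[missing] = filled[missing, j]
            out[c] = vals
        for j, c in enumerate(binary_cols):
            missing = out[c].isna().to_numpy()
            vals = out[c].to_numpy(dtype=float)
            vals[missing] = (filled[missing, nk + j] >= 0.5).astype(float)
            out[c] = vals

    if cat_cols and any(out[c].isna().any() for c in cat_cols):
        Xs, _, _ = _standardized_numeric_block(table, numeric_cols, binary_cols)
        for c in cat_cols:
            missing_idx = np.flatnonzero(out[c].isna().to_numpy())
            if missing_idx.size == 0:
                continue
            donor_idx = np.flatnonzero(out[c].notna().to_numpy())
            donors = Xs[donor_idx]
            donor_vals = out[c].to_numpy(dtype=object)[donor_idx]
            filled_vals = np.empty(missing_idx.size, dtype=object)
            chunk = 256
            for start in range(0, missing_idx.size, chunk):
                rows = missing_idx[start : start + chunk]
                d = nan_euclidean_distances(Xs[rows], donors)
                d = np.where(np.isnan(d), np.inf, d)
                order = np.argsort(d, axis=1, kind="stable")[:, :k]
                for i, row_order in enumerate(order):
                    vals, counts = np.unique(
                        donor_vals[row_order].astype(str), return_counts=True
                    )
                    # modal value; ties broken lexicographically (np.unique sorts)
                    filled_vals[start + i] = vals[np.argmax(counts)]
            col_vals = out[c].to_numpy(dtype=object)
            col_vals[missing_idx] = filled_vals
            out[c] = col_vals

    return out


def inject_missingness(
    table: pd.DataFrame,
    fraction: float,
    seed: int = 0,
    label_col: Optional[str] = None,
) -> tuple[pd.DataFrame, MissingnessMask]:
    """Withhold a random fraction of cells across all feature columns.

    Each feature cell is masked independently with probability ``fraction``
    (binomial cell count).  The table must be complete; the mask records the
    withheld positions for scoring.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    cols = [c for c in table.columns if c != label_col]
    if table[cols].isna().any().any():
        raise ValueError("table must be complete before injecting missingness")
    rng = np.random.default_rng(seed)
    out = table.copy()
    positions: list[tuple[int, str]] = []
    for c in cols:
        mask = rng.random(len(out)) < fraction
        rows = np.flatnonzero(mask)
        positions.extend((int(r), c) for r in rows)
        if out[c].dtype.kind in "fiu":
            vals = out[c].to_numpy(dtype=float)
            vals[mask] = np.nan
            out[c] = vals
        else:
            vals = out[c].to_numpy(dtype=object)
            vals[mask] = np.nan
            out[c] = vals
    return out, MissingnessMask(tuple(positions), fraction, seed)


def validate_imputation(
    table: pd.DataFrame,
    fraction: float = 0.1,
    k: int = 5,
    seed: int = 0,
    label_col: Optional[str] = LABEL_COLUMN,
) -> ImputationReport:
    """Score KNN imputation by the artificial-missingness protocol.

    Withholds ``fraction`` of the complete table's cells at random, imputes
    them, and reports per-numeric-feature MAPE (%) over the withheld cells
    only.  Zero-valued originals cannot enter a percentage error; they are
    excluded and counted.  Categorical features are scored by mismatch rate.
    """
    label_col = label_col if label_col in table.columns else None
    masked, mask = inject_missingness(table, fraction, seed=seed, label_col=label_col)
    completed = knn_impute(masked, k=k, label_col=label_col)

    mape: dict[str, float] = {}
    n_masked: dict[str, int] = {}
    n_zero: dict[str, int] = {}
    mismatch: dict[str, float] = {}
    for c in table.columns:
        if c == label_col:
            continue
        rows = mask.rows_for(c)
        n_masked[c] = int(rows.size)
        if rows.size == 0:
            continue
        orig = table[c].to_numpy()
        imp = completed[c].to_numpy()
        if table[c].dtype.kind in "fiu":
            o = orig[rows].astype(float)
            i = imp[rows].astype(float)
            nonzero = o != 0
            n_zero[c] = int((~nonzero).sum())
            if nonzero.any():
                mape[c] = float(100.0 * np.mean(np.abs(o[nonzero] - i[nonzero]) / np.abs(o[nonzero])))
            else:
                mape[c] = float("nan")
        else:
            mismatch[c] = float(np.mean(orig[rows].astype(str) != imp[rows].astype(str)))
    return ImputationReport(
        k=k,
        fraction=fraction,
        mape=mape,
        n_masked=n_masked,
        n_zero_excluded=n_zero,
        categorical_mismatch=mismatch,
    )
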