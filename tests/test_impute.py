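import numpy as np
import pandas as pd
import pytest

from edlama.datagen import GeneratorConfig, generate_visits
from edlama.impute import (
    encode_features,
    inject_missingness,
    knn_impute,
    validate_imputation,
)


# --- encoding ----------------------------------------------------------------


def _raw_frame():
    return pd.DataFrame(
        {
            "smoking_status": ["Current Smoker", "Former Smoker", "Never Smoker", "Unknown"],
            "sex": ["Male", "Female", "Male", "Female"],
            "age": [30.0, 40.0, 50.0, 60.0],
            "disposition": ["SAT", "LAMA", "SAT", "SAT"],
        }
    )


def test_n_minus_one_dummies_with_unknown_reference():
    vt = encode_features(_raw_frame())
    dummies = [c for c in vt.features if c.startswith("smoking_status=")]
    # 4 levels -> 3 dummies; "Unknown" is the dropped reference
    assert sorted(dummies) == [
        "smoking_status=Current Smoker",
        "smoking_status=Former Smoker",
        "smoking_status=Never Smoker",
    ]
    assert "sex=Male" in vt.features and "sex=Female" not in vt.features
    assert vt.schema["sex=Male"] == "binary"
    assert vt.schema["age"] == "numeric"


def test_label_coding_lama_is_one():
    vt = encode_features(_raw_frame())
    assert vt.df["disposition"].tolist() == [0, 1, 0, 0]


def test_unknown_category_rejected():
    bad = _raw_frame()
    bad.loc[0, "sex"] = "Other"
    with pytest.raises(ValueError, match="unknown category"):
        encode_features(bad, categories={"sex": ["Male", "Female"]})


def test_repeated_vitals_averaged():
    raw = pd.DataFrame(
        {
            "pulse_rate_1": [80.0, 70.0],
            "pulse_rate_2": [90.0, 74.0],
            "age": [20.0, 30.0],
            "disposition": ["SAT", "LAMA"],
        }
    )
    vt = encode_features(raw)
    assert vt.df["pulse_rate"].tolist() == [85.0, 72.0]
    assert "pulse_rate_1" not in vt.df.columns


def test_arrival_timestamp_reduced_to_month_and_hour():
    raw = pd.DataFrame(
        {
            "arrival_time": pd.to_datetime(["2019-03-05 14:22:31", "2019-11-20 03:05:00"]),
            "age": [20.0, 30.0],
            "disposition": ["SAT", "LAMA"],
        }
    )
    vt = encode_features(raw)
    assert vt.df["month_of_year"].tolist() == [3.0, 11.0]
    assert vt.df["hour_of_day"].tolist() == [14.0, 3.0]
    assert "arrival_time" not in vt.df.columns


# --- knn imputation ----------------------------------------------------------


def test_identity_on_complete_table(small_visits):
    table, _ = small_visits
    out = knn_impute(table.head(500), k=3, label_col="disposition")
    pd.testing.assert_frame_equal(out, table.head(500))


def test_k1_duplicate_donor_recovers_exactly():
    rng = np.random.default_rng(0)
    base = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
    full = pd.concat([base, base], ignore_index=True)
    masked = full.copy()
    # mask cells only in the first copy; the twin donor stays complete
    for j, col in enumerate(full.columns):
        rows = rng.choice(60, size=6, replace=False)
        masked.loc[rows, col] = np.nan
    out = knn_impute(masked, k=1)
    assert np.allclose(out.to_numpy(), full.to_numpy())


def test_equidistant_neighbors_average():
    # three donors at identical distance in the observed coordinate
    df = pd.DataFrame(
        {
            "x": [0.0, 0.0, 0.0, 0.0],
            "y": [1.0, 2.0, 3.0, np.nan],
        }
    )
    out = knn_impute(df, k=3)
    assert out.loc[3, "y"] == pytest.approx(2.0)


def test_locality_only_missing_cells_change(small_visits):
    table, _ = small_visits
    sub = table.head(800).reset_index(drop=True)
    masked, mask = inject_missingness(sub, 0.05, seed=3, label_col="disposition")
    out = knn_impute(masked, k=5, label_col="disposition")
    assert not out.drop(columns="disposition").isna().any().any()
    masked_cells = set(mask.positions)
    for col in sub.columns:
        if col == "disposition":
            continue
        changed = np.flatnonzero(
            ~(out[col].to_numpy() == sub[col].to_numpy())
            if sub[col].dtype == object
            else ~np.isclose(out[col].to_numpy(dtype=float), sub[col].to_numpy(dtype=float))
        )
        assert all((int(r), col) in masked_cells for r in changed), col


def test_binary_columns_thresholded(encoded_table):
    df = encoded_table.df.head(400).reset_index(drop=True).copy()
    col = "sex=Male"
    df.loc[0:30, col] = np.nan
    out = knn_impute(df, k=5, label_col="disposition")
    assert set(out[col].unique()) <= {0.0, 1.0}


def test_entirely_missing_column_rejected():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [np.nan] * 3})
    with pytest.raises(ValueError, match="entirely missing"):
        knn_impute(df, k=1)


def test_consistency_mape_shrinks_with_cluster_noise():
    """Tighter clusters -> nearer donors -> lower imputation error."""
    rng = np.random.default_rng(8)
    centers = rng.normal(size=(12, 4)) * 10
    mapes = []
    for noise in (2.0, 0.5, 0.05):
        pts = centers[rng.integers(0, 12, size=600)] + noise * rng.normal(size=(600, 4))
        df = pd.DataFrame(pts + 100.0, columns=list("abcd"))  # keep positive for MAPE
        rep = validate_imputation(df, fraction=0.1, k=5, seed=1, label_col=None)
        mapes.append(np.mean(list(rep.mape.values())))
    assert mapes[0] > mapes[1] > mapes[2]


# --- missingness injection + validation protocol ------------------------------


def test_injection_binomial_count_and_reproducibility():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(1000, 10)), columns=[f"c{j}" for j in range(10)])
    masked, mask = inject_missingness(df, 0.1, seed=4)
    expected = 1000 * 10 * 0.1
    sigma = np.sqrt(1000 * 10 * 0.1 * 0.9)
    assert abs(len(mask) - expected) <= 3 * sigma
    masked2, mask2 = inject_missingness(df, 0.1, seed=4)
    assert mask.positions == mask2.positions
    pd.testing.assert_frame_equal(masked, masked2)


def test_injection_requires_complete_table():
    df = pd.DataFrame({"a": [1.0, np.nan]})
    with pytest.raises(ValueError, match="complete"):
        inject_missingness(df, 0.1)
    with pytest.raises(ValueError):
        inject_missingness(pd.DataFrame({"a": [1.0]}), 1.5)


def test_mape_arithmetic_single_cell():
    # one masked cell, original 100, nearest donor 98 -> MAPE 2%
    df = pd.DataFrame({"x": [100.0, 98.0, 98.0], "y": [1.0, 1.0, 1.0]})
    masked = df.copy()
    masked.loc[0, "x"] = np.nan
    out = knn_impute(masked, k=2)
    err = 100 * abs(df.loc[0, "x"] - out.loc[0, "x"]) / 100.0
    assert err == pytest.approx(2.0)


def test_validation_report_layout_and_zero_exclusion():
    table, _ = generate_visits(GeneratorConfig(n=1200, seed=21))
    rep = validate_imputation(table, fraction=0.1, k=5, seed=2)
    frame = rep.to_frame()
    assert list(frame.columns) == ["Feature", "MAPE (%)"]
    assert {"bmi", "pulse_rate", "temperature_f"} <= set(frame["Feature"])
    vital_mape = frame.set_index("Feature")["MAPE (%)"]
    assert (vital_mape.loc[["bmi", "systolic_bp", "temperature_f"]] >= 0).all()
    # categorical columns get a mismatch rate, not a MAPE
    assert "smoking_status" in rep.categorical_mismatch
    assert "smoking_status" not in rep.mape


def test_zero_valued_originals_excluded_from_mape():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "mostly_zero": np.where(rng.random(600) < 0.5, 0.0, 100.0),
            "positive": rng.uniform(10, 20, size=600),
        }
    )
    rep = validate_imputation(df, fraction=0.1, k=5, seed=1, label_col=None)
    assert rep.n_zero_excluded["mostly_zero"] > 0
    assert rep.n_zero_excluded["positive"] == 0
    assert np.isfinite(rep.mape["positive"])
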