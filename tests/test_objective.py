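import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edlama.objective import (
    CVObjective,
    VisitTable,
    auc,
    audit_leakage,
    cv_objective,
    metric_suite,
    rebalance,
    split_train_test,
    train_learner,
)

from conftest import brute_force_auc, toy_frame


# --- splitting ---------------------------------------------------------------


def test_split_sizes_and_disjointness(encoded_table):
    split = split_train_test(encoded_table, ratio=0.8, seed=0)
    n = len(encoded_table.df)
    assert len(split.train_ids) == round(0.8 * n)
    assert len(split.test_ids) == n - len(split.train_ids)
    assert not set(split.train_ids) & set(split.test_ids)


def test_split_stratification_keeps_both_classes_everywhere(encoded_table):
    split = split_train_test(encoded_table, ratio=0.8, seed=1, k=4)
    y = encoded_table.df["disposition"]
    assert y.loc[split.test_ids].nunique() == 2
    for f in range(split.k):
        ids = split.fold_of[split.fold_of == f].index
        assert y.loc[ids].nunique() == 2


def test_split_determinism(encoded_table):
    s1 = split_train_test(encoded_table, seed=5)
    s2 = split_train_test(encoded_table, seed=5)
    assert np.array_equal(s1.train_ids, s2.train_ids)
    assert np.array_equal(s1.test_ids, s2.test_ids)
    assert s1.fold_of.equals(s2.fold_of)


def test_split_rejects_tiny_class():
    df = pd.DataFrame({"x": np.arange(10.0), "disposition": [0] * 9 + [1]})
    vt = VisitTable(df, "disposition", {"x": "numeric"})
    with pytest.raises(ValueError, match="at least 2"):
        split_train_test(vt)


# --- rebalancing -------------------------------------------------------------


def _imbalanced(n0=990, n1=10, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x": rng.normal(size=n0 + n1), "label": [0] * n0 + [1] * n1})
    return df


def test_undersample_equalizes_counts():
    out = rebalance(_imbalanced(), "label", "undersample", seed=1)
    assert out["label"].value_counts().tolist() == [10, 10]


def test_oversample_keeps_all_and_duplicates_minority():
    df = _imbalanced()
    out = rebalance(df, "label", "oversample", seed=1)
    counts = out["label"].value_counts()
    assert counts[0] == counts[1] == 990
    # every original row still present at least once (ids preserved)
    assert set(df.index) <= set(out.index)


def test_balanced_input_is_noop():
    df = _imbalanced(n0=50, n1=50)
    out = rebalance(df, "label", "oversample", seed=0)
    pd.testing.assert_frame_equal(out, df)


def test_single_class_rejected():
    df = pd.DataFrame({"x": [1.0, 2.0], "label": [0, 0]})
    with pytest.raises(ValueError, match="both classes"):
        rebalance(df, "label", "oversample")


def test_original_frame_unmodified():
    df = _imbalanced()
    snapshot = df.copy()
    rebalance(df, "label", "undersample", seed=2)
    pd.testing.assert_frame_equal(df, snapshot)


# --- learner -----------------------------------------------------------------


def test_separable_toy_data_perfect_training_auc():
    df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)], "label": [0] * 20 + [1] * 20})
    model = train_learner({"n_estimators": 1, "max_depth": 1, "learning_rate": 0.9}, df, "label")
    assert auc(model.predict_proba(df), df["label"]) == 1.0


def test_learner_determinism(labeled_frame):
    params = {"n_estimators": 5, "max_depth": 3, "learning_rate": 0.3, "gamma": 0.1}
    m1 = train_learner(params, labeled_frame, "label", seed=3)
    m2 = train_learner(params, labeled_frame, "label", seed=3)
    assert np.array_equal(m1.predict_proba(labeled_frame), m2.predict_proba(labeled_frame))


def test_l2_limit_drives_predictions_to_base_rate(labeled_frame):
    base_rate = labeled_frame["label"].mean()
    preds = {}
    for lam in (1.0, 1e4, 1e9):
        model = train_learner(
            {"n_estimators": 10, "max_depth": 3, "learning_rate": 0.5, "reg_lambda": lam},
            labeled_frame,
            "label",
        )
        p = model.predict_proba(labeled_frame)
        preds[lam] = np.abs(p - base_rate).max()
    assert preds[1e9] < preds[1e4] < preds[1.0]
    assert preds[1e9] < 0.01


def test_single_class_training_rejected():
    df = pd.DataFrame({"x": [1.0, 2.0], "label": [1, 1]})
    with pytest.raises(ValueError):
        train_learner({"n_estimators": 1}, df, "label")


# --- metrics -----------------------------------------------------------------


def test_auc_trivial_cases():
    assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auc([0.2, 0.8], [1, 0]) == 0.0
    assert auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75
    assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5  # all ties
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [1, 1])


@given(st.integers(0, 10_000))
def test_auc_matches_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    labels = rng.integers(0, 2, size=n)
    if labels.sum() in (0, n):
        labels[0], labels[-1] = 0, 1
    scores = rng.normal(size=n).round(1)  # coarse grid forces ties
    assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


def test_metric_suite_confusion_arithmetic():
    # TP=8 FN=2 TN=5 FP=5 at threshold 0.5
    labels = np.array([1] * 10 + [0] * 10)
    scores = np.r_[np.full(8, 0.9), np.full(2, 0.1), np.full(5, 0.1), np.full(5, 0.9)]
    m = metric_suite(scores, labels)
    assert m.sensitivity == pytest.approx(0.8)
    assert m.specificity == pytest.approx(0.5)
    assert m.accuracy == pytest.approx(0.65)


def test_metric_suite_degenerate_scores():
    labels = np.array([1, 1, 0, 0])
    m = metric_suite(np.zeros(4), labels)
    assert m.sensitivity == 0.0
    assert m.specificity == 1.0
    assert m.accuracy == 0.5


def test_all_correct_predictions():
    m = metric_suite([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert (m.accuracy, m.auc, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0, 1.0)


# --- cross-validated objective ------------------------------------------------


def test_cv_objective_stability(labeled_frame):
    sol = {"n_estimators": 4, "max_depth": 2, "learning_rate": 0.4}
    r1 = cv_objective(sol, labeled_frame, "label", k=4, mode="oversample", seed=7)
    r2 = cv_objective(sol, labeled_frame, "label", k=4, mode="oversample", seed=7)
    assert r1.mean_auc == r2.mean_auc
    assert [m.as_dict() for m in r1.folds] == [m.as_dict() for m in r2.folds]


def test_cv_objective_signal_free_data_near_chance():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(2000, 5)), columns=[f"f{j}" for j in range(5)])
    df["label"] = rng.integers(0, 2, size=2000)
    val = CVObjective(df, "label", k=4, mode="undersample", seed=0)(
        {"n_estimators": 5, "max_depth": 3, "learning_rate": 0.3}
    )
    assert 0.45 <= val <= 0.55


def test_cv_fold_guard_rejects_class_starved_folds():
    df = toy_frame(n=30)
    df["label"] = [1] * 3 + [0] * 27
    with pytest.raises(ValueError):
        CVObjective(df, "label", k=10, mode="oversample", seed=0)


def test_leakage_audit_flags_nothing_on_clean_run(encoded_table):
    split = split_train_test(encoded_table, seed=2)
    cv = CVObjective(
        encoded_table.df.loc[split.train_ids],
        encoded_table.label_col,
        k=4,
        mode="oversample",
        seed=2,
    )
    report = audit_leakage(cv, split.test_ids)
    assert report["clean"]
    # fitting sets really are rebalanced: duplicated minority ids present
    fold = cv.audit()[0]
    assert len(fold["fit_ids"]) > len(set(fold["fit_ids"]))
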