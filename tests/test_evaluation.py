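"""Metric suite: AUROC vs brute force, reports, correlations, Bayes oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvhtraj import (ValidationError, bayes_auroc_oracle, classification_report,
                     evaluate_multiclass, latest_label_correlations,
                     multiclass_auc, roc_auc, stationary_distribution, stay_matrix)
from cvhtraj.evaluation import plot_roc
from cvhtraj.sequences import SUBMETRIC_ORDER, PatientSequence


def pairwise_auc(scores, labels):
    """O(n^2) oracle: P(score+ > score-) + 0.5 P(equal)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_auc_known_values():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75


def test_roc_auc_single_class_undefined():
    with pytest.raises(ValidationError, match="one class"):
        roc_auc([0.1, 0.2], [1, 1])


def test_roc_auc_equals_pairwise_oracle_exactly(rng):
    for _ in range(200):
        n = int(rng.integers(4, 50))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pairwise_auc(list(scores), list(labels))


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=5), min_size=4, max_size=30),
       st.data())
def test_complement_symmetry(score_ints, data):
    labels = data.draw(st.lists(st.sampled_from([0, 1]), min_size=len(score_ints),
                                max_size=len(score_ints)))
    labels = np.array(labels)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    scores = np.array(score_ints, dtype=float)
    assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(1.0)


def test_multiclass_auc_perfect_and_uniform():
    y = np.array([0, 1, 2, 0, 1, 2])
    onehot = np.eye(3)[y]
    assert multiclass_auc(onehot, y, "micro") == 1.0
    assert multiclass_auc(onehot, y, "macro") == 1.0
    assert all(v == 1.0 for v in multiclass_auc(onehot, y, "per_class").values())
    uniform = np.full((6, 3), 1 / 3)
    assert multiclass_auc(uniform, y, "micro") == 0.5


def test_multiclass_agrees_with_flattened_and_per_class_oracles(rng):
    proba = rng.random((6, 3))
    proba /= proba.sum(axis=1, keepdims=True)
    y = np.array([0, 0, 1, 1, 2, 2])
    onehot = np.eye(3)[y]
    assert multiclass_auc(proba, y, "micro") == \
        pairwise_auc(list(proba.ravel()), list(onehot.ravel()))
    per = multiclass_auc(proba, y, "per_class")
    for c in range(3):
        assert per[c] == pairwise_auc(list(proba[:, c]), list((y == c).astype(int)))
    assert multiclass_auc(proba, y, "macro") == pytest.approx(np.mean(list(per.values())))


def test_multiclass_auc_cross_checked_against_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    proba = rng.random((40, 3))
    proba /= proba.sum(axis=1, keepdims=True)
    y = rng.integers(0, 3, 40)
    assert multiclass_auc(proba, y, "micro") == pytest.approx(
        roc_auc_score(np.eye(3)[y].ravel(), proba.ravel()))
    assert multiclass_auc(proba, y, "macro") == pytest.approx(
        roc_auc_score(y, proba, multi_class="ovr", average="macro"))


def test_absent_class_reported_nan_and_excluded_from_macro(rng):
    proba = rng.random((10, 3))
    y = np.array([0, 1] * 5)  # class 2 absent
    per = multiclass_auc(proba, y, "per_class")
    assert np.isnan(per[2])
    defined = [per[0], per[1]]
    assert multiclass_auc(proba, y, "macro") == pytest.approx(np.mean(defined))


def test_classification_report_perfect_and_hand_case():
    rep = classification_report([0, 1, 2], [0, 1, 2])
    assert rep["accuracy"] == 1.0
    assert all(v["precision"] == v["recall"] == v["f1"] == 1.0
               for v in rep["per_class"].values())
    # binary confusion TP=2 FP=1 FN=1 TN=2 for class 1
    rep = classification_report([1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 0, 0], n_classes=2,
                                class_names=("neg", "pos"))
    assert rep["per_class"]["pos"]["precision"] == pytest.approx(2 / 3)
    assert rep["per_class"]["pos"]["recall"] == pytest.approx(2 / 3)
    assert rep["per_class"]["pos"]["f1"] == pytest.approx(2 / 3)


def test_never_predicted_class_reports_zero_with_flag():
    rep = classification_report([0, 0, 0, 0], [0, 0, 1, 1], n_classes=3)
    cell = rep["per_class"]["intermediate"]
    assert (cell["precision"], cell["recall"], cell["f1"]) == (0.0, 0.0, 0.0)
    assert cell["flagged"]


def test_report_macro_equals_mean_of_per_class(rng):
    proba = rng.random((60, 3))
    proba /= proba.sum(axis=1, keepdims=True)
    y = rng.integers(0, 3, 60)
    rep = evaluate_multiclass(proba, y)
    vals = [v for v in rep.per_class_auc.values() if not np.isnan(v)]
    assert rep.macro_auc == pytest.approx(np.mean(vals), abs=1e-9)
    assert rep.confusion.sum() == rep.n_test


def _seqs_with_labels(label_rows):
    return [PatientSequence(f"p{i}", ["bmipoor"], [10], "male", 50,
                            dict(zip(SUBMETRIC_ORDER, row)))
            for i, row in enumerate(label_rows)]


def test_correlations_identical_and_antialigned():
    rows = [(0, 0, 2, 2, 1), (1, 1, 1, 1, 0), (2, 2, 0, 0, 2)]
    corr = latest_label_correlations(_seqs_with_labels(rows))
    assert corr.loc["a1c", "ldl"] == pytest.approx(1.0)
    assert corr.loc["a1c", "bmi"] == pytest.approx(-1.0)   # 2<->0 swapped
    assert np.allclose(np.diag(corr), 1.0)
    assert np.allclose(corr, corr.T)


def test_zero_variance_submetric_reports_nan():
    rows = [(0, 1, 1, 2, 0), (0, 2, 1, 0, 1), (0, 0, 2, 1, 2)]
    corr = latest_label_correlations(_seqs_with_labels(rows))
    assert corr.loc["a1c"].drop("a1c").isna().all()


def test_bayes_oracle_limits_and_enumeration(rng):
    assert bayes_auroc_oracle(np.eye(3), np.full(3, 1 / 3)) == 1.0
    assert bayes_auroc_oracle(np.full((3, 3), 1 / 3),
                              np.full(3, 1 / 3)) == pytest.approx(0.5, abs=1e-12)
    # cross-check the stay-0.9 value by direct simulation
    m = stay_matrix(0.9)
    pi = stationary_distribution(m)
    assert np.allclose(pi, 1 / 3)
    states = rng.choice(3, p=pi, size=200000)
    u = rng.random(len(states))
    nexts = (u[:, None] > m.cumsum(axis=1)[states]).sum(axis=1)
    scores = m[states]
    onehot = np.eye(3)[nexts]
    sim = roc_auc(scores.ravel(), onehot.ravel().astype(int))
    assert bayes_auroc_oracle(m, pi) == pytest.approx(sim, abs=0.01)


def test_plot_roc_writes_file(tmp_path, rng):
    proba = rng.random((30, 3))
    proba /= proba.sum(axis=1, keepdims=True)
    y = rng.integers(0, 3, 30)
    path = plot_roc(proba, y, tmp_path / "roc.png", title="demo")
    assert path.exists() and path.stat().st_size > 0
    with pytest.raises(ValidationError):
        plot_roc(np.zeros((0, 3)), np.zeros(0, dtype=int), tmp_path / "no.png")
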