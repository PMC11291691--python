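import math

import numpy as np
import pytest
from scipy import integrate, stats

from qcla.evaluation import (
    CLASS_ORDER,
    ConfusionMatrix,
    bonferroni,
    compare_proportions,
    confusion,
    format_metric,
    metrics_from_confusion,
    overall_accuracy,
    pearson,
    phi_from_chi2,
    two_sample_t,
    variance_f_test,
)

# Published Phase-2 confusion matrices (rows predicted, columns true).
SEM_MATRIX = np.array(
    [[29, 16, 4, 0], [6, 31, 1, 3], [6, 20, 42, 14], [2, 7, 9, 42]]
)
RS_MATRIX = np.array(
    [[10, 28, 2, 0], [22, 15, 1, 15], [11, 31, 51, 44], [0, 0, 2, 0]]
)


def test_confusion_counts_match_brute_force_tally():
    rng = np.random.default_rng(3)
    true = rng.choice(CLASS_ORDER, size=200)
    pred = rng.choice(CLASS_ORDER, size=200)
    cm = confusion(true, pred)
    for i, p in enumerate(CLASS_ORDER):
        for j, t in enumerate(CLASS_ORDER):
            assert cm.counts[i, j] == sum(
                1 for tt, pp in zip(true, pred) if tt == t and pp == p
            )


def test_confusion_perfect_predictions_diagonal():
    labels = list(CLASS_ORDER) * 3
    cm = confusion(labels, labels)
    assert (cm.counts == np.diag([3, 3, 3, 3])).all()


def test_confusion_single_off_diagonal():
    cm = confusion(["depression"], ["anxiety"])
    assert cm.counts.sum() == 1
    assert cm.counts[CLASS_ORDER.index("anxiety"), CLASS_ORDER.index("depression")] == 1


def test_confusion_rejects_unknown_labels():
    with pytest.raises(ValueError):
        confusion(["joy"], ["harmony"])


def test_published_semantic_panel_reproduced():
    met = metrics_from_confusion(ConfusionMatrix(SEM_MATRIX))
    assert met.metric("sensitivity", "harmony") == pytest.approx(0.67, abs=0.005)
    assert met.metric("precision", "harmony") == pytest.approx(0.59, abs=0.005)
    assert met.metric("specificity", "harmony") == pytest.approx(0.89, abs=0.005)
    assert met.metric("accuracy", "harmony") == pytest.approx(0.85, abs=0.005)
    assert met.metric("f1", "harmony") == pytest.approx(0.63, abs=0.005)
    assert met.metric("precision", "depression") == pytest.approx(0.51, abs=0.005)
    assert met.metric("specificity", "satisfaction") == pytest.approx(0.94, abs=0.005)
    assert met.metric("sensitivity", "anxiety") == pytest.approx(0.71, abs=0.005)


def test_published_rating_scale_panel_reproduced():
    met = metrics_from_confusion(ConfusionMatrix(RS_MATRIX))
    assert met.metric("precision", "harmony") == pytest.approx(0.25, abs=0.005)
    assert met.metric("sensitivity", "depression") == pytest.approx(0.91, abs=0.005)
    assert met.metric("precision", "anxiety") == pytest.approx(0.00, abs=0.005)
    assert met.metric("specificity", "anxiety") == pytest.approx(0.99, abs=0.005)
    # zero precision and zero sensitivity: F1 is undefined, rendered as a dash
    assert math.isnan(met.metric("f1", "anxiety"))
    assert format_metric(met.metric("f1", "anxiety")) == "–"


def test_published_overall_accuracies():
    assert overall_accuracy(ConfusionMatrix(SEM_MATRIX)) == pytest.approx(0.621, abs=0.0005)
    assert overall_accuracy(ConfusionMatrix(RS_MATRIX)) == pytest.approx(0.328, abs=0.0005)


def test_overall_accuracy_edge_cases():
    assert overall_accuracy(ConfusionMatrix(np.diag([5, 5, 5, 5]))) == 1.0
    assert overall_accuracy(ConfusionMatrix(np.full((4, 4), 3))) == 0.25


def test_identity_matrix_gives_perfect_metrics():
    met = metrics_from_confusion(ConfusionMatrix(np.diag([4, 3, 2, 1])))
    assert np.allclose(met.per_class.to_numpy(float), 1.0)


def test_undefined_precision_for_never_predicted_class():
    counts = np.diag([5, 5, 5, 0])
    counts[0, 3] = 5  # anxiety rows all misclassified as harmony
    met = metrics_from_confusion(ConfusionMatrix(counts))
    assert math.isnan(met.metric("precision", "anxiety"))


def test_support_weighted_sensitivity_equals_overall_accuracy():
    rng = np.random.default_rng(9)
    for _ in range(20):
        counts = rng.integers(0, 30, size=(4, 4))
        if counts.sum() == 0 or (counts.sum(axis=0) == 0).any():
            continue
        cm = ConfusionMatrix(counts)
        met = metrics_from_confusion(cm)
        support = counts.sum(axis=0)
        sens = met.per_class.loc["sensitivity"].to_numpy(float)
        weighted = np.nansum(sens * support) / counts.sum()
        assert weighted == pytest.approx(overall_accuracy(cm), abs=1e-12)


def test_chi2_equal_proportions_is_zero():
    res = compare_proportions(50, 100, 50, 100)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.effect_size == pytest.approx(0.0, abs=1e-9)


def test_chi2_matches_textbook_four_cell_formula():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n_a, n_b = rng.integers(20, 120, size=2)
        c_a = rng.integers(1, n_a)
        c_b = rng.integers(1, n_b)
        obs = np.array([[c_a, n_a - c_a], [c_b, n_b - c_b]], dtype=float)
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        oracle = float(((obs - expected) ** 2 / expected).sum())
        res = compare_proportions(c_a, n_a, c_b, n_b)
        assert res.statistic == pytest.approx(oracle, rel=1e-10)
        assert res.df == 1


def test_chi2_symmetric_in_arguments():
    a = compare_proportions(60, 100, 30, 90)
    b = compare_proportions(30, 90, 60, 100)
    assert a.statistic == pytest.approx(b.statistic)


def test_published_phi_from_printed_statistics():
    # phi from the reported chi-square and its reported N convention
    assert phi_from_chi2(19.48, 231) == pytest.approx(0.29, abs=0.005)
    res = compare_proportions(144, 232, 76, 232, phi_n=231)
    assert res.effect_size == pytest.approx(math.sqrt(res.statistic / 231))


def test_t_test_identical_samples():
    res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_t_test_hand_computed_pooled_formula():
    res = two_sample_t([0, 0, 1, 1], [1, 1, 1, 1])
    # pooled variance = (3*(1/3) + 3*0)/6 = 1/6; t = -0.5/sqrt((1/6)(1/2))
    assert res.statistic == pytest.approx(-math.sqrt(3), rel=1e-9)
    assert res.df == 6


def test_t_test_antisymmetric():
    x, y = [1.0, 2, 3, 4], [2.0, 4, 5, 7]
    a, b = two_sample_t(x, y), two_sample_t(y, x)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_t_test_zero_variance_undefined():
    res = two_sample_t([1.0, 1.0], [1.0, 1.0])
    assert math.isnan(res.statistic)


def test_f_test_identity_and_scaling():
    x = np.array([1.0, 2, 3, 4, 5])
    assert variance_f_test(x, x).statistic == pytest.approx(1.0)
    y = 2 * (x - x.mean())
    assert variance_f_test(x, y).statistic == pytest.approx(0.25)


def test_f_test_p_matches_density_quadrature():
    x = np.array([1.0, 4, 2, 8, 5, 3])
    y = np.array([2.0, 2.5, 3, 3.5, 2.2, 2.8, 3.1])
    res = variance_f_test(x, y)
    dfn, dfd = res.df
    upper, _ = integrate.quad(lambda v: stats.f.pdf(v, dfn, dfd), res.statistic, np.inf)
    oracle = 2 * min(upper, 1 - upper)
    assert res.p_value == pytest.approx(oracle, abs=1e-6)


def test_pearson_limits_and_formula_oracle():
    x = np.arange(10.0)
    assert pearson(x, x)[0] == pytest.approx(1.0)
    assert pearson(x, -x)[0] == pytest.approx(-1.0)
    rng = np.random.default_rng(23)
    a, b = rng.normal(size=100), rng.normal(size=100)
    r, _ = pearson(a, b)
    oracle = np.cov(a, b)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
    assert r == pytest.approx(float(oracle), rel=1e-10)
    assert math.isnan(pearson(np.ones(5), a[:5])[0])


def test_bonferroni_threshold_and_identity():
    assert list(bonferroni([0.01, 0.04], alpha=0.05)) == [True, False]
    assert list(bonferroni([0.04], alpha=0.05)) == [True]


def test_bonferroni_flags_subset_of_uncorrected():
    rng = np.random.default_rng(31)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 30))
        corrected = bonferroni(p, 0.05)
        uncorrected = p <= 0.05
        assert not (corrected & ~uncorrected).any()
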