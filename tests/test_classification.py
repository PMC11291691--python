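import numpy as np
import pandas as pd
import pytest

from qcla.classification import (
    EmotionClassifier,
    TrainedClassifier,
    cross_validated_predictions,
    fit_multinomial,
    make_feature_set,
    make_grouped_folds,
    predict,
    select_dimensions,
)
from qcla.evaluation import CLASS_ORDER


def test_grouped_folds_exact_division():
    plan = make_grouped_folds([f"g{i}" for i in range(20)], n_folds=10, seed=1)
    sizes = [len(plan.test_groups(f)) for f in range(10)]
    assert sizes == [2] * 10


def test_grouped_folds_deterministic_and_seed_sensitive():
    groups = [f"g{i}" for i in range(30)]
    a = make_grouped_folds(groups, 10, seed=5)
    b = make_grouped_folds(groups, 10, seed=5)
    c = make_grouped_folds(groups, 10, seed=6)
    assert a.fold_of == b.fold_of
    assert a.fold_of != c.fold_of


def test_grouped_folds_require_enough_groups():
    with pytest.raises(ValueError):
        make_grouped_folds(["a", "b"], n_folds=3)


def test_rows_of_one_narrative_share_a_fold():
    groups = np.repeat([f"n{i}" for i in range(15)], 3)
    plan = make_grouped_folds(groups, 5, seed=2)
    folds = plan.fold_for_rows(groups)
    for g in set(groups):
        assert len(set(folds[groups == g])) == 1


def test_no_group_in_both_train_and_test():
    groups = np.repeat([f"n{i}" for i in range(24)], 2)
    plan = make_grouped_folds(groups, 6, seed=3)
    all_groups = set(groups)
    for fold in range(6):
        test = plan.test_groups(fold)
        train = all_groups - test
        assert not (train & test)


def _gaussian_clouds(rng, n=60, sep=4.0):
    X = np.vstack(
        [rng.normal(0, 1, size=(n, 5)), rng.normal(sep, 1, size=(n, 5))]
    )
    y = np.array(["harmony"] * n + ["depression"] * n)
    return X, y


def test_fit_on_separated_clouds_reaches_high_training_accuracy():
    rng = np.random.default_rng(8)
    X, y = _gaussian_clouds(rng)
    clf = fit_multinomial(X, y, ridge=1e-4)
    pred, probs = predict(clf, X)
    assert (pred == y).mean() >= 0.95
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_zero_features_predict_training_frequencies():
    X = np.zeros((40, 3))
    y = np.array(["harmony"] * 10 + ["depression"] * 30)
    clf = fit_multinomial(X, y)
    _, probs = predict(clf, X)
    h = CLASS_ORDER.index("harmony")
    d = CLASS_ORDER.index("depression")
    assert probs[:, h] == pytest.approx(0.25, abs=0.01)
    assert probs[:, d] == pytest.approx(0.75, abs=0.01)


def test_single_class_input_rejected():
    with pytest.raises(ValueError):
        fit_multinomial(np.ones((5, 2)), ["harmony"] * 5)


class _StubEstimator:
    """Fixed-probability estimator for exercising the decision layer."""

    def __init__(self, classes, probs):
        self.classes_ = np.asarray(classes)
        self._probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.tile(self._probs, (X.shape[0], 1))


def _stub_classifier(classes, probs, width):
    return TrainedClassifier(
        class_order=CLASS_ORDER,
        estimator=_StubEstimator(classes, probs),
        d_selected=width,
        ridge=1e-4,
        n_semantic=width,
        scale_mean=np.zeros(0),
        scale_std=np.zeros(0),
    )


def test_predict_argmax_and_tie_break():
    clf = _stub_classifier(CLASS_ORDER, [0.7, 0.1, 0.1, 0.1], width=3)
    labels, _ = predict(clf, np.zeros((2, 3)))
    assert set(labels) == {"harmony"}
    tie = _stub_classifier(CLASS_ORDER, [0.1, 0.4, 0.4, 0.1], width=3)
    labels, _ = predict(tie, np.zeros((1, 3)))
    assert labels[0] == "satisfaction"  # earlier in the class order


def test_predict_rejects_width_mismatch():
    clf = _stub_classifier(CLASS_ORDER, [0.25] * 4, width=3)
    with pytest.raises(ValueError):
        predict(clf, np.zeros((2, 5)))


def test_predict_matches_manual_softmax():
    rng = np.random.default_rng(12)
    # three classes so the fit is genuinely multinomial (one weight row each)
    X = np.vstack(
        [
            rng.normal(0, 1, size=(30, 5)),
            rng.normal(4, 1, size=(30, 5)),
            rng.normal(-4, 1, size=(30, 5)),
        ]
    )
    y = np.array(["harmony"] * 30 + ["depression"] * 30 + ["anxiety"] * 30)
    clf = fit_multinomial(X, y, ridge=1e-3)
    _, probs = predict(clf, X[:7])
    logits = X[:7] @ clf.coefficients.T + clf.intercepts
    manual = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    col = {c: j for j, c in enumerate(CLASS_ORDER)}
    for j, cls in enumerate(clf.estimator.classes_):
        assert np.allclose(probs[:, col[cls]], manual[:, j], atol=1e-9)


def test_grid_of_one_returns_that_value():
    rng = np.random.default_rng(1)
    X, y = _gaussian_clouds(rng, n=20)
    groups = np.arange(len(y))
    assert select_dimensions(X, y, groups, grid=[4], seed=1) == 4


def test_planted_signal_selects_few_dimensions():
    rng = np.random.default_rng(21)
    n = 200
    signal = rng.normal(size=(n, 5))
    noise = rng.normal(size=(n, 45))
    y = np.array(CLASS_ORDER)[(signal[:, 0] > 0).astype(int) + 2 * (signal[:, 1] > 0)]
    X = np.hstack([signal, noise])
    groups = np.arange(n) // 2
    d = select_dimensions(X, y, groups, grid=[2, 5, 10, 25, 50], seed=3, inner_folds=4)
    assert d <= 10


def _toy_feature_set(orthonormal_space, n_groups=16, per_group=3, seed=0):
    rng = np.random.default_rng(seed)
    vocab_by_class = {
        "harmony": ["calm", "content"],
        "satisfaction": ["happy"],
        "depression": ["sad", "gloomy"],
        "anxiety": ["worried"],
    }
    rows = []
    for g in range(n_groups):
        cond = CLASS_ORDER[g % 4]
        for r in range(per_group):
            words = list(rng.choice(vocab_by_class[cond], size=5))
            rows.append(
                {
                    "narrative_id": f"n{g}",
                    "condition": cond,
                    "phase": 1 if r == 0 else 2,
                    "words": ";".join(words),
                }
            )
    frame = pd.DataFrame(rows)
    return make_feature_set(frame, "words", orthonormal_space)


def test_cross_validated_predictions_partition_eval_rows(orthonormal_space):
    fs = _toy_feature_set(orthonormal_space)
    plan = make_grouped_folds(fs.groups, 4, seed=1)
    preds, d_per_fold = cross_validated_predictions(
        fs, plan, grid=[2, 6], seed=1, inner_folds=3
    )
    assert len(preds) == fs.n_rows
    assert preds["pred"].notna().all()
    assert len(d_per_fold) == 4
    # per-fold test sets tile all rows exactly once
    assert sorted(preds["fold"].value_counts().index) == [0, 1, 2, 3]
    assert preds.index.is_unique


def test_disjoint_vocabularies_classified_near_perfectly(orthonormal_space):
    fs = _toy_feature_set(orthonormal_space)
    plan = make_grouped_folds(fs.groups, 4, seed=1)
    preds, _ = cross_validated_predictions(fs, plan, grid=[6], seed=1)
    eval_rows = preds[preds["phase"] == 2]
    assert (eval_rows["true"] == eval_rows["pred"]).mean() >= 0.95


def test_words_beat_weak_scales_on_default_synthetic(small_study, small_space):
    """Directional check: informative words outclassify weak rating scales."""
    _, _, records = small_study
    words = EmotionClassifier.from_dataframe(
        records,
        kind="words",
        space=small_space,
        grid=(3, 8, 20, 40, 60),
        inner_folds=3,
        seed=7,
    ).fit()
    rs = EmotionClassifier.from_dataframe(records, kind="rs_totals", seed=7).fit()
    assert words.accuracy > rs.accuracy
    assert rs.accuracy > 0.25  # scales stay informative, just weaker


def test_accuracy_degrades_with_word_noise(small_space):
    """Monotone accuracy over increasing generator noise, fixed seeds."""
    from qcla.synthetic import SyntheticConfig, generate_study, records_to_frame
    from qcla.semantic import build_space_from_corpus

    accuracies = []
    for noise in (0.05, 0.35, 0.7):
        cfg = SyntheticConfig(
            n_phase1=48,
            n_phase2=96,
            n_corpus_responses=800,
            vocab_per_emotion=40,
            word_noise_low=noise,
            word_noise_high=noise,
            corpus_noise=0.1,
            seed=13,
        )
        corpus, p1, p2 = generate_study(cfg)
        space = build_space_from_corpus(corpus, k=40)
        res = EmotionClassifier.from_dataframe(
            records_to_frame(p1, p2),
            kind="words",
            space=space,
            n_folds=6,
            grid=(8, 24, 40),
            inner_folds=3,
            seed=13,
        ).fit()
        accuracies.append(res.accuracy)
    assert accuracies[0] >= accuracies[1] >= accuracies[2]


def test_missing_class_in_training_fold_warns_not_crashes(orthonormal_space, caplog):
    rng = np.random.default_rng(2)
    rows = []
    # anxiety appears in exactly one narrative; its fold's training pool
    # lacks the class entirely
    conds = ["harmony", "satisfaction", "depression"] * 5 + ["anxiety"]
    vocab = {
        "harmony": "calm",
        "satisfaction": "happy",
        "depression": "sad",
        "anxiety": "worried",
    }
    for g, cond in enumerate(conds):
        rows.append(
            {
                "narrative_id": f"n{g}",
                "condition": cond,
                "phase": 2,
                "words": ";".join([vocab[cond]] * 5),
            }
        )
    fs = make_feature_set(pd.DataFrame(rows), "words", orthonormal_space)
    plan = make_grouped_folds(fs.groups, 4, seed=0)
    with caplog.at_level("WARNING"):
        preds, _ = cross_validated_predictions(fs, plan, grid=[6], seed=0)
    assert preds["pred"].notna().all()
    assert any("missing" in r.message for r in caplog.records)
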