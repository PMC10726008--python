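import numpy as np
import pytest

from maldisub.models import (
    SplitSpec,
    evaluate_scores,
    fit_predict,
    permutation_importance,
    rfecv_select,
    scale_minmax,
    split_dataset,
    youden_threshold_cv,
)
from tests.conftest import make_feature_matrix


def _labeled_fm(n_lon=59, n_inf=41, n_feat=6, replicates=4, seed=0, sep=0.9):
    """Cohort-like matrix where the first feature separates the classes."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * n_lon + [1] * n_inf)
    presence = (rng.random((n_lon + n_inf, n_feat)) < 0.5).astype(int)
    presence[:, 0] = (rng.random(n_lon + n_inf) < np.where(labels == 1, sep, 1 - sep)).astype(int)
    rel = presence * rng.uniform(0.3, 1.0, presence.shape)
    return make_feature_matrix(presence, labels, rel_intensity=rel, replicates=replicates)


def roc_auc_oracle(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    s = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return s / (pos.size * neg.size)


def test_split_allocates_seventy_thirty_by_strain():
    fm = _labeled_fm()
    train, test = split_dataset(fm, SplitSpec(seed=3))
    tr_strains = set(train.presence.index.get_level_values("strain_id"))
    te_strains = set(test.presence.index.get_level_values("strain_id"))
    assert len(tr_strains) == 70 and len(te_strains) == 30
    assert tr_strains.isdisjoint(te_strains)
    # stratified: train class counts within 1 of (41, 29)
    counts = train.strain_labels().value_counts()
    assert abs(counts[0] - 41) <= 1 and abs(counts[1] - 29) <= 1


def test_split_is_deterministic_per_seed():
    fm = _labeled_fm()
    t1, _ = split_dataset(fm, SplitSpec(seed=5))
    t2, _ = split_dataset(fm, SplitSpec(seed=5))
    assert t1.presence.index.equals(t2.presence.index)


def test_split_needs_two_strains_per_class():
    fm = make_feature_matrix(np.ones((3, 2), int), [0, 0, 1])
    with pytest.raises(ValueError):
        split_dataset(fm, SplitSpec())


def test_minmax_scaling_contract():
    train = np.array([[0.0, 5.0, 2.0], [10.0, 5.0, 4.0], [5.0, 5.0, 6.0]])
    other = np.array([[20.0, 7.0, 5.0]])
    s_tr, s_ot, params = scale_minmax(train, other)
    assert s_tr[:, 0].min() == 0.0 and s_tr[:, 0].max() == 1.0
    np.testing.assert_array_equal(s_tr[:, 1], 0.0)  # constant column -> all zeros
    assert s_ot[0, 1] == pytest.approx(0.0)  # ... in the other set too
    assert s_ot[0, 0] == 2.0  # beyond the train max: not clipped


def test_rfecv_curve_length_and_tie_rule():
    rng = np.random.default_rng(1)
    X = rng.random((60, 18))
    y = np.array([0, 1] * 30)
    selected, curve = rfecv_select(X, y)
    assert len(curve) == 18  # one mean CV score per subset size
    assert 1 <= len(selected) <= 18
    # pure-noise features: the best size is whatever it is, but ties must go
    # to the smaller size — verified directly on the curve
    best = int(np.argmax(curve)) + 1
    assert len(selected) == best


def test_rfecv_recovers_planted_informative_features():
    # three independent, individually imperfect signal carriers: the CV score
    # keeps improving while they are added, so all three must be selected
    rng = np.random.default_rng(2)
    n = 120
    y = np.array([0] * 60 + [1] * 60)
    X = rng.random((n, 10)) * 0.3
    for j in range(3):
        X[:, j] += 0.35 * y + rng.normal(0, 0.25, n)
    names = [f"f{j}" for j in range(10)]
    selected, _curve = rfecv_select(X, y, feature_names=names)
    assert {"f0", "f1", "f2"}.issubset(set(selected))


def test_rfecv_single_feature_degenerate():
    X = np.array([[0.0], [1.0], [0.1], [0.9]] * 5)
    y = np.array([0, 1, 0, 1] * 5)
    selected, curve = rfecv_select(X, y)
    assert selected == ["0"] and len(curve) == 1


@pytest.mark.parametrize("kind", ["LR", "SVM", "RF"])
def test_classifiers_separate_toy_data_and_are_deterministic(kind):
    X = np.array([[0.0, 0.0], [0.1, 0.0], [1.0, 1.0], [0.9, 1.0]] * 5)
    y = np.array([0, 0, 1, 1] * 5)
    s1, _ = fit_predict(kind, X, y, X, seed=4)
    s2, _ = fit_predict(kind, X, y, X, seed=4)
    np.testing.assert_array_equal(s1, s2)
    assert (s1[y == 1] > 0.5).all() and (s1[y == 0] < 0.5).all()


def test_identical_rows_get_identical_scores():
    X = np.array([[0.2, 0.4]] * 8)
    y = np.array([0, 1] * 4)
    scores, _ = fit_predict("RF", X[:4], y[:4], X, seed=0)
    assert np.unique(scores).size == 1


def test_unknown_classifier_kind_rejected():
    with pytest.raises(ValueError, match="XGB"):
        fit_predict("XGB", np.zeros((2, 1)), np.array([0, 1]), np.zeros((1, 1)))


def test_random_forest_invariant_to_monotone_feature_scaling():
    rng = np.random.default_rng(6)
    X = rng.random((80, 5))
    y = (X[:, 0] + 0.2 * rng.random(80) > 0.6).astype(int)
    Xs, _, _ = scale_minmax(X)
    s_raw, _ = fit_predict("RF", X, y, X, seed=1)
    s_scaled, _ = fit_predict("RF", Xs, y, Xs, seed=1)
    np.testing.assert_allclose(s_raw, s_scaled, atol=1e-12)


def test_evaluate_perfect_separation():
    rep = evaluate_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.youden == pytest.approx(1.0) and rep.auc == 1.0


def test_evaluate_fixed_threshold_confusion():
    rep = evaluate_scores([0.9, 0.8, 0.7], [1, 1, 0], threshold=0.75)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0


def test_youden_identity_and_roc_monotonicity():
    rng = np.random.default_rng(7)
    scores = rng.random(60)
    labels = (rng.random(60) < 0.4).astype(int)
    rep = evaluate_scores(scores, labels)
    assert rep.youden == pytest.approx(rep.sensitivity + rep.specificity - 1.0, abs=1e-9)
    fpr = np.array([p[0] for p in rep.roc_points])
    tpr = np.array([p[1] for p in rep.roc_points])
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(8)
    for _ in range(10):
        n = int(rng.integers(10, 100))
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        scores = np.round(rng.random(n), 2)  # force ties
        rep = evaluate_scores(scores, labels)
        assert rep.auc == pytest.approx(roc_auc_oracle(scores, labels), abs=1e-9)


def test_evaluate_single_class_rejected():
    with pytest.raises(ValueError):
        evaluate_scores([0.1, 0.9], [1, 1])


def test_permutation_importance_identifies_signal_feature():
    rng = np.random.default_rng(9)
    n = 200
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.random((n, 4))
    X[:, 2] = y + 0.1 * rng.random(n)  # feature 2 carries all the signal
    scores, model = fit_predict("RF", X, y, X, seed=2)
    imp = permutation_importance(model, X, y, n_repeats=10, seed=2)
    assert imp.size == 4
    assert int(np.argmax(imp)) == 2
    null_features = [0, 1, 3]
    assert max(abs(imp[j]) for j in null_features) <= 0.05


def test_cv_threshold_lies_in_score_range():
    fm = _labeled_fm(n_lon=20, n_inf=20, replicates=2, seed=3)
    X = fm.rel_intensity.to_numpy()
    y = fm.labels.to_numpy()
    groups = fm.presence.index.get_level_values("strain_id").to_numpy()
    thr = youden_threshold_cv("LR", X, y, groups=groups, seed=0)
    assert 0.0 <= thr <= 1.0
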