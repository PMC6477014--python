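import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prevoid.models import (
    CVScheme,
    DegenerateTrainingError,
    StepwiseOrdinalRegression,
    cross_validate,
    predict_states,
    train_models,
    vote,
)
from prevoid.states import BladderState

E, H, T, F = BladderState


def _separable_blobs(n_per_class=30, seed=0, spread=0.05):
    """Four well-separated Gaussian blobs in a 5-feature space."""
    rng = np.random.default_rng(seed)
    centres = np.array(
        [[0, 0, 0, 0, 0], [5, 5, 0, 0, 1], [10, 10, 5, 0, 2], [15, 15, 10, 5, 3]], float
    )
    X = np.vstack([c + spread * rng.normal(size=(n_per_class, 5)) for c in centres])
    y = np.repeat(np.arange(4), n_per_class)
    return X, y, centres


def test_all_three_models_fit_separable_classes():
    X, y, centres = _separable_blobs()
    models = train_models(X, y, seed=0)
    for preds in (
        models.svm_model.predict(X),
        models.regression_model.predict(X),
        models.bagging_model.predict(X),
    ):
        assert (preds == y).mean() >= 0.99
    # class centroids get a unanimous correct opinion
    ops = predict_states(models, centres[3])
    assert ops == (F, F, F)
    assert all(o in BladderState for o in ops)


def test_training_metadata_counts_sum_to_training_size():
    X, y, _ = _separable_blobs(n_per_class=10)
    models = train_models(X, y, seed=1)
    meta = models.training_metadata
    assert sum(meta["class_counts"].values()) == meta["n_samples"] == len(y)


def test_duplicating_every_row_leaves_predictions_unchanged():
    X, y, _ = _separable_blobs(n_per_class=15)
    m1 = train_models(X, y, seed=2)
    m2 = train_models(np.vstack([X, X]), np.concatenate([y, y]), seed=2)
    assert np.array_equal(m1.predict_all(X), m2.predict_all(X))


def test_fixed_seed_gives_identical_bagging_draws():
    X, y, _ = _separable_blobs(n_per_class=20, spread=1.5)
    m1 = train_models(X, y, seed=3)
    m2 = train_models(X, y, seed=3)
    assert np.array_equal(m1.bagging_model.predict(X), m2.bagging_model.predict(X))


def test_single_class_training_is_degenerate():
    X = np.random.default_rng(0).normal(size=(20, 3))
    with pytest.raises(DegenerateTrainingError):
        train_models(X, np.zeros(20, dtype=int))


def test_regression_output_rounds_and_clips_to_valid_states():
    reg = StepwiseOrdinalRegression().fit(np.array([[0.0], [1.0]]), np.array([0.0, 3.0]))
    # raw 3.7 clips to full (index 3); raw −0.6 clips to empty
    assert reg.decision_function(np.array([[1.2333]]))[0] == pytest.approx(3.7, abs=1e-3)
    assert reg.predict(np.array([[1.2333]]))[0] == 3
    assert reg.predict(np.array([[-0.2]]))[0] == 0


@pytest.mark.parametrize(
    "opinions,expected",
    [
        ((F, F, H), F),  # strict majority
        ((E, T, F), T),  # mean index 5/3 rounds to 2
        ((E, H, F), H),  # mean index 4/3 rounds to 1
        ((E, E, E), E),
        ((H, F, F), F),
    ],
)
def test_vote_majority_and_mean_fallback(opinions, expected):
    assert vote(opinions) is expected


def test_vote_halfway_tie_rounds_to_safer_state():
    # no strict majority; weighted mean index (0+0+2·3)/4 = 1.5 rounds up to 3/4
    assert vote((E, E, F), weights=(1, 1, 2)) is T


@given(op=st.sampled_from(list(BladderState)))
def test_vote_idempotent_on_unanimity(op):
    assert vote((op, op, op)) is op


@given(
    ops=st.tuples(*[st.sampled_from(list(BladderState))] * 3),
    perm=st.permutations(range(3)),
)
def test_vote_permutation_invariant(ops, perm):
    assert vote(ops) is vote([ops[i] for i in perm])


def test_vote_rejects_wrong_arity_and_weights():
    with pytest.raises(ValueError):
        vote((E, H))
    with pytest.raises(ValueError):
        vote((E, H, F), weights=(0, 0, 0))


def _class_counts(y):
    return np.bincount(y, minlength=4)


def test_kfold_conserves_class_totals_and_separates_blobs():
    X, y, _ = _separable_blobs(n_per_class=25, seed=4)
    mats = cross_validate(X, y, CVScheme(kind="k_fold", k=10, seed=0))
    for cm in mats.values():
        assert np.array_equal(cm.column_totals, _class_counts(y))
    assert np.trace(mats["voting"].counts) / len(y) >= 0.95


def test_loocv_predicts_every_sample_once():
    X, y, _ = _separable_blobs(n_per_class=5, seed=5)
    mats = cross_validate(X, y, CVScheme(kind="loocv"))
    assert mats["voting"].total == len(y)


def test_holdout_partitions_without_overlap():
    X, y, _ = _separable_blobs(n_per_class=20, seed=6)
    mats = cross_validate(X, y, CVScheme(kind="holdout", test_fraction=0.5, seed=0))
    # holdout matrices only count the held-out half, stratified per class
    assert mats["voting"].total == len(y) // 2
    assert np.array_equal(mats["voting"].column_totals, _class_counts(y) // 2)


def test_k_larger_than_n_is_rejected():
    X, y, _ = _separable_blobs(n_per_class=2)
    with pytest.raises(ValueError):
        cross_validate(X, y, CVScheme(kind="k_fold", k=50))


def test_scheme_invariants():
    with pytest.raises(ValueError):
        CVScheme(kind="bootstrap")
    with pytest.raises(ValueError):
        CVScheme(kind="holdout", test_fraction=1.5)
    with pytest.raises(ValueError):
        CVScheme(kind="k_fold", k=1)
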