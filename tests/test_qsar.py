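import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import VotingClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from jnkscreen import bayesopt
from jnkscreen.bayesopt import Dimension
from jnkscreen.evaluation import roc_auc
from jnkscreen.qsar import (BASE_MODEL_NAMES, REFERENCE_OPTIMA,
                            EnsembleQSARClassifier, HyperparameterSpace,
                            make_base_model, train_base_models,
                            tune_hyperparameters)

# ---------------------------------------------------------------------------
# Bayesian optimizer
# ---------------------------------------------------------------------------

def test_bayesopt_finds_quadratic_optimum_and_is_deterministic():
    dims = [Dimension("x", -5.0, 5.0), Dimension("y", -5.0, 5.0)]
    objective = lambda p: -(p["x"] - 1.0) ** 2 - (p["y"] + 2.0) ** 2

    first = bayesopt.maximize(objective, dims, budget=40, n_initial=10, seed=3)
    second = bayesopt.maximize(objective, dims, budget=40, n_initial=10, seed=3)
    assert first.best_params == second.best_params
    assert first.best_value > -0.5  # near the optimum at (1, -2)
    assert len(first.trace) == 40


def test_bayesopt_budget_must_cover_initial_design():
    with pytest.raises(ValueError, match="initial design"):
        bayesopt.maximize(lambda p: 0.0, [Dimension("x", 0, 1)],
                          budget=5, n_initial=10, seed=0)


def test_log_and_int_dimensions_map_into_bounds():
    log_dim = Dimension("C", 1e-2, 1e2, "log")
    int_dim = Dimension("n", 50, 500, "int")
    for u in (0.0, 0.25, 0.5, 1.0):
        assert log_dim.contains(log_dim.from_unit(u))
        value = int_dim.from_unit(u)
        assert isinstance(value, int) and int_dim.contains(value)


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------

def test_default_bounds_contain_reference_optima():
    space = HyperparameterSpace()
    for model in BASE_MODEL_NAMES:
        assert space.contains(model, REFERENCE_OPTIMA[model])


def test_tuning_on_separable_data_reaches_high_auc(separable):
    """A perfect separator exists, so every tuned model should find it."""
    X, y = separable
    space = HyperparameterSpace(budget=12, n_initial=8, seed=2)
    results = tune_hyperparameters(X, y, space, folds=5)
    for model in BASE_MODEL_NAMES:
        assert results[model]["cv_auc"] >= 0.99
        dims = {d.name: d for d in space.dimensions(model)}
        for key, value in results[model]["params"].items():
            assert dims[key].contains(value)
        assert len(results[model]["trace"]) == 12


# ---------------------------------------------------------------------------
# base models
# ---------------------------------------------------------------------------

def test_rf_memorizes_small_toy():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(20, 4))
    y = np.array([0, 1] * 10)
    models = train_base_models(X, y, seed=0)
    assert (models["rf"].predict(X) == y).all()
    assert models["svm"].probability  # probability output enabled
    for model in models.values():
        assert model.predict_proba(X).shape == (20, 2)


def test_single_class_training_is_rejected():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError, match="single class"):
        train_base_models(X, np.ones(10, dtype=int))


def test_non_finite_features_are_rejected():
    X = np.random.default_rng(0).normal(size=(10, 3))
    X[3, 1] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        train_base_models(X, np.array([0, 1] * 5))


def test_reference_optima_are_valid_settings(separable):
    X, y = separable
    models = train_base_models(X, y, hyperparameters=REFERENCE_OPTIMA, seed=1)
    assert models["rf"].n_estimators == 283
    assert models["svm"].C == pytest.approx(4.691)
    assert models["ann"].hidden_layer_sizes == (201,)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

class _StubModel:
    classes_ = np.array([0, 1])

    def __init__(self, confidence):
        self._confidence = confidence

    def predict_proba(self, X):
        conf = np.full(len(X), self._confidence)
        return np.column_stack([1 - conf, conf])


def _stub_ensemble(confidences, weights=None):
    clf = EnsembleQSARClassifier(weights=weights)
    clf.base_models_ = dict(zip(BASE_MODEL_NAMES,
                                (_StubModel(c) for c in confidences)))
    clf.feature_names_in_ = None
    clf.classes_ = np.array([0, 1])
    return clf


def test_voting_is_the_mean_of_base_confidences():
    clf = _stub_ensemble([0.2, 0.4, 0.9])
    assert clf.voting_confidence(np.zeros((3, 2)))[0] == pytest.approx(0.5)
    weighted = _stub_ensemble([0.2, 0.4, 0.9], weights=(2, 1, 1))
    expected = (2 * 0.2 + 0.4 + 0.9) / 4
    assert weighted.voting_confidence(np.zeros((1, 2)))[0] == pytest.approx(expected)


def test_voting_matches_closed_form_on_fitted_ensemble(fitted_ensemble, small_selected):
    X, _, _ = small_selected
    base = fitted_ensemble.base_confidences(X)
    voting = fitted_ensemble.voting_confidence(X)
    assert np.allclose(voting, base.mean(axis=1), atol=1e-15)


def test_voting_cross_checked_against_sklearn(small_selected):
    """Independent route: sklearn's soft VotingClassifier over identical bases."""
    X, y, _ = small_selected
    ours = EnsembleQSARClassifier(build_stacking=False, random_state=4).fit(X, y)
    sk = VotingClassifier(
        [(n, make_base_model(n, REFERENCE_OPTIMA[n], seed=4))
         for n in BASE_MODEL_NAMES],
        voting="soft").fit(X.to_numpy(), y)
    theirs = sk.predict_proba(X.to_numpy())[:, 1]
    assert np.allclose(ours.voting_confidence(X), theirs, atol=1e-8)


def test_stacking_meta_features_are_out_of_fold(fitted_ensemble, small_selected):
    X, y, _ = small_selected
    clf = fitted_ensemble
    oof = clf.stacking_oof_features_
    assert oof.shape == (len(y), 3)
    folds = clf.stacking_fold_of_sample_
    assert set(folds) == set(range(clf.meta_folds))
    # reproduce fold 0's meta-features from scratch: models fitted WITHOUT fold 0
    test_idx = np.where(folds == 0)[0]
    train_idx = np.where(folds != 0)[0]
    values = X.to_numpy()
    for j, name in enumerate(BASE_MODEL_NAMES):
        model = make_base_model(name, REFERENCE_OPTIMA[name],
                                seed=clf.random_state)
        model.fit(values[train_idx], y[train_idx])
        proba = model.predict_proba(values[test_idx])[:, 1]
        assert np.allclose(proba, oof[test_idx, j], atol=1e-12)


def test_fused_models_do_not_trail_best_base(fitted_ensemble, small_selected):
    X, y, _ = small_selected
    X_train, X_test, y_train, y_test = train_test_split(
        X.to_numpy(), y, test_size=0.25, random_state=0, stratify=y)
    clf = EnsembleQSARClassifier(meta_folds=3, random_state=11).fit(X_train, y_train)
    base_aucs = [roc_auc(y_test, clf.base_confidences(X_test)[:, j])[0]
                 for j in range(3)]
    voting_auc = roc_auc(y_test, clf.voting_confidence(X_test))[0]
    stacking_auc = roc_auc(y_test, clf.stacking_confidence(X_test))[0]
    assert voting_auc >= max(base_aucs) - 0.02
    assert stacking_auc >= max(base_aucs) - 0.02


def test_unknown_fusion_rejected(small_selected):
    X, y, _ = small_selected
    with pytest.raises(ValueError, match="fusion"):
        EnsembleQSARClassifier(fusion="blending").fit(X, y)


# ---------------------------------------------------------------------------
# prediction interface
# ---------------------------------------------------------------------------

def test_predict_confidence_table(fitted_ensemble, small_selected):
    X, y, _ = small_selected
    table = fitted_ensemble.predict_confidence(X)
    assert list(table.columns) == ["conf_voting", "conf_stacking"]
    assert ((table >= 0) & (table <= 1)).all().all()
    assert list(table.index) == list(X.index)


def test_predictions_are_bit_reproducible(fitted_ensemble, small_selected):
    X, _, _ = small_selected
    a = fitted_ensemble.predict_confidence(X)
    b = fitted_ensemble.predict_confidence(X)
    pd.testing.assert_frame_equal(a, b)


def test_empty_matrix_gives_empty_table(fitted_ensemble, small_selected):
    X, _, _ = small_selected
    empty = X.iloc[:0]
    table = fitted_ensemble.predict_confidence(empty)
    assert len(table) == 0


def test_feature_mismatch_names_offenders(fitted_ensemble, small_selected):
    X, _, _ = small_selected
    renamed = X.rename(columns={X.columns[0]: "bogus_descriptor"})
    with pytest.raises(ValueError, match="bogus_descriptor"):
        fitted_ensemble.predict_confidence(renamed)


def test_all_models_rank_single_informative_feature_first():
    rng = np.random.default_rng(9)
    n = 150
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 5))
    X[:, 2] += 3.0 * y
    clf = EnsembleQSARClassifier(build_stacking=False, random_state=9).fit(X, y)
    for name in BASE_MODEL_NAMES:
        imp = permutation_importance(clf.base_models_[name], X, y,
                                     n_repeats=5, random_state=0)
        assert int(np.argmax(imp.importances_mean)) == 2
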