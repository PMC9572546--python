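"""Ensemble QSAR classification: RF + SVM (RBF) + single-hidden-layer ANN,
tuned by Gaussian-process Bayesian optimization under stratified 10-fold CV
and fused by soft Voting (weighted mean of class probabilities) or Stacking
(logistic-regression meta-learner trained on out-of-fold base confidences).

Active-class confidence is the positive-class probability in [0, 1]; the
downstream screening stage thresholds these confidences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import bayesopt
from .bayesopt import Dimension
from .descriptors import DescriptorMatrix

BASE_MODEL_NAMES = ("rf", "svm", "ann")

#: Hyperparameter optima reported for the original JNK1 training set; used as
#: ready-made settings when tuning is skipped.
REFERENCE_OPTIMA: dict[str, dict] = {
    "rf": {"n_estimators": 283, "max_depth": 25, "max_features": 0.231},
    "svm": {"C": 4.691, "gamma": 0.013},
    "ann": {"hidden_layer_sizes": 201, "alpha": 0.155},
}

ANN_MAX_ITER = 2000


@dataclass
class HyperparameterSpace:
    """Named bounds per base model plus the optimization budget.

    The default bounds bracket the reference optima above.
    """

    rf: list[Dimension] = field(default_factory=lambda: [
        Dimension("n_estimators", 50, 500, "int"),
        Dimension("max_depth", 3, 30, "int"),
        Dimension("max_features", 0.05, 1.0, "float"),
    ])
    svm: list[Dimension] = field(default_factory=lambda: [
        Dimension("C", 1e-2, 1e2, "log"),
        Dimension("gamma", 1e-4, 1.0, "log"),
    ])
    ann: list[Dimension] = field(default_factory=lambda: [
        Dimension("hidden_layer_sizes", 16, 256, "int"),
        Dimension("alpha", 1e-4, 10.0, "log"),
    ])
    budget: int = 50
    n_initial: int = 10
    seed: int = 0

    def dimensions(self, model: str) -> list[Dimension]:
        return getattr(self, model)

    def contains(self, model: str, params: dict) -> bool:
        dims = {d.name: d for d in self.dimensions(model)}
        return all(dims[k].contains(v) for k, v in params.items())


def make_base_model(name: str, params: dict, seed: int = 0,
                    ann_max_iter: int = ANN_MAX_ITER):
    """Instantiate an unfitted base classifier from named hyperparameters."""
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=int(params["n_estimators"]),
            max_depth=int(params["max_depth"]),
            max_features=float(params["max_features"]),
            random_state=seed, n_jobs=1)
    if name == "svm":
        return SVC(kernel="rbf", C=float(params["C"]), gamma=float(params["gamma"]),
                   probability=True, random_state=seed)
    if name == "ann":
        return MLPClassifier(
            hidden_layer_sizes=(int(params["hidden_layer_sizes"]),),
            alpha=float(params["alpha"]),
            max_iter=ann_max_iter, random_state=seed)
    raise ValueError(f"unknown base model {name!r}")


def _as_array(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    """Return (values, feature_names, compound_ids) for any accepted input."""
    if isinstance(X, DescriptorMatrix):
        return X.values, list(X.descriptor_names), list(X.compound_ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns], [str(i) for i in X.index]
    return np.asarray(X, dtype=float), None, None


def _validate_xy(values: np.ndarray, y: np.ndarray | None) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    if y is not None and len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")


def tune_hyperparameters(X, y, space: HyperparameterSpace | None = None,
                         folds: int = 10) -> dict[str, dict]:
    """Per-model Bayesian search maximizing mean stratified k-fold CV AUC.

    Returns {model: {"params": best, "cv_auc": best AUC, "trace": [...]}}.
    """
    space = space or HyperparameterSpace()
    values, _, _ = _as_array(X)
    y = np.asarray(y)
    _validate_xy(values, y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=space.seed)
    results: dict[str, dict] = {}
    for name in BASE_MODEL_NAMES:
        def objective(params: dict, _name=name) -> float:
            model = make_base_model(_name, params, seed=space.seed)
            scores = cross_val_score(model, values, y, cv=cv, scoring="roc_auc")
            return float(scores.mean())

        res = bayesopt.maximize(objective, space.dimensions(name),
                                budget=space.budget, n_initial=space.n_initial,
                                seed=space.seed)
        results[name] = {"params": res.best_params, "cv_auc": res.best_value,
                         "trace": res.trace}
    return results


def train_base_models(X, y, hyperparameters: dict[str, dict] | None = None,
                      seed: int = 0) -> dict[str, object]:
    """Fit RF, SVM and ANN with the given (or reference) hyperparameters."""
    hyperparameters = hyperparameters or REFERENCE_OPTIMA
    values, _, _ = _as_array(X)
    y = np.asarray(y)
    _validate_xy(values, y)
    fitted = {}
    for name in BASE_MODEL_NAMES:
        params = hyperparameters[name].get("params", hyperparameters[name])
        fitted[name] = make_base_model(name, params, seed=seed).fit(values, y)
    return fitted


class EnsembleQSARClassifier(BaseEstimator, ClassifierMixin):
    """Three tuned base classifiers fused by Voting and Stacking.

    One ``fit`` builds both fusion routes: the voting confidence is the
    closed-form weighted mean of base active-class probabilities, and the
    stacking route trains a logistic-regression meta-learner on k-fold
    out-of-fold base confidences (a sample's own in-fold prediction is never
    used as its meta-feature). ``fusion`` selects which route ``predict``
    and ``predict_proba`` expose; ``predict_confidence`` always reports both.

    Parameters
    ----------
    hyperparameters : per-model dicts; defaults to the reference optima.
    fusion : "voting" or "stacking".
    weights : voting weights over (rf, svm, ann); default equal.
    meta_folds : folds for out-of-fold stacking meta-features.
    build_stacking : build the stacking route even when fusion="voting"
        (default True; set False to skip the extra out-of-fold base fits
        when only the voting route is needed).
    random_state : seeds base models, fold shuffling and the meta-learner.
    """

    def __init__(self, hyperparameters: dict | None = None,
                 fusion: str = "voting",
                 weights: tuple[float, float, float] | None = None,
                 meta_folds: int = 5,
                 build_stacking: bool = True,
                 random_state: int = 0):
        self.hyperparameters = hyperparameters
        self.fusion = fusion
        self.weights = weights
        self.meta_folds = meta_folds
        self.build_stacking = build_stacking
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        if self.fusion not in ("voting", "stacking"):
            raise ValueError(f"unknown fusion strategy {self.fusion!r}")
        values, names, _ = _as_array(X)
        y = np.asarray(y).astype(int)
        _validate_xy(values, y)
        self.feature_names_in_ = names
        self.classes_ = np.unique(y)

        hp = self.hyperparameters or REFERENCE_OPTIMA
        self.base_models_ = {}
        for name in BASE_MODEL_NAMES:
            params = hp[name].get("params", hp[name])
            self.base_models_[name] = make_base_model(
                name, params, seed=self.random_state).fit(values, y)

        if self.build_stacking or self.fusion == "stacking":
            self._fit_stacking(values, y, hp)
        return self

    def _fit_stacking(self, values: np.ndarray, y: np.ndarray, hp: dict) -> None:
        cv = StratifiedKFold(n_splits=self.meta_folds, shuffle=True,
                             random_state=self.random_state)
        n = len(y)
        oof = np.full((n, len(BASE_MODEL_NAMES)), np.nan)
        fold_of_sample = np.full(n, -1, dtype=int)
        for fold, (train_idx, test_idx) in enumerate(cv.split(values, y)):
            fold_of_sample[test_idx] = fold
            for j, name in enumerate(BASE_MODEL_NAMES):
                params = hp[name].get("params", hp[name])
                model = make_base_model(name, params, seed=self.random_state)
                model.fit(values[train_idx], y[train_idx])
                proba = model.predict_proba(values[test_idx])
                oof[test_idx, j] = proba[:, list(model.classes_).index(1)]
        assert not np.isnan(oof).any()
        self.stacking_oof_features_ = oof
        self.stacking_fold_of_sample_ = fold_of_sample
        self.meta_model_ = LogisticRegression(random_state=self.random_state)
        self.meta_model_.fit(oof, y)

    # -- prediction --------------------------------------------------------

    def _check_features(self, X) -> np.ndarray:
        values, names, _ = _as_array(X)
        if names is not None and self.feature_names_in_ is not None:
            if names != self.feature_names_in_:
                extra = set(names) - set(self.feature_names_in_)
                missing = set(self.feature_names_in_) - set(names)
                if extra or missing:
                    raise ValueError(
                        f"feature mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
                # same names, different order: realign
                frame = pd.DataFrame(values, columns=names)
                values = frame[self.feature_names_in_].to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains non-finite values")
        return values

    def base_confidences(self, X) -> np.ndarray:
        """(n, 3) active-class probabilities from rf, svm, ann in order."""
        check_is_fitted(self, "base_models_")
        values = self._check_features(X)
        if values.shape[0] == 0:
            return np.empty((0, len(BASE_MODEL_NAMES)))
        cols = []
        for name in BASE_MODEL_NAMES:
            model = self.base_models_[name]
            proba = model.predict_proba(values)
            cols.append(proba[:, list(model.classes_).index(1)])
        return np.column_stack(cols)

    def voting_confidence(self, X) -> np.ndarray:
        base = self.base_confidences(X)
        w = np.asarray(self.weights if self.weights is not None
                       else np.ones(base.shape[1]), dtype=float)
        w = w / w.sum()
        return base @ w

    def stacking_confidence(self, X) -> np.ndarray:
        check_is_fitted(self, "meta_model_")
        base = self.base_confidences(X)
        if base.shape[0] == 0:
            return np.empty(0)
        proba = self.meta_model_.predict_proba(base)
        return proba[:, list(self.meta_model_.classes_).index(1)]

    def predict_proba(self, X) -> np.ndarray:
        conf = (self.voting_confidence(X) if self.fusion == "voting"
                else self.stacking_confidence(X))
        return np.column_stack([1.0 - conf, conf])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_confidence(self, X) -> pd.DataFrame:
        """Both fused confidences per compound (columns conf_voting, conf_stacking)."""
        _, _, ids = _as_array(X)
        voting = self.voting_confidence(X)
        stacking = self.stacking_confidence(X)
        index = pd.Index(ids if ids is not None else range(len(voting)),
                         name="compound_id")
        return pd.DataFrame({"conf_voting": voting, "conf_stacking": stacking},
                            index=index)


@dataclass
class EnsembleModel:
    """A fitted ensemble bundle: bases + both fusion routes + provenance."""

    classifier: EnsembleQSARClassifier
    hyperparameters: dict
    fusion: str
    selected_features: list[str] | None = None

    def predict_confidence(self, X) -> pd.DataFrame:
        return self.classifier.predict_confidence(X)


def build_ensemble(X, y, hyperparameters: dict | None = None,
                   fusion: str = "voting", weights=None, seed: int = 0,
                   meta_folds: int = 5,
                   selected_features: list[str] | None = None) -> EnsembleModel:
    """Fit the full ensemble (bases + voting + stacking) in one call."""
    clf = EnsembleQSARClassifier(hyperparameters=hyperparameters, fusion=fusion,
                                 weights=weights, meta_folds=meta_folds,
                                 random_state=seed).fit(X, y)
    return EnsembleModel(classifier=clf,
                         hyperparameters=hyperparameters or REFERENCE_OPTIMA,
                         fusion=fusion, selected_features=selected_features)


def predict_confidence(model: EnsembleModel | EnsembleQSARClassifier, X) -> pd.DataFrame:
    return model.predict_confidence(X)
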