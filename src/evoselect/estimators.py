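"""Classifier families, adaptive cross-validation and the BIC fitness.

Three families share one contract (fit / predict_proba / parameter_count /
inherent_importance): an elastic-net logistic regression, gradient-boosted
trees (gbtree booster) and a feed-forward network with a fixed architecture of
3 hidden layers x 300 ReLU units trained with Adam and early stopping
(patience 3 on validation loss).

Fitness of a (hyperparameters, feature subset) candidate is the Bayesian
Information Criterion computed from out-of-fold predictions,

    BIC = p * ln(n) - 2 * loglik,

where p is the number of selected features, n the number of scored samples
and loglik the summed validation log-likelihood (nats).  The complexity term
penalizes exactly what the evolutionary search selects over and is comparable
across families, including ones without a native likelihood.

The fold count adapts to model size: k is the smallest integer strictly above
n / p (so integer ratios round up), optionally capped, and folds are
stratified by label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .search_space import SearchSpace, default_space

__all__ = [
    "EstimatorSpec",
    "FitnessRecord",
    "CVPlan",
    "make_estimator",
    "build_cv_plan",
    "cv_fit",
    "bic_score",
    "FAMILIES",
]

FAMILIES = ("neural_net", "boosted_trees", "logistic_elasticnet")

#: class-probability floor used in the log-likelihood (avoids -inf)
PROB_FLOOR = 1e-12


@dataclass
class EstimatorSpec:
    """Family plus its fixed settings and tunable search space."""

    family: str
    fixed: dict = field(default_factory=dict)
    space: SearchSpace | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.space is None:
            self.space = default_space(self.family)
        defaults = {
            "neural_net": {
                "hidden_layers": 3,
                "hidden_units": 300,
                "patience": 3,
                "validation_fraction": 0.1,
            },
            "boosted_trees": {"booster": "gbtree"},
            "logistic_elasticnet": {"max_iter": 1000, "tol": 1e-4},
        }[self.family]
        self.fixed = {**defaults, **self.fixed}


class _Wrapped:
    """Shared implementation of the uniform estimator contract."""

    def __init__(self, spec: EstimatorSpec, hyperparams: dict, seed: int = 0):
        spec.space.validate(hyperparams)
        self.spec = spec
        self.hyperparams = dict(hyperparams)
        self.seed = seed

    def fit(self, X, y):
        self.n_features_ = np.asarray(X).shape[1]
        self._model = self._build()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self._model.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class LogisticElasticNet(_Wrapped):
    """Elastic-net logistic regression (saga); penalties mix in [0,1]."""

    def _build(self):
        h = self.hyperparams
        return LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            l1_ratio=float(h.get("l1_mix", 0.5)),
            C=1.0 / float(h.get("strength", 1.0)),
            max_iter=self.spec.fixed["max_iter"],
            tol=self.spec.fixed["tol"],
            random_state=self.seed,
        )

    def parameter_count(self) -> int:
        return self.n_features_ + 1

    def inherent_importance(self) -> np.ndarray:
        return np.abs(self._model.coef_[0])


class BoostedTrees(_Wrapped):
    """XGBoost with the gbtree booster; gain-based inherent importance."""

    def _build(self):
        h = self.hyperparams
        return XGBClassifier(
            booster=self.spec.fixed["booster"],
            learning_rate=float(h.get("eta", 0.3)),
            max_depth=int(h.get("max_depth", 6)),
            n_estimators=int(h.get("n_estimators", 100)),
            subsample=float(h.get("subsample", 1.0)),
            colsample_bytree=float(h.get("colsample_bytree", 1.0)),
            reg_lambda=float(h.get("reg_lambda", 1.0)),
            gamma=float(h.get("gamma", 0.0)),
            tree_method="hist",
            n_jobs=1,
            random_state=self.seed,
            eval_metric="logloss",
            importance_type="gain",
            verbosity=0,
        )

    def parameter_count(self) -> int:
        return int(self._model.get_booster().trees_to_dataframe().shape[0])

    def inherent_importance(self) -> np.ndarray:
        return np.asarray(self._model.feature_importances_, dtype=float)


class NeuralNet(_Wrapped):
    """3 x 300 ReLU network, Adam, early stopping patience 3 on validation loss.

    Inherent importance is unavailable for this family (``None``); use
    permutation importance instead.
    """

    def _build(self):
        h = self.hyperparams
        f = self.spec.fixed
        return MLPClassifier(
            hidden_layer_sizes=(f["hidden_units"],) * f["hidden_layers"],
            activation="relu",
            solver="adam",
            learning_rate_init=float(h.get("learning_rate", 1e-3)),
            batch_size=int(h.get("batch_size", 32)),
            max_iter=int(h.get("epochs", 100)),
            early_stopping=True,
            n_iter_no_change=f["patience"],
            validation_fraction=f["validation_fraction"],
            random_state=self.seed,
        )

    def parameter_count(self) -> int:
        return int(sum(w.size for w in self._model.coefs_) + sum(b.size for b in self._model.intercepts_))

    def inherent_importance(self):
        return None


def make_estimator(spec: EstimatorSpec, hyperparams: dict, seed: int = 0) -> _Wrapped:
    """Instantiate one family member at a hyperparameter assignment.

    Raises a ValueError naming the hyperparameter if the assignment falls
    outside the declared search space.
    """
    cls = {
        "logistic_elasticnet": LogisticElasticNet,
        "boosted_trees": BoostedTrees,
        "neural_net": NeuralNet,
    }[spec.family]
    return cls(spec, hyperparams, seed)


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------


@dataclass
class CVPlan:
    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]


def build_cv_plan(
    n: int, p: int, labels: np.ndarray, cap: int | None = None, seed: int = 0
) -> CVPlan:
    """Stratified k-fold plan with k = smallest integer strictly above n/p.

    Integer ratios round up by one (784/50 -> 16; 100/50 -> 3).  ``cap`` bounds
    k from above; if k exceeds the minority class count, k falls back to that
    count with a warning (never below 2).
    """
    labels = np.asarray(labels, dtype=int)
    if p < 1:
        raise ValueError("p must be >= 1")
    ratio = n / p
    k = math.floor(ratio) + 1
    k = max(k, 2)
    if cap is not None:
        k = min(k, cap)
    minority = int(np.bincount(labels).min())
    if k > minority:
        warnings.warn(f"k={k} exceeds minority count {minority}; reducing")
        k = max(2, minority)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(tr, va) for tr, va in skf.split(np.zeros(n), labels)]
    return CVPlan(k, folds)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------


def bic_score(p: int, n: int, loglik: float) -> float:
    """BIC = p ln(n) - 2 loglik (lower is better)."""
    return p * math.log(n) - 2.0 * loglik


@dataclass
class FitnessRecord:
    """One cross-validated candidate: chromosome, fitness and fold outputs."""

    hyperparams: dict
    feature_subset: tuple[int, ...]
    n: int
    p: int
    loglik: float
    bic: float
    fold_accuracy: list[float]
    fold_logloss: list[float]
    importances: np.ndarray | None = None
    lineage: str = "fresh"

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        expected = bic_score(self.p, self.n, self.loglik)
        if not math.isclose(self.bic, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("bic does not satisfy p*ln(n) - 2*loglik")


def cv_fit(
    spec: EstimatorSpec,
    hyperparams: dict,
    X: np.ndarray,
    y: np.ndarray,
    feature_subset,
    seed: int = 0,
    cap: int | None = 10,
    compute_importances: bool = True,
) -> FitnessRecord:
    """Cross-validated fit of one chromosome; returns its fitness record.

    Per fold: fit on the training folds restricted to the feature subset,
    predict the validation fold; the summed validation log-likelihood feeds
    the BIC with p = |subset|.  Degenerate single-class training folds are
    skipped with a warning.  Importances are inherent (|coef| / gain) averaged
    over folds, mapped back into the full candidate pool; for the network
    family a single-fold permutation importance is used instead.
    """
    subset = tuple(int(i) for i in feature_subset)
    if len(subset) == 0:
        raise ValueError("feature subset is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if max(subset) >= X.shape[1] or min(subset) < 0:
        raise ValueError("feature subset index out of range")
    Xs = X[:, subset]
    n, p = X.shape[0], len(subset)
    plan = build_cv_plan(n, p, y, cap=cap, seed=seed)

    loglik = 0.0
    scored = 0
    accs, losses = [], []
    imp_sum = np.zeros(p)
    imp_folds = 0
    last_model, last_val = None, None
    for f, (tr, va) in enumerate(plan.folds):
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"fold {f} has a single-class training split; skipped")
            continue
        est = make_estimator(spec, hyperparams, seed=seed + f)
        est.fit(Xs[tr], y[tr])
        proba = np.clip(est.predict_proba(Xs[va]), PROB_FLOOR, 1 - PROB_FLOOR)
        pv = proba[np.arange(len(va)), y[va]]
        loglik += float(np.log(pv).sum())
        scored += len(va)
        pred = (proba[:, 1] >= 0.5).astype(int)
        accs.append(float((pred == y[va]).mean()))
        losses.append(float(log_loss(y[va], proba[:, 1], labels=[0, 1])))
        if compute_importances:
            inh = est.inherent_importance()
            if inh is not None:
                imp_sum += inh
                imp_folds += 1
            else:
                last_model, last_val = est, (Xs[va], y[va])
    if scored == 0:
        raise RuntimeError("every fold was degenerate; cannot score chromosome")

    importances = None
    if compute_importances:
        if imp_folds > 0:
            sub_imp = imp_sum / imp_folds
        elif last_model is not None:
            from .explain import permutation_importance

            Xv, yv = last_val
            if len(np.unique(yv)) < 2:
                sub_imp = np.zeros(p)
            else:
                pi = permutation_importance(last_model, Xv, yv, n_repeats=5, seed=seed)
                sub_imp = pi["importance"]
        else:  # pragma: no cover
            sub_imp = np.zeros(p)
        importances = np.zeros(X.shape[1])
        importances[list(subset)] = sub_imp

    bic = bic_score(p, scored, loglik)
    return FitnessRecord(
        dict(hyperparams), subset, scored, p, loglik, bic, accs, losses, importances
    )
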