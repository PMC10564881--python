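"""Held-out testing, ROC/AUC, and model explanation.

Explanation methods: permutation importance (mean score drop over seeded
shuffles of one column) and Shapley-value attribution with an interventional
value function over a background sample.  Shapley values are computed exactly
by coalition enumeration for small feature counts and by seeded permutation
sampling otherwise; both satisfy local accuracy (attributions sum to the
prediction minus the background mean output).  For elastic-net logistic
models, odds ratios with Wald intervals come from an unpenalized refit on the
selected predictors, since penalized intervals are not well-defined.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_curve

from .estimators import EstimatorSpec, FitnessRecord, make_estimator

__all__ = [
    "TestReport",
    "roc_auc",
    "permutation_importance",
    "shapley_values",
    "shapley_importance",
    "lr_odds_ratios",
    "test_holdout",
    "report",
]


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoidal AUC.

    Equals the Mann-Whitney concordance probability (ties half credit).
    Raises on single-class labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    curve = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------


def _auc_of(model, X, y) -> float:
    return roc_auc(model.predict_proba(X)[:, 1], y)[1]


def permutation_importance(
    model, X, y, n_repeats: int = 10, seed: int = 0, score=_auc_of
) -> dict:
    """Mean drop in score when one feature's column is shuffled.

    Returns ``{"importance": mean drops, "sd": per-feature SDs, "baseline": s}``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    baseline = score(model, X, y)
    p = X.shape[1]
    drops = np.zeros((n_repeats, p))
    for r in range(n_repeats):
        for j in range(p):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            drops[r, j] = baseline - score(model, Xp, y)
    return {
        "importance": drops.mean(axis=0),
        "sd": drops.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(p),
        "baseline": baseline,
    }


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------


def _coalition_value(predict, x_row, background, subset_mask) -> float:
    """Interventional value: mean prediction with coalition features set to
    the explained row and the rest kept at background values."""
    Xb = background.copy()
    Xb[:, subset_mask] = x_row[subset_mask]
    return float(predict(Xb).mean())


def _exact_shapley(predict, x_row, background) -> np.ndarray:
    p = len(x_row)
    values = {}
    for bits in range(2**p):
        mask = np.array([(bits >> j) & 1 for j in range(p)], dtype=bool)
        values[bits] = _coalition_value(predict, x_row, background, mask)
    phi = np.zeros(p)
    for j in range(p):
        for bits in range(2**p):
            if (bits >> j) & 1:
                continue
            s = bin(bits).count("1")
            w = math.factorial(s) * math.factorial(p - s - 1) / math.factorial(p)
            phi[j] += w * (values[bits | (1 << j)] - values[bits])
    return phi


def _sampled_shapley(predict, x_row, background, n_samples, rng) -> np.ndarray:
    """Permutation-sampling estimator; each permutation's contributions
    telescope, so the estimate satisfies local accuracy exactly."""
    p = len(x_row)
    phi = np.zeros(p)
    mask = np.zeros(p, dtype=bool)
    for _ in range(n_samples):
        order = rng.permutation(p)
        mask[:] = False
        prev = _coalition_value(predict, x_row, background, mask)
        for j in order:
            mask[j] = True
            cur = _coalition_value(predict, x_row, background, mask)
            phi[j] += cur - prev
            prev = cur
    return phi / n_samples


def shapley_values(
    model,
    X_background,
    X_explain,
    n_samples: int = 200,
    seed: int = 0,
    exact: bool | None = None,
) -> np.ndarray:
    """Per-row Shapley attributions, shape (n_explain, p).

    ``exact=None`` enumerates coalitions exhaustively when p <= 10, otherwise
    samples ``n_samples`` seeded permutations per row.  The value function is
    the mean class-1 probability over the background sample with coalition
    features pinned to the explained row.
    """
    Xb = np.asarray(X_background, dtype=float)
    Xe = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if len(Xb) == 0:
        raise ValueError("background sample is empty")
    p = Xe.shape[1]
    if exact is None:
        exact = p <= 10

    def predict(A):
        return model.predict_proba(A)[:, 1]

    rng = np.random.default_rng(seed)
    out = np.empty_like(Xe)
    for i, row in enumerate(Xe):
        if exact:
            out[i] = _exact_shapley(predict, row, Xb)
        else:
            out[i] = _sampled_shapley(predict, row, Xb, n_samples, rng)
    return out


def shapley_importance(
    model, X_background, X_explain, n_samples: int = 200, seed: int = 0, exact=None
) -> np.ndarray:
    """Mean absolute Shapley attribution per feature over the explained rows."""
    return np.abs(shapley_values(model, X_background, X_explain, n_samples, seed, exact)).mean(axis=0)


# ---------------------------------------------------------------------------
# logistic odds ratios
# ---------------------------------------------------------------------------


def lr_odds_ratios(model, X, y, feature_names=None) -> pd.DataFrame:
    """Odds ratios + Wald 95% CI for a fitted elastic-net logistic model.

    Predictors with non-zero penalized coefficients are refit without penalty
    (statsmodels MLE); OR = exp(coefficient).  An empty selected set yields an
    intercept-only row.
    """
    coefs = model._model.coef_[0]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    sel = np.flatnonzero(np.abs(coefs) > 1e-10)
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(X.shape[1])]
    if len(sel) == 0:
        warnings.warn("no selected predictors; reporting intercept only")
        res = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        return pd.DataFrame(
            {"predictor": ["intercept"], "or": [float(np.exp(res.params[0]))],
             "ci_low": [np.nan], "ci_high": [np.nan]}
        )
    design = sm.add_constant(X[:, sel])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, design).fit(disp=0, maxiter=500)
    z = 1.959963984540054
    rows = []
    for i, j in enumerate(sel, start=1):
        b, se = res.params[i], res.bse[i]
        rows.append(
            {
                "predictor": names[j],
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * se)),
                "ci_high": float(np.exp(b + z * se)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# held-out testing
# ---------------------------------------------------------------------------


@dataclass
class TestReport:
    """Per-model held-out metrics (threshold 0.5) plus best-model pointers."""

    rows: pd.DataFrame
    roc_curves: list[np.ndarray]
    best_by: dict[str, int] = field(default_factory=dict)

    def best_row(self, metric: str = "auc") -> pd.Series:
        return self.rows.loc[self.best_by[metric]]


def test_holdout(
    records: list[FitnessRecord],
    spec: EstimatorSpec,
    X_train,
    y_train,
    X_test,
    y_test,
    seed: int = 0,
) -> TestReport:
    """Refit each candidate's frozen (hyperparams, subset) on the full training
    partition and score the untouched test partition.

    The test partition is never resampled and its labels are consumed only
    here, at metric time.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    y_test = np.asarray(y_test, dtype=int)
    if X_test.shape[1] != X_train.shape[1]:
        raise ValueError("test table lacks training features")
    rows, curves = [], []
    for i, rec in enumerate(records):
        cols = list(rec.feature_subset)
        if max(cols) >= X_test.shape[1]:
            raise ValueError(f"model {i}: feature {max(cols)} missing from test table")
        est = make_estimator(spec, rec.hyperparams, seed=seed)
        est.fit(X_train[:, cols], y_train)
        proba = est.predict_proba(X_test[:, cols])[:, 1]
        pred = (proba >= 0.5).astype(int)
        tp = int(((pred == 1) & (y_test == 1)).sum())
        fp = int(((pred == 1) & (y_test == 0)).sum())
        fn = int(((pred == 0) & (y_test == 1)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        curve, auc = roc_auc(proba, y_test)
        rows.append(
            {
                "model": i,
                "bic": rec.bic,
                "n_features": rec.p,
                "accuracy": float((pred == y_test).mean()),
                "precision": precision,
                "recall": recall,
                "auc": auc,
            }
        )
        curves.append(curve)
    frame = pd.DataFrame(rows)
    best_by = {m: int(frame[m].idxmax()) for m in ("accuracy", "precision", "recall", "auc")}
    return TestReport(frame, curves, best_by)


def report(test_report: TestReport, importances: pd.DataFrame | None, out_dir) -> dict:
    """Write the metric grid, importance list and ROC series to JSON/CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    test_report.rows.to_csv(out / "metrics.csv", index=False)
    if importances is not None:
        importances.to_csv(out / "importances.csv", index=False)
    payload = {
        "best_by": test_report.best_by,
        "best_auc": float(test_report.rows["auc"].max()),
        "n_models": int(len(test_report.rows)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    roc = test_report.roc_curves[test_report.best_by["auc"]]
    pd.DataFrame(roc, columns=["fpr", "tpr"]).to_csv(out / "roc_best.csv", index=False)
    return payload
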