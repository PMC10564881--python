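"""Tabular preparation chain and predictive-target construction.

Order of operations (fit on the training partition, apply to test):
sparsity filter -> outlier trim -> masked-NNMF imputation -> instrument
agglomeration -> min-max scaling -> per-feature normalizing-transform
selection.  Targets are built by agglomerating symptom items and labelling
subjects with a zero agglomerated score as not-cases.  Class imbalance in the
training partition is addressed with SMOTE oversampling followed by
edited-nearest-neighbour cleaning (SMOTEENN); the test partition is never
resampled.

The trim step uses same-partition statistics (it is stateless); every other
step is fitted on the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import FeatureAgglomeration
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler, PowerTransformer, QuantileTransformer

from .feature_table import BinaryTarget, FeatureTable

__all__ = [
    "SparseFeatureFilter",
    "MaskedNNMFImputer",
    "NormalizingTransformSelector",
    "TabularPreparer",
    "TransformReport",
    "drop_sparse_features",
    "trim_outliers",
    "impute_nnmf",
    "agglomerate_items",
    "scale_minmax",
    "select_normalizing_transform",
    "binarize_target",
    "SMOTEENN",
    "resample_smoteenn",
    "univariate_odds_ratio",
]


# ---------------------------------------------------------------------------
# sparsity filter
# ---------------------------------------------------------------------------


class SparseFeatureFilter(BaseEstimator, TransformerMixin):
    """Drop features whose missing fraction exceeds ``max_missing`` (default 0.40).

    Strictly-greater comparison: a feature at exactly the threshold is kept,
    one above it is discarded.
    """

    def __init__(self, max_missing: float = 0.40):
        self.max_missing = max_missing

    def fit(self, table: FeatureTable, y=None):
        if not 0 < self.max_missing < 1:
            raise ValueError("max_missing must be in (0,1)")
        frac = table.missing_fraction()
        self.dropped_ = list(frac.index[frac > self.max_missing])
        self.retained_ = list(frac.index[frac <= self.max_missing])
        if not self.retained_:
            raise ValueError("sparsity filter would drop every feature")
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        return table.select_features(self.retained_)


def drop_sparse_features(table: FeatureTable, max_missing: float = 0.40) -> FeatureTable:
    return SparseFeatureFilter(max_missing).fit_transform(table)


# ---------------------------------------------------------------------------
# outlier trim (stateless, same-partition statistics)
# ---------------------------------------------------------------------------


def trim_outliers(table: FeatureTable, k_sd: float = 3.0) -> FeatureTable:
    """Clip observed values of continuous features into mean +/- k_sd * sd.

    Statistics are computed per feature on the observed entries of the same
    partition (sample sd, ddof=1).  Zero-variance features are left unchanged
    with a warning.
    """
    out = table.copy()
    cont = [
        name
        for name in out.feature_names
        if out.feature_meta.loc[name, "dtype"] == "continuous"
    ]
    for name in cont:
        col = out.values[name]
        obs = col[out.mask[name]]
        if len(obs) < 2:
            continue
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"feature {name!r} has zero variance; not trimmed")
            continue
        mu = obs.mean()
        lo, hi = mu - k_sd * sd, mu + k_sd * sd
        out.values[name] = col.clip(lower=lo, upper=hi)
    return out


# ---------------------------------------------------------------------------
# masked non-negative matrix factorization imputation
# ---------------------------------------------------------------------------


class MaskedNNMFImputer(BaseEstimator, TransformerMixin):
    """Fill unobserved cells with a low-rank non-negative reconstruction.

    Minimizes ||M * (X - WH)||_F^2 over observed cells only, by multiplicative
    updates; values are shifted to be non-negative first and the offset is
    undone afterwards.  Observed entries are returned bit-identical.  The
    feature factor ``H_`` is fitted on the training partition; ``transform``
    on new data re-estimates only the per-subject weights ``W``.
    """

    def __init__(self, rank: int = 10, max_iter: int = 500, tol: float = 1e-5, seed: int = 0):
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    @staticmethod
    def _mu_steps(X, M, W, H, update_h: bool, max_iter: int, tol: float):
        """Mask-weighted multiplicative updates; returns (W, H, objective trace)."""
        eps = 1e-12
        MX = M * X
        obj = []
        prev = None
        for _ in range(max_iter):
            WH = W @ H
            W *= (MX @ H.T) / ((M * WH) @ H.T + eps)
            if update_h:
                WH = W @ H
                H *= (W.T @ MX) / (W.T @ (M * WH) + eps)
            resid = M * (X - W @ H)
            cur = float((resid * resid).sum())
            obj.append(cur)
            if prev is not None and prev - cur <= tol * max(prev, 1e-30):
                break
            prev = cur
        return W, H, obj

    def fit(self, table: FeatureTable, y=None):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        X = table.as_array()
        M = table.mask.to_numpy(dtype=float)
        obs_min = np.nanmin(np.where(M > 0, X, np.nan))
        self.offset_ = float(min(obs_min, 0.0))
        Xs = np.where(M > 0, X - self.offset_, 0.0)
        rng = np.random.default_rng(self.seed)
        n, p = Xs.shape
        scale = np.sqrt(Xs[M > 0].mean() / self.rank) if (M > 0).any() else 1.0
        W = rng.uniform(0.1, 1.0, size=(n, self.rank)) * scale
        H = rng.uniform(0.1, 1.0, size=(self.rank, p)) * scale
        W, H, obj = self._mu_steps(Xs, M, W, H, True, self.max_iter, self.tol)
        if len(obj) >= self.max_iter:
            warnings.warn("masked NNMF did not converge; returning best iterate")
        self.W_, self.H_, self.objective_trace_ = W, H, obj
        self.feature_names_ = list(table.feature_names)
        return self

    def _fill(self, table: FeatureTable, W: np.ndarray) -> FeatureTable:
        recon = W @ self.H_ + self.offset_
        out = table.copy()
        vals = out.values.to_numpy(dtype=float)
        miss = ~out.mask.to_numpy()
        vals[miss] = recon[miss]
        out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
        return out

    def transform(self, table: FeatureTable) -> FeatureTable:
        if list(table.feature_names) != self.feature_names_:
            raise ValueError("feature set does not match the fitted imputer")
        if table.mask.to_numpy().all():
            return table.copy()
        X = table.as_array()
        M = table.mask.to_numpy(dtype=float)
        Xs = np.where(M > 0, X - self.offset_, 0.0)
        rng = np.random.default_rng(self.seed + 1)
        W = rng.uniform(0.1, 1.0, size=(Xs.shape[0], self.rank))
        W, _, _ = self._mu_steps(Xs, M, W, self.H_.copy(), False, self.max_iter, self.tol)
        return self._fill(table, W)

    def fit_transform(self, table: FeatureTable, y=None, **kw) -> FeatureTable:
        self.fit(table)
        return self._fill(table, self.W_)


def impute_nnmf(
    table: FeatureTable, rank: int = 10, max_iter: int = 500, tol: float = 1e-5, seed: int = 0
) -> FeatureTable:
    return MaskedNNMFImputer(rank, max_iter, tol, seed).fit_transform(table)


# ---------------------------------------------------------------------------
# feature agglomeration -> single summary score
# ---------------------------------------------------------------------------


def agglomerate_items(items: pd.DataFrame) -> pd.Series:
    """Recursively merge related columns into one continuous summary.

    Ward-linkage hierarchical merging on Euclidean column distance, pooled to
    the root with the size-weighted mean: the root summary equals the mean of
    all leaf columns.  Deterministic given the input.  A single column is
    returned unchanged.
    """
    if items.shape[1] == 0:
        raise ValueError("need at least one item column")
    if items.isna().any().any():
        raise ValueError("agglomeration requires complete items (impute first)")
    if items.shape[1] == 1:
        return items.iloc[:, 0].copy()
    agg = FeatureAgglomeration(n_clusters=1, linkage="ward", pooling_func=np.mean)
    score = agg.fit_transform(items.to_numpy(dtype=float))[:, 0]
    return pd.Series(score, index=items.index, name="agglomerated")


# ---------------------------------------------------------------------------
# min-max scaling (train-fitted affine map, no clipping on test)
# ---------------------------------------------------------------------------


class _TableMinMax(BaseEstimator, TransformerMixin):
    def fit(self, table: FeatureTable, y=None):
        self.scaler_ = MinMaxScaler(clip=False)
        self.scaler_.fit(table.as_array())
        const = self.scaler_.data_range_ == 0
        if const.any():
            names = list(np.asarray(table.feature_names)[const])
            warnings.warn(f"constant features mapped to 0: {names}")
        self.feature_names_ = list(table.feature_names)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        out = table.copy()
        arr = self.scaler_.transform(table.as_array())
        # constant train features -> 0 everywhere
        const = self.scaler_.data_range_ == 0
        arr[:, const] = 0.0
        out.values = pd.DataFrame(arr, index=out.values.index, columns=out.values.columns)
        return out


def scale_minmax(
    train: FeatureTable, test: FeatureTable | None = None
) -> FeatureTable | tuple[FeatureTable, FeatureTable]:
    """Map each feature so the train min -> 0 and max -> 1; the same affine map
    is applied to the test partition (values outside [0,1] are preserved)."""
    mm = _TableMinMax().fit(train)
    if test is None:
        return mm.transform(train)
    return mm.transform(train), mm.transform(test)


# ---------------------------------------------------------------------------
# normalizing-transform selection (none / power / quantile)
# ---------------------------------------------------------------------------


@dataclass
class TransformReport:
    """Per-feature record of the chosen normalizing transform."""

    feature: str
    chosen: str
    stat_before: float
    stat_after: float


def _anderson_stat(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.std(ddof=1) == 0:
        return float("inf")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson((x - x.mean()) / x.std(ddof=1), dist="norm")
    return float(res.statistic)


class NormalizingTransformSelector(BaseEstimator, TransformerMixin):
    """Pick, per feature, the version most resembling a normal distribution.

    Candidates: untransformed, Yeo-Johnson power transform, rank-based
    quantile-to-normal transform.  Normality is measured with the
    Anderson-Darling statistic on standardized values.  A feature already
    consistent with normality at the 5% level is left untransformed; otherwise
    the minimum-statistic candidate wins, with ties broken in the order
    none > power > quantile.
    """

    #: Anderson-Darling 5% critical value for the normal family
    AD_CRIT_5PCT = 0.787

    def fit(self, table: FeatureTable, y=None):
        X = table.values
        self.transforms_: dict[str, str] = {}
        self.fitted_: dict[str, object] = {}
        self.report_: list[TransformReport] = []
        for name in table.feature_names:
            x = X[name].to_numpy(dtype=float)
            if table.feature_meta.loc[name, "dtype"] != "continuous" or len(x) < 20:
                self.transforms_[name] = "none"
                continue
            before = _anderson_stat(x)
            if not np.isfinite(before):
                warnings.warn(f"feature {name!r} is constant; left untransformed")
                self.transforms_[name] = "none"
                self.report_.append(TransformReport(name, "none", before, before))
                continue
            if before <= self.AD_CRIT_5PCT:
                self.transforms_[name] = "none"
                self.report_.append(TransformReport(name, "none", before, before))
                continue
            col = x.reshape(-1, 1)
            cands: dict[str, tuple[object, float]] = {"none": (None, before)}
            pt = PowerTransformer(method="yeo-johnson", standardize=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                xp = pt.fit_transform(col)[:, 0]
            cands["power"] = (pt, _anderson_stat(xp))
            qt = QuantileTransformer(
                output_distribution="normal",
                n_quantiles=min(len(x), 1000),
                random_state=0,
            )
            xq = qt.fit_transform(col)[:, 0]
            cands["quantile"] = (qt, _anderson_stat(xq))
            # min statistic; ties (to printed precision) prefer none > power > quantile
            best = min(cands.values(), key=lambda t: t[1])[1]
            for pref in ("none", "power", "quantile"):
                if cands[pref][1] <= best + 1e-9:
                    chosen = pref
                    break
            self.transforms_[name] = chosen
            if chosen != "none":
                self.fitted_[name] = cands[chosen][0]
            self.report_.append(TransformReport(name, chosen, before, cands[chosen][1]))
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        out = table.copy()
        for name, kind in self.transforms_.items():
            if kind == "none" or name not in out.values.columns:
                continue
            col = out.values[name].to_numpy(dtype=float).reshape(-1, 1)
            out.values[name] = self.fitted_[name].transform(col)[:, 0]
        return out

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.feature, r.chosen, r.stat_before, r.stat_after) for r in self.report_],
            columns=["feature", "chosen", "stat_before", "stat_after"],
        )


def select_normalizing_transform(feature: pd.Series) -> tuple[pd.Series, TransformReport]:
    """Single-column convenience wrapper around the selector."""
    table = FeatureTable(feature.to_frame(), feature.to_frame().notna())
    sel = NormalizingTransformSelector().fit(table)
    out = sel.transform(table)
    rep = sel.report_[0] if sel.report_ else TransformReport(feature.name, "none", np.nan, np.nan)
    return out.values.iloc[:, 0], rep


# ---------------------------------------------------------------------------
# target construction
# ---------------------------------------------------------------------------


def binarize_target(symptom_items: pd.DataFrame, name: str = "target") -> BinaryTarget:
    """Agglomerate symptom items and label zero-score subjects as not-cases.

    Items must be non-negative and complete; label is 1 iff the agglomerated
    score is strictly positive.
    """
    if (symptom_items.to_numpy(dtype=float) < 0).any():
        raise ValueError("symptom items must be non-negative")
    score = agglomerate_items(symptom_items)
    labels = (score > 0).astype(int)
    if labels.min() == labels.max():
        warnings.warn(f"target {name!r} is single-class")
    return BinaryTarget(labels, source_items=list(symptom_items.columns), name=name)


# ---------------------------------------------------------------------------
# SMOTEENN resampling
# ---------------------------------------------------------------------------


class SMOTEENN(BaseEstimator):
    """SMOTE minority oversampling followed by edited-nearest-neighbour cleaning.

    SMOTE synthesizes minority points as convex combinations of a minority
    point and one of its ``k_smote`` nearest minority neighbours until classes
    balance.  ENN then removes any point (either class) whose ``k_enn``
    nearest neighbours do not all share its label.  Training-partition only.
    """

    def __init__(self, k_smote: int = 5, k_enn: int = 3, seed: int = 0):
        self.k_smote = k_smote
        self.k_enn = k_enn
        self.seed = seed

    def fit_resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTEENN requires both classes present")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        rng = np.random.default_rng(self.seed)

        Xmin = X[y == minority]
        k = self.k_smote
        if n_min <= k:
            k = max(1, n_min - 1)
            warnings.warn(f"minority count {n_min} < k+1; reducing SMOTE k to {k}")
        n_new = n_maj - n_min
        synth = np.empty((n_new, X.shape[1]))
        provenance = []
        if n_new > 0:
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
            _, idx = nn.kneighbors(Xmin)
            base = rng.integers(0, len(Xmin), size=n_new)
            pick = rng.integers(1, k + 1, size=n_new)
            gaps = rng.uniform(size=n_new)
            for t in range(n_new):
                i = base[t]
                j = idx[i, pick[t]]
                synth[t] = Xmin[i] + gaps[t] * (Xmin[j] - Xmin[i])
                provenance.append((i, j, gaps[t]))
        X_all = np.vstack([X, synth])
        y_all = np.concatenate([y, np.full(n_new, minority, dtype=int)])
        synthetic_flag = np.concatenate(
            [np.zeros(len(y), dtype=bool), np.ones(n_new, dtype=bool)]
        )

        # ENN cleaning: drop points whose k_enn neighbours do not all agree
        nn_all = NearestNeighbors(n_neighbors=self.k_enn + 1).fit(X_all)
        _, nbr = nn_all.kneighbors(X_all)
        nbr_labels = y_all[nbr[:, 1:]]
        keep = (nbr_labels == y_all[:, None]).all(axis=1)
        # never let ENN erase a class entirely
        for c in classes:
            if not keep[y_all == c].any():
                keep[y_all == c] = True
                warnings.warn(f"ENN would remove class {c} entirely; kept as-is")

        self.minority_class_ = int(minority)
        self.synthetic_mask_ = synthetic_flag[keep]
        self.synthetic_provenance_ = provenance
        self.kept_original_mask_ = keep[: len(y)]
        return X_all[keep], y_all[keep]


def resample_smoteenn(
    train: FeatureTable, target: BinaryTarget, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Resample the training partition; returns a plain (X, y) because the
    synthetic rows have no subject identity or missingness provenance."""
    sampler = SMOTEENN(seed=seed)
    Xr, yr = sampler.fit_resample(train.as_array(), target.as_array())
    Xdf = pd.DataFrame(Xr, columns=train.feature_names)
    return Xdf, pd.Series(yr, name=target.name)


# ---------------------------------------------------------------------------
# univariate odds ratios
# ---------------------------------------------------------------------------


def univariate_odds_ratio(
    feature: pd.Series | np.ndarray, target: BinaryTarget | np.ndarray
) -> dict:
    """Per-unit odds ratio from a single-predictor logistic fit with Wald 95% CI.

    Returns ``{"or": ..., "ci": (lo, hi), "diverged": bool}``; divergence is
    flagged on perfect separation or a non-converged fit.
    """
    x = np.asarray(feature, dtype=float)
    y = target.as_array() if isinstance(target, BinaryTarget) else np.asarray(target, int)
    Xd = sm.add_constant(x)
    diverged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params[1]) > 30:
            diverged = True
        beta = res.params[1]
        se = res.bse[1]
    except Exception:
        return {"or": float("inf"), "ci": (0.0, float("inf")), "diverged": True}
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return {"or": float(np.exp(beta)), "ci": (float(np.exp(lo)), float(np.exp(hi))), "diverged": diverged}


# ---------------------------------------------------------------------------
# the full preparation pipeline
# ---------------------------------------------------------------------------


class TabularPreparer(BaseEstimator, TransformerMixin):
    """Train-fitted preparation chain applied unchanged to the test partition.

    ``instrument_groups`` optionally maps a summary-column name to the list of
    item columns that are agglomerated into it (replacing the items).
    """

    def __init__(
        self,
        max_missing: float = 0.40,
        k_sd: float = 3.0,
        nnmf_rank: int = 10,
        nnmf_max_iter: int = 500,
        nnmf_tol: float = 1e-5,
        instrument_groups: dict[str, list[str]] | None = None,
        seed: int = 0,
    ):
        self.max_missing = max_missing
        self.k_sd = k_sd
        self.nnmf_rank = nnmf_rank
        self.nnmf_max_iter = nnmf_max_iter
        self.nnmf_tol = nnmf_tol
        self.instrument_groups = instrument_groups
        self.seed = seed

    def _agglomerate(self, table: FeatureTable) -> FeatureTable:
        if not self.instrument_groups:
            return table
        vals = table.values.copy()
        mask = table.mask.copy()
        meta = table.feature_meta.copy()
        for summary, items in self.instrument_groups.items():
            present = [c for c in items if c in vals.columns]
            if not present:
                continue
            score = agglomerate_items(vals[present])
            vals = vals.drop(columns=present)
            mask = mask.drop(columns=present)
            meta = meta.drop(index=present)
            vals[summary] = score
            mask[summary] = True
            meta.loc[summary] = {"domain": "summary", "dtype": "continuous"}
        return FeatureTable(vals, mask, meta)

    def fit(self, train: FeatureTable, y=None):
        self.filter_ = SparseFeatureFilter(self.max_missing).fit(train)
        t = self.filter_.transform(train)
        t = trim_outliers(t, self.k_sd)
        self.imputer_ = MaskedNNMFImputer(
            self.nnmf_rank, self.nnmf_max_iter, self.nnmf_tol, self.seed
        )
        t = self.imputer_.fit_transform(t)
        t = self._agglomerate(t)
        self.scaler_ = _TableMinMax().fit(t)
        t = self.scaler_.transform(t)
        self.transformer_ = NormalizingTransformSelector().fit(t)
        self.train_prepared_ = self.transformer_.transform(t)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        t = self.filter_.transform(table)
        t = trim_outliers(t, self.k_sd)  # same-partition statistics by contract
        t = self.imputer_.transform(t)
        t = self._agglomerate(t)
        t = self.scaler_.transform(t)
        return self.transformer_.transform(t)
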