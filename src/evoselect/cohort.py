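"""Synthetic multidomain cohort and timecourse generator.

Emulates the statistical structure of a transdiagnostic youth cohort: ~1120
subjects, 160 mixed-domain candidate predictors with non-normal marginals and
low-rank correlation, binary condition targets with case rates from ~12% to
~75%, planted informative feature subsets (linear, interaction and threshold
effects) and configurable MCAR/MAR missingness.  Also generates per-subject
component timecourses with planted connectivity states so the dynamic
connectivity stage is testable without any imaging download.

All randomness flows from a single master seed via named substreams.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .feature_table import BinaryTarget, FeatureTable

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SyntheticCohort",
    "StateSpec",
    "TimecourseSet",
    "generate_cohort",
    "generate_timecourses",
    "split_cohort",
]

_EFFECT_TYPES = {"linear", "interaction", "threshold"}
_MARGINALS = {"normal", "lognormal", "skewed-mixture"}


def _rng(seed: int, name: str) -> np.random.Generator:
    # SeedSequence with a stable per-name offset; hash() is salted per process,
    # so derive the offset from the name bytes instead.
    offset = int.from_bytes(name.encode()[:4].ljust(4, b"\0"), "little")
    return np.random.default_rng(np.random.SeedSequence([seed, offset]))


@dataclass
class CohortSpec:
    """Design of one synthetic cohort.

    ``informative_map`` maps target name -> list of (feature_index,
    effect_type, effect_size) with effect sizes in standardized units.
    ``noise_scale`` is the scale of the logistic noise in the label model;
    0 makes labels a deterministic threshold of the generating score.
    """

    n_subjects: int = 1120
    n_features: int = 160
    domain_blocks: list[tuple[str, int]] = field(default_factory=list)
    informative_map: dict[str, list[tuple[int, str, float]]] = field(default_factory=dict)
    case_rate: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"
    marginal_family: str = "normal"
    latent_rank: int = 5
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.domain_blocks:
            self.domain_blocks = [("domain", self.n_features)]
        if sum(s for _, s in self.domain_blocks) != self.n_features:
            raise ValueError("domain_blocks sizes must sum to n_features")
        if not 0 <= self.missing_rate <= 0.6:
            raise ValueError("missing_rate must be in [0, 0.6]")
        if self.missing_mechanism not in {"MCAR", "MAR"}:
            raise ValueError("missing_mechanism must be MCAR or MAR")
        if self.marginal_family not in _MARGINALS:
            raise ValueError(f"marginal_family must be one of {_MARGINALS}")
        if not 1 <= self.latent_rank < min(self.n_subjects, self.n_features):
            raise ValueError("latent_rank must be < min(n_subjects, n_features)")
        for target, effects in self.informative_map.items():
            idx = [i for i, _, _ in effects]
            if len(set(idx)) != len(idx):
                raise ValueError(f"informative indices for {target} must be unique")
            if any(i < 0 or i >= self.n_features for i in idx):
                raise ValueError("informative feature index out of range")
            for _, kind, _ in effects:
                if kind not in _EFFECT_TYPES:
                    raise ValueError(f"unknown effect type {kind!r}")
        for target, rate in self.case_rate.items():
            if not 0 < rate < 1:
                raise ValueError(f"case_rate for {target} must be in (0,1)")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream scoring.

    ``bayes_probs`` are the class-1 probabilities of the generating model
    (the Bayes-optimal classifier's scores); ``bayes_auc`` is their empirical
    AUC against the sampled labels.
    """

    informative: dict[str, list[int]]
    scores: dict[str, pd.Series]
    bayes_probs: dict[str, pd.Series]
    bayes_auc: dict[str, float]

    def to_json(self, path) -> None:
        payload = {
            "informative": self.informative,
            "bayes_auc": self.bayes_auc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SyntheticCohort:
    """Bundle returned by :func:`generate_cohort`."""

    complete: FeatureTable
    masked: FeatureTable
    targets: dict[str, BinaryTarget]
    ground_truth: GroundTruth


def _empirical_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance (ties get half credit)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = pos.sum(), (~pos).sum()
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _latent_gaussian(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-rank-plus-noise correlated standard normals (Gaussian copula base)."""
    n, p, r = spec.n_subjects, spec.n_features, spec.latent_rank
    loadings = rng.normal(size=(p, r)) * 0.4
    factors = rng.normal(size=(n, r))
    noise = rng.normal(size=(n, p))
    raw = factors @ loadings.T + noise
    raw -= raw.mean(axis=0)
    raw /= raw.std(axis=0)
    return raw


def _apply_marginals(z: np.ndarray, family: str, rng: np.random.Generator) -> np.ndarray:
    """Per-feature marginal transform of copula normals (non-normal marginals)."""
    if family == "normal":
        return z.copy()
    out = np.empty_like(z)
    p = z.shape[1]
    if family == "lognormal":
        sigmas = rng.uniform(0.4, 1.0, size=p)
        for j in range(p):
            out[:, j] = np.exp(sigmas[j] * z[:, j])
        return out
    # skewed-mixture: mix exponentiated and shifted components per feature
    kinds = rng.integers(0, 3, size=p)
    for j in range(p):
        if kinds[j] == 0:
            out[:, j] = np.exp(0.7 * z[:, j])
        elif kinds[j] == 1:
            out[:, j] = z[:, j] ** 2 + 0.5 * z[:, j]
        else:
            out[:, j] = z[:, j]
    return out


def _effect_score(
    values: np.ndarray, effects: list[tuple[int, str, float]]
) -> np.ndarray:
    """Generating score from planted effects on standardized observed features.

    linear      beta * z_i
    threshold   beta * 1[x_i > 70th percentile]
    interaction beta * z_i * z_{i+1}
    """
    n, p = values.shape
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    score = np.zeros(n)
    for idx, kind, beta in effects:
        if kind == "linear":
            score += beta * z[:, idx]
        elif kind == "threshold":
            thr = np.quantile(values[:, idx], 0.70)
            score += beta * (values[:, idx] > thr)
        elif kind == "interaction":
            partner = (idx + 1) % p
            score += beta * z[:, idx] * z[:, partner]
    return score


def _calibrate_labels(
    score: np.ndarray, rate: float, noise_scale: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Choose the intercept so the expected case rate matches, then sample."""
    if noise_scale == 0:
        b = -np.quantile(score, 1 - rate)
        labels = (score + b > 0).astype(int)
        return labels, labels.astype(float)

    def gap(b: float) -> float:
        return expit((score + b) / noise_scale).mean() - rate

    lo, hi = -1e4, 1e4
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - guarded by spec validation
        raise ValueError(f"requested case_rate {rate} unreachable for planted effects")
    b = brentq(gap, lo, hi, xtol=1e-10)
    probs = expit((score + b) / noise_scale)
    labels = (rng.uniform(size=score.shape[0]) < probs).astype(int)
    return labels, probs


def _missingness_mask(
    values: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean observed-mask. MAR: P(missing) logistic in one fully observed
    anchor feature per domain block, intercept calibrated to the target rate."""
    n, p = values.shape
    rate = spec.missing_rate
    if rate == 0:
        return np.ones((n, p), dtype=bool)
    if spec.missing_mechanism == "MCAR":
        return rng.uniform(size=(n, p)) >= rate

    observed = np.ones((n, p), dtype=bool)
    start = 0
    for _, size in spec.domain_blocks:
        block = range(start, start + size)
        anchor = start  # first feature of each block stays fully observed
        a = values[:, anchor]
        a = (a - a.mean()) / (a.std() or 1.0)

        def gap(b: float) -> float:
            return expit(1.5 * a + b).mean() - rate

        b = brentq(gap, -50, 50)
        pmiss = expit(1.5 * a + b)
        for j in block:
            if j == anchor:
                continue
            observed[:, j] = rng.uniform(size=n) >= pmiss
        start += size
    return observed


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a complete table, a masked copy, binary targets and truth.

    The complete table is the data before missingness; the masked copy has
    unobserved cells set to NaN with ``mask=False``.  Labels are sampled from
    a logistic model on the planted effects, with the intercept calibrated so
    the empirical case rate matches the spec within binomial sampling error.
    """
    rng_x = _rng(spec.seed, "features")
    rng_y = _rng(spec.seed, "labels")
    rng_m = _rng(spec.seed, "missing")

    z = _latent_gaussian(spec, rng_x)
    values = _apply_marginals(z, spec.marginal_family, rng_x)

    subjects = pd.Index([f"S{i:05d}" for i in range(spec.n_subjects)], name="subject_id")
    names, metas = [], []
    for block, size in spec.domain_blocks:
        for j in range(size):
            names.append(f"{block}_{j:03d}")
            metas.append(block)
    columns = pd.Index(names)
    meta = pd.DataFrame({"domain": metas, "dtype": "continuous"}, index=columns)

    vdf = pd.DataFrame(values, index=subjects, columns=columns)
    complete = FeatureTable(vdf, pd.DataFrame(True, index=subjects, columns=columns), meta)

    targets: dict[str, BinaryTarget] = {}
    informative: dict[str, list[int]] = {}
    scores: dict[str, pd.Series] = {}
    probs_map: dict[str, pd.Series] = {}
    aucs: dict[str, float] = {}
    for name, effects in spec.informative_map.items():
        rate = spec.case_rate.get(name, 0.5)
        score = _effect_score(values, effects)
        labels, probs = _calibrate_labels(score, rate, spec.noise_scale, rng_y)
        targets[name] = BinaryTarget(pd.Series(labels, index=subjects), name=name)
        informative[name] = sorted(i for i, _, _ in effects)
        scores[name] = pd.Series(score, index=subjects)
        probs_map[name] = pd.Series(probs, index=subjects)
        if labels.min() == labels.max():
            aucs[name] = float("nan")
        elif spec.noise_scale == 0:
            aucs[name] = 1.0
        else:
            aucs[name] = _empirical_auc(probs, labels)
    # no planted targets at all -> still emit one pure-noise target if asked
    for name, rate in spec.case_rate.items():
        if name in targets:
            continue
        score = np.zeros(spec.n_subjects)
        labels, probs = _calibrate_labels(score, rate, max(spec.noise_scale, 1.0), rng_y)
        targets[name] = BinaryTarget(pd.Series(labels, index=subjects), name=name)
        informative[name] = []
        scores[name] = pd.Series(score, index=subjects)
        probs_map[name] = pd.Series(probs, index=subjects)
        aucs[name] = 0.5

    observed = _missingness_mask(values, spec, rng_m)
    masked_vals = vdf.where(pd.DataFrame(observed, index=subjects, columns=columns))
    masked = FeatureTable(
        masked_vals, pd.DataFrame(observed, index=subjects, columns=columns), meta
    )

    truth = GroundTruth(informative, scores, probs_map, aucs)
    return SyntheticCohort(complete, masked, targets, truth)


# ---------------------------------------------------------------------------
# timecourses with planted connectivity states
# ---------------------------------------------------------------------------


@dataclass
class StateSpec:
    """Planted brain-state layout for timecourse generation.

    ``centroids`` are correlation matrices (symmetric, unit diagonal, PSD);
    ``labels`` is the true state index per window; each window spans
    ``window_len`` timepoints (non-overlapping by construction).
    """

    centroids: list[np.ndarray]
    labels: list[int]
    window_len: int = 50
    sampling_interval: float = 0.8

    def __post_init__(self) -> None:
        for i, c in enumerate(self.centroids):
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ValueError(f"centroid {i} is not square")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"centroid {i} is not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise ValueError(f"centroid {i} does not have a unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValueError(f"centroid {i} is not positive semidefinite")
            self.centroids[i] = c
        k = len(self.centroids)
        if any(l < 0 or l >= k for l in self.labels):
            raise ValueError("state label out of range")
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2 timepoints")

    @property
    def true_switches(self) -> int:
        lab = np.asarray(self.labels)
        return int((lab[1:] != lab[:-1]).sum())


@dataclass
class TimecourseSet:
    """Per-subject component activity matrices (components x timepoints)."""

    data: list[np.ndarray]
    sampling_interval: float
    planted: StateSpec | None = None

    def __post_init__(self) -> None:
        comps = {d.shape[0] for d in self.data}
        if len(comps) > 1:
            raise ValueError("all subjects must share the component count")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_components(self) -> int:
        return self.data[0].shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data[0].shape[1]


def generate_timecourses(
    n_subjects: int, n_components: int, state_spec: StateSpec, seed: int = 0
) -> TimecourseSet:
    """Sample component timecourses whose windowed correlations follow the
    planted state sequence (window w's data ~ N(0, centroid[label_w]))."""
    for c in state_spec.centroids:
        if c.shape[0] != n_components:
            raise ValueError("centroid size must equal n_components")
    rng = _rng(seed, "timecourse")
    chols = [np.linalg.cholesky(c + 1e-10 * np.eye(n_components)) for c in state_spec.centroids]
    w = state_spec.window_len
    data = []
    for _ in range(n_subjects):
        segs = []
        for lab in state_spec.labels:
            white = rng.normal(size=(n_components, w))
            segs.append(chols[lab] @ white)
        data.append(np.concatenate(segs, axis=1))
    return TimecourseSet(data, state_spec.sampling_interval, state_spec)


def split_cohort(
    table: FeatureTable,
    targets: dict[str, BinaryTarget],
    train_fraction: float,
    seed: int = 0,
):
    """Random (unstratified) row split into disjoint, exhaustive partitions.

    Returns ``((train_table, train_targets), (test_table, test_targets))``.
    1120 rows at fraction 0.7 give the canonical 784/336 partition.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0,1)")
    n = table.shape[0]
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty partition")
    rng = _rng(seed, "split")
    perm = rng.permutation(n)
    ids = table.subject_ids
    train_ids, test_ids = ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]
    tr = table.select_subjects(train_ids)
    te = table.select_subjects(test_ids)
    tr_t = {k: v.select_subjects(train_ids) for k, v in targets.items()}
    te_t = {k: v.select_subjects(test_ids) for k, v in targets.items()}
    return (tr, tr_t), (te, te_t)
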