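"""Static and dynamic functional-connectivity metrics from component timecourses.

Static connectivity is the Fisher z-transform (z = atanh(k)) of the Pearson
correlation over every unordered component pair.  Dynamic metrics come from an
established sliding-window scheme: windowed correlation matrices are pooled
across subjects, clustered with k-means into recurring connectivity states,
and each subject's trajectory through states is summarized by four fluidity
metrics — states traversed, switch count, maximal L1 span among visited state
centroids, and total L1 distance traveled over switches.  Nuisance signals
(site, motion, realignment parameters) are removed by ordinary least squares
residualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .cohort import TimecourseSet

__all__ = [
    "WindowSpec",
    "DynamicConnectivityMetrics",
    "static_connectivity",
    "sliding_windows",
    "cluster_states",
    "dynamic_metrics",
    "select_k_elbow",
    "residualize",
]

#: cap applied to |r| before atanh so degenerate correlations stay finite
_R_CAP = 0.999999


@dataclass
class WindowSpec:
    """Sliding-window layout. ``length_s`` in seconds (40-60 s is the robust
    range); ``step`` in timepoints; rectangular (no taper)."""

    length_s: float = 45.0
    step: int = 1

    def to_timepoints(self, sampling_interval: float) -> int:
        w = int(round(self.length_s / sampling_interval))
        if w < 2:
            raise ValueError("window shorter than 2 timepoints at this sampling interval")
        return w


@dataclass
class DynamicConnectivityMetrics:
    """Per-subject brain-state fluidity summary."""

    n_states_traversed: int
    n_switches: int
    max_l1_span: float
    total_l1_distance: float


def _upper(mat: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle vectorization (i<j)."""
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def static_connectivity(tc: TimecourseSet) -> np.ndarray:
    """Fisher-z connectivity vector per subject, shape (n_subjects, C(C-1)/2).

    Correlations with |k| = 1 (e.g. duplicated components) are capped at
    atanh(0.999999) with a warning; constant components are an error.
    """
    out = []
    for s, data in enumerate(tc.data):
        if data.shape[1] < 3:
            raise ValueError("need at least 3 timepoints")
        sds = data.std(axis=1)
        if (sds == 0).any():
            bad = int(np.flatnonzero(sds == 0)[0])
            raise ValueError(f"component {bad} of subject {s} is constant")
        r = np.corrcoef(data)
        v = _upper(r)
        if (np.abs(v) >= 1 - 1e-12).any():
            warnings.warn(
                f"subject {s}: perfect correlation capped at atanh({_R_CAP})"
            )
        out.append(np.arctanh(np.clip(v, -_R_CAP, _R_CAP)))
    return np.asarray(out)


def sliding_windows(
    data: np.ndarray, window_len: int, step: int = 1
) -> np.ndarray:
    """Per-window correlation matrices for one subject (components x time).

    Returns shape (n_windows, C, C) with n_windows = (T - w)//step + 1; each
    matrix is symmetric with a unit diagonal.
    """
    C, T = data.shape
    if window_len > T:
        raise ValueError(f"window ({window_len}) longer than series ({T})")
    if window_len < 2:
        raise ValueError("window must span at least 2 timepoints")
    starts = range(0, T - window_len + 1, step)
    mats = np.empty((len(list(starts)), C, C))
    for w, start in enumerate(range(0, T - window_len + 1, step)):
        seg = data[:, start : start + window_len]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = np.corrcoef(seg)
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 1.0)
        mats[w] = r
    return mats


def windows_for_set(tc: TimecourseSet, spec: WindowSpec | None = None) -> list[np.ndarray]:
    """Sliding windows for every subject using a shared :class:`WindowSpec`.

    If the timecourses carry a planted state layout, the planted window length
    and a step equal to it are used so recovered windows align with the truth.
    """
    if tc.planted is not None and spec is None:
        w, step = tc.planted.window_len, tc.planted.window_len
    else:
        spec = spec or WindowSpec()
        w, step = spec.to_timepoints(tc.sampling_interval), spec.step
    return [sliding_windows(d, w, step) for d in tc.data]


def cluster_states(
    windows: list[np.ndarray], k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pool windowed correlations across subjects and k-means them into states.

    Windows are vectorized by the upper triangle.  Returns (centroids, labels)
    with centroids of shape (k, C(C-1)/2) and one 0-based label sequence per
    subject.  The returned solution has the lowest inertia over ``n_init``
    seeded restarts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vecs = [np.array([_upper(m) for m in w]) for w in windows]
    X = np.vstack(vecs)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of windows ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    flat = km.fit_predict(X)
    labels, pos = [], 0
    for v in vecs:
        labels.append(flat[pos : pos + len(v)])
        pos += len(v)
    return km.cluster_centers_, labels


def select_k_elbow(
    windows: list[np.ndarray], ks: range = range(2, 9), seed: int = 0
) -> int:
    """Elbow of the k-means inertia curve (max distance to the chord)."""
    vecs = np.vstack([np.array([_upper(m) for m in w]) for w in windows])
    inert = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(vecs)
        inert.append(km.inertia_)
    xs = np.array(list(ks), dtype=float)
    ys = np.asarray(inert)
    xs_n = (xs - xs.min()) / (xs.max() - xs.min())
    ys_n = (ys - ys.min()) / (ys.max() - ys.min() or 1.0)
    p0, p1 = np.array([xs_n[0], ys_n[0]]), np.array([xs_n[-1], ys_n[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    pts = np.column_stack([xs_n, ys_n]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0])
    return int(xs[int(np.argmax(dist))])


def dynamic_metrics(labels: np.ndarray, centroids: np.ndarray) -> DynamicConnectivityMetrics:
    """Fluidity summary of one subject's state-label sequence.

    states traversed = distinct labels; switches = consecutive unequal labels;
    total L1 distance = sum over switches of the L1 distance between the two
    centroids; max L1 span = largest pairwise L1 distance among *visited*
    centroids.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    centroids = np.asarray(centroids, dtype=float)
    visited = np.unique(labels)
    n_states = len(visited)
    changes = labels[1:] != labels[:-1]
    n_switches = int(changes.sum())
    total = 0.0
    for a, b in zip(labels[:-1][changes], labels[1:][changes]):
        total += float(np.abs(centroids[a] - centroids[b]).sum())
    span = 0.0
    for i in range(n_states):
        for j in range(i + 1, n_states):
            d = float(np.abs(centroids[visited[i]] - centroids[visited[j]]).sum())
            span = max(span, d)
    return DynamicConnectivityMetrics(n_states, n_switches, span, total)


def residualize(features: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of each feature column on the covariates (plus intercept).

    Residuals are orthogonal to every covariate column.  Rank-deficient
    designs raise an error naming the collinear columns.
    """
    F = np.asarray(features, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    design = np.column_stack([np.ones(len(C)), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        kept = [0]
        for j in range(1, design.shape[1]):
            trial = design[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept):
                bad.append(j - 1)  # covariate index (intercept excluded)
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, F, rcond=None)
    return F - design @ beta
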