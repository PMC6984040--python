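"""The four pairwise interactivity features and the cyclicity spectrum.

Given a conditioned ROI-by-time matrix this module computes

* the skew-symmetric **lead matrix** of pairwise signed algebraic areas
  ``A_kl = 1/2 * closed-loop integral of (x_l dx_k - x_k dx_l)``, whose
  spectral phases encode the collective temporal ordering of the signals;
* the symmetric zero-lag Pearson **correlation matrix**;
* the **lagged correlation matrix** (extremal cross-correlation per pair)
  with its antisymmetric **time delay matrix** in seconds;
* the symmetric non-negative **DTW distance matrix**.

Sign conventions (frozen by regression tests): ``A[k, l] > 0`` and
``tdm[k, l] > 0`` both mean ROI ``l`` follows ROI ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _dtw
from .preprocess import end_match

FEATURE_KINDS = ("lead", "corr", "lagged_corr", "time_delay", "dtw")

_METRICS = {"abs": 0, "sq": 1}


def _check_square(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {values.shape}")
    return values


@dataclass
class LeadMatrix:
    """Skew-symmetric matrix of pairwise signed areas."""

    values: np.ndarray
    roi_names: list[str] = field(default_factory=list)
    kind: str = "lead"

    def __post_init__(self) -> None:
        self.values = _check_square(self.values)
        dev = np.abs(self.values + self.values.T).max()
        scale = max(np.abs(self.values).max(), 1.0)
        if dev > 1e-10 * scale:
            raise ValueError(f"lead matrix not skew-symmetric: max |A + A^T| = {dev}")


@dataclass
class CorrMatrix:
    """Symmetric zero-lag correlation matrix with unit diagonal."""

    values: np.ndarray
    roi_names: list[str] = field(default_factory=list)
    kind: str = "corr"

    def __post_init__(self) -> None:
        self.values = _check_square(self.values)
        dev = np.abs(self.values - self.values.T).max()
        if dev > 1e-10:
            raise ValueError(f"correlation matrix not symmetric: {dev}")
        if np.abs(np.diag(self.values) - 1.0).max() > 1e-10:
            raise ValueError("correlation diagonal must be 1")
        if np.abs(self.values).max() > 1.0 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class LaggedCorrResult:
    """Extremal lagged correlations (lcm) and their delays in seconds (tdm)."""

    lcm: np.ndarray
    tdm: np.ndarray
    max_lag_s: float
    roi_names: list[str] = field(default_factory=list)
    kind: str = "lagged_corr"

    def __post_init__(self) -> None:
        self.lcm = _check_square(self.lcm)
        self.tdm = _check_square(self.tdm)
        if np.abs(self.lcm - self.lcm.T).max() > 1e-10:
            raise ValueError("lagged correlation matrix not symmetric")
        if np.abs(self.tdm + self.tdm.T).max() > 1e-10:
            raise ValueError("time delay matrix not antisymmetric")
        if np.abs(self.tdm).max() > self.max_lag_s + 1e-9:
            raise ValueError("time delays exceed max_lag")


@dataclass
class DtwMatrix:
    """Symmetric non-negative all-pairs DTW distance matrix."""

    values: np.ndarray
    roi_names: list[str] = field(default_factory=list)
    kind: str = "dtw"

    def __post_init__(self) -> None:
        self.values = _check_square(self.values)
        if self.values.min() < 0:
            raise ValueError("DTW distances must be non-negative")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("DTW matrix not symmetric")
        if np.abs(np.diag(self.values)).max() > 1e-10:
            raise ValueError("DTW diagonal must be 0")


@dataclass
class CyclicitySpectrum:
    """Eigen-structure of a lead matrix.

    ``eigenvalues`` are sorted by descending magnitude (purely imaginary, in
    conjugate pairs); ``phases`` are the arguments of the leading
    eigenvector's components after rotating component 0 to phase 0.
    """

    eigenvalues: np.ndarray
    leading_eigenvector: np.ndarray
    phases: np.ndarray
    degenerate: bool = False
    near_tie: bool = False


def lead_matrix(
    series: np.ndarray, end_matched: bool = False, roi_names=None
) -> LeadMatrix:
    """Pairwise signed areas over the closed discrete curve of each row pair.

    The shoelace rule over consecutive samples (including the closing
    segment) is exact for polygonal paths:
    ``A[k, l] = 1/2 sum_t (x_k[t] x_l[t+1] - x_k[t+1] x_l[t])``.
    Requires first == last per row (end-matched); pass ``end_matched=True``
    to enforce it internally.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("series must be 2-D with at least 3 time points")
    if end_matched:
        X = end_match(X)
    else:
        gap = np.abs(X[:, 0] - X[:, -1]).max()
        scale = max(np.abs(X).max(), 1.0)
        if gap > 1e-9 * scale:
            raise ValueError(
                "series is not end-matched (first != last sample); "
                "end-match it or pass end_matched=True"
            )
    Xn = np.roll(X, -1, axis=1)
    A = 0.5 * (X @ Xn.T - Xn @ X.T)
    A = 0.5 * (A - A.T)  # kill round-off asymmetry
    np.fill_diagonal(A, 0.0)
    return LeadMatrix(A, list(roi_names or []))


def cyclicity_spectrum(lm: LeadMatrix, tie_rtol: float = 1e-3) -> CyclicitySpectrum:
    """Eigen-decomposition of a skew-symmetric lead matrix.

    The leading eigenvector is the one paired with the eigenvalue of largest
    magnitude and positive imaginary part (the conjugate choice fixes the
    direction of traversal); phases are reported with component 0 rotated
    to zero. A near-tie in magnitude beyond the conjugate pair is flagged
    and resolved deterministically by index.
    """
    A = lm.values
    w, V = np.linalg.eig(A)
    order = np.argsort(-np.abs(w), kind="stable")
    w, V = w[order], V[:, order]
    top = np.abs(w[0])
    if top == 0.0:
        n = A.shape[0]
        return CyclicitySpectrum(w, np.zeros(n, complex), np.zeros(n), degenerate=True)
    near_tie = len(w) > 2 and np.abs(w[2]) > (1.0 - tie_rtol) * top
    pick = 0 if w[0].imag > 0 else 1
    v = V[:, pick]
    ref = v[0]
    if np.abs(ref) < 1e-12 * np.abs(v).max():
        ref = v[np.argmax(np.abs(v))]  # component 0 vanishes: anchor elsewhere
    v = v * (np.conj(ref) / np.abs(ref))
    phases = np.mod(np.angle(v), 2.0 * np.pi)
    phases[np.abs(v) < 1e-12 * np.abs(v).max()] = 0.0
    return CyclicitySpectrum(w, v, phases, degenerate=False, near_tie=near_tie)


def recover_ordering(spec: CyclicitySpectrum) -> np.ndarray:
    """Cyclic temporal ordering: ROI indices sorted by eigenvector phase.

    Rotation-equivalent orders are considered equal (compare with
    :func:`cyclic_order_equal`). Ties leave tied ROIs adjacent.
    """
    if spec.degenerate:
        raise ValueError("degenerate spectrum: ordering undefined")
    return np.argsort(spec.phases, kind="stable")


def cyclic_order_equal(a, b) -> bool:
    """True if two index sequences are equal up to rotation."""
    a, b = list(a), list(b)
    if len(a) != len(b):
        return False
    if not a:
        return True
    doubled = a + a
    return any(doubled[i : i + len(b)] == b for i in range(len(a)))


def pairwise_order_agreement(phases: np.ndarray, offsets: np.ndarray) -> float:
    """Fraction of ROI pairs whose circular order matches the planted one."""
    ph_d = phases[:, None] - phases[None, :]
    of_d = offsets[:, None] - offsets[None, :]
    iu = np.triu_indices(len(phases), k=1)
    return float(np.mean(np.sign(np.sin(ph_d[iu])) == np.sign(np.sin(of_d[iu]))))


def correlation_matrix(series: np.ndarray, roi_names=None) -> CorrMatrix:
    """Zero-lag Pearson correlation of all row pairs."""
    X = np.asarray(series, dtype=float)
    flat = np.flatnonzero(np.std(X, axis=1) == 0)
    if flat.size:
        names = [roi_names[i] for i in flat] if roi_names else flat.tolist()
        raise ValueError(f"constant rows {names}: correlation undefined")
    R = np.corrcoef(X)
    R = np.clip(0.5 * (R + R.T), -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrMatrix(R, list(roi_names or []))


def _corr_at_lag(X: np.ndarray, tau: int) -> np.ndarray:
    """R[k, l] = Pearson corr of x_k(t + tau) with x_l(t) on the overlap."""
    n = X.shape[1]
    if tau >= 0:
        A, B = X[:, tau:], X[:, : n - tau]
    else:
        A, B = X[:, : n + tau], X[:, -tau:]
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(A, axis=1)
    sb = np.linalg.norm(B, axis=1)
    denom = np.outer(sa, sb)
    denom[denom == 0] = np.inf
    return (A @ B.T) / denom


def lagged_correlation(
    series: np.ndarray,
    max_lag: int = 5,
    tr: float = 2.0,
    interpolate: str = "none",
    roi_names=None,
) -> LaggedCorrResult:
    """Extremal cross-correlation and its lag for every ROI pair.

    For each pair the cross-correlation is evaluated at integer lags
    ``tau in [-max_lag, max_lag]`` on the overlapping segment; the extremum
    is the lag maximizing ``|r|`` (ties broken toward smaller ``|tau|``).
    The signed correlation goes into ``lcm``; the delay of ``l`` behind
    ``k`` in seconds, ``tdm[k, l] = -tau* . tr``, is antisymmetric.
    ``interpolate='parabolic'`` refines the delay with a 3-point parabola
    around the discrete peak.
    """
    X = np.asarray(series, dtype=float)
    n_roi, n_time = X.shape
    if not 0 < max_lag < n_time / 4:
        raise ValueError(f"max_lag must lie in (0, n_time/4) = (0, {n_time / 4})")
    if interpolate not in ("none", "parabolic"):
        raise ValueError("interpolate must be 'none' or 'parabolic'")
    lags = sorted(range(-max_lag, max_lag + 1), key=lambda t: (abs(t), t))
    stack = np.stack([_corr_at_lag(X, tau) for tau in lags])  # (n_lags, N, N)
    best = np.argmax(np.abs(stack), axis=0)  # first max -> smallest |tau|
    kk, ll = np.meshgrid(np.arange(n_roi), np.arange(n_roi), indexing="ij")
    r_best = stack[best, kk, ll]
    tau_best = np.asarray(lags, dtype=float)[best]
    if interpolate == "parabolic":
        by_tau = {tau: i for i, tau in enumerate(lags)}
        absstack = np.abs(stack)
        for k in range(n_roi):
            for l in range(n_roi):
                t0 = int(tau_best[k, l])
                if abs(t0) >= max_lag:
                    continue
                ym = absstack[by_tau[t0 - 1], k, l]
                y0 = absstack[by_tau[t0], k, l]
                yp = absstack[by_tau[t0 + 1], k, l]
                denom = ym - 2 * y0 + yp
                if denom < 0:  # genuine interior peak
                    tau_best[k, l] = t0 + 0.5 * (ym - yp) / denom
    # Derive the lower triangle from the upper one: the extremum search is
    # direction-symmetric (corr(x_k(t+tau), x_l(t)) == corr(x_l(t-tau), x_k(t)))
    # so this enforces exact symmetry/antisymmetry without changing values.
    iu = np.triu_indices(n_roi, k=1)
    lcm = np.zeros((n_roi, n_roi))
    tdm = np.zeros((n_roi, n_roi))
    lcm[iu] = r_best[iu]
    tdm[iu] = -tau_best[iu] * tr
    lcm = lcm + lcm.T
    np.fill_diagonal(lcm, 1.0)
    tdm = tdm - tdm.T
    lcm = np.clip(lcm, -1.0, 1.0)
    return LaggedCorrResult(lcm, tdm, max_lag * tr, list(roi_names or []))


def dtw_distance(
    x: np.ndarray,
    y: np.ndarray,
    local_metric: str = "abs",
    window: int | None = None,
) -> tuple[float, list[tuple[int, int]]]:
    """DTW distance and warping path between two scalar series.

    Dynamic program over the accumulated-cost matrix with the usual
    monotonicity/continuity constraints; ``window`` (samples) optionally
    restricts alignment to a Sakoe-Chiba band.
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    if local_metric not in _METRICS:
        raise ValueError(f"local_metric must be one of {tuple(_METRICS)}")
    w = -1 if window is None else int(window)
    if w >= 0 and w < abs(len(x) - len(y)):
        raise ValueError("window too narrow for the length difference")
    C = _dtw.accumulated_cost(x, y, _METRICS[local_metric], w)
    return float(C[-1, -1]), _dtw.backtrack(C)


def dtw_matrix(
    series: np.ndarray,
    local_metric: str = "abs",
    window: int | None = None,
    roi_names=None,
) -> DtwMatrix:
    """All-pairs DTW distances (each unordered pair computed once)."""
    X = np.ascontiguousarray(series, dtype=float)
    if local_metric not in _METRICS:
        raise ValueError(f"local_metric must be one of {tuple(_METRICS)}")
    w = -1 if window is None else int(window)
    D = _dtw.all_pairs(X, _METRICS[local_metric], w)
    return DtwMatrix(D, list(roi_names or []))


def vectorize_upper(matrix) -> np.ndarray:
    """Row-major upper triangle (diagonal excluded): N(N-1)/2 entries."""
    values = matrix.values if hasattr(matrix, "values") else matrix
    values = _check_square(np.asarray(values, dtype=float))
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def matricize(vector: np.ndarray, kind: str, diag: float | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` for a symmetry class.

    ``kind='skew'`` restores ``A`` with ``A_lk = -A_kl`` and zero diagonal;
    symmetric kinds mirror the upper triangle, with diagonal 1 for
    correlations and 0 otherwise unless ``diag`` overrides it.
    """
    vector = np.asarray(vector, dtype=float).ravel()
    m = vector.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number")
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vector
    if kind in ("lead", "skew", "time_delay"):
        out = out - out.T
    elif kind in ("corr", "lagged_corr", "dtw", "symmetric"):
        out = out + out.T
        np.fill_diagonal(out, 1.0 if kind in ("corr", "lagged_corr") else 0.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if diag is not None:
        np.fill_diagonal(out, diag)
    return out


def extract_feature(
    series: np.ndarray,
    kind: str,
    tr: float = 2.0,
    max_lag: int = 5,
    interpolate: str = "none",
    local_metric: str = "abs",
    window: int | None = None,
    roi_names=None,
):
    """Compute one feature matrix object from a conditioned series."""
    if kind == "lead":
        return lead_matrix(series, end_matched=True, roi_names=roi_names)
    if kind == "corr":
        return correlation_matrix(series, roi_names=roi_names)
    if kind in ("lagged_corr", "time_delay"):
        return lagged_correlation(
            series, max_lag=max_lag, tr=tr, interpolate=interpolate,
            roi_names=roi_names,
        )
    if kind == "dtw":
        return dtw_matrix(series, local_metric=local_metric, window=window,
                          roi_names=roi_names)
    raise ValueError(f"unknown feature kind {kind!r}; expected {FEATURE_KINDS}")


def feature_vector(feature, kind: str) -> np.ndarray:
    """Upper-triangle vector of the matrix a feature kind designates."""
    if kind == "time_delay":
        return vectorize_upper(feature.tdm)
    if kind == "lagged_corr" and isinstance(feature, LaggedCorrResult):
        return vectorize_upper(feature.lcm)
    return vectorize_upper(feature)


class FeatureExtractor:
    """sklearn-style transformer: stack of ROI-by-time matrices -> vectors.

    ``transform`` maps an array of shape ``(n_records, n_rois, n_time)`` (or
    a list of 2-D matrices) to ``(n_records, n_rois*(n_rois-1)/2)`` feature
    vectors of the requested kind.
    """

    def __init__(
        self,
        kind: str = "lead",
        tr: float = 2.0,
        max_lag: int = 5,
        interpolate: str = "none",
        local_metric: str = "abs",
        window: int | None = None,
    ):
        self.kind = kind
        self.tr = tr
        self.max_lag = max_lag
        self.interpolate = interpolate
        self.local_metric = local_metric
        self.window = window

    def get_params(self, deep: bool = True) -> dict:
        return {
            "kind": self.kind,
            "tr": self.tr,
            "max_lag": self.max_lag,
            "interpolate": self.interpolate,
            "local_metric": self.local_metric,
            "window": self.window,
        }

    def set_params(self, **params) -> "FeatureExtractor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "FeatureExtractor":
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for series in X:
            feat = extract_feature(
                series,
                self.kind,
                tr=self.tr,
                max_lag=self.max_lag,
                interpolate=self.interpolate,
                local_metric=self.local_metric,
                window=self.window,
            )
            rows.append(feature_vector(feat, self.kind))
        return np.asarray(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
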