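"""Time-series conditioning: centering, detrending, scaling, end-matching,
Bessel band-pass filtering and global signal regression.

Every step is a pure function of an ROI-by-time matrix. The pipeline order is
fixed: GSR (optional) -> mean-center/detrend -> end-match (cyclicity path
only) -> scale -> band-pass (optional); :class:`TimeSeriesCleaner` exposes it
as a sklearn-style stateless transformer and :func:`run_pipeline` applies it
to a whole panel with provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .panel import TimeSeriesPanel

SCALINGS = ("quadratic_variation", "norm", "std")
_SCALING_ALIASES = {"qv": "quadratic_variation", "norm": "norm", "std": "std"}


@dataclass
class PreprocessConfig:
    """Conditioning choices.

    ``filter_band`` is ``None`` or ``(low_hz, high_hz)``; the study baseline
    is (0.008, 0.08) with (0.008, 0.2) as the wide alternative. ``scaling``
    is one of ``quadratic_variation`` (sum of squared successive differences
    scaled to 1), ``norm`` (unit l2 norm) or ``std`` (unit sample SD).
    ``zero_phase`` selects forward-backward filtering, which preserves the
    relative timing that lag-sensitive features depend on.
    """

    do_gsr: bool = False
    filter_band: tuple[float, float] | None = (0.008, 0.08)
    filter_order: int = 4
    scaling: str = "quadratic_variation"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        self.scaling = _SCALING_ALIASES.get(self.scaling, self.scaling)
        if self.scaling not in SCALINGS:
            raise ValueError(f"scaling must be one of {SCALINGS}, got {self.scaling!r}")
        if self.filter_band is not None:
            low, high = self.filter_band
            if not 0 < low < high:
                raise ValueError("filter_band must satisfy 0 < low < high")

    def describe(self) -> str:
        band = "none" if self.filter_band is None else f"{self.filter_band}"
        return (
            f"gsr={self.do_gsr}, band={band}, order={self.filter_order}, "
            f"scaling={self.scaling}, zero_phase={self.zero_phase}"
        )


def mean_center_detrend(series: np.ndarray) -> np.ndarray:
    """Remove each row's best-fit line (mean and linear trend)."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise ValueError("need at least 3 time points to detrend")
    constant = np.ptp(series, axis=-1) == 0
    out = np.where(constant[..., None], 0.0, series)
    if np.any(constant):
        warnings.warn("constant row(s) returned as zeros", stacklevel=2)
        non_const = ~constant
        if np.any(non_const):
            out[non_const] = _signal.detrend(series[non_const], type="linear")
        return out
    return _signal.detrend(series, type="linear")


def quadratic_variation(series: np.ndarray) -> np.ndarray:
    """Discrete QV per row: sum of squared successive differences."""
    return np.sum(np.diff(series, axis=-1) ** 2, axis=-1)


def scale_rows(
    series: np.ndarray, method: str = "quadratic_variation", roi_names=None
) -> np.ndarray:
    """Scale each row so its QV, l2 norm, or sample SD equals one."""
    series = np.asarray(series, dtype=float)
    method = _SCALING_ALIASES.get(method, method)
    if method == "quadratic_variation":
        denom = np.sqrt(quadratic_variation(series))
    elif method == "norm":
        denom = np.linalg.norm(series, axis=-1)
    elif method == "std":
        denom = np.std(series, axis=-1, ddof=1)
    else:
        raise ValueError(f"unknown scaling {method!r}")
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        names = (
            [roi_names[i] for i in bad] if roi_names is not None else bad.tolist()
        )
        raise ValueError(f"zero {method} in rows {names}: cannot scale")
    return series / denom[..., None]


def end_match(series: np.ndarray) -> np.ndarray:
    """Subtract the linear ramp through each row's endpoints.

    Closes the path for signed-area computation: the first and last samples
    coincide afterwards. Idempotent.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 time points to end-match")
    ramp = np.linspace(0.0, 1.0, n)
    first = series[..., :1]
    last = series[..., -1:]
    return series - (first + (last - first) * ramp)


def bandpass_bessel(
    series: np.ndarray,
    band: tuple[float, float],
    order: int = 4,
    tr: float = 2.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Bessel band-pass with magnitude-normalized (-3 dB) cutoffs.

    Zero-phase (forward-backward) application by default, so the overall
    magnitude response is the squared single-pass response and the phase
    response is flat -- relative timing between rows is preserved.
    """
    series = np.asarray(series, dtype=float)
    low, high = band
    nyq = 0.5 / tr
    if not 0 < low < high:
        raise ValueError("band must satisfy 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    b, a = _signal.bessel(order, [low, high], btype="bandpass", fs=1.0 / tr, norm="mag")
    if zero_phase:
        return _signal.filtfilt(b, a, series, axis=-1)
    return _signal.lfilter(b, a, series, axis=-1)


def bessel_gain(
    freq_hz, band: tuple[float, float], order: int = 4, tr: float = 2.0,
    zero_phase: bool = True,
):
    """Analytic magnitude response at ``freq_hz`` (squared when zero-phase)."""
    b, a = _signal.bessel(order, list(band), btype="bandpass", fs=1.0 / tr, norm="mag")
    freq_hz = np.atleast_1d(np.asarray(freq_hz, dtype=float))
    _, h = _signal.freqz(b, a, worN=2 * np.pi * freq_hz * tr)
    mag = np.abs(h)
    return mag**2 if zero_phase else mag


def global_signal_regress(series: np.ndarray) -> np.ndarray:
    """Regress the across-ROI mean time course out of every row.

    Each row is replaced by its OLS residual against (intercept, global
    signal); residuals are exactly orthogonal to the global signal. A
    constant global signal degenerates to intercept-only regression.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 ROIs for global signal regression")
    g = series.mean(axis=0)
    n = series.shape[-1]
    if np.ptp(g) == 0:
        warnings.warn(
            "constant global signal: regressing against intercept only",
            stacklevel=2,
        )
        design = np.ones((n, 1))
    else:
        design = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    return series - (design @ beta).T


class TimeSeriesCleaner:
    """Stateless sklearn-style transformer applying the fixed pipeline.

    ``feature_kind='lead'`` inserts end-matching before scaling (the signed
    area needs a closed path); the other feature kinds skip it.
    """

    def __init__(
        self,
        config: PreprocessConfig | None = None,
        feature_kind: str = "corr",
        tr: float = 2.0,
    ):
        self.config = config
        self.feature_kind = feature_kind
        self.tr = tr

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "feature_kind": self.feature_kind, "tr": self.tr}

    def set_params(self, **params) -> "TimeSeriesCleaner":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "TimeSeriesCleaner":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        cfg = self.config or PreprocessConfig()
        out = np.asarray(X, dtype=float)
        if cfg.do_gsr:
            out = global_signal_regress(out)
        out = mean_center_detrend(out)
        if self.feature_kind == "lead":
            out = end_match(out)
        out = scale_rows(out, cfg.scaling)
        if cfg.filter_band is not None:
            out = bandpass_bessel(
                out, cfg.filter_band, cfg.filter_order, self.tr, cfg.zero_phase
            )
        return out

    def steps(self) -> list[str]:
        cfg = self.config or PreprocessConfig()
        seq = []
        if cfg.do_gsr:
            seq.append("gsr")
        seq.append("center_detrend")
        if self.feature_kind == "lead":
            seq.append("end_match")
        seq.append(f"scale:{cfg.scaling}")
        if cfg.filter_band is not None:
            mode = "zero_phase" if cfg.zero_phase else "causal"
            seq.append(f"bandpass:{cfg.filter_band}:order{cfg.filter_order}:{mode}")
        return seq


def run_pipeline(
    panel: TimeSeriesPanel,
    config: PreprocessConfig | None = None,
    feature_kind: str = "corr",
) -> TimeSeriesPanel:
    """Apply the conditioning pipeline to every record of a panel."""
    cleaner = TimeSeriesCleaner(config=config, feature_kind=feature_kind, tr=panel.tr)
    note = "preprocess[" + " -> ".join(cleaner.steps()) + f"] for {feature_kind}"
    return panel.map_matrices(cleaner.transform, note=note)
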