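"""Synthetic cyclic time-series panels with planted structure.

The generator emulates the statistical structure the analysis pipeline
assumes of resting-state BOLD ROI series: each region carries a *cyclic*
signal -- a periodic driver observed through a monotone re-parameterization
of time -- with a per-region phase offset that defines a planted temporal
ordering. Subjects get stable signatures (phase and amplitude perturbations
shared across their two visits), every region shares a slow global
component, and observation noise is AR(1)-autocorrelated to mimic the
serial dependence of hemodynamic signals. A group effect can be injected on
chosen ROI pairs to give the patient group a known, recoverable difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .panel import Record, TimeSeriesPanel

__all__ = [
    "SyntheticParams",
    "make_panel",
    "planted_ordering",
    "inject_group_effect",
    "DegenerateOrderingWarning",
]


class DegenerateOrderingWarning(UserWarning):
    """Raised when tied phase offsets make the planted ordering ambiguous."""


@dataclass
class SyntheticParams:
    """Knobs of the synthetic cohort.

    Parameters
    ----------
    n_subjects, n_patients:
        Cohort size and how many subjects carry the "patient" label
        (defaults mirror an imbalanced 50/29 case-control cohort).
    n_rois, n_time, tr:
        Panel geometry: 33 regions, 300 samples at TR = 2 s by default.
    phase_offsets:
        Per-ROI offsets ``delta_k`` in radians defining the planted cyclic
        ordering; evenly spaced on the circle when omitted.
    driver_harmonics:
        ``(frequency_hz, amplitude)`` pairs of the periodic driver; the
        first entry is the fundamental.
    reparam_strength:
        Amplitude ``s`` of the monotone warp
        ``phi(t) = t + (s / omega) sin(omega t + u)``; must be < 1 so that
        ``phi' = 1 + s cos(.) > 0`` everywhere. ``u`` is redrawn per visit.
    warp_freq_hz:
        Frequency of the warp modulation (``omega = 2 pi warp_freq_hz``).
    signature_strength:
        Scale of subject-specific per-ROI phase perturbations (radians) and
        amplitude jitter, drawn once per subject and shared across visits.
    noise_sd, noise_ar_coeff:
        Stationary SD and AR(1) coefficient of the observation noise.
    global_amp:
        Amplitude of the shared slow global component (white noise low-passed
        below 0.05 Hz, added identically to every ROI, redrawn per visit).
    group_effect:
        ``(roi_i, roi_j, delta)`` triples applied to patient subjects by
        :func:`inject_group_effect`. In the default ``coupling`` mode each
        listed pair receives a shared extra oscillator at
        ``effect_freq_hz`` with amplitude ``effect_amp`` and a phase gap of
        ``delta`` between the two regions -- because the signed area is
        bilinear and cross-frequency areas vanish over full cycles, this
        alters the listed pair's interaction while leaving other pairs
        essentially untouched. The ``phase`` mode instead shifts the pair's
        driver phase gap by ``delta`` (split antisymmetrically), which also
        perturbs pairs that share one of the two regions.
    n_visits, n_runs:
        Two visits, one run per visit by default.
    """

    n_subjects: int = 79
    n_patients: int | None = None  # default: the 50/79 cohort ratio
    n_rois: int = 33
    n_time: int = 300
    tr: float = 2.0
    phase_offsets: np.ndarray | None = None
    driver_harmonics: tuple[tuple[float, float], ...] = ((0.02, 1.0), (0.04, 0.4))
    reparam_strength: float = 0.3
    warp_freq_hz: float = 0.005
    signature_strength: float = 0.3
    noise_sd: float = 0.3
    noise_ar_coeff: float = 0.5
    global_amp: float = 0.5
    group_effect: tuple[tuple[int, int, float], ...] = ()
    effect_mode: str = "coupling"
    effect_amp: float = 0.5
    effect_freq_hz: float = 0.03
    n_visits: int = 2
    n_runs: int = 1
    seed: int = 0

    def offsets(self) -> np.ndarray:
        if self.phase_offsets is None:
            return 2.0 * np.pi * np.arange(self.n_rois) / self.n_rois
        out = np.asarray(self.phase_offsets, dtype=float)
        if out.shape != (self.n_rois,):
            raise ValueError(
                f"phase_offsets has shape {out.shape}, expected ({self.n_rois},)"
            )
        return out

    def validate(self) -> None:
        if self.n_time < 2:
            raise ValueError("n_time must be >= 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.patient_count() <= self.n_subjects:
            raise ValueError("n_patients must lie in [0, n_subjects]")
        if not 0 <= self.noise_ar_coeff < 1:
            raise ValueError("noise_ar_coeff must lie in [0, 1)")
        if self.reparam_strength >= 1.0 or self.reparam_strength < 0.0:
            raise ValueError(
                "reparam_strength must lie in [0, 1): the warp "
                "phi(t) = t + (s/omega) sin(omega t + u) is monotone only "
                f"for s < 1 (got s={self.reparam_strength})"
            )
        off = self.offsets()
        if np.any(off < 0) or np.any(off >= 2 * np.pi):
            raise ValueError("phase_offsets must lie in [0, 2*pi)")
        if not self.driver_harmonics:
            raise ValueError("at least one driver harmonic is required")
        for f, _ in self.driver_harmonics:
            if f <= 0:
                raise ValueError("driver harmonic frequencies must be positive")
        if self.effect_mode not in ("coupling", "phase"):
            raise ValueError("effect_mode must be 'coupling' or 'phase'")
        for i, j, _ in self.group_effect:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"unknown ROI index in group_effect pair ({i}, {j})")
            if i == j:
                raise ValueError("group_effect pair must name two distinct ROIs")

    def subject_ids(self) -> list[str]:
        width = len(str(self.n_subjects))
        return [f"sub-{i + 1:0{width}d}" for i in range(self.n_subjects)]

    def patient_count(self) -> int:
        if self.n_patients is not None:
            return self.n_patients
        return int(round(self.n_subjects * 50 / 79))

    def labels(self) -> dict[str, str]:
        ids = self.subject_ids()
        n_pat = self.patient_count()
        return {
            sid: ("patient" if i < n_pat else "control")
            for i, sid in enumerate(ids)
        }


def _warp(t: np.ndarray, strength: float, omega: float, u: float) -> np.ndarray:
    """phi(t) = t + (s/omega) sin(omega t + u); strictly increasing for s < 1."""
    if strength == 0.0:
        return t
    phi = t + (strength / omega) * np.sin(omega * t + u)
    if np.any(np.diff(phi) <= 0):  # guards the invariant, not reachable for s<1
        raise ValueError("non-monotone warp: reduce reparam_strength")
    return phi


def _driver(theta: np.ndarray, harmonics: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Periodic driver as a function of fundamental phase theta (radians)."""
    f0 = harmonics[0][0]
    out = np.zeros_like(theta)
    for f, amp in harmonics:
        out += amp * np.cos((f / f0) * theta)
    return out


def _slow_global(n_time: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD low-frequency (< 0.05 Hz) smooth process."""
    white = rng.standard_normal(n_time + 200)  # pad to damp filter transients
    nyq = 0.5 / tr
    b, a = _signal.butter(4, 0.05 / nyq, btype="low")
    slow = _signal.filtfilt(b, a, white)[100 : 100 + n_time]
    sd = slow.std()
    return slow / sd if sd > 0 else slow


def _ar1_noise(
    shape: tuple[int, int], coeff: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if coeff == 0.0:
        return sd * white
    # lfilter(b=[1], a=[1, -coeff]) realizes e_t = coeff*e_{t-1} + w_t;
    # scaling by sqrt(1-coeff^2) keeps the stationary SD equal to sd.
    out = _signal.lfilter([1.0], [1.0, -coeff], white, axis=-1)
    return sd * np.sqrt(1.0 - coeff**2) * out


def _subject_draws(
    params: SyntheticParams, ss: np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject signature phases (radians) and mixing amplitudes."""
    rng = np.random.default_rng(ss)
    sig = params.signature_strength * rng.standard_normal(params.n_rois)
    amp = 1.0 + 0.2 * params.signature_strength * rng.standard_normal(params.n_rois)
    amp = np.clip(amp, 0.2, None)
    return sig, amp


def _make_record_matrix(
    params: SyntheticParams,
    offsets: np.ndarray,
    signature: np.ndarray,
    amplitudes: np.ndarray,
    visit_ss: np.random.SeedSequence,
    effects: tuple[tuple[int, int, float], ...] = (),
) -> np.ndarray:
    rng = np.random.default_rng(visit_ss)
    t = np.arange(params.n_time) * params.tr
    u = rng.uniform(0.0, 2.0 * np.pi)
    omega_w = 2.0 * np.pi * params.warp_freq_hz
    phi = _warp(t, params.reparam_strength, omega_w, u)
    f0 = params.driver_harmonics[0][0]
    theta = 2.0 * np.pi * f0 * phi  # fundamental phase along the warped clock
    g = params.global_amp * _slow_global(params.n_time, params.tr, rng)
    shifts = offsets + signature
    X = amplitudes[:, None] * _driver(
        theta[None, :] - shifts[:, None], params.driver_harmonics
    )
    X = X + g[None, :]
    X = X + _ar1_noise(X.shape, params.noise_ar_coeff, params.noise_sd, rng)
    # coupling-mode group effect: a pair-private oscillator at a distinct
    # frequency, drawn last so the preceding stream matches the no-effect run
    for i, j, delta in effects:
        psi = rng.uniform(0.0, 2.0 * np.pi)
        theta_c = 2.0 * np.pi * params.effect_freq_hz * phi
        X[i] += params.effect_amp * np.cos(theta_c - psi)
        X[j] += params.effect_amp * np.cos(theta_c - psi - delta)
    return X


def _metadata(params: SyntheticParams, ss: np.random.SeedSequence) -> dict[str, dict]:
    """Plausible per-subject demographics, independent of the signals."""
    rng = np.random.default_rng(ss)
    meta: dict[str, dict] = {}
    for sid, group in params.labels().items():
        if group == "patient":
            age = rng.normal(53.0, 10.3)
            hearing = bool(rng.random() < 38 / 50)
            female = bool(rng.random() < 21 / 50)
        else:
            age = rng.normal(47.8, 11.1)
            hearing = bool(rng.random() < 12 / 29)
            female = bool(rng.random() < 15 / 29)
        meta[sid] = {
            "age": float(np.clip(age, 18.0, 90.0)),
            "sex": "F" if female else "M",
            "hearing_loss": hearing,
        }
    return meta


def make_panel(
    params: SyntheticParams,
    _phase_delta: dict[int, float] | None = None,
    _effects: tuple[tuple[int, int, float], ...] = (),
    _only_group: str | None = None,
    _base: TimeSeriesPanel | None = None,
) -> TimeSeriesPanel:
    """Generate a deterministic synthetic cohort.

    ROI ``k`` of subject ``s`` at visit ``v`` is
    ``a_k * r(theta_v(t) - delta_k - sig_k) + global + AR(1) noise`` where the
    signature ``sig_k`` and amplitudes ``a_k`` are drawn once per subject and
    the warp phase, global component and noise are redrawn per visit/run.

    The private arguments support :func:`inject_group_effect` (regeneration
    of a subset of subjects with shifted phase offsets).
    """
    params.validate()
    offsets = params.offsets()
    root = np.random.SeedSequence(params.seed)
    meta_ss, *subject_ss = root.spawn(params.n_subjects + 1)
    labels = params.labels()
    records: list[Record] = []
    for sid, s_ss in zip(params.subject_ids(), subject_ss):
        sig_ss, *visit_ss = s_ss.spawn(params.n_visits * params.n_runs + 1)
        signature, amplitudes = _subject_draws(params, sig_ss)
        affected = _only_group is None or labels[sid] == _only_group
        roi_offsets = offsets.copy()
        if _phase_delta and affected:
            for roi, d in _phase_delta.items():
                roi_offsets[roi] += d
        effects = _effects if affected else ()
        i = 0
        for visit in range(1, params.n_visits + 1):
            for run in range(1, params.n_runs + 1):
                reuse = (
                    _base is not None
                    and _only_group is not None
                    and not affected
                )
                if reuse:
                    records.append(_base.get(sid, visit, run))
                else:
                    X = _make_record_matrix(
                        params, roi_offsets, signature, amplitudes,
                        visit_ss[i], effects,
                    )
                    records.append(Record(sid, visit, run, X))
                i += 1
    roi_names = [f"ROI{i + 1:02d}" for i in range(params.n_rois)]
    return TimeSeriesPanel(
        roi_names=roi_names,
        records=records,
        labels=labels,
        tr=params.tr,
        metadata=_metadata(params, meta_ss),
        provenance=[f"synthetic(seed={params.seed})"],
    )


def planted_ordering(params: SyntheticParams) -> np.ndarray:
    """Ground-truth cyclic ordering: ROI indices sorted by phase offset.

    The cyclicity extractor should recover this order (up to rotation).
    Ties are legal but ambiguous; they trigger a
    :class:`DegenerateOrderingWarning`.
    """
    offsets = params.offsets()
    order = np.argsort(offsets, kind="stable")
    if np.unique(offsets).size < offsets.size:
        warnings.warn(
            "tied phase offsets: ordering within tied blocks is arbitrary",
            DegenerateOrderingWarning,
            stacklevel=2,
        )
    return order


def inject_group_effect(
    panel: TimeSeriesPanel, params: SyntheticParams
) -> TimeSeriesPanel:
    """Re-generate patient records with the configured ROI-pair effects.

    ``coupling`` mode (default) adds a pair-private oscillator with phase
    gap ``delta`` to each listed pair; ``phase`` mode shifts the pair's
    driver phase gap by exactly ``delta`` (split antisymmetrically:
    ``delta_i -= delta/2``, ``delta_j += delta/2``). Entries with
    ``delta == 0`` are identities and are skipped. Control records are
    returned untouched (same array objects).
    """
    params.validate()
    active = tuple((i, j, d) for i, j, d in params.group_effect if d != 0.0)
    if not active:
        return panel
    if params.effect_mode == "phase":
        delta_map: dict[int, float] = {}
        for i, j, d in active:
            delta_map[i] = delta_map.get(i, 0.0) - d / 2.0
            delta_map[j] = delta_map.get(j, 0.0) + d / 2.0
        out = make_panel(
            params, _phase_delta=delta_map, _only_group="patient", _base=panel
        )
    else:
        out = make_panel(
            params, _effects=active, _only_group="patient", _base=panel
        )
    out.provenance.append(
        f"group_effect(mode={params.effect_mode}, pairs={list(active)!r})"
    )
    return out


def phi_is_monotone(params: SyntheticParams, n_probe: int = 10) -> bool:
    """Numerically verify phi' > 0 at every sample over random warp phases."""
    t = np.arange(params.n_time) * params.tr
    omega_w = 2.0 * np.pi * params.warp_freq_hz
    rng = np.random.default_rng(params.seed)
    for _ in range(n_probe):
        u = rng.uniform(0, 2 * np.pi)
        phi = t + (params.reparam_strength / omega_w) * np.sin(omega_w * t + u)
        if np.any(np.diff(phi) <= 0):
            return False
    return True
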