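"""Synthetic trace generation with ground truth.

This module stands in for raw recordings from spontaneously beating
iPSC-derived cardiomyocytes: ventricular-like action-potential trains,
Fura-2 ratio Ca2+-transient trains with controllable interval/amplitude
variability and a caffeine-evoked store-release pulse, and MAP/ECG-like beat
sequences with up to three repolarization peaks. Every generated trace is
accompanied by a :class:`GroundTruth` record, which is what the analysis
modules are tested against (closure property: analysing a noise-free
generated trace must recover its own parameters).

Generation is a pure function of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from ._waveform import T_HALF_UP, RepolFit, fit_repolarization
from .errors import ParameterError, PlacementError, ProtocolError
from .trace_io import Annotation, AnnotationLabel, Trace, TraceKind

__all__ = [
    "APTrainParams",
    "EventSpec",
    "CaTrainParams",
    "RepolSeqParams",
    "RealizedEvent",
    "GroundTruth",
    "generate_ap_train",
    "generate_ca_train",
    "generate_repol_sequence",
]

#: Ca2+ transient kinetics (seconds): fast rise, slower decay
CA_TAU_RISE = 0.08
CA_TAU_DECAY = 0.40
#: caffeine-evoked release kinetics (whole-store dump, slow decline)
CAFF_TAU_RISE = 0.15
CAFF_TAU_DECAY = 2.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APTrainParams:
    """Regular spontaneous AP train (defaults: the control-line phenotype)."""

    n_beats: int = 10
    bpm: float = 41.0
    apd50_ms: float = 204.4
    apd90_ms: float = 329.7
    apa_mV: float = 117.85
    mdp_mV: float = -68.35
    noise_sd_mV: float = 0.0
    dt_s: float = 5e-5  # 20 kHz, the patch-clamp digitisation rate
    seed: int = 0

    def __post_init__(self):
        if self.n_beats < 1:
            raise ParameterError("n_beats must be >= 1")
        if not self.bpm > 0:
            raise ParameterError("bpm must be > 0")
        period_ms = 60000.0 / self.bpm
        if not (0 < self.apd50_ms <= self.apd90_ms < period_ms):
            raise ParameterError(
                f"need 0 < APD50 <= APD90 < cycle length "
                f"({self.apd50_ms}, {self.apd90_ms}, {period_ms:.1f} ms)"
            )
        if not self.apa_mV > 0:
            raise ParameterError("apa_mV must be > 0")
        if self.noise_sd_mV < 0:
            raise ParameterError("noise_sd_mV must be >= 0")
        if not self.dt_s > 0:
            raise ParameterError("dt_s must be > 0")


@dataclass(frozen=True)
class EventSpec:
    """An afterdepolarization or burst to inject into an AP train.

    ``offset_fraction`` positions the event peak: for an EAD, as a fraction of
    the repolarization interval (activation to APD90); for a DAD or burst
    onset, as a fraction of the diastolic interval (repolarization completion
    to next activation). For bursts, ``relative_amplitude_pct`` sets the
    elevation of the burst diastolic plateau above the MDP (in % of APA),
    ``width_ms`` the intra-burst cycle length, and ``burst_upstroke_mV`` the
    upstroke amplitude above the burst plateau.
    """

    type: Literal["EAD", "DAD", "burst"]
    beat_index: int
    relative_amplitude_pct: float = 10.0
    offset_fraction: float = 0.5
    width_ms: float = 40.0
    burst_n_upstrokes: int = 5
    burst_upstroke_mV: float = 45.0

    def __post_init__(self):
        if self.type not in ("EAD", "DAD", "burst"):
            raise ParameterError(f"unknown event type {self.type!r}")
        if self.beat_index < 0:
            raise ParameterError("beat_index must be >= 0")
        if not (0 < self.offset_fraction < 1):
            raise PlacementError("offset_fraction must lie strictly in (0, 1)")
        if not self.width_ms > 0:
            raise ParameterError("width_ms must be > 0")
        if self.type == "burst" and self.burst_n_upstrokes < 2:
            raise ParameterError("a burst needs >= 2 upstrokes")


@dataclass(frozen=True)
class CaTrainParams:
    """Spontaneous Ca2+-transient train, optionally ending in a caffeine puff.

    Amplitudes are in the same instrument-relative units as the baseline
    (Fura-2 ratio units); no absolute Ca2+ calibration is attempted.
    """

    n_transients: int = 10
    rate_hz: float = 0.5
    amplitude_mean: float = 0.5
    amplitude_cv: float = 0.0
    interval_cv: float = 0.0
    diastolic_level: float = 1.0
    diastolic_drift_per_s: float = 0.0
    noise_sd: float = 0.0
    caffeine_time_s: Optional[float] = None
    caffeine_amplitude: float = 2.0
    dt_s: float = 0.05  # 20 Hz camera rate
    seed: int = 0

    def __post_init__(self):
        if self.n_transients < 1:
            raise ParameterError("n_transients must be >= 1")
        if not self.rate_hz > 0:
            raise ParameterError("rate_hz must be > 0")
        if not self.amplitude_mean > 0:
            raise ParameterError("amplitude_mean must be > 0")
        if self.amplitude_cv < 0 or self.interval_cv < 0:
            raise ParameterError("CVs must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not self.dt_s > 0:
            raise ParameterError("dt_s must be > 0")


@dataclass(frozen=True)
class RepolSeqParams:
    """MAP/ECG-like beat sequence with up to three repolarization peaks.

    ``peak_templates`` are ``(delay_ms after activation, height, width_ms)``
    tuples with strictly increasing delays. ``merge_pattern`` flags, per beat,
    whether the second peak is pulled toward the first until the inter-peak
    valley rises above ~95% of the smaller peak height (i.e. the waves
    "merge" in the T2 sense).
    """

    n_beats: int = 10
    peak_templates: tuple = ((220.0, 0.30, 60.0),)
    merge_pattern: Optional[tuple] = None
    noise_sd: float = 0.0
    cycle_length_s: float = 1.0
    dt_s: float = 1e-3
    seed: int = 0
    merge_target_fraction: float = 0.95

    def __post_init__(self):
        if self.n_beats < 1:
            raise ParameterError("n_beats must be >= 1")
        tmpl = tuple(tuple(float(x) for x in p) for p in self.peak_templates)
        if not 1 <= len(tmpl) <= 3:
            raise ParameterError("between 1 and 3 peak templates are supported")
        delays = [p[0] for p in tmpl]
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ParameterError("peak delays must be strictly increasing")
        for d, h, w in tmpl:
            if h <= 0 or w <= 0 or d <= 0:
                raise ParameterError("peak delay, height and width must be > 0")
        if delays[0] < 60.0:
            raise ParameterError("first peak delay must be >= 60 ms (clear of the upstroke)")
        if tmpl[-1][0] * 1e-3 > 0.8 * self.cycle_length_s:
            raise ParameterError("last peak delay exceeds 80% of the cycle length")
        object.__setattr__(self, "peak_templates", tmpl)
        mp = self.merge_pattern
        if mp is None:
            mp = tuple(False for _ in range(self.n_beats))
        else:
            mp = tuple(bool(x) for x in mp)
            if len(mp) != self.n_beats:
                raise ParameterError("merge_pattern length must equal n_beats")
            if any(mp) and len(tmpl) < 2:
                raise ParameterError("merging requires at least two peak templates")
        object.__setattr__(self, "merge_pattern", mp)
        if not self.dt_s > 0 or not self.cycle_length_s > 0:
            raise ParameterError("dt_s and cycle_length_s must be > 0")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RealizedEvent:
    """An injected event with its realised (grid-snapped) times/amplitudes."""

    type: str
    beat_index: int
    onset_time: float
    peak_time: float
    amplitude: float
    relative_amplitude_pct: float
    n_upstrokes: int = 0
    plateau_level: float = float("nan")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a trace.

    Only the fields relevant to the generated modality are populated; the
    rest stay at their empty defaults.
    """

    activation_times: tuple = ()
    apd50_ms: tuple = ()
    apd90_ms: tuple = ()
    apa_mV: tuple = ()
    mdp_mV: tuple = ()
    bpm: Optional[float] = None
    events: tuple = ()
    transient_onsets: tuple = ()
    transient_amplitudes: tuple = ()
    diastolic_level: Optional[float] = None
    caffeine_time: Optional[float] = None
    caffeine_amplitude: Optional[float] = None
    rhythm_category: Optional[str] = None
    repol_peak_times: tuple = ()   # per beat: tuple of peak times (s)
    repol_merged: tuple = ()       # per beat: tuple of merged flags per peak
    wave_labels: tuple = ()        # e.g. ("T1", "T2", "U")

    def to_dict(self) -> dict:
        import dataclasses as _dc

        def conv(x):
            if isinstance(x, RealizedEvent):
                return _dc.asdict(x)
            if isinstance(x, tuple):
                return [conv(e) for e in x]
            return x

        return {k: conv(v) for k, v in _dc.asdict(self).items()}


# ---------------------------------------------------------------------------
# AP train
# ---------------------------------------------------------------------------

#: diastolic lead-in before the first beat, seconds
AP_LEAD_IN = 0.15


def generate_ap_train(
    params: APTrainParams, events: Sequence[EventSpec] = ()
) -> tuple[Trace, GroundTruth]:
    """Generate a membrane-potential trace of ``n_beats`` identical APs.

    Per-beat features of the noise-free waveform match the requested
    APD50/APD90/APA/MDP analytically (well within 0.5%). Events are injected
    as localised depolarizations whose local-minimum-to-peak amplitude equals
    ``relative_amplitude_pct`` % of the APA exactly on the noise-free trace;
    Gaussian noise is added last. Reproducible per seed.
    """
    p = params
    period = 60.0 / p.bpm
    apd50_s = p.apd50_ms * 1e-3
    apd90_s = p.apd90_ms * 1e-3
    fit = fit_repolarization(apd50_s, apd90_s)

    duration = AP_LEAD_IN + p.n_beats * period
    n = int(round(duration / p.dt_s)) + 1
    t = np.arange(n) * p.dt_s
    v = np.full(n, p.mdp_mV, dtype=float)

    beat_starts = AP_LEAD_IN + period * np.arange(p.n_beats)
    act_times = beat_starts + T_HALF_UP
    for s in beat_starts:
        i0 = max(int((s - 0.003) / p.dt_s), 0)
        i1 = min(int((s + period) / p.dt_s) + 1, n)
        tau = t[i0:i1] - s
        v[i0:i1] += p.apa_mV * fit.waveform(tau)

    realized = []
    for ev in events:
        realized.append(_inject_event(v, t, p, ev, act_times, apd90_s))

    if p.noise_sd_mV > 0:
        rng = np.random.default_rng(p.seed)
        v = v + rng.normal(0.0, p.noise_sd_mV, n)

    trace = Trace(
        id=f"ap_train_seed{p.seed}",
        kind=TraceKind.MEMBRANE_POTENTIAL,
        t0=0.0,
        dt=p.dt_s,
        samples=v,
    )
    nb = p.n_beats
    truth = GroundTruth(
        activation_times=tuple(act_times),
        apd50_ms=(p.apd50_ms,) * nb,
        apd90_ms=(p.apd90_ms,) * nb,
        apa_mV=(p.apa_mV,) * nb,
        mdp_mV=(p.mdp_mV,) * nb,
        bpm=p.bpm,
        events=tuple(realized),
    )
    return trace, truth


def _inject_event(
    v: np.ndarray,
    t: np.ndarray,
    p: APTrainParams,
    ev: EventSpec,
    act_times: np.ndarray,
    apd90_s: float,
) -> RealizedEvent:
    dt = p.dt_s
    n = v.size
    if ev.beat_index >= act_times.size:
        raise PlacementError(
            f"event beat_index {ev.beat_index} beyond the {act_times.size}-beat train"
        )
    t_act = act_times[ev.beat_index]
    t_rc = t_act + apd90_s  # analytic repolarization-completion time
    t_next = act_times[ev.beat_index + 1] if ev.beat_index + 1 < act_times.size else t[-1]

    if ev.type == "burst":
        return _inject_burst(v, t, p, ev, t_rc, t_next)

    half = 0.5 * ev.width_ms * 1e-3
    if ev.type == "EAD":
        t_c = t_act + ev.offset_fraction * apd90_s
        t_a, t_b = t_c - half, t_c + half
        if not (t_a > t_act + 2e-3):
            raise PlacementError("EAD window starts before the AP peak region")
        if not (t_c < t_rc):
            raise PlacementError("EAD peak must precede repolarization completion")
    else:  # DAD
        t_c = t_rc + ev.offset_fraction * (t_next - t_rc)
        t_a, t_b = t_c - half, t_c + half
        if not (t_a > t_rc):
            raise PlacementError("DAD window starts before repolarization completes")
        if not (t_b < t_next - 5e-3):
            raise PlacementError("DAD window runs into the next activation")

    # snap the anchor points to the sample grid so the injected amplitude is
    # exactly measurable as local-minimum-to-peak on the sampled trace
    i_a, i_c, i_b = (int(round(x / dt)) for x in (t_a, t_c, t_b))
    if not (0 <= i_a < i_c < i_b < n):
        raise PlacementError("event window does not fit on the sample grid")
    amp = ev.relative_amplitude_pct / 100.0 * p.apa_mV
    base = v[i_a]
    tail = v[i_b]
    j = np.arange(i_a, i_c + 1)
    v[i_a : i_c + 1] = base + amp * 0.5 * (1 - np.cos(np.pi * (j - i_a) / (i_c - i_a)))
    j = np.arange(i_c, i_b + 1)
    v[i_c : i_b + 1] = tail + (base + amp - tail) * 0.5 * (
        1 + np.cos(np.pi * (j - i_c) / (i_b - i_c))
    )
    return RealizedEvent(
        type=ev.type,
        beat_index=ev.beat_index,
        onset_time=float(t[i_a]),
        peak_time=float(t[i_c]),
        amplitude=float(amp),
        relative_amplitude_pct=float(ev.relative_amplitude_pct),
    )


#: cosine ramp up/down of the burst diastolic plateau, seconds
BURST_RAMP = 0.05


def _inject_burst(
    v: np.ndarray,
    t: np.ndarray,
    p: APTrainParams,
    ev: EventSpec,
    t_rc: float,
    t_next: float,
) -> RealizedEvent:
    dt = p.dt_s
    intra_cl = ev.width_ms * 1e-3
    n_up = ev.burst_n_upstrokes
    elevation = ev.relative_amplitude_pct / 100.0 * p.apa_mV
    t_start = t_rc + ev.offset_fraction * (t_next - t_rc)
    t_stop = t_start + 2 * BURST_RAMP + n_up * intra_cl
    if not (t_start > t_rc and t_stop < t_next - 0.01):
        raise PlacementError("burst does not fit inside the diastolic interval")

    # elevated diastolic plateau with cosine shoulders
    i0, i1 = int(round(t_start / dt)), int(round(t_stop / dt))
    seg_t = t[i0 : i1 + 1]
    prof = np.full(seg_t.size, elevation)
    up = seg_t < t_start + BURST_RAMP
    prof[up] = elevation * 0.5 * (1 - np.cos(np.pi * (seg_t[up] - t_start) / BURST_RAMP))
    dn = seg_t > t_stop - BURST_RAMP
    prof[dn] = elevation * 0.5 * (1 - np.cos(np.pi * (t_stop - seg_t[dn]) / BURST_RAMP))
    v[i0 : i1 + 1] += prof

    # rapid low-amplitude upstrokes riding on the plateau
    from scipy.special import expit

    up_t_half, up_k = 1.0e-3, 0.2e-3
    fall_m, fall_k = 0.45 * intra_cl, 0.07 * intra_cl
    first_up = t_start + BURST_RAMP + 0.25 * intra_cl
    for k in range(n_up):
        s = first_up + k * intra_cl
        j0 = max(int((s - 0.003) / dt), 0)
        j1 = min(int((s + intra_cl) / dt) + 1, v.size)
        tau = t[j0:j1] - s
        v[j0:j1] += ev.burst_upstroke_mV * expit((tau - up_t_half) / up_k) * expit(
            -(tau - fall_m) / fall_k
        )
    return RealizedEvent(
        type="burst",
        beat_index=ev.beat_index,
        onset_time=float(t_start),
        peak_time=float(first_up),
        amplitude=float(ev.burst_upstroke_mV),
        relative_amplitude_pct=float(ev.relative_amplitude_pct),
        n_upstrokes=n_up,
        plateau_level=float(p.mdp_mV + elevation),
    )


# ---------------------------------------------------------------------------
# Ca2+ train
# ---------------------------------------------------------------------------

#: quiescent baseline before the first transient, seconds (defines F0)
CA_LEAD_IN = 2.0


def _ca_pulse(tau: np.ndarray, amplitude: float, tau_r: float, tau_d: float) -> np.ndarray:
    """Instantaneous-onset double-exponential pulse, peak-normalised."""
    t_pk = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    norm = math.exp(-t_pk / tau_d) - math.exp(-t_pk / tau_r)
    out = np.zeros_like(tau)
    m = tau >= 0
    out[m] = amplitude / norm * (np.exp(-tau[m] / tau_d) - np.exp(-tau[m] / tau_r))
    return out


def generate_ca_train(params: CaTrainParams) -> tuple[Trace, GroundTruth]:
    """Generate a fluorescence-ratio trace of spontaneous Ca2+ transients.

    Baseline = ``diastolic_level + drift * t``; transient onsets at intervals
    with the requested CV (truncated normal), amplitudes with the requested
    CV; an optional caffeine pulse (slow, large, annotated ``caffeine_puff``)
    emulates whole-store release. Seeded and deterministic.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    mean_int = 1.0 / p.rate_hz
    if p.n_transients > 1:
        intervals = rng.normal(mean_int, p.interval_cv * mean_int, p.n_transients - 1)
        intervals = np.clip(intervals, 0.25 * mean_int, None)
    else:
        intervals = np.empty(0)
    onsets = CA_LEAD_IN + np.concatenate([[0.0], np.cumsum(intervals)])
    amps = rng.normal(p.amplitude_mean, p.amplitude_cv * p.amplitude_mean, p.n_transients)
    amps = np.clip(amps, 0.1 * p.amplitude_mean, None)

    if p.caffeine_time_s is not None:
        if p.caffeine_time_s <= onsets[-1]:
            raise ProtocolError(
                "caffeine puff must come after the last spontaneous transient "
                f"(caffeine at {p.caffeine_time_s} s, last onset {onsets[-1]:.2f} s)"
            )
        duration = p.caffeine_time_s + 12.0
    else:
        duration = onsets[-1] + 3.0 * mean_int

    n = int(round(duration / p.dt_s)) + 1
    t = np.arange(n) * p.dt_s
    y = p.diastolic_level + p.diastolic_drift_per_s * t
    for onset, amp in zip(onsets, amps):
        y += _ca_pulse(t - onset, amp, CA_TAU_RISE, CA_TAU_DECAY)

    annotations = []
    if p.caffeine_time_s is not None:
        y += _ca_pulse(t - p.caffeine_time_s, p.caffeine_amplitude,
                       CAFF_TAU_RISE, CAFF_TAU_DECAY)
        annotations.append(
            Annotation(p.caffeine_time_s, AnnotationLabel.CAFFEINE_PUFF, "40 mmol/L")
        )

    if p.noise_sd > 0:
        y = y + rng.normal(0.0, p.noise_sd, n)

    trace = Trace(
        id=f"ca_train_seed{p.seed}",
        kind=TraceKind.FLUORESCENCE_RATIO,
        t0=0.0,
        dt=p.dt_s,
        samples=y,
        annotations=tuple(annotations),
    )
    truth = GroundTruth(
        transient_onsets=tuple(float(x) for x in onsets),
        transient_amplitudes=tuple(float(x) for x in amps),
        diastolic_level=p.diastolic_level,
        caffeine_time=p.caffeine_time_s,
        caffeine_amplitude=(p.caffeine_amplitude if p.caffeine_time_s is not None else None),
        rhythm_category=_intended_category(p.interval_cv, p.amplitude_cv),
    )
    return trace, truth


def _intended_category(interval_cv: float, amplitude_cv: float,
                       thr_i: float = 0.15, thr_a: float = 0.15) -> str:
    irregular = interval_cv > thr_i
    varying = amplitude_cv > thr_a
    return {(False, False): "R", (False, True): "Ra",
            (True, False): "I", (True, True): "Ia"}[(irregular, varying)]


# ---------------------------------------------------------------------------
# repolarization-peak beat sequences
# ---------------------------------------------------------------------------

REPOL_LEAD_IN = 0.2
#: upstroke spike shape (Gaussian), seconds
SPIKE_SIGMA = 0.004


def _gaussian(tau, height, sigma):
    return height * np.exp(-0.5 * (tau / sigma) ** 2)


def _beat_repol_curve(tau: np.ndarray, peaks) -> np.ndarray:
    y = np.zeros_like(tau)
    for d_s, h, sig_s in peaks:
        y += _gaussian(tau - d_s, h, sig_s)
    return y


def _valley_fraction(peaks) -> tuple[float, list[float], list[float]]:
    """Valley fraction between peaks 1 and 2 of an analytic peak sum.

    Returns ``(fraction, maxima_times, maxima_heights)``; fraction is 1.0
    when the first two templates have fused into a single maximum.
    """
    t_lo = peaks[0][0] - 4 * peaks[0][2]
    t_hi = peaks[-1][0] + 4 * peaks[-1][2]
    tt = np.linspace(t_lo, t_hi, 4001)
    yy = _beat_repol_curve(tt, peaks)
    from scipy.signal import argrelextrema

    idx = argrelextrema(yy, np.greater)[0]
    times = [float(tt[i]) for i in idx]
    heights = [float(yy[i]) for i in idx]
    if len(idx) < 2:
        return 1.0, times, heights
    i1, i2 = idx[0], idx[1]
    valley = float(np.min(yy[i1:i2 + 1]))
    frac = valley / min(heights[0], heights[1])
    return frac, times, heights


def _merge_second_peak(peaks: list, target: float) -> list:
    """Move peak 2 toward peak 1 until the valley fraction reaches ``target``."""
    d1 = peaks[0][0]
    d2_orig = peaks[1][0]
    frac0, _, _ = _valley_fraction(peaks[:2])
    if frac0 >= target:
        return peaks
    lo, hi = d1 + 0.25 * (d2_orig - d1), d2_orig  # lo: essentially fused
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        trial = [peaks[0], (mid, peaks[1][1], peaks[1][2])]
        frac, times, _ = _valley_fraction(trial)
        if frac >= target or len(times) < 2:
            lo = mid
        else:
            hi = mid
    d2_new = hi  # the last separation with fraction still < target from above
    # step slightly inside so the fraction clears the target but two maxima remain
    for d2_try in np.linspace(lo, hi, 25)[::-1]:
        trial = [peaks[0], (d2_try, peaks[1][1], peaks[1][2])] + list(peaks[2:])
        frac, times, _ = _valley_fraction(trial[:2])
        if frac >= target and len(times) >= 2:
            return trial
    raise ParameterError("could not merge peak 2 while keeping two maxima")


def generate_repol_sequence(params: RepolSeqParams) -> tuple[Trace, GroundTruth]:
    """Generate a MAP-like beat sequence with configurable repolarization peaks.

    Each beat is a sharp upstroke spike followed by 1-3 Gaussian
    repolarization peaks on a zero baseline. For beats flagged in
    ``merge_pattern``, peak 2 is moved toward peak 1 until the inter-peak
    valley exceeds ``merge_target_fraction`` x the smaller peak height, which
    is how "merging" T-waves are emulated. Truth labels: peak 1 is T1; peak 2
    is T2 when it merges in at least one beat, otherwise U; peak 3 is U.
    """
    p = params
    base_peaks = [(d * 1e-3, h, (w * 1e-3) / 2.355) for d, h, w in p.peak_templates]
    if len(base_peaks) >= 2:
        frac_nat, times_nat, _ = _valley_fraction(base_peaks[:2])
        if frac_nat >= 0.90 or len(times_nat) < 2:
            raise ParameterError(
                "unmerged templates already overlap beyond the merge criterion; "
                "separate the first two peaks"
            )

    duration = REPOL_LEAD_IN + p.n_beats * p.cycle_length_s
    n = int(round(duration / p.dt_s)) + 1
    t = np.arange(n) * p.dt_s
    y = np.zeros(n)
    spike_height = 2.5 * max(h for _, h, _ in base_peaks)

    beat_starts = REPOL_LEAD_IN + p.cycle_length_s * np.arange(p.n_beats)
    peak_times_truth = []
    merged_truth = []
    for b, s in enumerate(beat_starts):
        peaks = list(base_peaks)
        if p.merge_pattern[b]:
            peaks = _merge_second_peak(peaks, p.merge_target_fraction)
        i0 = max(int((s - 0.05) / p.dt_s), 0)
        i1 = min(int((s + p.cycle_length_s) / p.dt_s) + 1, n)
        tau = t[i0:i1] - s
        y[i0:i1] += _gaussian(tau, spike_height, SPIKE_SIGMA)
        y[i0:i1] += _beat_repol_curve(tau, peaks)
        # analytic truth: local maxima of the summed repolarization curve
        frac, times, _ = _valley_fraction(peaks)
        if len(peaks) >= 3:
            # recompute maxima over all three peaks for truth times
            _, times3, _ = _valley_fraction(peaks)
            tt = np.linspace(peaks[0][0] - 4 * peaks[0][2],
                             peaks[-1][0] + 4 * peaks[-1][2], 6001)
            yy = _beat_repol_curve(tt, peaks)
            from scipy.signal import argrelextrema
            idx = argrelextrema(yy, np.greater)[0]
            times = [float(tt[i]) for i in idx]
        peak_times_truth.append(tuple(s + x for x in times))
        flags = [False] * len(times)
        if p.merge_pattern[b] and len(times) >= 2:
            flags[1] = True
        merged_truth.append(tuple(flags))

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        y = y + rng.normal(0.0, p.noise_sd, n)

    n_pos = len(base_peaks)
    labels = ["T1"]
    if n_pos >= 2:
        labels.append("T2" if any(p.merge_pattern) else "U")
    if n_pos >= 3:
        labels.append("U")

    trace = Trace(
        id=f"repol_seq_seed{p.seed}",
        kind=TraceKind.MAP,
        t0=0.0,
        dt=p.dt_s,
        samples=y,
    )
    truth = GroundTruth(
        activation_times=tuple(float(s) for s in beat_starts),
        repol_peak_times=tuple(peak_times_truth),
        repol_merged=tuple(merged_truth),
        wave_labels=tuple(labels),
    )
    return trace, truth
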