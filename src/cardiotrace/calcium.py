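"""Ca2+-transient quantification and rhythm classification.

Works on Fura-2 ratio traces (F340/F380, background-subtracted per channel).
Spontaneous transients are located as prominence-based peaks above the local
diastolic baseline; each carries its amplitude (peak minus the preceding
diastolic level), onset and inter-transient interval. The sarcoplasmic
reticulum (SR) Ca2+ content is probed by a saturating caffeine puff that dumps
the whole store: its evoked amplitude is the SR load, and the ratio of the
spontaneous transient amplitude to the caffeine amplitude is the fractional
SR Ca2+ release.

Rhythm is classified on two axes — interval regularity and amplitude
stability — via coefficients of variation: R (regular, stable), Ra (regular,
varying amplitude), I (irregular, stable), Ia (irregular, varying). The CV
threshold on each axis defaults to 0.15 and is exposed in the analysis
configuration.

Amplitudes can be expressed as raw ratio-unit differences or as dF/F0
(difference normalised to the pre-event baseline); the two conventions give
the same fractional release whenever the same baseline serves numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    AlignmentError,
    ContractError,
    InsufficientDataError,
    ProtocolError,
    SignalQualityError,
    TruncationError,
)
from .trace_io import AnalysisConfig, Annotation, AnnotationLabel, Trace, TraceKind, smooth

__all__ = [
    "CaTransient",
    "CaffeineResponse",
    "RhythmClassification",
    "compute_ratio",
    "detect_transients",
    "diastolic_level",
    "caffeine_response",
    "fractional_release",
    "classify_rhythm",
]

AmplitudeConvention = Literal["raw", "df_f0"]


@dataclass(frozen=True)
class CaTransient:
    onset_time: float
    peak_time: float
    amplitude: float          # peak - preceding diastolic level, ratio units
    diastolic_pre: float
    interval_to_next: Optional[float]  # peak-to-peak, s; None for the last


@dataclass(frozen=True)
class CaffeineResponse:
    caffeine_time: float
    peak_time: float
    peak_amplitude: float
    baseline_pre: float
    convention: AmplitudeConvention


@dataclass(frozen=True)
class RhythmClassification:
    category: Literal["R", "Ra", "I", "Ia"]
    cv_interval: float
    cv_amplitude: float
    n_transients: int
    thresholds_used: tuple


def compute_ratio(
    f340: Trace, f380: Trace, background_340: float, background_380: float
) -> Trace:
    """Background-subtracted ratiometric trace (F340-bg)/(F380-bg).

    The channel traces must share t0, dt and length; the subtracted
    denominator must stay strictly positive everywhere.
    """
    if (
        f340.n != f380.n
        or abs(f340.t0 - f380.t0) > 1e-9
        or abs(f340.dt - f380.dt) > 1e-9 * f340.dt
    ):
        raise AlignmentError("f340/f380 traces are not time-aligned")
    den = f380.samples - background_380
    if np.any(den <= 0):
        raise SignalQualityError(
            "background-subtracted 380 nm channel is non-positive somewhere; "
            "check the background region"
        )
    ratio = (f340.samples - background_340) / den
    return Trace(
        id=f"{f340.id}_ratio",
        kind=TraceKind.FLUORESCENCE_RATIO,
        t0=f340.t0,
        dt=f340.dt,
        samples=ratio,
        annotations=tuple(f340.annotations),
    )


def _noise_sd(raw: np.ndarray) -> float:
    """Robust noise estimate from first differences (Gaussian assumption)."""
    return float(np.median(np.abs(np.diff(raw))) / 0.9539)


def detect_transients(trace: Trace, config: AnalysisConfig) -> list[CaTransient]:
    """Locate spontaneous Ca2+ transients on a ratio trace.

    The epoch from the first ``caffeine_puff`` annotation onward is excluded
    from spontaneous detection. Peaks are found on a lightly smoothed copy
    with a prominence floor well above the noise; the diastolic level before
    each transient is the median over the last quarter of the preceding
    inter-transient interval (the whole pre-train segment for the first).
    A flat trace yields an empty list.
    """
    if trace.kind is not TraceKind.FLUORESCENCE_RATIO:
        raise ContractError("transient detection expects a fluorescence_ratio trace")
    raw = trace.samples
    dt = trace.dt
    caffeine = trace.annotations_of(AnnotationLabel.CAFFEINE_PUFF)
    stop = trace.index_of(min(a.time for a in caffeine)) if caffeine else raw.size
    region = raw[:stop]
    if region.size < 5:
        return []
    w = config.smooth_samples(trace)
    x = smooth(region, w)
    # peak finding runs on the smoothed trace, so the noise floor scales with
    # the smoothed (not raw) noise level
    sd_sm = _noise_sd(region) / np.sqrt(max(w, 1))
    spread = float(np.percentile(x, 98) - np.percentile(x, 2))
    prom = max(6.5 * sd_sm, 0.04 * spread, 1e-12)
    min_dist = max(int(round(0.15 / dt)), 2)
    peaks, _ = find_peaks(x, prominence=prom, distance=min_dist)
    out: list[CaTransient] = []
    for k, p in enumerate(peaks):
        prev = peaks[k - 1] if k > 0 else 0
        rough = float(np.percentile(x[prev: p + 1], 5))
        thr = rough + 0.10 * (x[p] - rough)
        below = np.flatnonzero(x[prev:p] <= thr)
        onset = prev + int(below[-1]) if below.size else prev
        if k == 0:
            dia = float(np.median(raw[: max(onset, 1) + 1]))
        else:
            span = onset - prev
            j0 = onset - max(span // 4, 1)
            dia = float(np.median(raw[j0: onset + 1]))
        peak_val = float(np.max(raw[max(p - 2, 0): min(p + 3, region.size)]))
        amplitude = peak_val - dia
        if amplitude <= 0:
            continue
        out.append(
            CaTransient(
                onset_time=trace.t0 + onset * dt,
                peak_time=trace.t0 + p * dt,
                amplitude=amplitude,
                diastolic_pre=dia,
                interval_to_next=None,
            )
        )
    # fill peak-to-peak intervals
    import dataclasses as _dc

    for k in range(len(out) - 1):
        out[k] = _dc.replace(
            out[k], interval_to_next=out[k + 1].peak_time - out[k].peak_time
        )
    return out


def diastolic_level(
    transients: Sequence[CaTransient], trace: Optional[Trace] = None
) -> float:
    """Mean pre-transient diastolic level; whole-trace median as fallback."""
    if transients:
        return float(np.mean([t.diastolic_pre for t in transients]))
    if trace is not None:
        return float(np.median(trace.samples))
    raise ContractError("no transients and no trace to take a baseline from")


def caffeine_response(
    trace: Trace,
    config: AnalysisConfig,
    convention: AmplitudeConvention = "raw",
) -> CaffeineResponse:
    """Caffeine-evoked (whole-SR-store) release amplitude.

    The peak is searched over ``caffeine_search_window_s`` (default 10 s)
    after the single ``caffeine_puff`` annotation; the reference level is the
    median over ``caffeine_baseline_window_s`` (default 2 s) immediately
    before the puff. ``convention="df_f0"`` normalises the difference to that
    baseline.
    """
    puffs = trace.annotations_of(AnnotationLabel.CAFFEINE_PUFF)
    if len(puffs) != 1:
        raise ProtocolError(
            f"expected exactly one caffeine_puff annotation, found {len(puffs)}"
        )
    t_caf = puffs[0].time
    raw = trace.samples
    i_caf = trace.index_of(t_caf)
    i0 = trace.index_of(max(t_caf - config.caffeine_baseline_window_s, trace.t0))
    if i_caf <= i0:
        raise ProtocolError("no pre-caffeine baseline samples")
    baseline = float(np.median(raw[i0:i_caf]))
    i_end = trace.index_of(min(t_caf + config.caffeine_search_window_s, trace.t_end))
    if i_end <= i_caf + 1:
        raise TruncationError("no samples after the caffeine puff")
    seg = raw[i_caf + 1: i_end + 1]
    peak_rel = int(np.argmax(seg))
    peak_val = float(seg[peak_rel])
    diff = peak_val - baseline
    if diff <= 0:
        raise SignalQualityError("no caffeine-evoked rise above baseline")
    amplitude = diff / baseline if convention == "df_f0" else diff
    return CaffeineResponse(
        caffeine_time=t_caf,
        peak_time=trace.t0 + (i_caf + 1 + peak_rel) * trace.dt,
        peak_amplitude=amplitude,
        baseline_pre=baseline,
        convention=convention,
    )


def fractional_release(
    transients: Sequence[CaTransient],
    caffeine: CaffeineResponse,
    config: AnalysisConfig,
) -> float:
    """Fractional SR Ca2+ release.

    Mean amplitude of the last ``n_last_transients`` pre-caffeine transients
    divided by the caffeine-evoked amplitude, both in the caffeine response's
    amplitude convention.
    """
    if caffeine.peak_amplitude <= 0:
        raise ContractError("caffeine amplitude must be positive")
    pre = [t for t in transients if t.peak_time < caffeine.caffeine_time]
    if not pre:
        raise ContractError("no spontaneous transients precede the caffeine puff")
    tail = pre[-config.n_last_transients:]
    if caffeine.convention == "df_f0":
        amps = [t.amplitude / t.diastolic_pre for t in tail]
    else:
        amps = [t.amplitude for t in tail]
    return float(np.mean(amps) / caffeine.peak_amplitude)


def classify_rhythm(
    transients: Sequence[CaTransient], config: AnalysisConfig
) -> RhythmClassification:
    """Two-axis CV classification of the release rhythm (R / Ra / I / Ia)."""
    n = len(transients)
    if n < config.min_transients:
        raise InsufficientDataError(
            f"need >= {config.min_transients} transients, got {n}", count=n
        )
    intervals = np.array(
        [t.interval_to_next for t in transients if t.interval_to_next is not None]
    )
    amps = np.array([t.amplitude for t in transients])
    cv_i = float(np.std(intervals, ddof=1) / np.mean(intervals))
    cv_a = float(np.std(amps, ddof=1) / np.mean(amps))
    irregular = cv_i > config.cv_interval_threshold
    varying = cv_a > config.cv_amplitude_threshold
    category = {(False, False): "R", (False, True): "Ra",
                (True, False): "I", (True, True): "Ia"}[(irregular, varying)]
    return RhythmClassification(
        category=category,
        cv_interval=cv_i,
        cv_amplitude=cv_a,
        n_transients=n,
        thresholds_used=(config.cv_interval_threshold, config.cv_amplitude_threshold),
    )
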