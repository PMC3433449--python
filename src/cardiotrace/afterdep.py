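"""Early/delayed afterdepolarization and burst-episode detection.

An afterdepolarization is a low-amplitude depolarizing deflection that either
interrupts phases 2-3 of the AP (an EAD, before repolarization completes) or
arises from the diastolic baseline after repolarization completes (a DAD).
Events are kept when their amplitude reaches ``ad_threshold_pct`` % (default
3%) of the preceding AP's amplitude. "Completion of repolarization" is
operationalised as the crossing of ``peak - repol_complete_fraction * APA``
(default 0.90, i.e. the APD90 level), a noise-robust surrogate for the return
to the diastolic potential.

Amplitude conventions: an EAD is measured from the local minimum that precedes
its peak on the repolarization limb (the deflection interrupts an otherwise
monotone decay); a DAD is measured from the diastolic baseline (median
potential over the central half of the diastole preceding the event). Extrema
are located on a smoothed copy and the amplitudes then read from the raw trace
around the located indices.

A burst episode is a maximal run of >= 2 rapid spontaneous upstrokes (cycle
length < 50% of the trace median) taking off from a diastolic potential
depolarized by >= 10 mV relative to the trace MDP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .ap_features import APFeatures, APFeatureSet
from .errors import ContractError, TruncationError
from .trace_io import AnalysisConfig, AnnotationLabel, Trace, smooth

logger = logging.getLogger(__name__)

__all__ = [
    "AfterdepEvent",
    "BurstEpisode",
    "repolarization_complete_time",
    "detect_afterdepolarizations",
    "detect_bursts",
]


@dataclass(frozen=True)
class AfterdepEvent:
    """A detected EAD or DAD with absolute and APA-relative amplitude."""

    type: str  # "EAD" | "DAD"
    parent_ap_index: int
    onset_time: float
    peak_time: float
    amplitude_mV: float
    relative_amplitude_pct: float
    takeoff_mV: float


@dataclass(frozen=True)
class BurstEpisode:
    """A run of rapid upstrokes from a depolarized diastolic potential."""

    start_time: float
    end_time: float
    mdp_mV: float
    max_upstroke_amplitude_mV: float
    n_upstrokes: int

    def __post_init__(self):
        if not self.end_time > self.start_time:
            raise ContractError("burst end must follow its start")
        if self.n_upstrokes < 2:
            raise ContractError("a burst needs >= 2 upstrokes")


def repolarization_complete_time(
    trace: Trace, ap: APFeatures, config: AnalysisConfig
) -> float:
    """First crossing of ``peak - repol_complete_fraction * APA`` after the peak.

    Linearly interpolated between samples. Raises :class:`TruncationError`
    when the trace ends before the level is reached.
    """
    x = smooth(trace.samples, config.smooth_samples(trace))
    dt = trace.dt
    peak = trace.index_of(ap.window.peak_time)
    level = ap.peak_mV - config.repol_complete_fraction * ap.apa_mV
    seg = x[peak:]
    below = np.flatnonzero(seg <= level)
    if below.size == 0:
        raise TruncationError(
            f"repolarization of AP at t={ap.activation_time:.3f} s truncated by trace end"
        )
    j = int(below[0])
    if j == 0:
        return trace.t0 + peak * dt
    i = peak + j
    frac = (x[i - 1] - level) / (x[i - 1] - x[i])
    return trace.t0 + (i - 1 + frac) * dt


def detect_afterdepolarizations(
    trace: Trace, features: APFeatureSet, config: AnalysisConfig
) -> list[AfterdepEvent]:
    """Detect EADs and DADs between each AP peak and the next activation.

    Candidates are local maxima of the smoothed trace in that span, each
    requiring a preceding local minimum (which excludes the repolarization
    trajectory itself). Events whose amplitude reaches
    ``ad_threshold_pct`` % of the parent APA are kept, typed by whether
    their onset precedes (EAD) or follows (DAD) the repolarization-completion
    time, and returned in time order. Events within ``pace_artifact_ms`` of a
    pacing annotation are discarded as stimulus artifacts.
    """
    if not features.aps:
        logger.info("no complete AP available; no afterdepolarization search")
        return []
    raw = trace.samples
    w = config.smooth_samples(trace)
    x = smooth(raw, w)
    dt = trace.dt
    n = raw.size
    pace_times = np.array(
        [a.time for a in trace.annotations_of(AnnotationLabel.PACE_PULSE)]
    )
    events: list[AfterdepEvent] = []
    aps = features.aps
    margin = max(int(round(2e-3 / dt)), 1)

    for i, ap in enumerate(aps):
        try:
            t_rc = repolarization_complete_time(trace, ap, config)
        except TruncationError:
            logger.info("AP %d: repolarization truncated; skipping its events", i)
            continue
        peak = trace.index_of(ap.window.peak_time)
        nxt = (trace.index_of(aps[i + 1].activation_time) - margin
               if i + 1 < len(aps) else n)
        seg_start = peak + margin
        if nxt - seg_start < 3:
            continue
        seg = x[seg_start:nxt]
        # candidates need a prominence well clear of smoothed noise but below
        # the reporting threshold, so borderline events are still measured
        prom_floor = max(0.6 * config.ad_threshold_pct / 100.0 * ap.apa_mV, 1e-9)
        cand, _ = find_peaks(seg, prominence=prom_floor)
        prev_cand = 0
        for c in cand:
            c_abs = seg_start + c
            # preceding minimum between the previous candidate (or the AP peak)
            # and this candidate, located on the smoothed trace
            lo = seg_start + prev_cand
            m_abs = lo + int(np.argmin(x[lo:c_abs])) if c_abs > lo else lo
            prev_cand = c
            # refine extrema on the raw trace around the located indices
            c_r = _refine(raw, c_abs, w, np.argmax)
            m_r = _refine(raw, m_abs, w, np.argmin)
            onset_t = trace.t0 + m_r * dt
            peak_t = trace.t0 + c_r * dt
            if onset_t <= ap.window.peak_time:
                continue
            if onset_t < t_rc:
                ev_type = "EAD"
                amplitude = float(raw[c_r] - raw[m_r])
                takeoff = float(raw[m_r])
            else:
                ev_type = "DAD"
                baseline = _diastolic_baseline(raw, trace, t_rc, onset_t)
                amplitude = float(raw[c_r] - baseline)
                takeoff = float(raw[m_r])
            rel = 100.0 * amplitude / ap.apa_mV
            if rel < config.ad_threshold_pct:
                continue
            if pace_times.size and np.min(
                np.abs(pace_times - peak_t)
            ) < config.pace_artifact_ms * 1e-3:
                continue
            events.append(
                AfterdepEvent(
                    type=ev_type,
                    parent_ap_index=i,
                    onset_time=onset_t,
                    peak_time=peak_t,
                    amplitude_mV=amplitude,
                    relative_amplitude_pct=rel,
                    takeoff_mV=takeoff,
                )
            )
    events.sort(key=lambda e: e.peak_time)
    return events


def _refine(raw: np.ndarray, idx: int, w: int, picker) -> int:
    lo = max(idx - w, 0)
    hi = min(idx + w + 1, raw.size)
    return lo + int(picker(raw[lo:hi]))


def _diastolic_baseline(raw: np.ndarray, trace: Trace, t_rc: float, t_onset: float
                        ) -> float:
    """Median potential over the central 50% of the diastole before the event."""
    span = t_onset - t_rc
    i0 = trace.index_of(t_rc + 0.25 * span)
    i1 = trace.index_of(t_rc + 0.75 * span)
    if i1 <= i0:
        i0, i1 = trace.index_of(t_rc), trace.index_of(t_onset)
    return float(np.median(raw[i0: i1 + 1]))


def detect_bursts(
    trace: Trace, features: APFeatureSet, config: AnalysisConfig
) -> list[BurstEpisode]:
    """Find maximal runs of rapid upstrokes from a depolarized diastole.

    A run qualifies when consecutive cycle lengths fall below 50% of the
    trace's median cycle length and every intra-run diastolic minimum stays
    >= 10 mV above the trace MDP. Reports the most negative diastolic
    potential within the run and the largest upstroke amplitude (peak minus
    the adjacent intra-run diastolic minimum).
    """
    aps = features.aps
    if len(aps) < 3:
        return []
    x = smooth(trace.samples, config.smooth_samples(trace))
    dt = trace.dt
    acts = np.array([ap.activation_time for ap in aps])
    peaks_mV = np.array([ap.peak_mV for ap in aps])
    cls = np.diff(acts)
    median_cl = float(np.median(cls))
    trace_mdp = float(min(min(ap.mdp_pre_mV, ap.mdp_post_mV) for ap in aps))

    def gap_min(k: int) -> float:
        """Minimum smoothed potential between upstrokes k and k+1."""
        i0 = trace.index_of(aps[k].window.peak_time)
        i1 = trace.index_of(acts[k + 1])
        return float(np.min(x[i0:i1])) if i1 > i0 else float(x[i0])

    short = cls < 0.5 * median_cl
    episodes: list[BurstEpisode] = []
    k = 0
    while k < short.size:
        if not short[k]:
            k += 1
            continue
        j = k
        while j < short.size and short[j] and gap_min(j) >= trace_mdp + 10.0:
            j += 1
        first, last = k, j  # upstrokes first..last inclusive form the run
        k = j + 1
        if last - first + 1 < 2:
            continue
        gap_mins = [gap_min(g) for g in range(first, last)]
        mdp_run = float(np.min(gap_mins))
        intra_cl = float(np.median(cls[first:last]))
        amps = []
        for u in range(first, last + 1):
            if u == first:
                ref = gap_mins[0]
            else:
                ref = gap_mins[u - 1 - first]
            amps.append(peaks_mV[u] - ref)
        episodes.append(
            BurstEpisode(
                start_time=float(acts[first]),
                end_time=float(acts[last] + intra_cl),
                mdp_mV=mdp_run,
                max_upstroke_amplitude_mV=float(np.max(amps)),
                n_upstrokes=last - first + 1,
            )
        )
    return episodes
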