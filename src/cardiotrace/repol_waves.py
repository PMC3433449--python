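"""T1/T2/U labelling of repolarization peaks on MAP/ECG beat sequences.

Within each beat's repolarization segment, up to three prominence-ranked
local maxima are retained (re-sorted by time). A peak counts as *merged* with
its predecessor when the valley between them rises above
``merge_valley_fraction`` (default 0.90) of the smaller peak height, heights
measured above the beat's diastolic baseline — a geometric proxy for two
waves visually fusing.

The first repolarization peak is always the T1 wave. The second-position
peak is labelled T2 when it merges with T1 in at least ``min_evidence`` beats
(default 1, i.e. "occasionally merges"), U when it never does; a third peak
is always a U wave. The T2/U distinction mirrors the cellular EAD/DAD
dichotomy: T2 waves ride on incomplete repolarization, U waves arise after it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .ap_features import APWindow
from .errors import ContractError
from .trace_io import AnalysisConfig, Trace, smooth

__all__ = ["BeatRepolPeaks", "WaveLabels", "detect_repol_peaks", "label_waves"]

#: dead time after the beat activation before repolarization peaks are sought
UPSTROKE_CLEARANCE_S = 0.025


@dataclass(frozen=True)
class RepolPeak:
    time: float
    height: float      # above the beat's diastolic baseline
    prominence: float
    merged_with_previous: bool


@dataclass(frozen=True)
class BeatRepolPeaks:
    beat_index: int
    peaks: tuple  # RepolPeak, time-ordered, at most 3


@dataclass(frozen=True)
class WaveLabels:
    """Per-position wave labels with merge evidence.

    ``labels[0]`` is always ``"T1"``; position 2 is ``"T2"`` iff its merge
    evidence count reaches ``min_evidence``; position 3 is always ``"U"``.
    """

    labels: tuple          # e.g. ("T1", "T2", "U")
    evidence: tuple        # beats in which that position merged with peak 1
    n_beats: int
    min_evidence: int = 1


def detect_repol_peaks(
    trace: Trace, beats: Sequence[APWindow], config: AnalysisConfig
) -> list[BeatRepolPeaks]:
    """Locate and flag repolarization peaks within each beat.

    ``beats`` come from :func:`cardiotrace.ap_features.detect_activations`
    (MAP input, typically with a lowered derivative threshold) or from
    externally provided onsets. Returns one record per beat; beats are
    processed independently.
    """
    if not beats:
        return []
    x = smooth(trace.samples, config.smooth_samples(trace))
    dt = trace.dt
    n = x.size
    sd = float(np.median(np.abs(np.diff(trace.samples))) / 0.9539)
    out: list[BeatRepolPeaks] = []
    for b, wdw in enumerate(beats):
        i0 = trace.index_of(wdw.activation_time + UPSTROKE_CLEARANCE_S)
        i1 = (trace.index_of(beats[b + 1].activation_time) - 2
              if b + 1 < len(beats) else n)
        seg = x[i0:i1]
        if seg.size < 5:
            out.append(BeatRepolPeaks(beat_index=b, peaks=()))
            continue
        baseline = float(np.percentile(seg, 10))
        span = float(np.max(seg) - baseline)
        prom = max(0.005 * span, 8.0 * sd, 1e-12)
        idx, props = find_peaks(seg, prominence=prom)
        if idx.size == 0:
            out.append(BeatRepolPeaks(beat_index=b, peaks=()))
            continue
        order = np.argsort(props["prominences"])[::-1][:3]
        keep = np.sort(idx[order])
        proms = {i: p for i, p in zip(idx, props["prominences"])}
        peaks: list[RepolPeak] = []
        for j, p in enumerate(keep):
            merged = False
            if j > 0:
                prev = keep[j - 1]
                valley = float(np.min(seg[prev: p + 1])) - baseline
                h_prev = float(seg[prev]) - baseline
                h_this = float(seg[p]) - baseline
                merged = valley > config.merge_valley_fraction * min(h_prev, h_this)
            peaks.append(
                RepolPeak(
                    time=trace.t0 + (i0 + p) * dt,
                    height=float(seg[p]) - baseline,
                    prominence=float(proms[p]),
                    merged_with_previous=merged,
                )
            )
        out.append(BeatRepolPeaks(beat_index=b, peaks=tuple(peaks)))
    return out


def label_waves(beats: Sequence[BeatRepolPeaks], min_evidence: int = 1) -> WaveLabels:
    """Assign T1/T2/U labels per peak position across beats.

    Beats with zero peaks are skipped; labelling is a pure function of the
    per-beat merged flags, so beat order is irrelevant.
    """
    populated = [b for b in beats if b.peaks]
    if not populated:
        raise ContractError("no beat contains a repolarization peak")
    n_positions = max(len(b.peaks) for b in populated)
    evidence = [0] * n_positions
    for b in populated:
        for j, pk in enumerate(b.peaks):
            if j > 0 and pk.merged_with_previous:
                evidence[j] += 1
    labels = ["T1"]
    if n_positions >= 2:
        labels.append("T2" if evidence[1] >= min_evidence else "U")
    if n_positions >= 3:
        labels.append("U")
    return WaveLabels(
        labels=tuple(labels),
        evidence=tuple(evidence[: len(labels)]),
        n_beats=len(populated),
        min_evidence=min_evidence,
    )
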