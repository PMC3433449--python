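"""Action-potential detection and feature extraction.

Detects upstrokes in membrane-potential (or MAP) traces and measures, per AP,
the maximum diastolic potential (MDP), AP amplitude (APA = peak - preceding
MDP), and AP durations at 50% and 90% repolarization (APD50/APD90, measured
from the activation time — the instant of maximum upstroke velocity — to the
linearly interpolated level crossing on the repolarization limb). Per trace it
reports the beating rate (BPM = 60 / mean cycle length) and a heuristic
ventricular-like flag.

Detection operates on a moving-average-smoothed copy of the trace, with the
upstroke velocity computed as a central difference spanning the smoothing
window; this keeps the derivative threshold meaningful in the presence of
realistic recording noise at 20 kHz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ContractError
from .trace_io import AnalysisConfig, Trace, TraceKind, smooth

logger = logging.getLogger(__name__)

__all__ = [
    "APWindow",
    "APFeatures",
    "APFeatureSet",
    "AdrenalineEffect",
    "detect_activations",
    "extract_ap_features",
    "summarize_adrenaline_effect",
    "windows_from_onsets",
]


@dataclass(frozen=True)
class APWindow:
    """One detected AP: activation, peak, and the enclosing MDP-to-MDP span."""

    activation_time: float  # max-upstroke-velocity time, s
    peak_time: float
    peak_mV: float
    window_start: float  # preceding MDP time, s
    window_end: float    # following MDP time, s

    def __post_init__(self):
        if not (self.window_start <= self.activation_time <= self.peak_time < self.window_end):
            raise ContractError("AP window times out of order")


@dataclass(frozen=True)
class APFeatures:
    """Per-AP feature record; durations are ``None`` when not measurable."""

    window: APWindow
    mdp_pre_mV: float
    mdp_post_mV: float
    apa_mV: float
    apd50_ms: Optional[float]
    apd90_ms: Optional[float]
    cycle_length_s: Optional[float]  # to the next activation; None for the last AP

    @property
    def activation_time(self) -> float:
        return self.window.activation_time

    @property
    def peak_mV(self) -> float:
        return self.window.peak_mV

    @property
    def complete(self) -> bool:
        return self.apd50_ms is not None and self.apd90_ms is not None


@dataclass(frozen=True)
class APFeatureSet:
    """Per-trace AP feature table.

    ``metadata`` records measurement conventions, notably that APD is
    referenced to the activation time (maximum dV/dt), not the AP peak.
    """

    aps: tuple
    bpm: Optional[float]
    ventricular_like: Optional[bool]
    notices: tuple = ()
    metadata: dict = field(default_factory=lambda: {"apd_reference": "activation_max_dvdt"})

    @property
    def complete_aps(self) -> tuple:
        return tuple(ap for ap in self.aps if ap.complete)

    def __len__(self) -> int:
        return len(self.aps)

    def _mean(self, attr: str) -> float:
        vals = [getattr(ap, attr) for ap in self.complete_aps]
        if not vals:
            raise ContractError(f"no complete APs to average {attr} over")
        return float(np.mean(vals))

    @property
    def mean_apd50_ms(self) -> float:
        return self._mean("apd50_ms")

    @property
    def mean_apd90_ms(self) -> float:
        return self._mean("apd90_ms")

    @property
    def mean_apa_mV(self) -> float:
        return self._mean("apa_mV")

    @property
    def mean_mdp_mV(self) -> float:
        return self._mean("mdp_pre_mV")


@dataclass(frozen=True)
class AdrenalineEffect:
    """Within-cell drug effect relative to the same cell's baseline."""

    bpm_pct_increase: float
    apd50_pct_decrease: float
    apd90_pct_decrease: float
    apa_delta_mV: float
    mdp_delta_mV: float


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _smoothed_and_derivative(trace: Trace, config: AnalysisConfig):
    """Smoothed signal and its central-difference velocity in mV/s."""
    w = config.smooth_samples(trace)
    x = smooth(trace.samples, w)
    span = max(w, 1)
    d = np.zeros_like(x)
    d[span:-span] = (x[2 * span:] - x[: -2 * span]) / (2 * span * trace.dt)
    return x, d, w


def detect_activations(trace: Trace, config: AnalysisConfig) -> list[APWindow]:
    """Locate AP upstrokes and their MDP-to-MDP windows.

    An upstroke fires where the smoothed velocity exceeds
    ``config.derivative_threshold`` (mV/ms) with a ``refractory_ms`` lockout;
    the activation time is the centre of the velocity maximum near the
    crossing. The MDP between consecutive upstrokes is the minimum of the
    smoothed trace. A trace with no suprathreshold upstroke yields an empty
    list.
    """
    if trace.kind not in (TraceKind.MEMBRANE_POTENTIAL, TraceKind.MAP, TraceKind.ECG):
        raise ContractError(f"cannot detect APs on a {trace.kind.value} trace")
    if trace.duration < 1.0:
        raise ContractError("trace shorter than 1 s")
    x, d, w = _smoothed_and_derivative(trace, config)
    thr = config.derivative_threshold * 1e3  # mV/ms -> mV/s
    above = d > thr
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    refractory = config.refractory_ms * 1e-3
    dt = trace.dt

    act_idx: list[int] = []
    last_t = -np.inf
    search = max(int(round(0.005 / dt)), 2)  # velocity max within 5 ms of crossing
    for e in edges:
        t_e = e * dt
        if t_e - last_t < refractory:
            continue
        hi = min(e + search, d.size)
        seg = d[e:hi]
        dmax = seg.max()
        plateau = np.flatnonzero(seg >= 0.995 * dmax)
        centre = e + int(round(0.5 * (plateau[0] + plateau[-1])))
        act_idx.append(centre)
        last_t = t_e
    if not act_idx:
        return []

    windows = []
    n = x.size
    for i, a in enumerate(act_idx):
        nxt = act_idx[i + 1] if i + 1 < len(act_idx) else n
        prev = act_idx[i - 1] if i > 0 else 0
        peak_rel = int(np.argmax(x[a:nxt]))
        peak = a + peak_rel
        mdp_pre = prev + int(np.argmin(x[prev:a])) if a > prev else prev
        # search the following MDP from the peak on, so a trace truncated
        # mid-AP ends its window at the trace end rather than mid-upstroke
        mdp_post = peak + 1 + int(np.argmin(x[peak + 1: nxt])) if nxt > peak + 1 else n - 1
        windows.append(
            APWindow(
                activation_time=trace.t0 + a * dt,
                peak_time=trace.t0 + peak * dt,
                peak_mV=float(x[peak]),
                window_start=trace.t0 + mdp_pre * dt,
                window_end=trace.t0 + min(mdp_post, n - 1) * dt,
            )
        )
    return windows


def windows_from_onsets(trace: Trace, onsets: Sequence[float]) -> list[APWindow]:
    """Build beat windows from externally supplied onsets (ECG-style input)."""
    onsets = sorted(onsets)
    out = []
    for i, s in enumerate(onsets):
        end = onsets[i + 1] if i + 1 < len(onsets) else trace.t_end
        out.append(
            APWindow(
                activation_time=s,
                peak_time=s,
                peak_mV=float(trace.samples[trace.index_of(s)]),
                window_start=s,
                window_end=end,
            )
        )
    return out


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _crossing_time(x: np.ndarray, dt: float, start: int, stop: int, level: float
                   ) -> Optional[float]:
    """First downward crossing of ``level`` in ``x[start:stop]``, interpolated."""
    seg = x[start:stop]
    below = np.flatnonzero(seg <= level)
    if below.size == 0:
        return None
    j = below[0]
    if j == 0:
        return start * dt
    i = start + j
    frac = (x[i - 1] - level) / (x[i - 1] - x[i])
    return (i - 1 + frac) * dt


def extract_ap_features(
    trace: Trace, windows: Sequence[APWindow], config: AnalysisConfig
) -> APFeatureSet:
    """Measure per-AP features and the trace BPM.

    APD_f is the time from activation to the first crossing of
    ``peak - f * APA`` on the repolarization limb, linearly interpolated
    between samples. APs whose repolarization never reaches the level inside
    their window (e.g. truncated by the trace end) keep ``None`` durations
    and are excluded from averages, with a logged notice.
    """
    if not windows:
        return APFeatureSet(aps=(), bpm=None, ventricular_like=None,
                            notices=("no APs detected",))
    if any(b.activation_time <= a.activation_time for a, b in zip(windows, windows[1:])):
        raise ContractError("AP windows out of order")
    x = smooth(trace.samples, config.smooth_samples(trace))
    dt = trace.dt
    notices: list[str] = []
    aps: list[APFeatures] = []
    for i, wdw in enumerate(windows):
        a = trace.index_of(wdw.activation_time)
        peak = trace.index_of(wdw.peak_time)
        start = trace.index_of(wdw.window_start)
        end = trace.index_of(wdw.window_end)
        mdp_pre = float(x[start])
        mdp_post = float(x[end])
        apa = wdw.peak_mV - mdp_pre
        durations = {}
        for f in (0.50, 0.90):
            level = wdw.peak_mV - f * apa
            t_cross = _crossing_time(x, dt, peak, end + 1, level)
            if t_cross is None:
                durations[f] = None
            else:
                durations[f] = (t_cross - (a * dt)) * 1e3
        if durations[0.50] is None or durations[0.90] is None:
            msg = (f"AP {i}: repolarization does not reach the APD level inside "
                   f"its window (truncated?); durations omitted")
            notices.append(msg)
            logger.info(msg)
        cl = (windows[i + 1].activation_time - wdw.activation_time
              if i + 1 < len(windows) else None)
        aps.append(
            APFeatures(
                window=wdw,
                mdp_pre_mV=mdp_pre,
                mdp_post_mV=mdp_post,
                apa_mV=float(apa),
                apd50_ms=durations[0.50],
                apd90_ms=durations[0.90],
                cycle_length_s=cl,
            )
        )
    cls = [ap.cycle_length_s for ap in aps if ap.cycle_length_s is not None]
    bpm = 60.0 / float(np.mean(cls)) if len(windows) >= 2 and cls else None
    ventricular = _ventricular_like(trace, x, aps)
    return APFeatureSet(aps=tuple(aps), bpm=bpm, ventricular_like=ventricular,
                        notices=tuple(notices))


def _ventricular_like(trace: Trace, x: np.ndarray, aps: Sequence[APFeatures]
                      ) -> Optional[bool]:
    """Heuristic subtype flag: modest APD90/APD50 ratio plus a plateau.

    Ventricular-like APs have a discernible plateau, so time spent above
    ``peak - 0.3 APA`` is an appreciable fraction of APD90 and APD90/APD50
    stays below 2. Heuristic only; excluded from quantitative claims.
    """
    complete = [ap for ap in aps if ap.complete]
    if not complete:
        return None
    ratios = [ap.apd90_ms / ap.apd50_ms for ap in complete]
    if float(np.mean(ratios)) >= 2.0:
        return False
    dt = trace.dt
    fracs = []
    for ap in complete:
        peak = trace.index_of(ap.window.peak_time)
        end = trace.index_of(ap.window.window_end)
        level = ap.peak_mV - 0.3 * ap.apa_mV
        above = np.count_nonzero(x[peak:end] > level) * dt * 1e3
        fracs.append(above / ap.apd90_ms)
    return float(np.mean(fracs)) > 0.15


def summarize_adrenaline_effect(
    baseline: APFeatureSet, drug: APFeatureSet
) -> AdrenalineEffect:
    """Within-cell percent/delta changes of the drug trace vs baseline.

    Percent changes are relative to the baseline mean of the same cell;
    APA and MDP are reported as absolute drug-minus-baseline deltas (mV).
    """
    for name, fs in (("baseline", baseline), ("drug", drug)):
        if not fs.complete_aps:
            raise ContractError(f"{name} feature set is empty")
    if baseline.bpm is None or drug.bpm is None:
        raise ContractError("both conditions need >= 2 beats for a BPM")
    if baseline.bpm == 0:
        raise ContractError("baseline BPM is zero; percent change undefined")
    return AdrenalineEffect(
        bpm_pct_increase=100.0 * (drug.bpm - baseline.bpm) / baseline.bpm,
        apd50_pct_decrease=100.0
        * (baseline.mean_apd50_ms - drug.mean_apd50_ms)
        / baseline.mean_apd50_ms,
        apd90_pct_decrease=100.0
        * (baseline.mean_apd90_ms - drug.mean_apd90_ms)
        / baseline.mean_apd90_ms,
        apa_delta_mV=drug.mean_apa_mV - baseline.mean_apa_mV,
        mdp_delta_mV=drug.mean_mdp_mV - baseline.mean_mdp_mV,
    )
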