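"""Trace data model, delimited-text I/O and analysis configuration.

A :class:`Trace` is a uniformly sampled time series — membrane potential in mV
(patch-clamp or monophasic-AP catheter) or Fura-2 fluorescence (single channel
or 340/380 ratio) — with protocol annotations (pacing pulses, drug application,
caffeine puffs). Traces live on disk as two-column delimited text
(``time_s,value``) with an optional ``<stem>.events`` sidecar holding the
annotations, so that any plotting or acquisition tool can read them.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterError, SamplingError, TraceFormatError

__all__ = [
    "TraceKind",
    "AnnotationLabel",
    "Annotation",
    "Trace",
    "AnalysisConfig",
    "read_trace",
    "write_trace",
]

#: relative tolerance on inter-sample spacing before a file is rejected
UNIFORMITY_RTOL = 1e-6

EVENTS_SUFFIX = ".events"


class TraceKind(str, Enum):
    MEMBRANE_POTENTIAL = "membrane_potential"
    FLUORESCENCE_340 = "fluorescence_340"
    FLUORESCENCE_380 = "fluorescence_380"
    FLUORESCENCE_RATIO = "fluorescence_ratio"
    MAP = "map"
    ECG = "ecg"


#: kinds carrying a voltage in mV
VOLTAGE_KINDS = frozenset({TraceKind.MEMBRANE_POTENTIAL, TraceKind.MAP, TraceKind.ECG})


class AnnotationLabel(str, Enum):
    PACE_PULSE = "pace_pulse"
    DRUG_ON = "drug_on"
    DRUG_OFF = "drug_off"
    CAFFEINE_PUFF = "caffeine_puff"
    CUSTOM = "custom"


@dataclass(frozen=True)
class Annotation:
    """A timestamped protocol event (time in seconds from the trace origin)."""

    time: float
    label: AnnotationLabel
    payload: str = ""

    def __post_init__(self):
        object.__setattr__(self, "label", AnnotationLabel(self.label))
        if self.label is AnnotationLabel.CUSTOM and not self.payload:
            raise ParameterError("custom annotations must carry a payload")


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled signal with protocol annotations.

    Parameters
    ----------
    id
        Free-form identifier (cell / recording name).
    kind
        Signal modality; immutable after construction.
    t0
        Time of the first sample, seconds.
    dt
        Sampling interval, seconds (strictly positive).
    samples
        Signal values; mV for voltage kinds, instrument units otherwise.
    annotations
        Protocol events; every time must fall inside the sampled span.
    """

    id: str
    kind: TraceKind
    t0: float
    dt: float
    samples: np.ndarray
    annotations: tuple[Annotation, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "kind", TraceKind(self.kind))
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ParameterError("a trace needs a 1-D sample array of length >= 2")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)
        if not (self.dt > 0) or not math.isfinite(self.dt):
            raise ParameterError(f"dt must be finite and > 0, got {self.dt}")
        anns = tuple(sorted(self.annotations, key=lambda a: a.time))
        t_end = self.t0 + (samples.size - 1) * self.dt
        for a in anns:
            if not (self.t0 <= a.time <= t_end + 0.5 * self.dt):
                raise ParameterError(
                    f"annotation at t={a.time} s outside trace span "
                    f"[{self.t0}, {t_end}] s"
                )
        object.__setattr__(self, "annotations", anns)

    # -- convenience ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (self.n - 1) * self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def index_of(self, t: float) -> int:
        """Nearest sample index to time ``t`` (clipped to the trace)."""
        return int(np.clip(round((t - self.t0) / self.dt), 0, self.n - 1))

    def annotations_of(self, label: AnnotationLabel | str) -> list[Annotation]:
        label = AnnotationLabel(label)
        return [a for a in self.annotations if a.label is label]

    def with_samples(self, samples: np.ndarray) -> "Trace":
        return dataclasses.replace(self, samples=samples)


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters in one serialisable object.

    Attributes
    ----------
    ad_threshold_pct
        Minimum afterdepolarization amplitude as % of the preceding AP
        amplitude (the classification threshold; default 3.0).
    repol_complete_fraction
        Fraction of APA that defines "completion of repolarization"
        (0.90 = the APD90 level).
    derivative_threshold
        Upstroke detection threshold, mV/ms.
    refractory_ms
        Lockout after a detected upstroke, ms.
    smooth_window_ms
        Moving-average window for voltage traces, ms.
    ratio_smooth_samples
        Moving-average window for fluorescence-ratio traces, samples.
    cv_interval_threshold / cv_amplitude_threshold
        Coefficient-of-variation boundaries of the rhythm taxonomy.
    min_transients
        Minimum number of transients required for rhythm classification.
    n_last_transients
        Pre-caffeine transients averaged for fractional release.
    merge_valley_fraction
        A repolarization peak counts as merged with its predecessor when the
        inter-peak valley exceeds this fraction of the smaller peak height.
    """

    ad_threshold_pct: float = 3.0
    repol_complete_fraction: float = 0.90
    derivative_threshold: float = 5.0
    refractory_ms: float = 100.0
    smooth_window_ms: float = 2.0
    ratio_smooth_samples: int = 3
    cv_interval_threshold: float = 0.15
    cv_amplitude_threshold: float = 0.15
    min_transients: int = 5
    n_last_transients: int = 3
    merge_valley_fraction: float = 0.90
    caffeine_search_window_s: float = 10.0
    caffeine_baseline_window_s: float = 2.0
    pace_artifact_ms: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not self.ad_threshold_pct > 0:
            raise ParameterError("ad_threshold_pct must be > 0")
        if not (0 < self.repol_complete_fraction <= 1):
            raise ParameterError("repol_complete_fraction must lie in (0, 1]")
        for name in (
            "derivative_threshold",
            "refractory_ms",
            "smooth_window_ms",
            "cv_interval_threshold",
            "cv_amplitude_threshold",
            "merge_valley_fraction",
            "caffeine_search_window_s",
            "caffeine_baseline_window_s",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.ratio_smooth_samples < 1:
            raise ParameterError("ratio_smooth_samples must be >= 1")
        if self.min_transients < 2:
            raise ParameterError("min_transients must be >= 2")
        if self.n_last_transients < 1:
            raise ParameterError("n_last_transients must be >= 1")

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def smooth_samples(self, trace: Trace) -> int:
        """Smoothing window in samples for this trace's modality."""
        if trace.kind in VOLTAGE_KINDS:
            w = int(round(self.smooth_window_ms * 1e-3 / trace.dt))
            if w < 1:
                raise ConfigurationError(
                    f"smooth_window_ms={self.smooth_window_ms} ms is below one "
                    f"sample at dt={trace.dt} s"
                )
            return w
        return int(self.ratio_smooth_samples)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _events_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + EVENTS_SUFFIX) if path.suffix == "" else path.parent / (path.stem + EVENTS_SUFFIX)


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_trace(path: str | Path, kind: TraceKind | str) -> Trace:
    """Read a two-column delimited trace file (``time_s,value``).

    The delimiter (comma or tab) is sniffed from the first line and a single
    header row is tolerated. ``dt`` is inferred from the median inter-sample
    interval; spacing must be uniform within ``UNIFORMITY_RTOL`` relative
    tolerance. A sidecar ``<stem>.events`` file (``time_s,label,payload``) is
    loaded when present.
    """
    path = Path(path)
    kind = TraceKind(kind)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise TraceFormatError(f"{path}: empty file")
    delim = _sniff_delimiter(first)

    def _is_header(line: str) -> bool:
        fields = line.strip().split(delim)
        try:
            [float(f) for f in fields]
            return False
        except ValueError:
            return True

    try:
        frame = pd.read_csv(
            path,
            sep=delim,
            header=0 if _is_header(first) else None,
            comment="#",
            dtype=float,
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise TraceFormatError(f"{path}: unparseable numeric data ({exc})") from exc
    if frame.shape[1] != 2:
        raise TraceFormatError(f"{path}: expected 2 columns, found {frame.shape[1]}")
    if len(frame) < 2:
        raise TraceFormatError(f"{path}: fewer than 2 samples")
    t = frame.iloc[:, 0].to_numpy()
    v = frame.iloc[:, 1].to_numpy()
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
        raise TraceFormatError(f"{path}: non-finite values")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise SamplingError(f"{path}: time column is not strictly increasing")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > UNIFORMITY_RTOL * dt:
        raise SamplingError(
            f"{path}: non-uniform sampling (max deviation "
            f"{np.max(np.abs(dts - dt)):.3g} s vs dt={dt:.3g} s)"
        )
    annotations = _read_events(_events_path(path))
    return Trace(id=path.stem, kind=kind, t0=float(t[0]), dt=dt, samples=v,
                 annotations=annotations)


def _read_events(path: Path) -> tuple[Annotation, ...]:
    if not path.exists():
        return ()
    anns: list[Annotation] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("time_s"):
            continue
        delim = _sniff_delimiter(line)
        parts = line.split(delim)
        if len(parts) < 2:
            raise TraceFormatError(f"{path}: bad annotation row {line!r}")
        payload = delim.join(parts[2:]) if len(parts) > 2 else ""
        try:
            anns.append(Annotation(float(parts[0]), AnnotationLabel(parts[1]), payload))
        except ValueError as exc:
            raise TraceFormatError(f"{path}: bad annotation row {line!r}") from exc
    return tuple(anns)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as comma-delimited text at full float precision.

    Annotations, when present, go to the ``<stem>.events`` sidecar; a trace
    without annotations produces no sidecar (and removes a stale one).
    """
    path = Path(path)
    t = trace.times()
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")
    ev = _events_path(path)
    if trace.annotations:
        with open(ev, "w") as fh:
            fh.write("time_s,label,payload\n")
            for a in trace.annotations:
                fh.write(f"{float(a.time)!r},{a.label.value},{a.payload}\n")
    elif ev.exists():
        ev.unlink()


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge replication; window in samples."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    from scipy.ndimage import uniform_filter1d

    window = int(window)
    if window % 2 == 0:
        window += 1  # odd window keeps the filter centred (no half-sample lag)
    return uniform_filter1d(np.asarray(values, dtype=float), size=window,
                            mode="nearest")
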