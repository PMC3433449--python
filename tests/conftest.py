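import numpy as np
import pytest

from cardiotrace import (
    AnalysisConfig,
    APTrainParams,
    Trace,
    TraceKind,
    detect_activations,
    extract_ap_features,
    generate_ap_train,
)

#: AP feature values of the healthy-control cell line during regular beating
CONTROL_ROW = dict(bpm=41.0, apd50_ms=204.4, apd90_ms=329.7, apa_mV=117.85, mdp_mV=-68.35)
#: and of the RyR2-mutant (CPVT) line
CPVT_ROW = dict(bpm=43.0, apd50_ms=238.6, apd90_ms=305.4, apa_mV=114.80, mdp_mV=-67.55)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def control_params():
    return APTrainParams(n_beats=10, **CONTROL_ROW)


def analyze_train(params, events=(), config=None):
    """Generate an AP train and run the full feature pipeline on it."""
    config = config or AnalysisConfig()
    trace, truth = generate_ap_train(params, events)
    windows = detect_activations(trace, config)
    features = extract_ap_features(trace, windows, config)
    return trace, truth, windows, features


@pytest.fixture
def linear_ap_trace():
    """Idealised AP: instantaneous upstroke to +30 mV at t=0.3 s, linear fall
    to -70 mV over 300 ms, then flat diastole. APD50/APD90 are exactly
    150/270 ms by similar triangles."""
    dt = 1e-4
    t = np.arange(0, 1.2, dt)
    v = np.full(t.size, -70.0)
    jump = 0.3
    ramp = (t >= jump) & (t < jump + 0.3)
    v[ramp] = 30.0 - 100.0 * (t[ramp] - jump) / 0.3
    return Trace(id="linear_ap", kind=TraceKind.MEMBRANE_POTENTIAL, t0=0.0, dt=dt, samples=v)
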