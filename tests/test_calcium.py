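import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiotrace import (
    AnalysisConfig,
    CaTrainParams,
    CaTransient,
    Trace,
    TraceKind,
    caffeine_response,
    classify_rhythm,
    compute_ratio,
    detect_transients,
    diastolic_level,
    fractional_release,
    generate_ca_train,
)
from cardiotrace.errors import (
    AlignmentError,
    ContractError,
    InsufficientDataError,
    ProtocolError,
    SignalQualityError,
    TruncationError,
)


def ratio_trace(samples, dt=0.05, annotations=()):
    return Trace(id="ca", kind=TraceKind.FLUORESCENCE_RATIO, t0=0.0, dt=dt,
                 samples=np.asarray(samples, float), annotations=annotations)


def make_transient(amplitude=0.5, dia=1.0, onset=0.0, interval=2.0):
    return CaTransient(onset_time=onset, peak_time=onset + 0.16, amplitude=amplitude,
                       diastolic_pre=dia, interval_to_next=interval)


class TestComputeRatio:
    def channel(self, samples, kind):
        return Trace(id="f", kind=kind, t0=0.0, dt=0.05,
                     samples=np.asarray(samples, float))

    def test_identical_channels_give_unit_ratio(self):
        f = np.full(50, 3.0)
        r = compute_ratio(self.channel(f, TraceKind.FLUORESCENCE_340),
                          self.channel(f, TraceKind.FLUORESCENCE_380), 0.0, 0.0)
        assert r.kind is TraceKind.FLUORESCENCE_RATIO
        np.testing.assert_allclose(r.samples, 1.0)

    def test_background_equal_to_signal_rejected(self):
        f = np.full(50, 3.0)
        with pytest.raises(SignalQualityError):
            compute_ratio(self.channel(f, TraceKind.FLUORESCENCE_340),
                          self.channel(f, TraceKind.FLUORESCENCE_380), 3.0, 3.0)

    def test_misaligned_channels_rejected(self):
        a = self.channel(np.ones(50), TraceKind.FLUORESCENCE_340)
        b = self.channel(np.ones(40), TraceKind.FLUORESCENCE_380)
        with pytest.raises(AlignmentError):
            compute_ratio(a, b, 0.0, 0.0)

    def test_inverse_construction_recovers_known_ratio(self):
        """Channels built from a known ratio trace reconstruct it exactly."""
        known, _ = generate_ca_train(CaTrainParams(n_transients=5))
        bg340, bg380 = 50.0, 30.0
        f380 = np.full(known.n, 200.0)
        f340 = known.samples * (f380 - bg380) + bg340
        r = compute_ratio(
            Trace(id="a", kind=TraceKind.FLUORESCENCE_340, t0=0.0, dt=known.dt, samples=f340),
            Trace(id="b", kind=TraceKind.FLUORESCENCE_380, t0=0.0, dt=known.dt, samples=f380),
            bg340, bg380)
        np.testing.assert_allclose(r.samples, known.samples, atol=1e-9)


class TestDetectTransients:
    def test_flat_trace_yields_nothing(self, config):
        assert detect_transients(ratio_trace(np.ones(400)), config) == []

    def test_flat_noisy_trace_yields_nothing(self, config):
        rng = np.random.default_rng(0)
        tr = ratio_trace(1.0 + rng.normal(0, 0.01, 600))
        assert detect_transients(tr, config) == []

    def test_noise_free_train_fully_recovered(self, config):
        trace, truth = generate_ca_train(CaTrainParams(n_transients=10))
        ts = detect_transients(trace, config)
        assert len(ts) == 10
        for t, onset, amp in zip(ts, truth.transient_onsets, truth.transient_amplitudes):
            assert abs(t.onset_time - onset) <= trace.dt + 1e-9
            assert t.amplitude == pytest.approx(amp, rel=0.03)

    def test_caffeine_epoch_excluded_from_spontaneous_count(self, config):
        trace, _ = generate_ca_train(
            CaTrainParams(n_transients=8, caffeine_time_s=22.0, caffeine_amplitude=2.0))
        ts = detect_transients(trace, config)
        assert len(ts) == 8
        assert all(t.peak_time < 22.0 for t in ts)

    def test_detection_count_over_rate_range(self, config):
        """Noise-free trains at physiological spontaneous rates are counted
        exactly at the 20 Hz camera rate."""
        for rate in (0.2, 0.5, 1.0, 2.0):
            trace, truth = generate_ca_train(
                CaTrainParams(n_transients=8, rate_hz=rate, seed=2))
            assert len(detect_transients(trace, config)) == 8, rate


class TestDiastolicAndCaffeine:
    def test_trivial_mean(self):
        ts = [make_transient(dia=1.0) for _ in range(4)]
        assert diastolic_level(ts) == 1.0

    def test_drifting_baseline_recovered(self, config):
        drift = 0.005
        trace, truth = generate_ca_train(
            CaTrainParams(n_transients=10, diastolic_drift_per_s=drift))
        ts = detect_transients(trace, config)
        expected = 1.0 + drift * np.mean([t.onset_time for t in ts])
        assert diastolic_level(ts) == pytest.approx(expected, rel=0.02)

    def test_elevated_diastole_scenario_differs_by_20_percent(self, config):
        def level(dia):
            trace, _ = generate_ca_train(
                CaTrainParams(n_transients=10, diastolic_level=dia))
            return diastolic_level(detect_transients(trace, config))

        assert level(1.2) / level(1.0) == pytest.approx(1.2, abs=0.024)

    def test_caffeine_amplitude_recovered_within_1_percent(self, config):
        trace, _ = generate_ca_train(
            CaTrainParams(n_transients=10, caffeine_time_s=26.0, caffeine_amplitude=2.0))
        caff = caffeine_response(trace, config)
        assert caff.peak_amplitude == pytest.approx(2.0, rel=0.01)

    def test_missing_caffeine_annotation_is_protocol_error(self, config):
        trace, _ = generate_ca_train(CaTrainParams(n_transients=5))
        with pytest.raises(ProtocolError):
            caffeine_response(trace, config)

    def test_caffeine_at_last_sample_is_truncation_error(self, config):
        from cardiotrace import Annotation

        n = 400
        tr = ratio_trace(np.ones(n), annotations=(
            Annotation((n - 1) * 0.05, "caffeine_puff"),))
        with pytest.raises(TruncationError):
            caffeine_response(tr, config)


class TestFractionalRelease:
    def make_caffeine(self, amp, convention="raw"):
        from cardiotrace.calcium import CaffeineResponse

        return CaffeineResponse(caffeine_time=30.0, peak_time=30.5,
                                peak_amplitude=amp, baseline_pre=1.0,
                                convention=convention)

    def test_half_amplitude_ratio(self, config):
        ts = [make_transient(amplitude=0.5, onset=2.0 * k) for k in range(5)]
        assert fractional_release(ts, self.make_caffeine(1.0), config) == pytest.approx(0.5)

    def test_equal_amplitudes_give_unity(self, config):
        ts = [make_transient(amplitude=1.3, onset=2.0 * k) for k in range(5)]
        assert fractional_release(ts, self.make_caffeine(1.3), config) == pytest.approx(1.0)

    def test_leak_scenario_raises_release_by_inverse_factor(self, config):
        """Reducing the caffeine-releasable store by 40% at unchanged
        transient amplitude raises fractional release by exactly 1/0.6."""
        def frac(caff_amp):
            trace, _ = generate_ca_train(
                CaTrainParams(n_transients=10, caffeine_time_s=26.0,
                              caffeine_amplitude=caff_amp))
            ts = detect_transients(trace, config)
            return fractional_release(ts, caffeine_response(trace, config), config)

        assert frac(0.9) / frac(1.5) == pytest.approx(1 / 0.6, rel=0.03)

    def test_convention_invariance_with_shared_baseline(self, config):
        """Switching numerator and denominator together between raw and
        dF/F0 leaves fractional release unchanged when both share the same
        pre-event baseline."""
        dia = 1.25
        ts = [make_transient(amplitude=0.5, dia=dia, onset=2.0 * k) for k in range(5)]
        raw = fractional_release(ts, self.make_caffeine(2.0), config)
        from cardiotrace.calcium import CaffeineResponse

        caff_norm = CaffeineResponse(caffeine_time=30.0, peak_time=30.5,
                                     peak_amplitude=2.0 / dia, baseline_pre=dia,
                                     convention="df_f0")
        assert fractional_release(ts, caff_norm, config) == pytest.approx(raw, rel=1e-12)

    def test_no_pre_caffeine_transients_rejected(self, config):
        with pytest.raises(ContractError):
            fractional_release([], self.make_caffeine(1.0), config)


class TestClassifyRhythm:
    def from_cvs(self, cv_i, cv_a, config, n=12, seed=0):
        rng = np.random.default_rng(seed)
        intervals = np.clip(rng.normal(2.0, 2.0 * cv_i, n), 0.3, None)
        amps = np.clip(rng.normal(0.5, 0.5 * cv_a, n), 0.05, None)
        ts = []
        t = 0.0
        for k in range(n):
            ts.append(CaTransient(onset_time=t, peak_time=t + 0.16,
                                  amplitude=float(amps[k]), diastolic_pre=1.0,
                                  interval_to_next=float(intervals[k]) if k < n - 1 else None))
            t += intervals[k]
        return classify_rhythm(ts, config)

    @pytest.mark.parametrize("cv_i,cv_a,want", [
        (0.02, 0.02, "R"), (0.02, 0.45, "Ra"), (0.45, 0.02, "I"), (0.45, 0.45, "Ia"),
    ])
    def test_four_categories(self, config, cv_i, cv_a, want):
        assert self.from_cvs(cv_i, cv_a, config).category == want

    def test_too_few_transients_signalled_with_count(self, config):
        ts = [make_transient(onset=2.0 * k) for k in range(3)]
        with pytest.raises(InsufficientDataError) as exc:
            classify_rhythm(ts, config)
        assert exc.value.count == 3

    def test_time_rescaling_invariance(self, config):
        """Uniformly stretching all intervals leaves the category unchanged
        (CV is scale-free)."""
        base = self.from_cvs(0.3, 0.02, config, seed=4)
        ts = [make_transient(amplitude=0.5, onset=10.0 * k, interval=10.0 * (1 + 0.3 * (-1) ** k))
              for k in range(8)]
        scaled = [dataclasses.replace(t, interval_to_next=t.interval_to_next * 7)
                  for t in ts]
        assert (classify_rhythm(ts, config).category
                == classify_rhythm(scaled, config).category == base.category)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(cv_i=st.floats(0.0, 0.6), cv_a=st.floats(0.0, 0.6))
    def test_category_matches_two_axis_rule(self, cv_i, cv_a):
        """The reported category is a pure function of the measured CVs and
        the configured thresholds."""
        res = self.from_cvs(cv_i, cv_a, AnalysisConfig(), seed=9)
        want = {(False, False): "R", (False, True): "Ra",
                (True, False): "I", (True, True): "Ia"}[
            (res.cv_interval > 0.15, res.cv_amplitude > 0.15)]
        assert res.category == want
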