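import numpy as np
import pytest

from cardiotrace import (
    APTrainParams,
    EventSpec,
    detect_afterdepolarizations,
    detect_bursts,
    generate_ap_train,
    repolarization_complete_time,
)
from cardiotrace._waveform import T_HALF_UP, fit_repolarization, repol_crossing_time
from cardiotrace.errors import TruncationError

from conftest import analyze_train


class TestRepolarizationCompleteTime:
    def test_linear_repolarization_fraction_090(self, linear_ap_trace, config):
        """+30 to -70 mV linearly over 300 ms: the 90% level sits at 270 ms."""
        from cardiotrace import detect_activations, extract_ap_features

        windows = detect_activations(linear_ap_trace, config)
        fs = extract_ap_features(linear_ap_trace, windows, config)
        t_rc = repolarization_complete_time(linear_ap_trace, fs.aps[0], config)
        assert (t_rc - fs.aps[0].window.peak_time) * 1e3 == pytest.approx(270.0, abs=3.0)

    def test_linear_repolarization_fraction_one(self, linear_ap_trace, config):
        from cardiotrace import detect_activations, extract_ap_features

        cfg = config.replace(repol_complete_fraction=1.0)
        windows = detect_activations(linear_ap_trace, cfg)
        fs = extract_ap_features(linear_ap_trace, windows, cfg)
        t_rc = repolarization_complete_time(linear_ap_trace, fs.aps[0], cfg)
        assert (t_rc - fs.aps[0].window.peak_time) * 1e3 == pytest.approx(300.0, abs=3.0)

    def test_matches_analytic_root_of_template(self, control_params, config):
        """On the generated double-logistic AP, the measured completion time
        agrees with the closed-form root solved by bisection on the template
        itself (an independent oracle)."""
        trace, truth, windows, fs = analyze_train(control_params)
        fit = fit_repolarization(0.2044, 0.3297)
        t_expected = repol_crossing_time(fit, 0.1, 0.8) - T_HALF_UP
        ap = fs.aps[2]
        t_rc = repolarization_complete_time(trace, ap, config)
        assert (t_rc - ap.activation_time) == pytest.approx(t_expected, abs=1e-3)

    def test_truncated_repolarization_signalled(self, config):
        from cardiotrace import Trace, detect_activations, extract_ap_features

        p = APTrainParams(n_beats=2, dt_s=1e-4)
        trace, _ = generate_ap_train(p)
        cut = trace.index_of(60 / p.bpm + 0.15 + 0.150)
        clipped = Trace(id="cut", kind=trace.kind, t0=0.0, dt=trace.dt,
                        samples=trace.samples[:cut])
        windows = detect_activations(clipped, config)
        fs = extract_ap_features(clipped, windows, config)
        with pytest.raises(TruncationError):
            repolarization_complete_time(clipped, fs.aps[-1], config)


def detect_events(pct, ev_type, offset, config, n_beats=4, **kw):
    ev = EventSpec(type=ev_type, beat_index=1, relative_amplitude_pct=pct,
                   offset_fraction=offset, **kw)
    _, _, _, fs = None, None, None, None
    trace, truth, windows, fs = analyze_train(APTrainParams(n_beats=n_beats), [ev], config)
    return detect_afterdepolarizations(trace, fs, config), truth


class TestAfterdepDetection:
    def test_clean_train_has_no_events(self, control_params, config):
        trace, _, _, fs = analyze_train(control_params)
        assert detect_afterdepolarizations(trace, fs, config) == []

    def test_dad_threshold_is_sharp_at_3_percent(self, config):
        below, _ = detect_events(2.9, "DAD", 0.5, config)
        above, _ = detect_events(3.1, "DAD", 0.5, config)
        assert below == []
        assert len(above) == 1 and above[0].type == "DAD"
        assert above[0].relative_amplitude_pct == pytest.approx(3.1, abs=0.01)

    def test_ead_at_10_percent_on_phase3_limb(self, config):
        events, truth = detect_events(10.0, "EAD", 0.65, config)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "EAD"
        assert ev.relative_amplitude_pct == pytest.approx(10.0, abs=0.5)
        # takeoff above the APD90 level: repolarization not yet complete
        assert ev.takeoff_mV > -68.35 + 0.1 * 117.85 - 1.0
        assert ev.onset_time == pytest.approx(truth.events[0].onset_time, abs=2e-3)

    def test_event_phase_constraints_hold(self, config):
        """Every reported event satisfies its phase window: EAD onsets before,
        DAD onsets after, the repolarization-completion time."""
        evs = [EventSpec(type="EAD", beat_index=1, relative_amplitude_pct=8.0,
                         offset_fraction=0.7),
               EventSpec(type="DAD", beat_index=2, relative_amplitude_pct=6.0,
                         offset_fraction=0.4)]
        trace, truth, windows, fs = analyze_train(APTrainParams(n_beats=5), evs, config)
        events = detect_afterdepolarizations(trace, fs, config)
        assert sorted(e.type for e in events) == ["DAD", "EAD"]
        for e in events:
            ap = fs.aps[e.parent_ap_index]
            t_rc = repolarization_complete_time(trace, ap, config)
            if e.type == "EAD":
                assert ap.window.peak_time < e.onset_time < t_rc
            else:
                assert t_rc < e.onset_time < fs.aps[e.parent_ap_index + 1].activation_time

    def test_raising_threshold_never_adds_events(self, config):
        evs = [EventSpec(type="DAD", beat_index=1, relative_amplitude_pct=4.0),
               EventSpec(type="DAD", beat_index=2, relative_amplitude_pct=10.0,
                         offset_fraction=0.6)]
        trace, _, _, fs = analyze_train(APTrainParams(n_beats=5), evs, config)
        counts = [len(detect_afterdepolarizations(trace, fs,
                                                  config.replace(ad_threshold_pct=thr)))
                  for thr in (2.0, 3.0, 5.0, 8.0, 12.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[1] == 2 and counts[-1] == 0


class TestBurstDetection:
    BURST = EventSpec(type="burst", beat_index=1, relative_amplitude_pct=15.57,
                      offset_fraction=0.1, width_ms=180.0, burst_n_upstrokes=4,
                      burst_upstroke_mV=95.0)

    def test_regular_train_has_no_bursts(self, control_params, config):
        trace, _, _, fs = analyze_train(control_params)
        assert detect_bursts(trace, fs, config) == []

    def test_burst_mdp_and_upstroke_amplitude_recovered(self, config):
        """A burst from a -50 mV plateau with 95 mV upstrokes is reported
        with both numbers within 2%."""
        trace, truth, _, fs = analyze_train(APTrainParams(n_beats=6), [self.BURST], config)
        episodes = detect_bursts(trace, fs, config)
        assert len(episodes) == 1
        ep = episodes[0]
        assert ep.n_upstrokes == 4
        assert ep.mdp_mV == pytest.approx(truth.events[0].plateau_level, rel=0.02)
        assert ep.max_upstroke_amplitude_mV == pytest.approx(95.0, rel=0.02)

    def test_two_bursts_yield_disjoint_episodes(self, config):
        b2 = EventSpec(type="burst", beat_index=3, relative_amplitude_pct=15.57,
                       offset_fraction=0.1, width_ms=180.0, burst_n_upstrokes=3,
                       burst_upstroke_mV=60.0)
        trace, _, _, fs = analyze_train(APTrainParams(n_beats=6), [self.BURST, b2], config)
        episodes = detect_bursts(trace, fs, config)
        assert len(episodes) == 2
        assert episodes[0].end_time < episodes[1].start_time
        assert [e.n_upstrokes for e in episodes] == [4, 3]
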