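"""Blip detection, cycle-delta classification, absolute rise, scoring, streaming."""

import numpy as np
import pytest

from vae_impedance.acquisition import ImpedanceTrace, replay
from vae_impedance.config import AppConfig, DetectionConfig
from vae_impedance.detection import (
    StreamAnalyzer,
    analyze_trace,
    compare_cycles,
    detect_absolute_rise,
    detect_blips,
    run_stream,
    vae_score,
)
from vae_impedance.respiratory import (
    INVALID_CYCLESET,
    RespiratoryCycle,
    CycleSet,
    analyze_respiration,
)
from vae_impedance.report import window_record_lines
from vae_impedance.sqi import SQIReport, compute_sqi
from vae_impedance.synthetic import SimEvent, SimulationConfig, generate


def _first_alarm(assessments):
    return next((a for a in assessments if a.alarm), None)


def _make_cycles(eei_eii_pairs, t0=0.0, period=5.0):
    cycles = []
    for i, (eei, eii) in enumerate(eei_eii_pairs):
        start = t0 + i * period
        cycles.append(
            RespiratoryCycle(
                t_start=start, t_end=start + period, t_peak=start + period / 2,
                z_min=eei - 1.0, z_max=eii + 1.0, z_p25=eei, z_p75=eii,
                n_samples=int(period * 100),
            )
        )
    return CycleSet(tuple(cycles), 60.0 / period, True,
                    tuple(c.t_peak for c in cycles))


def _good_sqi():
    return SQIReport(0.95, 1.0, 0.9, 1.0, 0.9, 0.9)


def _bad_sqi():
    return SQIReport(0.1, 0.0, 0.2, 0.1, 0.1, 0.2)


class TestDetectBlips:
    def test_clean_ventilation_has_no_blips(self):
        cfg = SimulationConfig(duration_s=60, noise_sigma_ohm=0.2, seed=9)
        trace = generate(cfg).trace
        _, cycles = analyze_respiration(trace)
        assert detect_blips(trace, cycles) == []

    def test_rectangular_pulse_recovered(self):
        cfg = SimulationConfig(
            duration_s=60, resp_amplitude_ohm=5.0, noise_sigma_ohm=0.1, seed=9,
            events=(SimEvent("blip", t_start=27.3, duration_s=1.0, magnitude=15.0),),
        )
        trace = generate(cfg).trace
        _, cycles = analyze_respiration(trace)
        blips = detect_blips(trace, cycles)
        assert len(blips) == 1
        b = blips[0]
        assert b.t_onset == pytest.approx(27.3, abs=0.02)
        assert b.duration == pytest.approx(1.0, abs=0.15)
        assert b.amplitude == pytest.approx(15.0, abs=2.0)

    def test_long_excursion_is_not_a_blip(self):
        cfg = SimulationConfig(
            duration_s=60, resp_amplitude_ohm=5.0, noise_sigma_ohm=0.1, seed=9,
            events=(SimEvent("blip", t_start=25.0, duration_s=5.0, magnitude=15.0),),
        )
        trace = generate(cfg).trace
        _, cycles = analyze_respiration(trace)
        hits = [b for b in detect_blips(trace, cycles) if 24 < b.t_onset < 31]
        assert hits == []

    def test_unventilated_uses_absolute_floor(self):
        cfg = SimulationConfig(
            duration_s=60, resp_rate_bpm=0, resp_amplitude_ohm=0,
            noise_sigma_ohm=0.05, seed=2,
            events=(SimEvent("blip", t_start=30.0, duration_s=0.5, magnitude=2.0),),
        )
        trace = generate(cfg).trace
        _, cycles = analyze_respiration(trace)
        assert not cycles.valid
        blips = detect_blips(trace, cycles)
        assert len(blips) == 1
        assert blips[0].t_onset == pytest.approx(30.0, abs=0.02)


class TestCompareCycles:
    def test_identical_cycles_are_stable(self):
        cs = _make_cycles([(100.0, 106.0)] * 4)
        deltas = compare_cycles(cs, tau=0.1)
        assert [d.classification for d in deltas] == ["stable"] * 3
        assert all(d.d_eei == 0.0 and d.d_eii == 0.0 for d in deltas)

    def test_isolated_eii_rise_is_tidal_volume_signature(self):
        cs = _make_cycles([(100.0, 106.0), (100.0, 109.0), (100.0, 109.0)])
        deltas = compare_cycles(cs, tau=0.1)
        assert deltas[0].classification == "tv_change"
        assert deltas[1].classification == "stable"

    def test_paired_rise_is_vae_or_peep(self):
        pairs = [(100.0 + 0.5 * i, 106.0 + 0.5 * i) for i in range(5)]
        deltas = compare_cycles(_make_cycles(pairs), tau=0.1)
        assert all(d.classification == "vae_or_peep" for d in deltas)

    def test_isolated_eei_rise_is_peep_tv_edge(self):
        cs = _make_cycles([(100.0, 106.0), (100.5, 106.0)])
        assert compare_cycles(cs, tau=0.1)[0].classification == "peep_tv_edge"

    def test_fewer_than_two_cycles_gives_empty_list(self):
        assert compare_cycles(_make_cycles([(100.0, 106.0)])) == []
        assert compare_cycles(INVALID_CYCLESET) == []


class TestAbsoluteRise:
    def _flat(self, n=6000, level=250.0, rate=100.0, seed=0):
        rng = np.random.default_rng(seed)
        return ImpedanceTrace(np.arange(n) / rate,
                              level + rng.normal(0, 0.05, n), rate)

    def test_flat_unventilated_trace_scores_zero(self):
        comp, _ = detect_absolute_rise(self._flat(), INVALID_CYCLESET)
        assert comp == pytest.approx(0.0, abs=5.0)

    def test_sustained_step_reaches_alarm_threshold(self):
        trace = self._flat()
        z = trace.z.copy()
        z[trace.t >= 30.0] += 2.0
        comp, _ = detect_absolute_rise(
            ImpedanceTrace(trace.t, z, trace.rate_hz), INVALID_CYCLESET
        )
        assert comp >= 50.0

    def test_half_second_transient_does_not_fire_absolute_path(self):
        trace = self._flat()
        z = trace.z.copy()
        z[(trace.t >= 30.0) & (trace.t < 30.5)] += 2.0
        comp, _ = detect_absolute_rise(
            ImpedanceTrace(trace.t, z, trace.rate_hz), INVALID_CYCLESET
        )
        assert comp < 50.0

    def test_valid_ventilation_routes_to_trend_path(self):
        cfg = SimulationConfig(duration_s=60, noise_sigma_ohm=0.1, seed=1,
                               events=(SimEvent("baseline_step", 30.0, 0.0, 2.0),))
        trace = generate(cfg).trace
        _, cycles = analyze_respiration(trace)
        assert cycles.valid
        comp, _ = detect_absolute_rise(trace, cycles)
        assert comp == 0.0


class TestVAEScore:
    def test_null_evidence_scores_zero(self):
        a = vae_score([], [], 0.0, _good_sqi())
        assert a.score == 0.0 and not a.alarm and not a.suppressed

    def test_five_consecutive_paired_rises_alarm(self):
        pairs = [(100.0 + 0.5 * i, 106.0 + 0.5 * i) for i in range(6)]
        deltas = compare_cycles(_make_cycles(pairs), tau=0.1)
        a = vae_score(deltas, [], 0.0, _good_sqi())
        assert a.score >= 50.0 and a.alarm
        assert "PEEP" in a.advisory

    def test_low_sqi_suppresses_but_flags(self):
        pairs = [(100.0 + 0.5 * i, 106.0 + 0.5 * i) for i in range(6)]
        deltas = compare_cycles(_make_cycles(pairs), tau=0.1)
        a = vae_score(deltas, [], 0.0, _bad_sqi())
        assert a.score >= 50.0 and not a.alarm and a.suppressed

    def test_absolute_path_bypasses_sqi_gate(self):
        a = vae_score([], [], 80.0, _bad_sqi())
        assert a.alarm and not a.suppressed

    def test_score_is_max_of_components_and_bounded(self):
        pairs = [(100.0 + 0.5 * i, 106.0 + 0.5 * i) for i in range(20)]
        deltas = compare_cycles(_make_cycles(pairs), tau=0.1)
        a = vae_score(deltas, [], 30.0, _good_sqi())
        assert a.score == max(a.trend_component, a.blip_component,
                              a.absolute_component)
        assert 0.0 <= a.score <= 100.0


class TestEndToEnd:
    def test_gradual_ramp_alarms_within_six_cycles(self):
        cfg = SimulationConfig(
            duration_s=110, noise_sigma_ohm=0.2, seed=17,
            events=(SimEvent("ramp", t_start=45.0, duration_s=30.0, magnitude=1.0),),
        )
        a = analyze_trace(generate(cfg).trace)
        fa = _first_alarm(a)
        assert fa is not None
        assert 45.0 < fa.t_window <= 45.0 + 6 * 5.0

    def test_tidal_volume_step_never_alarms(self):
        for seed in range(5):
            cfg = SimulationConfig(
                duration_s=90, resp_amplitude_ohm=5.0, noise_sigma_ohm=0.2,
                seed=seed,
                events=(SimEvent("tv_step", t_start=45.0, duration_s=0.0,
                                 magnitude=1.8),),
            )
            a = analyze_trace(generate(cfg).trace)
            assert _first_alarm(a) is None

    def test_apnea_step_alarms_via_absolute_path(self):
        cfg = SimulationConfig(
            duration_s=90, resp_rate_bpm=0, noise_sigma_ohm=0.1, seed=3,
            events=(SimEvent("baseline_step", 30.0, 0.0, 2.0),
                    SimEvent("baseline_step", 60.0, 0.0, 2.0),),
        )
        a = analyze_trace(generate(cfg).trace)
        fa = _first_alarm(a)
        assert fa is not None
        assert fa.absolute_component >= 50.0
        assert not fa.cycles_valid

    def test_ventilated_step_alarms_via_trend_path(self):
        cfg = SimulationConfig(
            duration_s=110, noise_sigma_ohm=0.2, seed=3,
            events=(SimEvent("ramp", t_start=45.0, duration_s=20.0, magnitude=2.0),),
        )
        a = analyze_trace(generate(cfg).trace)
        fa = _first_alarm(a)
        assert fa is not None
        assert fa.trend_component >= 50.0
        assert fa.absolute_component == 0.0

    def test_score_monotone_in_ramp_slope(self):
        peaks = []
        for magnitude in (0.3, 0.6, 1.0, 2.0):
            cfg = SimulationConfig(
                duration_s=110, noise_sigma_ohm=0.2, seed=23,
                events=(SimEvent("ramp", t_start=45.0, duration_s=30.0,
                                 magnitude=magnitude),),
            )
            a = analyze_trace(generate(cfg).trace)
            peaks.append(max(w.score for w in a))
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))


class TestStreaming:
    def test_stream_equals_batch_bit_for_bit(self):
        cfg = SimulationConfig(
            duration_s=120, noise_sigma_ohm=0.2, seed=5,
            events=(SimEvent("ramp", 45.0, 30.0, 1.0),
                    SimEvent("blip", 90.0, 1.0, 14.0)),
        )
        trace = generate(cfg).trace
        batch = window_record_lines(analyze_trace(trace))
        for chunk_s in (0.5, 1.0, 7.3):
            streamed = window_record_lines(run_stream(replay(trace, chunk_s)))
            assert streamed == batch

    def test_short_stream_withholds_assessment(self):
        cfg = SimulationConfig(duration_s=8, seed=0)
        assert analyze_trace(generate(cfg).trace) == []

    def test_final_partial_window_assessed_when_long_enough(self):
        cfg = SimulationConfig(duration_s=47, noise_sigma_ohm=0.1, seed=0)
        a = analyze_trace(generate(cfg).trace)
        assert a[-1].t_window == pytest.approx(47.0, abs=0.05)

    def test_alarm_hysteresis_holds_two_windows(self):
        cfg = SimulationConfig(
            duration_s=120, noise_sigma_ohm=0.2, seed=11,
            events=(SimEvent("ramp", t_start=40.0, duration_s=25.0, magnitude=1.5),),
        )
        a = analyze_trace(generate(cfg).trace)
        flags = [w.alarm for w in a]
        assert any(flags)
        first = flags.index(True)
        run_len = 0
        for f in flags[first:]:
            if f:
                run_len += 1
            else:
                break
        assert run_len >= 3  # raised windows plus two quiet hysteresis windows

    def test_push_after_finish_rejected(self):
        cfg = SimulationConfig(duration_s=40, seed=0)
        trace = generate(cfg).trace
        analyzer = StreamAnalyzer(AppConfig())
        analyzer.push(trace)
        analyzer.finish()
        with pytest.raises(RuntimeError):
            analyzer.push(trace)
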