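"""a.c. pipeline (N_p, p, k_X, beta) and d.c. level segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerogate.gating_kinetics import (
    ClosedStateDistribution,
    RateModel,
    simulate_ensemble,
)
from aerogate.protocols import constant, sinusoid, triangle
from aerogate.trace_analysis import (
    AnalysisConfig,
    AnalysisError,
    analyze,
    closed_probability,
    closing_rate,
    estimate_pore_count,
    expected_current_ratio,
    level_segmentation,
    normalized_ensemble_current,
    rectification_from_loop,
    segment_cycles,
)
from aerogate.traces import CurrentTrace

QUIET = RateModel(polarity="none", closing_prefactor=0.0, opening_rate=0.0)
EPS_POINT = ClosedStateDistribution(mean_ratio=0.14, sd_ratio=0.0)


def _sine_trace(open_iv, n_pores=3, duration=10.0, freq=0.1, noise_sd=0.0,
                seed=0, model=QUIET, dist=EPS_POINT, rate=1000.0):
    proto = sinusoid(0.2, freq, duration=duration, sample_rate=rate)
    return simulate_ensemble(n_pores, model, dist, open_iv, proto,
                             noise_sd=noise_sd, seed=seed), proto


class TestSegmentCycles:
    def test_ten_seconds_at_tenth_hertz_is_one_cycle(self, wt_open_iv):
        trace, proto = _sine_trace(wt_open_iv, duration=10.0)
        assert segment_cycles(trace, proto).n_cycles == 1

    def test_fifty_cycles(self, wt_open_iv):
        trace, proto = _sine_trace(wt_open_iv, duration=500.0)
        assert segment_cycles(trace, proto).n_cycles == 50

    def test_partial_cycles_discarded(self, wt_open_iv):
        trace, proto = _sine_trace(wt_open_iv, duration=25.0)
        assert segment_cycles(trace, proto).n_cycles == 2

    def test_non_periodic_protocol_rejected(self, wt_open_iv):
        proto = constant(-0.1, duration=1.0, sample_rate=1000.0)
        trace = simulate_ensemble(1, QUIET, EPS_POINT, wt_open_iv, proto, seed=0)
        with pytest.raises(AnalysisError):
            segment_cycles(trace, proto)


class TestPoreCount:
    def test_exact_multiple_recovers_count(self, wt_open_iv):
        trace, proto = _sine_trace(wt_open_iv, n_pores=3)
        cycles = segment_cycles(trace, proto)
        n_p, r2 = estimate_pore_count(cycles.currents[0], cycles.voltage,
                                      wt_open_iv)
        assert n_p == pytest.approx(3.0, abs=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_noisy_ensemble_within_half_pore(self, wt_open_iv):
        i_max = 26 * float(np.max(np.abs(wt_open_iv.currents)))
        trace, proto = _sine_trace(wt_open_iv, n_pores=26, seed=8,
                                   noise_sd=0.02 * i_max, rate=10000.0)
        cycles = segment_cycles(trace, proto)
        n_p, _ = estimate_pore_count(cycles.currents[0], cycles.voltage,
                                     wt_open_iv)
        assert n_p == pytest.approx(26.0, abs=0.5)

    def test_zero_current_means_no_pores(self, wt_open_iv):
        trace, proto = _sine_trace(wt_open_iv)
        cycles = segment_cycles(trace, proto)
        with pytest.raises(AnalysisError):
            estimate_pore_count(np.zeros_like(cycles.voltage), cycles.voltage,
                                wt_open_iv)


class TestNormalizedEnsembleCurrent:
    def test_no_gating_gives_unity_ratio(self, wt_open_iv):
        trace, proto = _sine_trace(wt_open_iv, n_pores=5)
        cycles = segment_cycles(trace, proto)
        out = normalized_ensemble_current(cycles, wt_open_iv)
        sel = np.abs(cycles.voltage) > 0.02
        np.testing.assert_allclose(out["ratio"][sel], 1.0, atol=1e-4)

    def test_pore_count_weighted_mean(self, wt_open_iv):
        # two cycles, N_p = 1 and 9, pointwise ratios 1 and 0.5 away from the
        # regression window -> weighted mean 0.55
        trace, proto = _sine_trace(wt_open_iv, n_pores=1, duration=20.0)
        cycles = segment_cycles(trace, proto)
        i_open = np.asarray(wt_open_iv.interp(cycles.voltage))
        gated = np.where(np.abs(cycles.voltage) >= 0.06, 0.5, 1.0)
        cycles.currents = np.vstack([i_open, 9.0 * i_open * gated])
        out = normalized_ensemble_current(cycles, wt_open_iv)
        sel = np.abs(cycles.voltage) >= 0.08
        np.testing.assert_allclose(out["ratio"][sel], 0.55, atol=1e-9)
        np.testing.assert_allclose(out["n_p"], [1.0, 9.0], atol=1e-6)


class TestClosedProbability:
    def test_unity_ratio_means_open(self):
        p, _, _ = closed_probability(np.ones(10), 0.14)
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_ratio_at_epsilon_means_closed(self):
        p, _, _ = closed_probability(np.full(10, 0.14), 0.14)
        np.testing.assert_allclose(p, 1.0, atol=1e-12)

    def test_midpoint(self):
        p, _, _ = closed_probability(np.array([0.57]), 0.14)
        assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_mask_near_origin(self):
        v = np.linspace(-0.2, 0.2, 41)
        p, raw, mask = closed_probability(np.ones(41), 0.14, v, v_mask=0.02)
        assert not mask[np.abs(v) < 0.02].any()
        assert np.isnan(p[~mask]).all()
        assert np.isfinite(raw).all()

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=100, deadline=None)
    def test_forward_and_inverse_are_exact_inverses(self, p_true, eps):
        ratio = expected_current_ratio(p_true, eps)
        p, _, _ = closed_probability(np.array([ratio]), eps)
        assert p[0] == pytest.approx(p_true, abs=1e-12)


class TestClosingRate:
    def test_constant_probability_gives_zero_rate(self):
        n = 2048
        phase = np.arange(n) / n
        v = 0.2 * np.sin(2 * np.pi * phase)
        out = closing_rate(np.full(n, 0.4), np.ones(n, bool), v, 10.0)
        assert out["k_x_negative"] == pytest.approx(0.0, abs=1e-9)
        assert out["k_x_positive"] == pytest.approx(0.0, abs=1e-9)

    def test_logistic_max_slope(self):
        # analytic maximum slope of a logistic is 1/(4 tau)
        n, T, tau = 2048, 10.0, 0.2
        phase = np.arange(n) / n
        t = phase * T
        v = 0.2 * np.sin(2 * np.pi * phase)
        p = 1.0 / (1.0 + np.exp(-(t - 6.0) / tau))  # rises in the rising-|V|
        out = closing_rate(p, np.ones(n, bool), v, T)  # negative quarter
        assert out["k_x_negative"] == pytest.approx(1 / (4 * tau), rel=0.05)

    def test_invariant_to_gain_and_pore_count(self, wt_open_iv):
        model = RateModel(polarity="negative", critical_voltage=0.12,
                          closing_prefactor=2.0, closing_efold_voltage=0.04,
                          opening_rate=30.0, reopening_window=0.08)
        proto = sinusoid(0.2, 0.1, duration=300.0, sample_rate=2000.0)
        k = {}
        for n_pores in (5, 100):
            trace = simulate_ensemble(n_pores, model, EPS_POINT, wt_open_iv,
                                      proto, seed=12)
            summ = analyze(trace, wt_open_iv, proto)
            k[n_pores] = summ.k_x_negative
            # uniform gain change: scale currents and the reference IV equally
            gained = CurrentTrace(trace.time_s, trace.voltage_v,
                                  2.5 * trace.current_a)
            from aerogate.pore_transport import IVCurve
            iv_gain = IVCurve(wt_open_iv.voltages, 2.5 * wt_open_iv.currents)
            summ_gain = analyze(gained, iv_gain, proto)
            assert summ_gain.k_x_negative == pytest.approx(summ.k_x_negative,
                                                           rel=1e-6)
        assert k[100] == pytest.approx(k[5], rel=0.1)


class TestLevelSegmentation:
    def test_clean_two_level_trace(self):
        rng = np.random.default_rng(0)
        n = 20000
        i = np.full(n, -400e-12)
        i[n // 2:] = -56e-12  # 14% of the open level
        i += rng.normal(0, 4e-12, n)
        trace = CurrentTrace(np.arange(n) / 5000.0, np.full(n, -0.16), i)
        seg = level_segmentation(trace)
        labels = [lv.label for lv in seg.levels]
        assert labels == ["open", "gated"]
        assert seg.mean_ratio == pytest.approx(0.14, abs=0.01)

    def test_no_gating_single_level(self):
        rng = np.random.default_rng(1)
        n = 10000
        i = -400e-12 + rng.normal(0, 4e-12, n)
        trace = CurrentTrace(np.arange(n) / 5000.0, np.full(n, -0.16), i)
        seg = level_segmentation(trace)
        assert len(seg.levels) == 1
        assert seg.levels[0].label == "open"
        assert seg.event_ratios.size == 0

    def test_dwell_filter_drops_short_blips(self):
        rng = np.random.default_rng(2)
        n = 20000
        i = np.full(n, -400e-12)
        i[5000:5010] = -56e-12  # 2 ms blip at 5 kHz: below the 5 ms floor
        i[10000:15000] = -56e-12
        i += rng.normal(0, 4e-12, n)
        trace = CurrentTrace(np.arange(n) / 5000.0, np.full(n, -0.16), i)
        seg = level_segmentation(trace)
        assert sum(lv.label == "gated" for lv in seg.levels) == 1


class TestAnalyzePipeline:
    def test_non_gating_input_recovers_transport_beta(self, wt_problem,
                                                      wt_open_iv):
        from aerogate.pore_transport import iv_curve, rectification_factor

        proto = triangle(0.2, 2.0, duration=5.0, sample_rate=10000.0)
        trace = simulate_ensemble(6, QUIET, EPS_POINT, wt_open_iv, proto, seed=0)
        summ = analyze(trace, wt_open_iv, proto)
        beta_ref = rectification_factor(
            iv_curve(wt_problem, np.linspace(-0.15, 0.15, 61)))
        assert summ.beta == pytest.approx(beta_ref, abs=1e-3)
        assert summ.k_x_negative == pytest.approx(0.0, abs=1e-3)
        assert summ.k_x_positive == pytest.approx(0.0, abs=1e-3)
        p = summ.p[summ.mask]
        np.testing.assert_allclose(p, 0.0, atol=1e-4)

    def test_round_trip_recovers_p_for_various_ensemble_sizes(self, wt_open_iv):
        from aerogate.gating_kinetics import closed_probability_ode

        model = RateModel(polarity="negative", critical_voltage=0.12,
                          closing_prefactor=2.0, closing_efold_voltage=0.04,
                          opening_rate=30.0, reopening_window=0.08)
        proto = sinusoid(0.2, 0.1, duration=100.0, sample_rate=2000.0)
        t, v = proto.samples()
        one = t < 10.0
        _, p_ode = closed_probability_ode(model, (t[one], v[one]))
        for n_pores in (5, 26, 100):
            trace = simulate_ensemble(n_pores, model,
                                      ClosedStateDistribution(0.14, 0.05),
                                      wt_open_iv, proto, seed=21)
            summ = analyze(trace, wt_open_iv, proto)
            p_ref = np.interp(summ.phase * 10.0, t[one], p_ode)
            m = summ.mask
            n_eff = n_pores * 10
            se = np.sqrt(
                (p_ref * (1 - p_ref) * 0.86**2 + p_ref * 0.05**2)
                / (n_eff * 0.86**2))
            tol = 3 * np.maximum(se, np.sqrt(0.25 / n_eff) * 0.25)
            assert np.all(np.abs(summ.p[m] - p_ref[m]) < tol[m] + 0.02)

    def test_empty_trace_errors(self, wt_open_iv):
        proto = sinusoid(0.2, 0.1, duration=10.0, sample_rate=1000.0)
        trace = CurrentTrace(np.arange(100) / 1000.0,
                             0.2 * np.sin(2 * np.pi * 0.1 *
                                          np.arange(100) / 1000.0),
                             np.zeros(100))
        with pytest.raises(AnalysisError):
            analyze(trace, wt_open_iv, proto)

    def test_stage_labels_in_errors(self, wt_open_iv):
        proto = sinusoid(0.2, 0.1, duration=10.0, sample_rate=1000.0)
        t = np.arange(10000) / 1000.0
        trace = CurrentTrace(t, 0.2 * np.sin(2 * np.pi * 0.1 * t),
                             np.zeros(t.size))
        with pytest.raises(AnalysisError, match="pore-count"):
            analyze(trace, wt_open_iv, proto)
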