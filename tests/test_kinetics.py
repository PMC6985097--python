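"""Calcium transient decomposition: normalization, filtering, features."""

import numpy as np
import pytest

from astroquant.errors import (
    InvalidParameterError,
    NormalizationError,
    UndefinedFeatureError,
)
from astroquant.kinetics import (
    CalciumTrace,
    classify_phase,
    compute_auc,
    detect_response,
    extract_features,
    extract_features_batch,
    find_peak,
    fit_decay,
    lowpass,
    normalize_f_f0,
    rise_time,
    summarize_response_rates,
)
from astroquant.simulate import generate_trace_set


def make_trace(f, dt=1.0, stimulus=20.0):
    f = np.asarray(f, float)
    return CalciumTrace(time_s=dt * np.arange(f.size), f=f, stimulus_time_s=stimulus)


class TestNormalize:
    def test_constant_trace_maps_to_one(self):
        norm = normalize_f_f0(make_trace(np.full(100, 5.0)))
        assert np.allclose(norm.f_over_f0, 1.0, atol=1e-15)
        assert norm.f0 == pytest.approx(5.0)

    def test_plateau_ratio(self):
        f = np.concatenate([np.full(30, 2.0), np.full(70, 6.0)])
        norm = normalize_f_f0(make_trace(f))
        assert norm.f_over_f0[-1] == pytest.approx(3.0)

    def test_zero_baseline_raises(self):
        f = np.concatenate([np.zeros(30), np.ones(70)])
        with pytest.raises(NormalizationError):
            normalize_f_f0(make_trace(f))

    def test_baseline_mean_is_exactly_one(self, trace_spec):
        traces, _ = generate_trace_set(trace_spec(seed=1, noise_sd=0.03))
        for tr in traces:
            norm = normalize_f_f0(tr)
            sel = (norm.time_s >= 0) & (norm.time_s < 20)
            assert abs(norm.f_over_f0[sel].mean() - 1.0) < 1e-12


class TestLowpass:
    def test_constant_trace_unchanged(self, flat_norm_trace):
        norm = flat_norm_trace(np.arange(100.0), np.ones(100))
        out = lowpass(norm, 0.2)
        assert np.allclose(out.f_over_f0, 1.0, atol=1e-9)

    def test_sinusoid_at_twice_cutoff_attenuated_tenfold(self, flat_norm_trace):
        t = np.arange(600.0)
        f = 1.0 + 0.5 * np.sin(2 * np.pi * 0.4 * t)  # 0.4 Hz = 2 x cutoff
        out = lowpass(flat_norm_trace(t, f), 0.2)
        mid = out.f_over_f0[100:500]
        # squared 2nd-order Butterworth response at 2x cutoff: 1/17 ~ 0.06
        assert np.abs(mid - 1.0).max() <= 0.1 * 0.5

    def test_zero_phase_step_half_rise_unshifted(self, flat_norm_trace):
        t = np.arange(300.0)
        f = np.where(t >= 150, 2.0, 1.0)
        out = lowpass(flat_norm_trace(t, f), 0.2)

        def half_rise(y):
            i = np.argmax(y >= 1.5)
            return t[i - 1] + (1.5 - y[i - 1]) / (y[i] - y[i - 1])

        assert abs(half_rise(out.f_over_f0) - half_rise(f)) <= 1.0

    def test_cutoff_at_nyquist_rejected(self, flat_norm_trace):
        norm = flat_norm_trace(np.arange(100.0), np.ones(100))
        with pytest.raises(InvalidParameterError):
            lowpass(norm, 0.5)

    def test_nonuniform_sampling_resampled(self, flat_norm_trace):
        t = np.sort(np.random.default_rng(0).uniform(0, 100, 200))
        norm = flat_norm_trace(t, np.ones(200))
        out = lowpass(norm, 0.01)
        assert np.allclose(np.diff(out.time_s), np.diff(out.time_s)[0])


class TestDetect:
    def test_nonresponder_trace(self, trace_spec):
        traces, _ = generate_trace_set(
            trace_spec(seed=2, nonresponder_fraction=1.0, noise_sd=0.02)
        )
        norm = normalize_f_f0(traces[0])
        responder, onset = detect_response(norm)
        assert responder is False and onset is None

    def test_noiseless_latency_recovered_within_sample(self, trace_spec):
        traces, _ = generate_trace_set(trace_spec(seed=3, latency_s=5.0, n_roi=1))
        norm = normalize_f_f0(traces[0])
        responder, onset = detect_response(norm)
        assert responder
        assert onset == pytest.approx(25.0, abs=1.0)

    def test_false_positive_rate_on_pure_noise(self, trace_spec):
        traces, _ = generate_trace_set(
            trace_spec(seed=4, n_roi=100, nonresponder_fraction=1.0, noise_sd=0.02)
        )
        hits = sum(detect_response(normalize_f_f0(tr))[0] for tr in traces)
        assert hits <= 5  # <= 5% false positives at k = 3


class TestRiseTime:
    def test_linear_ramp_rt_is_eight_tenths_of_ramp(self, flat_norm_trace):
        t = np.arange(100.0)
        f = np.interp(t, [0, 30, 40, 100], [1.0, 1.0, 2.0, 2.0])
        norm = flat_norm_trace(t, f)
        assert rise_time(norm, onset=30.0) == pytest.approx(8.0, abs=1e-9)

    def test_single_sample_step_rt_below_interval(self, flat_norm_trace):
        t = np.arange(100.0)
        f = np.where(t >= 25, 2.0, 1.0)
        assert rise_time(flat_norm_trace(t, f), onset=24.0) <= 1.0

    def test_simulator_rise_recovered_noiseless(self, trace_spec):
        traces, truth = generate_trace_set(trace_spec(seed=5, n_roi=1))
        norm = normalize_f_f0(traces[0])
        _, onset = detect_response(norm)
        rt = rise_time(norm, onset)
        true_rt = truth.traces["rise_time_10_90_s"].iloc[0]
        assert rt == pytest.approx(true_rt, rel=0.02)


class TestFitDecay:
    def test_noiseless_tau_recovered_to_permille(self, flat_norm_trace):
        t = np.arange(0.0, 260.0)
        f = 1.0 + np.exp(-t / 60.0)
        fit = fit_decay(flat_norm_trace(t, f), peak_time=0.0)
        assert fit.success
        assert fit.tau_s == pytest.approx(60.0, rel=1e-3)
        assert fit.a == pytest.approx(1.0, rel=1e-3)

    def test_noisy_tau_median_within_ten_percent(self, trace_spec):
        traces, _ = generate_trace_set(
            trace_spec(seed=6, n_roi=50, noise_sd=0.02, decay_tau_s=60.0)
        )
        taus = []
        for tr in traces:
            norm = normalize_f_f0(tr)
            _, onset = detect_response(norm)
            _, peak_time, _ = find_peak(norm, onset)
            fit = fit_decay(norm, peak_time)
            if fit.success:
                taus.append(fit.tau_s)
        assert len(taus) >= 45
        assert np.median(np.abs(np.array(taus) - 60.0) / 60.0) <= 0.10

    def test_flat_plateau_flags_failure(self, flat_norm_trace):
        t = np.arange(0.0, 100.0)
        fit = fit_decay(flat_norm_trace(t, np.full(100, 1.5)), peak_time=0.0)
        assert not fit.success
        assert fit.tau_s is None

    def test_t_end_bounded_by_300(self, flat_norm_trace):
        t = np.arange(0.0, 400.0)
        f = 1.0 + np.exp(-t / 50.0)
        fit = fit_decay(flat_norm_trace(t, f), peak_time=0.0)
        assert fit.t_end_s <= 300.0

    def test_monotone_tau_on_noiseless_inputs(self, trace_spec):
        fitted = []
        for tau in (40.0, 60.0, 80.0, 100.0):
            traces, _ = generate_trace_set(
                trace_spec(seed=7, n_roi=1, decay_tau_s=tau)
            )
            norm = normalize_f_f0(traces[0])
            _, onset = detect_response(norm)
            _, peak_time, _ = find_peak(norm, onset)
            fitted.append(fit_decay(norm, peak_time).tau_s)
        assert all(a < b for a, b in zip(fitted, fitted[1:]))


class TestAUC:
    def test_rectangle_area(self, flat_norm_trace):
        t = np.arange(0.0, 100.0)
        f = np.where((t >= 30) & (t <= 40), 2.0, 1.0)
        assert compute_auc(flat_norm_trace(t, f), 30.0, 40.0) == pytest.approx(10.0)

    def test_triangle_area(self, flat_norm_trace):
        t = np.arange(0.0, 100.0)
        f = 1.0 + np.interp(t, [30, 35, 40], [0.0, 2.0, 0.0], left=0, right=0)
        assert compute_auc(flat_norm_trace(t, f), 30.0, 40.0) == pytest.approx(10.0)

    def test_zero_amplitude_trace(self, flat_norm_trace):
        t = np.arange(0.0, 100.0)
        assert compute_auc(flat_norm_trace(t, np.ones(100)), 20.0, 90.0) == 0.0


class TestClassifyPhase:
    def test_pure_exponential_is_monophasic(self, flat_norm_trace):
        t = np.arange(0.0, 280.0)
        f = 1.0 + np.exp(-t / 60.0)
        assert classify_phase(flat_norm_trace(t, f), 0, 279.0) == "monophasic"

    def test_simulated_plateau_is_biphasic(self, trace_spec):
        traces, _ = generate_trace_set(
            trace_spec(seed=8, n_roi=1, biphasic_plateau_ratio=0.6)
        )
        ft = extract_features(traces[0])
        assert ft.phase == "biphasic"

    def test_half_amplitude_plateau_shorter_than_sustain_is_monophasic(
        self, flat_norm_trace
    ):
        t = np.arange(0.0, 300.0)
        f = np.ones(t.size)
        f[50] = 2.0                      # peak, amplitude 1
        f[51:61] = 1.5                   # exactly half amplitude for 10 s < 20 s
        assert classify_phase(flat_norm_trace(t, f), 50, 299.0) == "monophasic"

    def test_long_half_amplitude_plateau_is_biphasic(self, flat_norm_trace):
        t = np.arange(0.0, 300.0)
        f = np.ones(t.size)
        f[50] = 2.0
        f[51:101] = 1.5                  # half amplitude sustained 50 s >= 20 s
        assert classify_phase(flat_norm_trace(t, f), 50, 299.0) == "biphasic"


class TestExtractFeatures:
    def test_noiseless_responder_recovers_all_truth(self, trace_spec):
        spec = trace_spec(seed=9, n_roi=1, latency_s=10.0, decay_tau_s=80.0)
        traces, truth = generate_trace_set(spec)
        ft = extract_features(traces[0])
        row = truth.traces.iloc[0]
        assert ft.responder
        assert ft.latency_s == pytest.approx(row["latency_s"], abs=1.0)
        assert ft.rise_time_s == pytest.approx(row["rise_time_10_90_s"], rel=0.02)
        assert ft.decay_tau_s == pytest.approx(row["decay_tau_s"], rel=0.01)
        assert ft.phase == row["phase"]
        assert ft.t_end_s <= 300.0

    def test_nonresponder_short_circuits(self, trace_spec):
        traces, _ = generate_trace_set(
            trace_spec(seed=10, nonresponder_fraction=1.0, noise_sd=0.01)
        )
        ft = extract_features(traces[0])
        assert ft.responder is False
        assert ft.phase == "none"
        assert ft.latency_s is None and ft.decay_tau_s is None

    def test_corrupt_trace_flagged_batch_completes(self, trace_spec):
        traces, _ = generate_trace_set(trace_spec(seed=11, n_roi=3))
        traces[1].f[50:60] = np.nan
        feats = extract_features_batch(traces)
        assert len(feats) == 3
        assert feats[1].error is not None and feats[1].responder is None
        assert feats[0].responder and feats[2].responder

    def test_gain_invariance_of_features(self, trace_spec):
        traces, _ = generate_trace_set(trace_spec(seed=12, n_roi=1, noise_sd=0.02))
        tr = traces[0]
        ft1 = extract_features(tr)
        scaled = CalciumTrace(
            time_s=tr.time_s, f=3.7 * tr.f, stimulus_time_s=tr.stimulus_time_s
        )
        ft2 = extract_features(scaled)
        assert ft2.latency_s == pytest.approx(ft1.latency_s, abs=1e-9)
        assert ft2.rise_time_s == pytest.approx(ft1.rise_time_s, abs=1e-9)
        assert ft2.decay_tau_s == pytest.approx(ft1.decay_tau_s, rel=1e-6)
        assert ft2.auc == pytest.approx(ft1.auc, rel=1e-9)
        assert ft2.phase == ft1.phase


class TestSummarize:
    def test_nonresponder_percentage(self, trace_spec):
        traces, _ = generate_trace_set(
            trace_spec(seed=13, n_roi=10, nonresponder_fraction=0.2, noise_sd=0.01),
            group={"div": "7", "treatment": "control"},
        )
        feats = extract_features_batch(traces)
        table = summarize_response_rates(feats)
        assert table["percent_nonresponsive"].iloc[0] == pytest.approx(20.0)

    def test_attenuated_group_has_smaller_peak(self, trace_spec):
        feats = []
        for att, name in ((1.0, "control"), (0.2, "suramin")):
            traces, _ = generate_trace_set(
                trace_spec(seed=14, n_roi=8, treatment_attenuation=att,
                           noise_sd=0.02),
                group={"div": "7", "treatment": name},
            )
            feats.extend(extract_features_batch(traces))
        table = summarize_response_rates(feats).set_index("treatment")
        assert (
            table.loc["suramin", "peak_amplitude_mean"]
            < table.loc["control", "peak_amplitude_mean"]
        )

    def test_single_trace_group_sem_absent(self, trace_spec):
        traces, _ = generate_trace_set(
            trace_spec(seed=15, n_roi=1), group={"div": "7", "treatment": "c"}
        )
        table = summarize_response_rates(extract_features_batch(traces))
        assert np.isnan(table["latency_s_sem"].iloc[0])


def test_rise_time_requires_positive_amplitude(flat_norm_trace):
    t = np.arange(0.0, 100.0)
    norm = flat_norm_trace(t, np.ones(100))
    with pytest.raises(UndefinedFeatureError):
        rise_time(norm, onset=30.0)
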