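"""Synthetic gaze generation: kinematics, ground truth, determinism."""

import numpy as np
import pytest

from toolgaze.design import DesignParams, build_schedule
from toolgaze.detect import extract_saccades, velocity
from toolgaze.preprocess import detect_blinks, preprocess_trace
from toolgaze.simulate import (KinematicsParams, LatencyModel,
                               NoiseAndArtifactParams, main_sequence,
                               saccade_displacement, simulate_cohort,
                               simulate_trial)


def pick(schedule, **attrs):
    return next(s for s in schedule
                if all(getattr(s, k) == v for k, v in attrs.items()))


class TestMainSequence:
    def test_zero_amplitude(self, kinematics):
        assert main_sequence(0.0, kinematics) == (21.0, 0.0)

    def test_twelve_degree_duration(self, kinematics):
        d, _ = main_sequence(12.0, kinematics)
        assert d == pytest.approx(47.4)  # 21 + 2.2 * 12

    def test_peak_velocity_monotone(self, kinematics):
        amps = np.linspace(0, 30, 40)
        peaks = [main_sequence(a, kinematics)[1] for a in amps]
        assert np.all(np.diff(peaks) > 0)

    def test_negative_amplitude_rejected(self, kinematics):
        with pytest.raises(ValueError):
            main_sequence(-1.0, kinematics)


class TestWaveform:
    @pytest.mark.parametrize("profile", ["flat_top", "gaussian",
                                         "minimum_jerk"])
    @pytest.mark.parametrize("amp", [2.0, 12.0, 20.0])
    def test_displacement_reaches_amplitude(self, profile, amp):
        k = KinematicsParams(profile=profile)
        d, _ = main_sequence(amp, k)
        t = np.linspace(-5, d + 5, 2000)
        s, _ = saccade_displacement(t, amp, k)
        assert s[0] == 0.0
        assert s[-1] == pytest.approx(amp, abs=1e-9)
        assert np.all(np.diff(s) >= -1e-12)  # monotone

    def test_flat_top_peak_matches_main_sequence(self, kinematics):
        # the default profile honours the main-sequence peak at task size
        d, vp = main_sequence(12.0, kinematics)
        t = np.linspace(0, d, 5000)
        s, peak = saccade_displacement(t, 12.0, kinematics)
        num_peak = np.max(np.diff(s)) / (np.diff(t)[0] / 1000.0)
        assert peak == pytest.approx(vp, rel=1e-6)
        assert num_peak == pytest.approx(vp, rel=0.01)


class TestSimulateTrial:
    def test_fixed_latency_onset(self, default_schedule, default_params,
                                 kinematics, fixed_latency, clean_noise):
        spec = pick(default_schedule, tool_end="head", soa_ms=400,
                    saccade_direction="right")
        _, truth = simulate_trial(spec, default_params, kinematics,
                                  fixed_latency, clean_noise,
                                  np.random.default_rng(0),
                                  latency_override=400.0)
        assert truth["true_onset_ms"] == pytest.approx(1300.0)  # 500+400+400
        assert truth["true_srt_ms"] == pytest.approx(400.0)

    def test_red_trial_has_no_saccade(self, default_schedule, default_params,
                                      kinematics, fixed_latency, clean_noise):
        spec = pick(default_schedule, tool_end="red")
        trace, truth = simulate_trial(spec, default_params, kinematics,
                                      fixed_latency, clean_noise,
                                      np.random.default_rng(0))
        assert np.isnan(truth["true_srt_ms"])
        v = velocity(trace).v
        assert np.nanmax(v) < 100.0

    def test_sampled_peak_velocity_within_5pct(self, default_schedule,
                                               default_params, kinematics,
                                               fixed_latency, clean_noise):
        spec = pick(default_schedule, tool_end="head", soa_ms=400,
                    saccade_direction="right")
        trace, truth = simulate_trial(spec, default_params, kinematics,
                                      fixed_latency, clean_noise,
                                      np.random.default_rng(0))
        v = velocity(trace).v
        assert np.nanmax(v) == pytest.approx(truth["true_peak_vel"],
                                             rel=0.05)

    def test_displacement_integral_matches_amplitude(self, default_schedule,
                                                     default_params,
                                                     kinematics,
                                                     fixed_latency,
                                                     clean_noise):
        spec = pick(default_schedule, tool_end="handle", soa_ms=200,
                    saccade_direction="left")
        trace, truth = simulate_trial(spec, default_params, kinematics,
                                      fixed_latency, clean_noise,
                                      np.random.default_rng(0))
        # position right after the saccade equals the true landing point
        i = int((truth["true_onset_ms"] + 60) / trace.dt_ms)
        assert trace.x[i] == pytest.approx(truth["true_landing_x"],
                                           abs=0.05)
        assert trace.y[i] == pytest.approx(truth["true_landing_y"],
                                           abs=0.05)

    def test_late_latency_becomes_omission(self, default_schedule,
                                           default_params, kinematics,
                                           fixed_latency, clean_noise):
        spec = pick(default_schedule, tool_end="head", soa_ms=600,
                    saccade_direction="right")
        _, truth = simulate_trial(spec, default_params, kinematics,
                                  fixed_latency, clean_noise,
                                  np.random.default_rng(0),
                                  latency_override=2000.0)
        assert truth["omitted"]
        assert np.isnan(truth["true_srt_ms"])

    def test_detection_recovers_onset_noise_free(self, default_schedule,
                                                 default_params, kinematics,
                                                 clean_noise):
        lat = LatencyModel(subject_sd=0.0)
        rng = np.random.default_rng(11)
        dt = kinematics.dt_ms
        checked = 0
        for spec in default_schedule[:60]:
            if spec.is_red:
                continue
            trace, truth = simulate_trial(spec, default_params, kinematics,
                                          lat, clean_noise, rng)
            if truth["omitted"]:
                continue
            clean, _ = preprocess_trace(trace)
            large = [e for e in extract_saccades(clean) if e.is_large]
            assert large
            true_idx = round(truth["true_onset_ms"] / dt)
            assert abs(large[0].onset_idx - true_idx) <= 1
            assert large[0].landing_x == pytest.approx(
                truth["true_landing_x"], abs=0.05)
            checked += 1
        assert checked > 40


class TestCohort:
    def test_blinks_always_detectable(self, small_params, kinematics):
        noise = NoiseAndArtifactParams(blink_rate=60.0)
        sub = next(simulate_cohort(1, small_params, kinematics,
                                   noise=noise, master_seed=5))
        blinks = detect_blinks(sub.trace)
        assert len(blinks) > 0
        assert all(b - a >= 10 for a, b in blinks)
        # every injected blink interval lies inside a detectable gap
        trial_len = 600
        n_checked = 0
        for tid, field in zip(sub.truth.trial_id, sub.truth.blink_intervals):
            if not field:
                continue
            for chunk in field.split(";"):
                a, b = (int(v) for v in chunk.split(":"))
                lo, hi = tid * trial_len + a, tid * trial_len + b
                assert sub.trace.missing[lo:hi].all()
                assert any(s <= lo and hi <= e for s, e in blinks)
                n_checked += 1
        assert n_checked > 0

    def test_zero_variance_cohort_identical_srts(self, small_params,
                                                 kinematics, clean_noise):
        lat = LatencyModel(subject_sd=0.0, trial_sd=0.0, exgauss_tau=0.0)
        subs = list(simulate_cohort(2, small_params, kinematics, lat,
                                    clean_noise, master_seed=3))
        srt = lambda s: sorted(
            s.truth.dropna(subset=["true_srt_ms"])
            .groupby(["tool_end", "soa_ms"])["true_srt_ms"].mean().items())
        assert srt(subs[0]) == srt(subs[1])

    def test_master_seed_determinism(self, small_params, kinematics):
        a = next(simulate_cohort(1, small_params, kinematics, master_seed=9))
        b = next(simulate_cohort(1, small_params, kinematics, master_seed=9))
        np.testing.assert_array_equal(a.trace.x, b.trace.x)
        np.testing.assert_array_equal(a.trace.missing, b.trace.missing)
        assert a.truth.equals(b.truth)
        c = next(simulate_cohort(1, small_params, kinematics, master_seed=10))
        assert not np.array_equal(a.trace.x, c.trace.x)

    def test_cohort_shapes(self, small_params, kinematics):
        subs = list(simulate_cohort(2, small_params, kinematics,
                                    master_seed=0))
        assert len(subs) == 2
        for s in subs:
            assert len(s.schedule) == 20
            assert len(s.truth) == 20
            assert len(s.trace) == 20 * 600  # 2 s per trial at 300 Hz

    def test_min_blink_duration_enforced(self):
        with pytest.raises(ValueError, match="10 samples"):
            NoiseAndArtifactParams(blink_duration_ms=(20.0, 50.0))
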