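"""Generator ground truth: beat trains, breath cycles, SCR counts, activity
regimes, session assembly and cohort structure."""

import numpy as np
import pytest
from scipy.signal import periodogram

from wearanx.exceptions import InvalidParameterError, InvalidPlanError
from wearanx.simulate import (
    CHANNEL_RATES,
    CohortConfig,
    ConditionInterval,
    SubjectProfile,
    build_plan,
    generate_acc,
    generate_bvp,
    generate_cohort,
    generate_ecg,
    generate_eda,
    generate_resp,
    generate_session,
    generate_temp,
)


class TestECG:
    def test_metronomic_beats(self):
        p = SubjectProfile(baseline_hr=60, sdnn=0.0)
        _, beats = generate_ecg(p, 10, 256, seed=0)
        assert beats.size == 10
        assert np.all(beats > 0) and np.all(beats <= 10)
        assert np.allclose(np.diff(beats), 1.0)

    def test_rr_moments_recovered(self):
        p = SubjectProfile(baseline_hr=60, sdnn=0.05)
        _, beats = generate_ecg(p, 300, 256, seed=7)
        rr = np.diff(beats)
        assert abs(rr.mean() - 1.0) < 0.02
        assert abs(rr.std() - 0.05) < 0.01

    def test_anxious_state_raises_hr(self):
        p = SubjectProfile(baseline_hr=60, sdnn=0.03)
        p.deltas.hr_delta = 20.0
        _, beats = generate_ecg(p, 300, 256, state=True, seed=3)
        hr = 60.0 / np.diff(beats)
        assert abs(hr.mean() - 80.0) < 2.0

    @pytest.mark.parametrize("kwargs", [
        dict(duration_s=0, fs=256), dict(duration_s=-5, fs=256),
        dict(duration_s=10, fs=32),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            generate_ecg(SubjectProfile(), **kwargs)


class TestEDA:
    def test_no_scrs_no_noise_is_constant_tonic(self):
        p = SubjectProfile(eda_tonic=2.5, scr_rate=0.0)
        s = generate_eda(p, 60, 4, seed=0, noise_std=0.0, drift_amp=0.0)
        assert np.allclose(s, 2.5)

    def test_poisson_scr_count(self):
        p = SubjectProfile(scr_rate=6.0)
        _, events = generate_eda(p, 600, 4, seed=5, return_events=True)
        assert abs(events.size - 60) < 3 * np.sqrt(60)

    def test_anxious_state_raises_mean(self):
        p = SubjectProfile(scr_rate=2.0)
        lo = generate_eda(p, 300, 4, state=False, seed=9)
        hi = generate_eda(p, 300, 4, state=True, seed=9)
        assert hi.mean() > lo.mean()

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            SubjectProfile(scr_rate=-1.0)


class TestResp:
    def test_symmetric_halfcycles(self):
        p = SubjectProfile(resp_rate=12, ie_ratio=1.0)
        s = generate_resp(p, 60, 128, seed=1, jitter_cv=0.0, noise_std=0.0)
        crossings = np.flatnonzero(np.diff(np.signbit(s)))
        halves = np.diff(crossings) / 128.0
        assert np.allclose(halves, 2.5, atol=0.05)

    def test_ie_ratio_ground_truth(self):
        p = SubjectProfile(resp_rate=14, ie_ratio=0.5)
        _, cycles = generate_resp(p, 300, 128, seed=2, return_cycles=True)
        inhale = np.array([pk - t0 for t0, pk, _ in cycles])
        exhale = np.array([t1 - pk for _, pk, t1 in cycles])
        assert abs(inhale.mean() / exhale.mean() - 0.5) < 0.025

    def test_anxious_resp_delta(self):
        p = SubjectProfile(resp_rate=12)
        p.deltas.resp_delta = 4.0
        _, cycles = generate_resp(p, 300, 128, state=True, seed=3,
                                  return_cycles=True)
        rate = 60.0 * len(cycles) / (cycles[-1][2] - cycles[0][0])
        assert abs(rate - 16.0) < 1.0

    def test_invalid_ie_ratio(self):
        with pytest.raises(InvalidParameterError):
            SubjectProfile(ie_ratio=0.0)


class TestACC:
    def test_seated_noiseless_unit_gravity(self):
        acc = generate_acc("seated", 10, 64, seed=0, base_noise=0.0)
        net = np.sqrt((acc ** 2).sum(axis=0))
        assert np.allclose(net, 1.0)

    def test_walking_spectral_peak_near_2hz(self):
        acc = generate_acc("walking", 60, 64, seed=4)
        net = np.sqrt((acc ** 2).sum(axis=0))
        freqs, power = periodogram(net, 64)
        band = freqs > 0.5
        assert abs(freqs[band][np.argmax(power[band])] - 2.0) < 0.2

    def test_variable_more_dynamic_than_seated(self):
        seated = generate_acc("seated", 120, 64, seed=6)
        var = generate_acc("variable", 120, 64, seed=6)
        net_s = np.sqrt((seated ** 2).sum(axis=0))
        net_v = np.sqrt((var ** 2).sum(axis=0))
        assert net_v.std() > net_s.std()

    def test_unknown_activity(self):
        with pytest.raises(InvalidParameterError):
            generate_acc("running", 10, 64, seed=0)


class TestTempBVP:
    def test_temp_constant_without_drift(self):
        p = SubjectProfile(temp_base=33.0)
        s = generate_temp(p, 60, 4, seed=0, drift_std=0.0, noise_std=0.0)
        assert np.allclose(s, 33.0)

    def test_temp_anxious_shift(self):
        p = SubjectProfile(temp_base=33.0)
        s = generate_temp(p, 60, 4, state=True, seed=0, drift_std=0.0,
                          noise_std=0.0)
        assert np.allclose(s, 33.0 + p.deltas.temp_delta)

    @pytest.mark.parametrize("hr,expected", [(60, 1.0), (90, 1.5)])
    def test_bvp_dominant_frequency_is_heart_rate(self, hr, expected):
        p = SubjectProfile(baseline_hr=hr, sdnn=0.0)
        s = generate_bvp(p, 60, 64, seed=1, noise_std=0.0)
        freqs, power = periodogram(s, 64)
        band = (freqs >= 0.5) & (freqs <= 3.5)
        assert abs(freqs[band][np.argmax(power[band])] - expected) < 0.05


class TestSession:
    def test_single_relaxation_interval(self):
        plan = [ConditionInterval(0, 300, "relaxation")]
        rec = generate_session(SubjectProfile(), plan, seed=0, label_noise=0.0)
        iv = rec.annotations[0]
        assert iv.anxious_truth == 0
        assert 6 <= iv.stai_y6 <= 10

    def test_calibration_like_sequence_low_high_high(self):
        # guided relaxation, then cold pressor, then social stress
        plan = [ConditionInterval(0, 300, "relaxation"),
                ConditionInterval(300, 600, "cold_pressor"),
                ConditionInterval(600, 900, "tsst")]
        rec = generate_session(SubjectProfile(), plan, seed=2, label_noise=0.0)
        scores = [iv.stai_y6 for iv in rec.annotations]
        assert scores[0] < 11 and scores[1] >= 11 and scores[2] >= 11

    def test_duration_and_sample_counts(self):
        plan = [ConditionInterval(0, 120, "relaxation"),
                ConditionInterval(120, 300, "cold_pressor")]
        rec = generate_session(SubjectProfile(), plan, seed=0)
        assert rec.duration_s == 300
        for name, ch in rec.channels.items():
            # per-interval rendering must concatenate to the exact count
            expected = round(120 * ch.fs) + round(180 * ch.fs)
            assert ch.samples.size == expected == round(300 * CHANNEL_RATES[name])

    def test_overlapping_plan_rejected(self):
        plan = [ConditionInterval(0, 300, "relaxation"),
                ConditionInterval(200, 500, "tsst")]
        with pytest.raises(InvalidPlanError):
            generate_session(SubjectProfile(), plan, seed=0)


class TestCohort:
    def test_wild_anxious_time_fraction(self):
        cfg = CohortConfig(n_subjects=25, subset="in_the_wild",
                           session_duration_s=1800, seed=11,
                           wild_noise_snr=None)
        recs = generate_cohort(cfg)
        fracs = [sum(iv.duration_s for iv in r.annotations if iv.anxious_truth)
                 / r.duration_s for r in recs]
        assert abs(np.mean(fracs) - 0.1934) < 0.02

    def test_calibration_all_seated(self, calib_cohort):
        from wearanx.simulate import CONDITION_ACTIVITY

        for rec in calib_cohort:
            for iv in rec.annotations:
                assert CONDITION_ACTIVITY[iv.condition] == "seated"

    def test_determinism_bit_for_bit(self):
        cfg = CohortConfig(n_subjects=2, subset="in_lab",
                           session_duration_s=300, seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ra, rb in zip(a, b):
            for name in ra.channels:
                assert np.array_equal(ra.channels[name].samples,
                                      rb.channels[name].samples)
            assert np.array_equal(ra.true_beats_s, rb.true_beats_s)

    def test_unknown_subset_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortConfig(subset="outer_space")

    @pytest.mark.parametrize("duration", [137.0, 300.0])
    def test_sampling_consistency(self, duration):
        plan = build_plan("calibration", duration)
        rec = generate_session(SubjectProfile(), plan, seed=1)
        for name, ch in rec.channels.items():
            per_interval = sum(round(iv.duration_s * ch.fs)
                               for iv in rec.annotations)
            assert ch.samples.size == per_interval
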