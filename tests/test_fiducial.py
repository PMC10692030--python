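"""Fiducial-point detection and time-domain feature arithmetic."""

import numpy as np
import pytest

import wristpulse as wp
from wristpulse.fiducial import aggregate_subject, compute_features, pulse_width
from wristpulse.signal_io import CycleSegment
from wristpulse.synthetic import GROUP_SHAPES, CycleShape


def segment_from_wave(wave, start=0):
    return CycleSegment(start, start + wave.size, wave, float(wave[0]))


@pytest.fixture(scope="module")
def clean_cycle():
    wave, truth = wp.generate_cycle(GROUP_SHAPES[1], 0.761, 200.0)
    return segment_from_wave(wave), truth


class TestDetectFiducials:
    def test_all_seven_points_within_one_sample_of_truth(self, clean_cycle):
        seg, truth = clean_cycle
        fp = wp.detect_fiducials(seg, 200.0)
        detected = dict(A=fp.t_a, B=fp.t_b, C=fp.t_c, D=fp.t_d,
                        E=fp.t_e, F=fp.t_f, G=fp.t_g)
        for name, t in detected.items():
            true_idx = truth[name]
            assert abs(t * 200.0 - true_idx) <= 1.0, name

    def test_notch_amplitude_below_adjacent_peaks(self, clean_cycle):
        seg, _ = clean_cycle
        fp = wp.detect_fiducials(seg, 200.0)
        assert fp.amp_e <= min(fp.amp_d, fp.amp_f)
        assert fp.amp_b == max(fp.amp_b, fp.amp_c, fp.amp_d, fp.amp_e, fp.amp_f)

    def test_single_bump_cycle_flagged_unusable(self):
        shape = CycleShape(1.0, 0.3, 0.06, 0.0, 0.5, 0.05, 0.0, 0.7, 0.05)
        wave, _ = wp.generate_cycle(shape, 0.8, 200.0)
        fp = wp.detect_fiducials(segment_from_wave(wave), 200.0)
        assert fp is None or not (fp.has_c and fp.has_d and fp.has_f)

    def test_amplitude_scaling_scales_amplitudes_not_times(self, clean_cycle):
        seg, _ = clean_cycle
        fp1 = wp.detect_fiducials(seg, 200.0)
        fp2 = wp.detect_fiducials(segment_from_wave(seg.samples * 10.0), 200.0)
        assert fp1.t_b == fp2.t_b and fp1.t_e == fp2.t_e and fp1.t_d == fp2.t_d
        np.testing.assert_allclose(fp2.amp_b, 10 * fp1.amp_b)
        np.testing.assert_allclose(fp2.amp_e, 10 * fp1.amp_e)

    def test_start_index_shift_changes_nothing(self, clean_cycle):
        seg, _ = clean_cycle
        shifted = segment_from_wave(seg.samples, start=5000)
        f1 = compute_features(wp.detect_fiducials(seg, 200.0), seg, 200.0)
        f2 = compute_features(wp.detect_fiducials(shifted, 200.0), shifted, 200.0)
        assert f1.as_dict() == f2.as_dict()


class TestPulseWidth:
    def test_triangle_closed_form(self):
        """Symmetric triangle of height 1, base d: width at fraction f is f*d."""
        fs = 1000.0
        half = 200  # samples per side -> base d = 0.4 s
        tri = np.concatenate([np.linspace(0, 1, half + 1),
                              np.linspace(1, 0, half + 1)[1:], np.zeros(100)])
        seg = segment_from_wave(tri)
        d = 2 * half / fs
        assert pulse_width(seg, 1.0, 1 / 3, fs) == pytest.approx(d / 3, abs=1e-9)
        assert pulse_width(seg, 1.0, 1 / 5, fs) == pytest.approx(d / 5, abs=1e-9)

    def test_gaussian_closed_form(self):
        """Gaussian bump: width = 2*sigma*sqrt(2*ln(1/(1-f)))."""
        period, fs, sigma_frac = 1.0, 2000.0, 0.05
        shape = CycleShape(1.0, 0.5, sigma_frac, 0.0, 0.6, 0.05, 0.0, 0.7, 0.05)
        wave, _ = wp.generate_cycle(shape, period, fs)
        seg = segment_from_wave(wave)
        sigma_t = sigma_frac * period
        for f in (1 / 3, 1 / 5):
            expected = 2 * sigma_t * np.sqrt(2 * np.log(1 / (1 - f)))
            assert pulse_width(seg, wave.max() - wave[0], f, fs) == pytest.approx(
                expected, rel=2e-3)

    def test_narrower_fraction_gives_narrower_width(self, clean_cycle):
        seg, _ = clean_cycle
        h1 = seg.samples.max() - seg.samples[0]
        assert pulse_width(seg, h1, 1 / 5, 200.0) <= pulse_width(seg, h1, 1 / 3, 200.0)

    def test_threshold_never_reached_raises(self, clean_cycle):
        seg, _ = clean_cycle
        with pytest.raises(ValueError, match="threshold"):
            pulse_width(seg, 100.0, 1 / 3, 200.0)


class TestComputeFeatures:
    def test_t5_from_notch_and_cycle_end(self):
        """Landmark times t(E), t(G) determine t5 = T - t4 (checked against
        the published group-1 medians as one consistent numeric instance)."""
        fs = 1000.0
        fp = wp.FiducialPoints(
            t_a=0.0, t_b=0.145, t_c=0.214, t_d=0.239, t_e=0.348, t_f=0.43,
            t_g=0.760, amp_a=0.0, amp_b=1.0, amp_c=0.8, amp_d=0.81,
            amp_e=0.478, amp_f=0.54, amp_g=0.0)
        wave, _ = wp.generate_cycle(GROUP_SHAPES[1], 0.761, fs)
        seg = segment_from_wave(wave)
        f = compute_features(fp, seg, fs)
        assert f.T == pytest.approx(0.761, abs=1e-9)
        assert f.t5 == pytest.approx(0.761 - 0.348, abs=1e-9)
        assert f.t4 + f.t5 == pytest.approx(f.T, abs=1e-12)

    def test_ratio_features_equal_their_quotients(self, clean_cycle):
        seg, _ = clean_cycle
        f = compute_features(wp.detect_fiducials(seg, 200.0), seg, 200.0)
        assert f.h4_h1 == f.h4 / f.h1
        assert f.t1_T == f.t1 / f.T
        assert f.t5_t4 == f.t5 / f.t4
        assert f.w1_T == f.w1 / f.T
        assert 0 <= f.h4_h1 <= 1 and f.h1 > 0
        assert f.t1 < f.t2 <= f.t3 < f.t4 < f.T

    def test_features_match_dense_grid_oracle(self):
        """Sampled-cycle features agree with the analytic dense-grid values
        to one sample / one percent."""
        from wristpulse.synthetic import shape_features
        fs = 200.0
        for g in (1, 2, 3):
            period = wp.GROUP_PERIODS[g]
            wave, _ = wp.generate_cycle(GROUP_SHAPES[g], period, fs)
            seg = segment_from_wave(wave)
            f = compute_features(wp.detect_fiducials(seg, fs), seg, fs)
            oracle = shape_features(GROUP_SHAPES[g], period)
            for k in ("t1", "t4", "T", "w1", "w2"):
                assert abs(f.as_dict()[k] - oracle[k]) <= 1.5 / fs, (g, k)
            for k in ("h1", "h4_h1", "h3_h1"):
                assert f.as_dict()[k] == pytest.approx(oracle[k], rel=0.02), (g, k)


class TestAggregateSubject:
    def test_median_of_identical_cycles_is_any_cycle(self, clean_cycle):
        seg, _ = clean_cycle
        f = compute_features(wp.detect_fiducials(seg, 200.0), seg, 200.0)
        agg = aggregate_subject([f, f, f, f])
        assert agg.as_dict() == pytest.approx(f.as_dict())

    def test_single_outlier_does_not_move_the_median(self, clean_cycle):
        seg, _ = clean_cycle
        f = compute_features(wp.detect_fiducials(seg, 200.0), seg, 200.0)
        outlier = wp.TimeDomainFeatures(**{k: v * 50 for k, v in f.as_dict().items()})
        agg = aggregate_subject([f] * 9 + [outlier])
        assert agg.as_dict() == pytest.approx(f.as_dict())

    def test_fewer_than_three_cycles_excluded(self, clean_cycle):
        seg, _ = clean_cycle
        f = compute_features(wp.detect_fiducials(seg, 200.0), seg, 200.0)
        with pytest.raises(ValueError, match="excluded"):
            aggregate_subject([f, f])
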