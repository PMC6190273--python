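import math

import numpy as np
import pytest

from avfppg.features import features_from_record
from avfppg.grading import dos_to_class
from avfppg.synth import (
    AsymmetryParams,
    JitterParams,
    PulseShapeParams,
    add_noise,
    asymmetry_for_dos,
    generate_cohort,
    generate_subject,
    read_record_csv,
    write_record_csv,
)


class TestParams:
    def test_pulse_shape_rejects_overlong_systole(self):
        with pytest.raises(ValueError):
            PulseShapeParams(heart_rate=120, rise_time=0.3, notch_delay=0.25)

    @pytest.mark.parametrize("depth", [0.0, 1.0, -0.2])
    def test_notch_depth_strictly_interior(self, depth):
        with pytest.raises(ValueError):
            PulseShapeParams(notch_depth=depth)

    def test_asymmetry_requires_positive_ratio(self):
        with pytest.raises(ValueError):
            AsymmetryParams(amplitude_ratio=0.0)
        with pytest.raises(ValueError):
            AsymmetryParams(foot_delay=math.nan)

    def test_dos_coupling_is_monotone(self):
        lo, hi = asymmetry_for_dos(0.2), asymmetry_for_dos(0.6)
        assert hi.foot_delay > lo.foot_delay
        assert hi.rise_time_skew > lo.rise_time_skew
        assert hi.amplitude_ratio < lo.amplitude_ratio
        assert hi.notch_shift > lo.notch_shift


class TestGenerateSubject:
    def test_record_shape_and_meta(self):
        rec, meta = generate_subject(0.4, duration=8.0, seed=3)
        assert len(rec.right) == len(rec.left) == 8000
        assert rec.fs == 1000.0
        assert meta.dos == pytest.approx(0.4)
        assert meta.D == 1.0
        assert meta.d == pytest.approx(math.sqrt(0.6))
        assert meta.true_class == dos_to_class(0.4)

    def test_total_occlusion_meta_diameter(self):
        _, meta = generate_subject(1.0, duration=8.0, seed=0)
        assert meta.d == 0.0

    def test_deterministic_under_seed(self):
        r1, _ = generate_subject(0.5, duration=6.0, seed=9)
        r2, _ = generate_subject(0.5, duration=6.0, seed=9)
        np.testing.assert_array_equal(r1.right, r2.right)
        np.testing.assert_array_equal(r1.left, r2.left)

    def test_zero_dos_channels_identical_up_to_jitter(self):
        rec, _ = generate_subject(0.0, duration=8.0, seed=7, jitter=JitterParams.off())
        np.testing.assert_allclose(rec.right, rec.left, atol=1e-12)
        fv = features_from_record(rec).as_array()
        assert np.all(fv < np.array([0.002, 0.002, 0.002, 0.01]))

    def test_features_monotone_in_dos_without_jitter(self):
        """Every raw asymmetry feature is non-decreasing along a DOS grid."""
        prev = None
        for dos in np.arange(0.0, 1.0, 0.1):
            rec, _ = generate_subject(
                float(dos), duration=10.0, seed=2, jitter=JitterParams.off()
            )
            fv = features_from_record(rec).as_array()
            if prev is not None:
                assert np.all(fv >= prev - 1e-9), f"feature decreased at DOS {dos}"
            prev = fv

    def test_rejects_invalid_dos_and_short_duration(self):
        with pytest.raises(ValueError):
            generate_subject(1.2, duration=10.0, seed=0)
        with pytest.raises(ValueError):
            generate_subject(0.5, duration=2.0, seed=0)  # < 5 beat periods

    def test_annotations_cover_both_channels(self):
        rec, _ = generate_subject(0.3, duration=8.0, seed=4, jitter=JitterParams.off())
        for ch in ("right", "left"):
            ann = rec.annotations[ch]
            assert len(ann["foot"]) >= 7
            assert np.all(np.diff(ann["foot"]) > 0)
            assert np.all(ann["peak"] > ann["foot"])
            present = ann["notch"] >= 0
            assert present.mean() > 0.9
            assert np.all(ann["notch"][present] > ann["peak"][present])


class TestGenerateCohort:
    def test_counts_and_labels(self):
        cohort = generate_cohort(4, seed=1)
        assert len(cohort) == 12
        labels = [meta.true_class for _, meta in cohort]
        assert labels.count(1) == labels.count(2) == labels.count(3) == 4
        for _, meta in cohort:
            assert meta.true_class == dos_to_class(meta.dos)

    def test_bitwise_reproducible(self):
        a = generate_cohort(2, seed=5)
        b = generate_cohort(2, seed=5)
        for (ra, _), (rb, _) in zip(a, b):
            np.testing.assert_array_equal(ra.right, rb.right)

    def test_rejects_bad_intervals(self):
        with pytest.raises(ValueError):
            generate_cohort(2, class_dos_ranges=((0.3, 0.1), (0.3, 0.5), (0.5, 0.8)))
        with pytest.raises(ValueError):
            generate_cohort(0)


class TestAddNoise:
    def test_empirical_snr_matches_target(self):
        rec, _ = generate_subject(0.3, duration=10.0, seed=8)
        for color in ("white", "signal"):
            for target in (40.0, 30.0, 20.0):
                noisy = add_noise(rec.left, target, seed=2, color=color)
                w = noisy - rec.left
                p_s = np.mean((rec.left - rec.left.mean()) ** 2)
                realized = 10.0 * np.log10(p_s / np.mean(w**2))
                assert realized == pytest.approx(target, abs=0.5)

    def test_mean_snr_calibration_over_records(self):
        """Mean |empirical - target| below 0.2 dB over many 10 s records."""
        errs = []
        for k in range(20):
            rec, _ = generate_subject(0.2 + 0.02 * (k % 10), duration=10.0, seed=k)
            noisy = add_noise(rec.right, 30.0, seed=100 + k)
            w = noisy - rec.right
            p_s = np.mean((rec.right - rec.right.mean()) ** 2)
            errs.append(abs(10.0 * np.log10(p_s / np.mean(w**2)) - 30.0))
        assert np.mean(errs) < 0.2

    def test_infinite_snr_returns_input(self):
        x = np.sin(np.linspace(0, 10, 5000))
        np.testing.assert_array_equal(add_noise(x, math.inf, seed=0), x)

    def test_zero_power_signal_raises(self):
        with pytest.raises(ValueError, match="zero power"):
            add_noise(np.zeros(1000), 20.0)

    def test_signal_color_preserves_spectrum_shape(self):
        """Surrogate noise concentrates its power in the signal band."""
        rec, _ = generate_subject(0.3, duration=10.0, seed=8)
        x = rec.left
        w = add_noise(x, 20.0, seed=3, color="signal") - x
        spec = np.abs(np.fft.rfft(w)) ** 2
        freqs = np.fft.rfftfreq(len(w), d=1e-3)
        in_band = spec[freqs <= 20].sum() / spec.sum()
        assert in_band > 0.95


class TestRecordCsv:
    def test_round_trip(self, tmp_path):
        rec, _ = generate_subject(0.2, duration=6.0, seed=2)
        path = tmp_path / "rec.csv"
        write_record_csv(rec, path)
        back = read_record_csv(path)
        np.testing.assert_allclose(back.right, rec.right, atol=1e-9)
        np.testing.assert_allclose(back.left, rec.left, atol=1e-9)

    def test_header_flag_round_trip(self, tmp_path):
        rec, _ = generate_subject(0.2, duration=6.0, seed=2)
        path = tmp_path / "rec.csv"
        write_record_csv(rec, path, header=True)
        back = read_record_csv(path)  # header sniffed
        np.testing.assert_allclose(back.left, rec.left, atol=1e-9)
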