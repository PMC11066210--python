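import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swaylab.errors import InvalidParameterError
from swaylab.features import (
    FEATURE_NAMES,
    average_jerk,
    cross_correlation,
    difference_sum,
    extract_features,
    sample_entropy,
    shannon_entropy,
    sparsity,
    spectral_features,
    stat_features,
)
from swaylab.types import IMURecording


def sampen_naive(x, m=2, r_frac=0.2):
    """Independent O(N^2) pair-counting sample entropy oracle."""
    x = np.asarray(x, dtype=float)
    n = x.size
    r = r_frac * np.std(x, ddof=1)
    nt = n - m
    a = b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            if np.max(np.abs(x[i : i + m] - x[j : j + m])) <= r:
                b += 1
                if np.max(np.abs(x[i : i + m + 1] - x[j : j + m + 1])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.log(n - m)
    return -math.log(a / b)


def make_recording(ml, ap, vt, fs=128.0):
    return IMURecording(
        subject_id="S001", placement="lumbar", role="center",
        condition="EOSS", fs=fs, ml=ml, ap=ap, vt=vt,
    )


class TestStatFeatures:
    def test_hand_values(self):
        sd, skew, kurt = stat_features(np.array([1.0, 2, 3, 4, 5]))
        assert sd == pytest.approx(math.sqrt(2.5))  # 1.5811
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_constant_guard(self):
        assert stat_features(np.array([3.0, 3, 3, 3])) == (0.0, 0.0, 0.0)

    def test_gaussian_kurtosis_limit(self, rng):
        x = rng.standard_normal(10**5)
        _, _, kurt = stat_features(x)
        assert abs(kurt) < 0.1


class TestSparsity:
    def test_one_hot_is_one(self):
        assert sparsity(np.array([0.0, 0, 1, 0])) == pytest.approx(1.0)

    def test_constant_magnitude_is_zero(self):
        assert sparsity(np.array([1.0, 1, 1, 1])) == pytest.approx(0.0)

    def test_hand_evaluation(self):
        # (sqrt(4) - 2/sqrt(2)) / (sqrt(4) - 1) = 2 - sqrt(2)
        assert sparsity(np.array([1.0, 1, 0, 0])) == pytest.approx(
            2 - math.sqrt(2)
        )

    def test_all_zero_guard(self):
        assert sparsity(np.zeros(8)) == 0.0


class TestShannonEntropy:
    def test_constant_is_zero(self):
        assert shannon_entropy(np.full(64, 2.5)) == 0.0

    def test_equal_bin_counts_hit_maximum(self):
        x = np.repeat(np.arange(16.0), 10)
        assert shannon_entropy(x, n_bins=16) == pytest.approx(4.0)

    def test_uniform_monte_carlo(self, rng):
        x = rng.uniform(size=10**4)
        assert shannon_entropy(x) == pytest.approx(4.0, abs=0.05)


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.full(32, 1.0)) == 0.0

    def test_alternating_signal_matches_oracle(self):
        x = np.tile([1.0, 2.0], 32)
        assert sample_entropy(x) == pytest.approx(sampen_naive(x), abs=1e-12)

    def test_white_noise_matches_oracle(self, rng):
        x = rng.standard_normal(512)
        val = sample_entropy(x)
        assert val > 0.5
        assert val == pytest.approx(sampen_naive(x), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_entropy(np.arange(3.0))


class TestSpectralFeatures:
    def test_pure_tone(self):
        t = np.arange(256) / 128.0
        ent, f_main, p_main, f_sec, p_sec = spectral_features(
            np.sin(2 * np.pi * 8 * t), 128.0
        )
        assert f_main == pytest.approx(8.0)
        assert ent == pytest.approx(0.0, abs=1e-6)
        assert p_main >= p_sec

    def test_two_tone_peaks_match_fft_oracle(self):
        t = np.arange(256) / 128.0
        x = 2 * np.sin(2 * np.pi * 4 * t) + np.sin(2 * np.pi * 10 * t)
        ent, f_main, p_main, f_sec, p_sec = spectral_features(x, 128.0)
        # independent oracle: raw FFT magnitudes
        mag = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(256, 1 / 128.0)
        order = np.argsort(mag[1:])[::-1]
        assert f_main == pytest.approx(freqs[1:][order[0]]) == 4.0
        assert f_sec == pytest.approx(freqs[1:][order[1]]) == 10.0
        assert p_main > p_sec > 0

    def test_constant_guard(self):
        assert spectral_features(np.full(64, 3.0), 128.0) == (0, 0, 0, 0, 0)

    def test_frequencies_within_nyquist(self, rng):
        x = rng.standard_normal(512)
        _, f_main, _, f_sec, _ = spectral_features(x, 128.0)
        assert 0 <= f_main <= 64.0 and 0 <= f_sec <= 64.0


class TestTimeDomain:
    def test_difference_sum_hand_values(self):
        assert difference_sum(np.array([0.0, 1, 2, 3])) == 3.0
        assert difference_sum(np.array([0.0, 2, 1])) == 3.0
        assert difference_sum(np.full(16, 4.2)) == 0.0

    def test_difference_sum_offset_invariant(self, rng):
        x = rng.normal(size=100)
        assert difference_sum(x + 7.5) == pytest.approx(difference_sum(x))

    def test_average_jerk_hand_values(self):
        assert average_jerk(np.arange(10.0), 128.0) == pytest.approx(128.0)
        assert average_jerk(np.arange(0, 5, 0.5), 128.0) == pytest.approx(64.0)
        assert average_jerk(np.full(16, 1.0), 128.0) == 0.0


class TestCrossCorrelation:
    def test_self_and_negated(self, rng):
        x = rng.normal(size=64)
        assert cross_correlation(x, x) == pytest.approx(1.0)
        assert cross_correlation(x, -x) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        x, y = rng.standard_normal((2, 10**4))
        assert abs(cross_correlation(x, y)) < 0.05

    def test_constant_guard(self):
        assert cross_correlation(np.full(8, 1.0), np.arange(8.0)) == 0.0

    def test_affine_invariance_and_symmetry(self, rng):
        x, y = rng.standard_normal((2, 128))
        r = cross_correlation(x, y)
        assert cross_correlation(y, x) == pytest.approx(r)
        assert cross_correlation(2.5 * x + 3, y) == pytest.approx(r)


class TestExtractFeatures:
    def test_yields_exactly_42_named_features(self, rng):
        rec = make_recording(*rng.standard_normal((3, 256)))
        feats = extract_features(rec)
        assert tuple(feats) == FEATURE_NAMES
        assert len(feats) == 42
        assert all(np.isfinite(v) for v in feats.values())

    def test_all_zero_recording_hits_guards(self):
        rec = make_recording(np.zeros(256), np.zeros(256), np.zeros(256))
        feats = extract_features(rec)
        assert len(feats) == 42
        assert all(np.isfinite(v) for v in feats.values())
        assert feats["ML_sd"] == 0.0 and feats["xcorr_MLAP"] == 0.0

    def test_axis_permutation_symmetry(self, rng):
        ml, ap, vt = rng.standard_normal((3, 256))
        feats = extract_features(make_recording(ml, ap, vt))
        swapped = extract_features(make_recording(ap, ml, vt))
        for name in ("sd", "sample_entropy", "main_freq", "difference_sum"):
            assert swapped[f"ML_{name}"] == pytest.approx(feats[f"AP_{name}"])
            assert swapped[f"AP_{name}"] == pytest.approx(feats[f"ML_{name}"])
        assert swapped["xcorr_MLAP"] == pytest.approx(feats["xcorr_MLAP"])
        assert swapped["xcorr_MLVT"] == pytest.approx(feats["xcorr_APVT"])
        assert swapped["xcorr_APVT"] == pytest.approx(feats["xcorr_MLVT"])


class TestAffineInvariance:
    """Distribution-shape features are unchanged under x → a·x + b (a > 0)."""

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        a=st.sampled_from([0.5, 1.5, 2.0, 3.0]),
        b=st.sampled_from([-5.0, 0.0, 2.5]),
        seed=st.integers(0, 50),
    )
    def test_invariant_features(self, a, b, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        y = a * x + b
        _, skew0, kurt0 = stat_features(x)
        _, skew1, kurt1 = stat_features(y)
        assert skew1 == pytest.approx(skew0, abs=1e-9)
        assert kurt1 == pytest.approx(kurt0, abs=1e-9)
        assert shannon_entropy(y) == pytest.approx(shannon_entropy(x), abs=1e-9)
        assert sample_entropy(y) == pytest.approx(sample_entropy(x), abs=1e-9)
        f0 = spectral_features(x, 128.0)
        f1 = spectral_features(y, 128.0)
        assert f1[1] == pytest.approx(f0[1])  # main frequency

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.sampled_from([0.5, 2.0, 10.0]), seed=st.integers(0, 50))
    def test_scale_equivariant_features(self, a, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        sd0, _, _ = stat_features(x)
        sd1, _, _ = stat_features(a * x)
        assert sd1 == pytest.approx(a * sd0, rel=1e-12)
        assert difference_sum(a * x) == pytest.approx(
            a * difference_sum(x), rel=1e-12
        )
        assert average_jerk(a * x, 128.0) == pytest.approx(
            a * average_jerk(x, 128.0), rel=1e-12
        )
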