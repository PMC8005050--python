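"""The 21/18 per-burst predictors against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neckcast.device_models import AWT, Burst, EOBS
from neckcast.features import (
    BURST_FEATURE_NAMES,
    CONTINUOUS_FEATURE_NAMES,
    ICV_SENTINEL,
    WM_SENTINEL,
    axis_moments,
    combined_features,
    feature_table,
    feature_vector,
    weighted_mean_frequency,
)
from neckcast.preprocess import LabeledDataset


def brute_moments(values):
    """Independent single-pass oracle: plain-python moment formulas."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    skew = m3 / m2**1.5
    kurt = m4 / m2**2 - 3.0
    return mean, sd, mean / sd, kurt, skew


def brute_wm(values, rate):
    """DFT-by-definition oracle for the weighted mean frequency."""
    n = len(values)
    centered = [v - sum(values) / n for v in values]
    num = den = 0.0
    for k in range(1, n // 2 + 1):
        re = sum(c * math.cos(-2 * math.pi * k * j / n) for j, c in enumerate(centered))
        im = sum(c * math.sin(-2 * math.pi * k * j / n) for j, c in enumerate(centered))
        amp = math.hypot(re, im)
        num += (k * rate / n) * amp
        den += amp
    return num / den


def _burst(sway, surge, heave):
    return Burst(
        individual="a", device=EOBS.name, start_time=0.0,
        samples_sway=sway, samples_surge=surge, samples_heave=heave,
    )


class TestAxisMoments:
    def test_hand_arithmetic_12345(self):
        mean, sd, icv, kurt, skew = axis_moments([1, 2, 3, 4, 5])
        assert mean == 3
        assert sd == pytest.approx(1.5811, abs=1e-4)
        assert icv == pytest.approx(1.8974, abs=1e-4)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_constant_sequence_sentinels(self):
        mean, sd, icv, kurt, skew = axis_moments([7.0] * 10)
        assert (mean, sd) == (7.0, 0.0)
        assert icv == ICV_SENTINEL
        assert kurt == 0.0 and skew == 0.0
        _, _, icv_neg, _, _ = axis_moments([-7.0] * 10)
        assert icv_neg == -ICV_SENTINEL

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            axis_moments([1, 2, 3, 4])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(2048, 100, 82)
        got = axis_moments(values)
        expected = brute_moments(list(values))
        np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestWeightedMeanFrequency:
    def test_sinusoid_lands_within_one_bin(self):
        rate, n = EOBS.sample_rate, 82
        t = np.arange(n) / rate
        wm = weighted_mean_frequency(np.sin(2 * np.pi * 4.0 * t), rate)
        assert abs(wm - 4.0) < rate / n  # one DFT bin width

    def test_white_noise_near_mid_band(self):
        # flat expected spectrum -> wm concentrates near the mean bin freq
        rate, n = EOBS.sample_rate, 82
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)[1:]
        rng = np.random.default_rng(0)
        wms = [
            weighted_mean_frequency(rng.normal(size=n), rate) for _ in range(400)
        ]
        assert np.mean(wms) == pytest.approx(freqs.mean(), rel=0.05)

    def test_constant_input_sentinel(self):
        assert weighted_mean_frequency(np.full(82, 3.0), 33.8) == WM_SENTINEL

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_dft_by_definition(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, 40)  # small n: the oracle is O(n^2)
        got = weighted_mean_frequency(values, 33.8)
        assert got == pytest.approx(brute_wm(list(values), 33.8), rel=1e-9)


class TestCombinedFeatures:
    def test_gravity_on_heave(self):
        n = 82
        q, pitch, roll = combined_features(
            np.zeros(n), np.zeros(n), np.ones(n)
        )
        assert (q, pitch, roll) == (1.0, 0.0, 0.0)

    def test_head_pitched_up_surge_carries_minus_g(self):
        n = 82
        _, pitch, _ = combined_features(np.zeros(n), -np.ones(n), np.zeros(n))
        assert pitch == pytest.approx(math.pi / 2)

    def test_roll_quadrant(self):
        n = 82
        _, _, roll = combined_features(np.ones(n), np.zeros(n), np.zeros(n))
        assert roll == pytest.approx(math.pi / 2)

    def test_q_matches_per_sample_norm_loop(self, rng):
        s, u, h = (rng.normal(0, 1, 82) for _ in range(3))
        q, _, _ = combined_features(s, u, h)
        oracle = sum(
            math.sqrt(a * a + b * b + c * c) for a, b, c in zip(s, u, h)
        ) / 82
        assert q == pytest.approx(oracle, rel=1e-12)

    def test_q_jensen_lower_bound(self, rng):
        for _ in range(20):
            s, u, h = (rng.normal(0, 2, 82) for _ in range(3))
            q, _, _ = combined_features(s, u, h)
            assert q >= math.sqrt(s.mean() ** 2 + u.mean() ** 2 + h.mean() ** 2) - 1e-12


class TestFeatureVector:
    def test_burst_mode_has_exactly_21_named_entries(self, rng):
        burst = _burst(*(rng.normal(2048, 50, 82) for _ in range(3)))
        vec = feature_vector(burst, "burst", sample_rate=33.8)
        assert tuple(vec) == BURST_FEATURE_NAMES
        assert len(vec) == 21

    def test_continuous_mode_has_exactly_18(self, rng):
        burst = _burst(*(rng.normal(0, 50, 30) for _ in range(3)))
        vec = feature_vector(burst, "continuous")
        assert tuple(vec) == CONTINUOUS_FEATURE_NAMES
        assert len(vec) == 18
        assert not any(k.startswith("wm_") for k in vec)

    def test_sample_order_only_affects_wm(self, rng):
        arrays = [rng.normal(2048, 50, 82) for _ in range(3)]
        burst = _burst(*arrays)
        perm = rng.permutation(82)
        shuffled = _burst(*(a[perm] for a in arrays))
        v0 = feature_vector(burst, "burst", sample_rate=33.8)
        v1 = feature_vector(shuffled, "burst", sample_rate=33.8)
        for name in BURST_FEATURE_NAMES:
            if not name.startswith("wm_"):
                assert v1[name] == pytest.approx(v0[name], rel=1e-9)

    def test_zero_g_offset_applies_to_orientation_only(self, rng):
        values = 2048 + rng.normal(0, 10, 82)
        burst = _burst(values, values, values + 512)
        with_off = feature_vector(
            burst, "burst", sample_rate=33.8, zero_g_count=2048.0
        )
        without = feature_vector(burst, "burst", sample_rate=33.8)
        assert with_off["mn_sway"] == without["mn_sway"]
        assert with_off["pitch"] != without["pitch"]

    def test_feature_table_column_layout(self, eobs_table):
        assert list(eobs_table.columns[:3]) == ["individual", "burst_id", "label"]
        assert tuple(eobs_table.columns[3:]) == BURST_FEATURE_NAMES

    def test_continuous_feature_table_has_18_predictors(self, awt_table):
        assert tuple(awt_table.columns[3:]) == CONTINUOUS_FEATURE_NAMES


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    shift=st.floats(-500, 500, allow_nan=False),
    scale=st.floats(0.1, 50, allow_nan=False),
    seed=st.integers(0, 2**20),
)
def test_shift_and_scale_laws(shift, scale, seed):
    """sd/skew/kurt/wm shift-invariant; mean/sd/q scale-equivariant;
    icv/skew/kurt/pitch/roll/wm scale-invariant."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0, 1, 82) + rng.uniform(-2, 2)
    rate = 33.8
    m0 = axis_moments(values)
    m_shift = axis_moments(values + shift)
    assert m_shift[0] == pytest.approx(m0[0] + shift, abs=1e-8)
    assert m_shift[1] == pytest.approx(m0[1], rel=1e-8)
    assert m_shift[3] == pytest.approx(m0[3], rel=1e-6, abs=1e-6)
    assert m_shift[4] == pytest.approx(m0[4], rel=1e-6, abs=1e-6)
    assert weighted_mean_frequency(values + shift, rate) == pytest.approx(
        weighted_mean_frequency(values, rate), rel=1e-8
    )
    m_scale = axis_moments(values * scale)
    assert m_scale[0] == pytest.approx(m0[0] * scale, rel=1e-8, abs=1e-10)
    assert m_scale[1] == pytest.approx(m0[1] * scale, rel=1e-8)
    assert m_scale[2] == pytest.approx(m0[2], rel=1e-8)  # icv invariant
    assert weighted_mean_frequency(values * scale, rate) == pytest.approx(
        weighted_mean_frequency(values, rate), rel=1e-8
    )
    q0, p0, r0 = combined_features(values, values[::-1], values + 1)
    q1, p1, r1 = combined_features(
        values * scale, values[::-1] * scale, (values + 1) * scale
    )
    assert q1 == pytest.approx(q0 * scale, rel=1e-8)
    assert p1 == pytest.approx(p0, rel=1e-8, abs=1e-10)
    assert r1 == pytest.approx(r0, rel=1e-8, abs=1e-10)
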