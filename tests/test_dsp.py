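"""The 17 DSP features against independent brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from glycocast import DSP_FEATURE_NAMES, extract_dsp_vector
from glycocast.dsp import (
    bg_risk_index,
    clock_time_features,
    cv,
    gmc_feature,
    haar_powers,
    psd_feature,
    tir,
)

from conftest import constant_series, make_series


def random_day_series(seed, low=60.0, high=350.0):
    rng = np.random.default_rng(seed)
    return make_series(rng.uniform(low, high, 96))


# ---------------------------------------------------------------- oracles --

def oracle_gmc(x, k, h):
    vals = [(x[i] - k * x[i + 1]) / h**k for i in range(len(x) - 1)]
    return sum(abs(v) for v in vals) / len(vals)


def oracle_tir(x, lo, hi):
    return sum(1 for v in x if lo <= v <= hi) / len(x)


def oracle_cv(x):
    m = sum(x) / len(x)
    var = sum((v - m) ** 2 for v in x) / len(x)
    return math.sqrt(var) / m


def oracle_risk(x, side):
    total = 0.0
    for v in x:
        g = 1.509 * (math.log(v) ** 1.084 - 5.381)
        if (side == "low" and g < 0) or (side == "high" and g > 0):
            total += 10.0 * g * g
    return total / len(x)


def oracle_haar_powers(x):
    """Hand-rolled orthonormal Haar cascade (length divisible by 8)."""
    x = np.asarray(x, float)
    x = x - x.mean()
    powers = []
    approx = x
    for _ in range(3):
        a = approx.reshape(-1, 2)
        detail = (a[:, 0] - a[:, 1]) / math.sqrt(2)
        approx = (a[:, 0] + a[:, 1]) / math.sqrt(2)
        powers.append(float(np.mean(detail**2)))
    return tuple(powers)


def oracle_clock(x, n_days, hour, minute):
    spd = 96
    slot = (hour * 60 + minute) // 15
    return sum(x[d * spd + slot] for d in range(n_days)) / n_days


# ------------------------------------------------------------------ tests --

class TestGMC:
    def test_constant_series_first_order_zero(self):
        assert gmc_feature(constant_series(130.0), 1.0) == 0.0

    def test_constant_series_second_order(self):
        # each term (c - 2c)/1 = -c, mean |.| = c
        assert gmc_feature(constant_series(130.0, n_days=1), 2.0, h_hours=1.0) == pytest.approx(130.0)

    def test_single_step_example(self):
        # only the first step is non-flat: (100 - 110)/0.25 = -40, so the
        # mean-|.| aggregate over the 95 steps is 40/95
        s = make_series([100.0] + [110.0] * 95)
        assert gmc_feature(s, 1.0) == pytest.approx(40.0 / 95)
        assert oracle_gmc([100.0, 110.0], 1.0, 0.25) == pytest.approx(40.0)

    @pytest.mark.parametrize("k", [1.0, 1.5, 2.0])
    def test_matches_oracle(self, k):
        for seed in range(10):
            s = random_day_series(seed)
            expect = oracle_gmc(s.values, k, 0.25)
            assert gmc_feature(s, k) == pytest.approx(expect, rel=1e-10)


class TestTIR:
    def test_all_in_range(self):
        assert tir(constant_series(120.0), 70, 180) == 1.0

    def test_inclusive_bounds(self):
        s = make_series([60.0, 70.0, 180.0, 181.0] + [250.0] * 92)
        assert tir(s, 70, 180) == pytest.approx(2 / 96)

    def test_empty_intersection(self):
        assert tir(constant_series(120.0), 300, 350) == 0.0

    def test_matches_oracle_and_partition_bound(self):
        ranges = [(300, 350), (70, 180), (250, 300), (180, 250)]
        for seed in range(10):
            s = random_day_series(seed)
            total = 0.0
            for lo, hi in ranges:
                val = tir(s, lo, hi)
                assert val == pytest.approx(oracle_tir(s.values, lo, hi), rel=1e-12)
                total += val
            assert total <= 1.0 + 1e-12


class TestCV:
    def test_constant_is_zero(self):
        assert cv(constant_series(150.0)) == 0.0

    def test_population_sd_convention(self):
        s = make_series([90.0, 110.0] * 48)
        assert cv(s) == pytest.approx(0.1)

    def test_scale_invariance_and_oracle(self):
        for seed in range(10):
            s = random_day_series(seed)
            assert cv(s) == pytest.approx(oracle_cv(s.values), rel=1e-10)
            assert cv(make_series(s.values * 1.5)) == pytest.approx(cv(s), rel=1e-10)


class TestPSD:
    def test_constant_is_negligible(self):
        assert psd_feature(constant_series(120.0)) < 1e-10

    def test_sinusoid_power_concentrates_at_one_cycle_per_day(self):
        from scipy.signal import welch

        rng = np.random.default_rng(0)
        t = np.arange(1344)
        x = 150 + 30 * np.sin(2 * np.pi * t / 96) + rng.normal(0, 0.3, 1344)
        s = make_series(x)
        f0 = 1 / 24  # cycles per hour
        # oracle: the same windowed periodogram computed directly
        f, pxx = welch(
            x - x.mean(), fs=4.0, window="hann", nperseg=256, noverlap=128,
            detrend=False,
        )
        i = int(np.searchsorted(f, f0))
        # the spectral peak sits in the two bins bracketing 1 cycle/day and
        # holds the bulk of the power (Hann leakage spreads a few percent)
        assert pxx.argmax() in (i - 1, i)
        assert pxx[i - 1 : i + 1].sum() / pxx.sum() > 0.90
        # and the integrated band feature around f0 dominates the total
        assert psd_feature(s, band=(f0 / 3, f0 * 3)) / psd_feature(s) > 0.95

    def test_parseval_for_white_noise(self):
        rng = np.random.default_rng(1)
        x = rng.normal(150, 20, 1344)
        s = make_series(np.clip(x, 60, 400))
        assert psd_feature(s) == pytest.approx(s.values.var(), rel=0.1)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="Welch"):
            psd_feature(constant_series(120.0, n_days=1), nperseg=256)


class TestRiskIndex:
    def test_neutral_point_zeroes_both_sides(self):
        x_star = brentq(lambda x: math.log(x) ** 1.084 - 5.381, 50, 300)
        assert x_star == pytest.approx(112.9, abs=0.5)
        s = constant_series(x_star)
        assert bg_risk_index(s, "low") == pytest.approx(0.0, abs=1e-12)
        assert bg_risk_index(s, "high") == pytest.approx(0.0, abs=1e-12)

    def test_low_reading_has_no_high_risk(self):
        assert bg_risk_index(constant_series(50.0), "high") == 0.0
        assert bg_risk_index(constant_series(50.0), "low") > 0.0

    def test_high_reading_has_no_low_risk(self):
        assert bg_risk_index(constant_series(300.0), "low") == 0.0
        assert bg_risk_index(constant_series(300.0), "high") > 0.0

    @pytest.mark.parametrize("side", ["low", "high"])
    def test_matches_oracle(self, side):
        for seed in range(10):
            s = random_day_series(seed)
            assert bg_risk_index(s, side) == pytest.approx(
                oracle_risk(s.values, side), rel=1e-10
            )


class TestHaarPowers:
    def test_constant_has_no_detail_energy(self):
        assert haar_powers(constant_series(100.0)) == (0.0, 0.0, 0.0)

    def test_alternating_signal_energy_at_level_one(self):
        s = make_series(np.where(np.arange(1344) % 2 == 0, 150.0, 148.0))
        p1, p2, p3 = haar_powers(s)
        assert p1 > 0
        assert p2 == pytest.approx(0.0, abs=1e-12)
        assert p3 == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_cascade(self):
        for seed in range(10):
            s = random_day_series(seed)
            np.testing.assert_allclose(
                haar_powers(s), oracle_haar_powers(s.values), rtol=1e-8
            )

    def test_energy_conservation(self):
        import pywt

        for seed in range(5):
            s = random_day_series(seed)
            x = s.values - s.values.mean()
            coeffs = pywt.wavedec(x, "haar", level=3, mode="periodization")
            energy = sum(float(np.sum(c**2)) for c in coeffs)
            assert energy == pytest.approx(float(np.sum(x**2)), rel=1e-8)


class TestClockFeatures:
    def test_constant(self):
        assert clock_time_features(constant_series(100.0)) == (100.0,) * 4

    def test_nine_am_slot(self):
        v = np.full(1344, 100.0)
        v[36::96] = 200.0  # 9:00 AM is slot 36
        feats = clock_time_features(make_series(v))
        assert feats == (100.0, 100.0, 200.0, 100.0)  # order: 10AM, 8PM, 9AM, 12AM

    def test_matches_oracle(self):
        rng = np.random.default_rng(7)
        s = make_series(rng.uniform(60, 350, 1344))
        expect = tuple(
            oracle_clock(s.values, 14, h, m) for h, m in ((10, 0), (20, 0), (9, 0), (0, 0))
        )
        np.testing.assert_allclose(clock_time_features(s), expect, rtol=1e-12)


class TestExtractVector:
    def test_canonical_order_and_length(self):
        assert len(DSP_FEATURE_NAMES) == 17
        rng = np.random.default_rng(3)
        s = make_series(rng.uniform(60, 350, 1344))
        v = extract_dsp_vector(s)
        assert v.values.shape == (17,)
        d = v.as_dict()
        assert d["GMC_1"] == pytest.approx(oracle_gmc(s.values, 1.0, 0.25), rel=1e-10)
        assert d["TIR_70_180"] == pytest.approx(oracle_tir(s.values, 70, 180))
        assert d["CV"] == pytest.approx(oracle_cv(s.values), rel=1e-10)
        assert d["LGBI"] == pytest.approx(oracle_risk(s.values, "low"), rel=1e-10)
        assert d["BG_9AM"] == pytest.approx(oracle_clock(s.values, 14, 9, 0), rel=1e-12)

    def test_constant_series_composition(self):
        v = extract_dsp_vector(constant_series(120.0)).as_dict()
        assert v["GMC_1"] == 0.0
        assert v["CV"] == 0.0
        assert v["TIR_70_180"] == 1.0
        assert v["TIR_300_350"] == 0.0
        assert v["P_WD1"] == v["P_WD2"] == v["P_WD3"] == 0.0

    def test_deterministic_and_metadata_invariant(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(60, 350, 1344)
        a = extract_dsp_vector(make_series(vals, patient_id="a", start="2020-01-01"))
        b = extract_dsp_vector(make_series(vals, patient_id="b", start="2021-06-01"))
        np.testing.assert_array_equal(a.values, b.values)

    def test_incomplete_series_rejected(self):
        v = np.full(1344, 120.0)
        v[5] = np.nan
        with pytest.raises(ValueError, match="impute"):
            extract_dsp_vector(make_series(v))
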