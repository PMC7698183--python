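import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mocap_hht.emd import (
    Decomposition1D,
    ResidualReached,
    SiftConfig,
    count_zero_crossings,
    decompose,
    envelopes,
    find_extrema,
    is_imf,
    sd_criterion,
    sift_once,
)
from tests.conftest import FS, match_corr


class TestFindExtrema:
    def test_sine_two_periods(self):
        t = np.linspace(0, 4 * np.pi, 500)
        max_idx, max_val, min_idx, min_val = find_extrema(np.sin(t))
        assert max_idx.size == 2 and min_idx.size == 2
        np.testing.assert_allclose(max_val, 1.0, atol=1e-3)
        np.testing.assert_allclose(min_val, -1.0, atol=1e-3)

    def test_monotone_ramp_has_none(self):
        max_idx, _, min_idx, _ = find_extrema(np.arange(10.0))
        assert max_idx.size == 0 and min_idx.size == 0

    def test_plateau_midpoint(self):
        max_idx, max_val, _, _ = find_extrema(np.array([0.0, 1.0, 1.0, 0.0]))
        np.testing.assert_array_equal(max_idx, [1])
        np.testing.assert_array_equal(max_val, [1.0])
        # longer plateau: midpoint of [1..3] is 2
        max_idx, _, _, _ = find_extrema(np.array([0.0, 1.0, 1.0, 1.0, 0.0]))
        np.testing.assert_array_equal(max_idx, [2])

    def test_constant_has_none(self):
        max_idx, _, min_idx, _ = find_extrema(np.full(20, 3.0))
        assert max_idx.size == 0 and min_idx.size == 0


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (np.sin(np.linspace(0, 4 * np.pi, 500) + 0.1), 4),
            (np.ones(10), 0),
            (np.array([-1.0, 0.0, 1.0]), 1),
            (np.array([1.0, 0.0, 1.0]), 1),  # zero touch counted once
            (np.array([1.0, -1.0, 1.0, -1.0]), 3),
        ],
    )
    def test_counting(self, x, expected):
        assert count_zero_crossings(x) == expected


class TestEnvelopes:
    def test_sine_mean_envelope_near_zero(self):
        t = np.linspace(0, 6 * np.pi, 1000)
        u, l = envelopes(np.sin(t))
        interior = slice(100, -100)
        assert np.max(np.abs(0.5 * (u + l))[interior]) < 0.02

    def test_triangle_wave_symmetric(self):
        from scipy.signal import sawtooth

        # 96 samples per 2*pi period puts every peak exactly on the grid
        t = np.arange(384) * (np.pi / 48)
        x = sawtooth(t + np.pi / 2, width=0.5)
        u, l = envelopes(x)
        np.testing.assert_allclose(u, -l, atol=1e-9)

    def test_monotone_ramp_is_residual(self):
        with pytest.raises(ResidualReached):
            envelopes(np.linspace(0, 1, 50))


class TestSifting:
    def test_sift_fixed_point_on_near_imf(self):
        t = np.linspace(0, 6 * np.pi, 1000)
        x = np.sin(t)
        c = sift_once(x)
        assert np.max(np.abs(c - x)) < 0.02

    def test_sift_removes_offset(self):
        t = np.linspace(0, 6 * np.pi, 1000)
        x = np.sin(t) + 5.0
        c = sift_once(x)
        interior = slice(100, -100)
        assert np.max(np.abs(np.mean(c[interior]))) < 0.05

    def test_sd_decreases_over_sifts(self, two_tone_series):
        x, _, _, _ = two_tone_series
        c = x * np.exp(0.1 * np.arange(x.size) / x.size)  # mild asymmetry
        sds = []
        for _ in range(4):
            c_new = sift_once(c)
            sds.append(sd_criterion(c, c_new))
            c = c_new
        assert sds == sorted(sds, reverse=True)

    @pytest.mark.parametrize(
        "old, new, expected",
        [
            (np.sin(np.arange(64.0)), np.sin(np.arange(64.0)), 0.0),
            (np.sin(np.arange(64.0)), np.zeros(64), 1.0),
            (np.sin(np.arange(64.0)), 0.9 * np.sin(np.arange(64.0)), 0.01),
        ],
    )
    def test_sd_criterion_algebra(self, old, new, expected):
        assert sd_criterion(old, new) == pytest.approx(expected, abs=1e-12)

    def test_sd_zero_energy_rejected(self):
        with pytest.raises(ZeroDivisionError):
            sd_criterion(np.zeros(16), np.ones(16))


class TestIsImf:
    def test_pure_sine_is_imf(self):
        t = np.linspace(0, 6 * np.pi, 1000)
        ok, diag = is_imf(np.sin(t))
        assert ok and diag["count_condition"] and diag["envelope_condition"]

    def test_offset_sine_is_not(self):
        t = np.linspace(0, 6 * np.pi, 1000)
        ok, diag = is_imf(np.sin(t) + 3.0)
        assert not ok
        assert diag["n_zero_crossings"] == 0  # offset kills the crossings

    def test_decompose_output_self_consistent(self, two_tone_series):
        x, _, _, _ = two_tone_series
        d = decompose(x)
        for c in d.imfs:
            ok, diag = is_imf(c)
            assert ok, diag


class TestDecompose:
    def test_pure_tone_single_imf(self):
        t = np.arange(0, 4, 1 / FS)
        x = np.sin(2 * np.pi * 5 * t)
        d = decompose(x)
        assert match_corr(d.imfs[0], x) > 0.99
        assert np.max(np.abs(d.residual)) < 0.1

    def test_constant_gives_no_imfs(self):
        x = np.full(100, 2.5)
        d = decompose(x)
        assert d.n_imfs == 0
        np.testing.assert_array_equal(d.residual, x)

    def test_two_tone_separation(self, two_tone_series):
        x, hi, lo, _ = two_tone_series
        d = decompose(x)
        assert d.n_imfs >= 2
        assert match_corr(d.imfs[0], hi) > 0.95
        assert match_corr(d.imfs[1], lo) > 0.95

    def test_zero_crossing_rate_decreases(self, two_tone_series):
        x, _, _, _ = two_tone_series
        d = decompose(x)
        rates = [count_zero_crossings(c) for c in d.imfs]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_completeness(self, two_tone_series):
        x, _, _, _ = two_tone_series
        d = decompose(x)
        err = np.max(np.abs(d.reconstruct() - x))
        assert err <= 1e-8 * np.max(np.abs(x))

    def test_linear_trend_recovered_as_residual(self):
        t = np.arange(0, 2, 1 / FS)
        x = 1.0 + 0.5 * t
        d = decompose(x)
        assert d.n_imfs == 0
        np.testing.assert_allclose(d.residual, x)

    def test_homogeneity(self, two_tone_series):
        x, _, _, _ = two_tone_series
        d1 = decompose(x)
        d2 = decompose(3.0 * x)
        assert d1.n_imfs == d2.n_imfs
        for c1, c2 in zip(d1.imfs, d2.imfs):
            np.testing.assert_allclose(3.0 * c1, c2, atol=1e-9)

    def test_max_imfs_cap(self, two_tone_series):
        x, _, _, _ = two_tone_series
        d = decompose(x, SiftConfig(max_imfs=1))
        assert d.n_imfs == 1
        err = np.max(np.abs(d.reconstruct() - x))
        assert err <= 1e-8 * np.max(np.abs(x))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 1000),
    n=st.integers(80, 300),
)
def test_completeness_property(seed, n):
    """sum(IMFs) + residual reproduces any random smooth signal."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)
    x = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(1, 20)
        x += rng.uniform(0.5, 2) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    x += rng.normal(0, 0.1, n)
    d = decompose(x)
    err = np.max(np.abs(d.reconstruct() - x))
    assert err <= 1e-8 * max(np.max(np.abs(x)), 1e-12)


def test_sift_config_validation():
    with pytest.raises(ValueError):
        SiftConfig(sd_stop=0.5)  # outside [sd_lo, sd_hi]
    with pytest.raises(ValueError):
        SiftConfig(max_sift_iters=0)
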