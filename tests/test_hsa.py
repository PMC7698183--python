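import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mocap_hht.emd import decompose
from mocap_hht.hsa import (
    InstantaneousTrack,
    WafaConfig,
    _wafa_window,
    analytic_signal,
    build_spectrum,
    instantaneous_freq_amp,
    stft_spectrum,
    wafa_smooth,
)
from mocap_hht.memd import DecompositionND
from tests.conftest import FS


class TestAnalyticSignal:
    def test_cos_maps_to_sin(self):
        t = np.arange(0, 4, 1 / FS)
        zr, zi = analytic_signal(np.cos(2 * np.pi * 5 * t))
        interior = slice(60, -60)
        assert np.max(np.abs(zi - np.sin(2 * np.pi * 5 * t))[interior]) < 0.01
        np.testing.assert_allclose(zr, np.cos(2 * np.pi * 5 * t), atol=1e-12)

    def test_constant_has_zero_imaginary(self):
        zr, zi = analytic_signal(np.full(128, 2.0))
        assert np.max(np.abs(zi)) < 1e-10

    def test_amplitude_of_scaled_cos(self):
        t = np.arange(0, 4, 1 / FS)
        zr, zi = analytic_signal(3.5 * np.cos(2 * np.pi * 6 * t))
        amp = np.hypot(zr, zi)
        interior = slice(60, -60)
        np.testing.assert_allclose(amp[interior], 3.5, rtol=0.01)


class TestInstantaneousFreqAmp:
    @pytest.mark.parametrize("f", [2.0, 5.0, 10.0])
    def test_monochromatic_recovery(self, f):
        t = np.arange(0, 4, 1 / FS)
        tr = instantaneous_freq_amp(1.7 * np.cos(2 * np.pi * f * t + 0.4), FS)
        interior = slice(40, -40)
        assert np.max(np.abs(tr.frequency[interior] - f)) < 0.01 * f
        assert np.max(np.abs(tr.amplitude[interior] - 1.7)) < 0.017

    def test_am_tone_mean_frequency(self):
        t = np.arange(0, 4, 1 / FS)
        env = 1 + 0.2 * np.sin(2 * np.pi * 0.5 * t)
        tr = instantaneous_freq_amp(env * np.cos(2 * np.pi * 8 * t), FS)
        interior = slice(40, -40)
        assert np.mean(tr.frequency[interior]) == pytest.approx(8.0, abs=0.2)

    def test_edges_masked_and_cap(self):
        t = np.arange(0, 2, 1 / FS)
        tr = instantaneous_freq_amp(np.cos(2 * np.pi * 5 * t), FS)
        assert not tr.valid[0] and not tr.valid[-1]
        assert tr.f_max == pytest.approx(30.0)
        assert np.all(tr.frequency <= tr.f_max)
        assert np.all(tr.frequency >= 0.0)
        assert np.all(tr.amplitude >= 0.0)


class TestWafa:
    def _track(self, f, a):
        f = np.asarray(f, float)
        a = np.asarray(a, float)
        valid = np.ones(f.size, bool)
        return InstantaneousTrack(a, f, valid, FS)

    def test_constant_frequency_exact(self):
        rng = np.random.default_rng(0)
        tr = self._track(np.full(101, 2.0), rng.uniform(0.1, 5.0, 101))
        sm, avg = wafa_smooth(tr, WafaConfig(31))
        np.testing.assert_allclose(sm, 2.0, atol=1e-12)
        assert avg == pytest.approx(2.0, abs=1e-12)

    def test_two_sample_worked_example(self):
        # window covering samples with (f, A) = (1,1) and (3,3):
        # weighted mean (1*1 + 3*3) / (1 + 3) = 2.5
        tr = self._track([1.0, 3.0, 0.0], [1.0, 3.0, 0.0])
        sm, _ = wafa_smooth(tr, WafaConfig(3))
        assert sm[1] == pytest.approx(2.5)

    def test_zero_amplitude_samples_contribute_nothing(self):
        tr1 = self._track([2.0, 4.0, 6.0], [1.0, 1.0, 1.0])
        sm1, _ = wafa_smooth(tr1, WafaConfig(3))
        # interleave zero-amplitude frames with arbitrary frequencies
        tr2 = self._track([2.0, 99.0, 4.0, 99.0, 6.0],
                          [1.0, 0.0, 1.0, 0.0, 1.0])
        sm2, _ = wafa_smooth(tr2, WafaConfig(5))
        assert sm2[2] == pytest.approx(sm1[1])

    def test_window_bounds_partition(self):
        # windows always contain k and stay inside [1, N]; the three
        # regimes tile [1, N] with no gaps
        n, m = 50, 7
        half = (m - 1) // 2
        for k in range(1, n + 1):
            lo, hi = _wafa_window(k, n, half)
            assert 1 <= lo <= k <= hi <= n
            assert hi - lo + 1 <= m

    def test_interior_window_is_full_length(self):
        n, m = 50, 7
        half = (m - 1) // 2
        full = [k for k in range(1, n + 1)
                if _wafa_window(k, n, half) == (k - half, k + half)]
        assert full[0] == half + 1
        assert full[-1] >= n - m  # right regime begins near the end

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WafaConfig(4)
        with pytest.raises(ValueError):
            WafaConfig(1)
        tr = self._track(np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="exceeds"):
            wafa_smooth(tr, WafaConfig(7))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 500), m=st.sampled_from([3, 5, 9, 31]))
    def test_smoothed_within_data_range(self, seed, m):
        """A weighted average never leaves the hull of its window values."""
        rng = np.random.default_rng(seed)
        n = 64
        f = rng.uniform(0.0, 30.0, n)
        a = rng.uniform(0.01, 5.0, n)
        sm, avg = wafa_smooth(self._track(f, a), WafaConfig(m))
        assert np.all(sm >= f.min() - 1e-9) and np.all(sm <= f.max() + 1e-9)
        assert f.min() - 1e-9 <= avg <= f.max() + 1e-9


class TestSpectrum:
    def test_pure_tone_ridge(self):
        t = np.arange(0, 4, 1 / FS)
        tone = np.cos(2 * np.pi * 6 * t)
        d1 = decompose(tone)
        decomp = DecompositionND([np.column_stack([c, c]) for c in d1.imfs],
                                 np.column_stack([d1.residual, d1.residual]))
        spec = build_spectrum(decomp, FS, ["a", "b"], ["a"])
        ridge = spec.table[spec.table.imf == 1]
        assert abs(ridge.frequency.mean() - 6.0) < 0.06
        assert spec.f_max == pytest.approx(30.0)
        assert np.all(spec.table.frequency <= spec.f_max)

    def test_empty_channel_subset_rejected(self):
        decomp = DecompositionND([], np.zeros((10, 2)))
        with pytest.raises(ValueError):
            build_spectrum(decomp, FS, ["a", "b"], [])

    def test_export_round_trip(self, tmp_path):
        t = np.arange(0, 2, 1 / FS)
        tone = np.cos(2 * np.pi * 6 * t)
        d1 = decompose(tone)
        decomp = DecompositionND([c[:, None] for c in d1.imfs], d1.residual[:, None])
        spec = build_spectrum(decomp, FS, ["ch"])
        import pandas as pd

        spec.to_csv(tmp_path / "s.csv")
        loaded = pd.read_csv(tmp_path / "s.csv")
        assert list(loaded.columns) == ["time", "frequency", "amplitude", "imf", "channel"]
        assert len(loaded) == len(spec.table)
        spec.to_npz(tmp_path / "s.npz")
        with np.load(tmp_path / "s.npz") as z:
            assert z["fs"] == FS


class TestStft:
    def test_tone_energy_in_correct_bin(self):
        t = np.arange(0, 4, 1 / FS)
        f, seg_t, mag = stft_spectrum(np.cos(2 * np.pi * 10 * t), FS)
        peak_bins = f[np.argmax(mag, axis=0)]
        mid = slice(5, -5)
        np.testing.assert_allclose(peak_bins[mid], 10.0, atol=f[1] - f[0])

    def test_two_tone_two_bands(self):
        t = np.arange(0, 4, 1 / FS)
        x = np.cos(2 * np.pi * 10 * t) + np.cos(2 * np.pi * 2 * t)
        f, seg_t, mag = stft_spectrum(x, FS)
        mean_mag = mag[:, 5:-5].mean(axis=1)
        # both tone bins dominate their neighbourhoods
        for tone in (2.0, 10.0):
            i = np.argmin(np.abs(f - tone))
            assert mean_mag[i] > 3 * np.median(mean_mag)

    def test_default_window_and_stride(self):
        t = np.arange(0, 4, 1 / FS)
        f, seg_t, mag = stft_spectrum(np.cos(2 * np.pi * 5 * t), FS)
        # 10-frame stride at 120 Hz = 0.1 s between segments
        assert np.diff(seg_t)[0] == pytest.approx(10 / FS)
        # 120-frame window gives 1 Hz bin spacing at 120 Hz
        assert f[1] - f[0] == pytest.approx(1.0)
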