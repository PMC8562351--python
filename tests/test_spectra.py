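"""Preprocessing chain: normalization, filtering, windowing, concatenation,
downsampling, and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lssnd import spectra as sp


def make_record(intensity, n=None, fiber="R1", sample="S01", acq=0,
                stages=("raw",)):
    intensity = np.asarray(intensity, dtype=float)
    wl = np.linspace(500.0, 1100.0, intensity.size)
    return sp.SpectrumRecord(wl, intensity, sample, fiber, acq, stages)


class TestNormalize:
    def test_known_values(self):
        out = sp.normalize_to_mean(make_record([1.0, 2.0, 3.0]))
        assert np.allclose(out.intensity, [0.5, 1.0, 1.5])

    def test_constant_trace(self):
        out = sp.normalize_to_mean(make_record(np.full(64, 5.0)))
        assert np.allclose(out.intensity, 1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_and_unit_mean(self, seed):
        rng = np.random.default_rng(seed)
        rec = make_record(rng.uniform(0.1, 5.0, 128))
        once = sp.normalize_to_mean(rec)
        twice = sp.normalize_to_mean(once)
        assert abs(once.intensity.mean() - 1.0) < 1e-9
        assert np.allclose(once.intensity, twice.intensity)

    def test_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            sp.normalize_to_mean(make_record(np.zeros(16)))


class TestGaussianSmooth:
    spec = sp.FilterSpec(sd_measures=20, kernel_measures=80)

    def _oracle(self, x, sd, width):
        """Direct-summation convolution with reflect padding."""
        radius = width // 2
        taps = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (taps / sd) ** 2)
        k /= k.sum()
        xp = np.pad(x, radius, mode="reflect")
        return np.array([np.dot(xp[i:i + 2 * radius + 1], k[::-1])
                         for i in range(x.size)])

    def test_impulse_response_matches_direct_convolution(self):
        x = np.zeros(401)
        x[200] = 1.0
        rec = make_record(x, stages=("raw", "normalized"))
        out = sp.gaussian_smooth(rec, self.spec)
        assert np.allclose(out.intensity, self._oracle(x, 20, 80), atol=1e-12)

    def test_constant_preserved(self):
        rec = make_record(np.full(200, 3.0), stages=("raw", "normalized"))
        out = sp.gaussian_smooth(rec, self.spec)
        assert np.allclose(out.intensity, 3.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        f = lambda x: sp.gaussian_smooth(
            make_record(x, stages=("raw", "normalized")), self.spec).intensity
        assert np.allclose(f(a + b), f(a) + f(b), atol=1e-9)

    def test_short_trace_rejected(self):
        rec = make_record(np.ones(40), stages=("raw", "normalized"))
        with pytest.raises(ValueError):
            sp.gaussian_smooth(rec, self.spec)


class TestWindow:
    def test_full_range_is_identity(self):
        rec = make_record(np.arange(sp.NATIVE_N_POINTS, dtype=float))
        out = sp.window_wavelengths(rec, 500.0, 1100.0)
        assert out.n_points == rec.n_points

    def test_three_windows_partition_native_grid(self):
        rec = make_record(np.ones(sp.NATIVE_N_POINTS))
        parts = [sp.window_wavelengths(rec, lo, hi)
                 for lo, hi in ((500, 700), (700, 900), (900, 1100))]
        assert sum(p.n_points for p in parts) == sp.NATIVE_N_POINTS
        all_wl = np.concatenate([p.wavelength_nm for p in parts])
        assert np.array_equal(np.unique(all_wl), rec.wavelength_nm)

    def test_middle_window_point_count(self):
        # 3648 points over [500, 1100]: 1216 fall in [700, 900)
        rec = make_record(np.ones(3648))
        assert sp.window_wavelengths(rec, 700, 900).n_points == 1216

    def test_empty_window_rejected(self):
        rec = make_record(np.ones(100))
        with pytest.raises(ValueError):
            sp.window_wavelengths(rec, 650.0, 650.2)


class TestConcatenate:
    def _prep(self, n=64, fiber="R1", acq=0, sample="S01"):
        rec = make_record(np.random.default_rng(0).uniform(1, 2, n),
                          fiber=fiber, acq=acq, sample=sample)
        return sp.gaussian_smooth(sp.normalize_to_mean(rec),
                                  sp.FilterSpec(2, 8))

    def test_lengths_add(self):
        out = sp.concatenate_fibers(self._prep(), self._prep(fiber="R2"))
        assert out.n_points == 128
        assert out.fiber == sp.CONCATENATED_FIBER

    def test_self_concatenation_symmetry(self):
        r = self._prep()
        out = sp.concatenate_fibers(r, r)
        assert np.array_equal(out.intensity[:64], out.intensity[64:])

    def test_metadata_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sp.concatenate_fibers(self._prep(acq=0), self._prep(fiber="R2",
                                                                acq=1))

    def test_order_enforced(self):
        raw = make_record(np.ones(64))
        with pytest.raises(sp.PipelineOrderError):
            sp.gaussian_smooth(raw)  # filter before normalize
        with pytest.raises(sp.PipelineOrderError):
            sp.concatenate_fibers(raw, make_record(np.ones(64), fiber="R2"))


class TestDownsample:
    def test_k1_identity(self):
        x = np.random.default_rng(0).normal(size=257)
        out = sp.downsample_array(x, 1.0)
        assert np.array_equal(out, x)

    @given(st.floats(1.0, 400.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_signals_exact(self, K):
        n = 1000
        x = 0.7 * np.arange(n) - 3.0
        out = sp.downsample_array(x, K)
        pos = np.linspace(0, n - 1, out.size)
        assert np.allclose(out, 0.7 * pos - 3.0, atol=1e-8)

    def test_native_concatenated_length_at_k50(self):
        assert sp.downsample_array(np.zeros(7296), 50.0).size == 146

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            sp.downsample_array(np.zeros(10), 0.5)


class TestFileIO:
    def _records(self, n_rec=6, n=32):
        rng = np.random.default_rng(1)
        recs = []
        for i in range(n_rec):
            for fiber in ("R1", "R2"):
                recs.append(make_record(rng.uniform(10, 1e4, n), fiber=fiber,
                                        sample=f"S{i:02d}", acq=i))
        return recs

    def test_round_trip_lossless(self, tmp_path):
        path = tmp_path / "spectra.csv"
        recs = self._records()
        sp.write_spectra(recs, path)
        back = sp.read_spectra(path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert np.array_equal(a.intensity, b.intensity)
            assert np.array_equal(a.wavelength_nm, b.wavelength_nm)
            assert (a.sample_id, a.fiber, a.acquisition_index) == \
                (b.sample_id, b.fiber, b.acquisition_index)

    def test_decreasing_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,intensity,sample_id,fiber,"
                        "acquisition_index\n"
                        "600,1.0,S01,R1,0\n500,1.1,S01,R1,0\n")
        with pytest.raises(sp.SpectrumFormatError, match="non-monotone"):
            sp.read_spectra(path)

    def test_unknown_fiber_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,intensity,sample_id,fiber,"
                        "acquisition_index\n500,1.0,S01,R9,0\n")
        with pytest.raises(sp.SpectrumFormatError, match="fiber"):
            sp.read_spectra(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("wavelength_nm,intensity,sample_id,fiber,"
                        "acquisition_index\n")
        with pytest.warns(UserWarning, match="empty"):
            assert sp.read_spectra(path) == []
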