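import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilspec import (SpectrumSet, average_replicates, read_spectra,
                      resample_to_unit_grid, savitzky_golay, splice_correct,
                      trim_wavelengths, write_spectra)
from .conftest import make_spectra


class TestIO:
    def test_round_trip_identity(self, tmp_path, small_set):
        p = tmp_path / "s.csv"
        write_spectra(small_set, p)
        back = read_spectra(p)
        assert back.sample_ids == small_set.sample_ids
        np.testing.assert_array_equal(back.wavelengths_nm, small_set.wavelengths_nm)
        np.testing.assert_array_equal(back.reflectance, small_set.reflectance)

    def test_small_round_trip_and_layouts(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,400,401,402\na,0.1,0.2,0.3\nb,0.4,0.5,0.6\n")
        s = read_spectra(p)
        assert s.reflectance.shape == (2, 3)
        # transposed layout: samples as columns
        q = tmp_path / "t.csv"
        q.write_text("wavelength,a,b\n400,0.1,0.4\n401,0.2,0.5\n402,0.3,0.6\n")
        t = read_spectra(q)
        np.testing.assert_array_equal(t.reflectance, s.reflectance)
        assert t.sample_ids == s.sample_ids

    def test_descending_header_sorted_ascending(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,402,401,400\na,0.3,0.2,0.1\n")
        s = read_spectra(p)
        np.testing.assert_array_equal(s.wavelengths_nm, [400, 401, 402])
        np.testing.assert_array_equal(s.reflectance, [[0.1, 0.2, 0.3]])

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,400,400,402\na,0.3,0.2,0.1\n")
        with pytest.raises(ValueError, match="duplicate wavelength 400"):
            read_spectra(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,400,401\na,0.3,oops\n")
        with pytest.raises(ValueError, match="sample 'a'.*401"):
            read_spectra(p)

    def test_derivative_order_in_comment_header(self, tmp_path, small_set):
        d = small_set.with_(derivative_order=1.5)
        p = tmp_path / "d.csv"
        write_spectra(d, p)
        assert p.read_text().startswith("# derivative_order=1.5")
        assert read_spectra(p).derivative_order == 1.5

    def test_empty_set_write_rejected(self, tmp_path):
        s = make_spectra(np.ones((1, 3)))
        s.reflectance = s.reflectance[:, :0]
        s.wavelengths_nm = s.wavelengths_nm[:0]
        with pytest.raises(ValueError):
            write_spectra(s, tmp_path / "e.csv")


class TestReplicateAveraging:
    def test_identical_replicates_unchanged(self):
        rep = np.linspace(0.1, 0.9, 30)
        avg, kept = average_replicates(np.tile(rep, (10, 1)))
        np.testing.assert_allclose(avg, rep)
        assert kept.size == 10

    def test_flipped_replicate_removed(self):
        # correlation of the sign-flipped copy with the pointwise median is -1
        rep = np.linspace(0.1, 0.9, 30)
        stack = np.vstack([np.tile(rep, (9, 1)), 1.0 - rep])
        avg, kept = average_replicates(stack, min_corr=0.98)
        np.testing.assert_allclose(avg, rep)
        assert 9 not in kept

    def test_two_parallel_replicates_averaged(self):
        avg, _ = average_replicates([[0.1, 0.2, 0.3], [0.3, 0.4, 0.5]])
        np.testing.assert_allclose(avg, [0.2, 0.3, 0.4])

    def test_all_abnormal_keeps_median_closest(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(size=(4, 50))  # mutually uncorrelated
        with pytest.warns(UserWarning, match="abnormal"):
            avg, kept = average_replicates(stack, min_corr=0.999999)
        assert kept.size == 1


class TestTrim:
    def test_full_range_trims_to_2000_bands(self):
        s = make_spectra(np.ones((1, 2151)), wl0=350.0)
        t = trim_wavelengths(s)
        assert t.n_bands == 2000
        assert t.wavelengths_nm[0] == 401 and t.wavelengths_nm[-1] == 2400

    def test_within_range_unchanged_and_idempotent(self, small_set):
        t = trim_wavelengths(small_set, 300, 3000)
        np.testing.assert_array_equal(t.reflectance, small_set.reflectance)
        t2 = trim_wavelengths(trim_wavelengths(small_set), 401, 2400)
        np.testing.assert_array_equal(
            t2.reflectance, trim_wavelengths(small_set, 401, 2400).reflectance)

    def test_inverted_bounds_rejected(self, small_set):
        with pytest.raises(ValueError):
            trim_wavelengths(small_set, 2400, 401)


class TestSpliceCorrection:
    def test_step_removed(self):
        vals = np.where(np.arange(990, 1011) >= 1000, 0.6, 0.5)
        s = make_spectra(vals[None, :], wl0=990.0)
        c = splice_correct(s)
        np.testing.assert_allclose(c.reflectance, 0.5)

    def test_continuous_line_unchanged_and_idempotent(self):
        wl = np.arange(990.0, 1011.0)
        s = make_spectra((0.3 + 1e-4 * wl)[None, :], wl0=990.0)
        c = splice_correct(s)
        np.testing.assert_allclose(c.reflectance, s.reflectance, atol=1e-12)
        c2 = splice_correct(c)
        np.testing.assert_allclose(c2.reflectance, c.reflectance, atol=1e-12)

    def test_junction_at_grid_edge_rejected(self):
        s = make_spectra(np.ones((1, 10)), wl0=1000.0)
        with pytest.raises(ValueError):
            splice_correct(s, junction_nm=1000.0)


class TestSavitzkyGolay:
    def test_quadratic_preserved_on_interior(self):
        x = np.arange(60.0)
        s = make_spectra((0.2 + 0.01 * x - 1e-4 * x**2)[None, :])
        sm = savitzky_golay(s, window=11, polyorder=2)
        interior = slice(5, -5)
        assert np.max(np.abs(
            sm.reflectance[0, interior] - s.reflectance[0, interior])) < 1e-10

    def test_constant_unchanged(self):
        s = make_spectra(np.full((2, 30), 0.42))
        np.testing.assert_allclose(savitzky_golay(s).reflectance, 0.42)

    def test_even_window_rejected(self, small_set):
        with pytest.raises(ValueError):
            savitzky_golay(small_set, window=4, polyorder=2)


class TestResample:
    def test_identity_on_unit_grid(self, small_set):
        r = resample_to_unit_grid(small_set)
        np.testing.assert_array_equal(r.reflectance, small_set.reflectance)

    def test_linear_signal_interpolated_exactly(self):
        wl = np.arange(400.0, 420.0, 2.0)
        s = SpectrumSet(["a"], wl, (0.001 * wl)[None, :])
        r = resample_to_unit_grid(s)
        np.testing.assert_allclose(r.reflectance[0], 0.001 * r.wavelengths_nm)

    def test_single_band_rejected(self):
        s = SpectrumSet(["a"], [500.0], [[0.5]])
        with pytest.raises(ValueError):
            resample_to_unit_grid(s)


class TestInvariants:
    def test_wavelengths_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SpectrumSet(["a"], [400.0, 400.0], [[0.1, 0.2]])

    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(2, 6), b=st.integers(3, 40), seed=st.integers(0, 10_000))
    def test_io_round_trip_property(self, tmp_path_factory, n, b, seed):
        rng = np.random.default_rng(seed)
        s = make_spectra(rng.uniform(1e-6, 1.0, size=(n, b)))
        p = tmp_path_factory.mktemp("rt") / "s.csv"
        write_spectra(s, p)
        back = read_spectra(p)
        np.testing.assert_array_equal(back.reflectance, s.reflectance)
        np.testing.assert_array_equal(back.wavelengths_nm, s.wavelengths_nm)
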