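import numpy as np
import pytest
from scipy.stats import pearsonr

from soilspec import (BandCombo, CorrelationMap, NiTable, build_feature_table,
                      compute_index, correlation_map, fod_transform,
                      render_combo, select_top_combos, INDEX_NAMES)
from soilspec.indices import map_to_long_frame
from .conftest import make_spectra


class TestFormulas:
    @pytest.mark.parametrize(
        "name,r1,r2,expected",
        [
            ("NDI", 0.6, 0.2, 0.5),
            ("BI", 3.0, 4.0, 5.0),
            ("DI", 2.0, 3.0, -1.0),
            ("PI", 2.0, 3.0, 6.0),
            ("SI", 2.0, 3.0, 5.0),
            ("RI", 6.0, 3.0, 2.0),
        ],
    )
    def test_scalar_values(self, name, r1, r2, expected):
        assert compute_index(name, r1, r2) == pytest.approx(expected)

    def test_zero_denominator_yields_nan_not_error(self):
        assert np.isnan(compute_index("RI", 1.0, 0.0))
        assert np.isnan(compute_index("NDI", 1.0, -1.0))

    def test_vectorized_matches_scalar(self, rng):
        a, b = rng.uniform(0.1, 1, 7), rng.uniform(0.1, 1, 7)
        for name in INDEX_NAMES:
            vec = compute_index(name, a, b)
            np.testing.assert_allclose(
                vec, [compute_index(name, x, y) for x, y in zip(a, b)])

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError):
            compute_index("XYZ", 1.0, 2.0)


def brute_force_map(dset, ni, name):
    """Per-pair loop with scipy's pearsonr as the independent oracle."""
    y = ni.aligned_to(dset.sample_ids)
    B = dset.n_bands
    out = np.full((B, B), np.nan)
    for i in range(B):
        for j in range(B):
            v = compute_index(name, dset.reflectance[:, i], dset.reflectance[:, j])
            fin = np.isfinite(v)
            if fin.sum() < 0.8 * y.size or np.ptp(v[fin]) == 0:
                continue
            out[i, j] = pearsonr(v[fin], y[fin]).statistic
    return out


class TestCorrelationMap:
    @pytest.mark.parametrize("name", INDEX_NAMES)
    def test_chunked_map_equals_brute_force(self, name, small_set, small_ni):
        dset = fod_transform(small_set, 0.4)
        m = correlation_map(dset, small_ni, name)
        oracle = brute_force_map(dset, small_ni, name)
        both = np.isfinite(m.r_matrix) & np.isfinite(oracle)
        np.testing.assert_allclose(m.r_matrix[both], oracle[both], atol=1e-12)
        np.testing.assert_array_equal(np.isfinite(m.r_matrix), np.isfinite(oracle))

    def test_planted_affine_feature_gives_r_one(self, small_ni):
        # DI at the pair (band 0, band 1) equals 2*Ni + 3 exactly
        ni = small_ni.ni_mg_per_kg
        R = np.column_stack([2 * ni + 3.5, np.full_like(ni, 0.5),
                             np.linspace(0.2, 0.4, ni.size)])
        dset = fod_transform(make_spectra(R), 0.0)
        m = correlation_map(dset, small_ni, "DI")
        assert m.r_matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_ni_gives_all_undefined(self, small_set):
        ni = NiTable(small_set.sample_ids, np.full(small_set.n_samples, 30.0))
        with pytest.warns(UserWarning, match="constant"):
            m = correlation_map(fod_transform(small_set, 0.0), ni, "NDI")
        assert np.all(np.isnan(m.r_matrix))

    def test_id_mismatch_rejected(self, small_set, small_ni):
        bad = NiTable([f"X{i}" for i in range(len(small_ni))], small_ni.ni_mg_per_kg)
        with pytest.raises(ValueError, match="ids"):
            correlation_map(fod_transform(small_set, 0.0), bad, "NDI")

    def test_antisymmetric_and_symmetric_structure(self, small_set, small_ni):
        dset = fod_transform(small_set, 0.0)
        for name, kind in (("NDI", "anti"), ("DI", "anti"), ("PI", "sym"),
                           ("SI", "sym"), ("BI", "sym")):
            m = correlation_map(dset, small_ni, name).r_matrix
            fin = np.isfinite(m) & np.isfinite(m.T)
            if kind == "anti":
                np.testing.assert_allclose(m[fin], -m.T[fin], atol=1e-12)
            else:
                np.testing.assert_allclose(m[fin], m.T[fin], atol=1e-12)

    def test_ratio_index_swap_asymmetry_exists(self, small_set, small_ni):
        # RI is reciprocal under swapping, and |r| is NOT swap-invariant:
        # there must be pairs where the two orientations genuinely differ
        m = correlation_map(fod_transform(small_set, 0.0), small_ni, "RI").r_matrix
        off = ~np.eye(m.shape[0], dtype=bool)
        diffs = np.abs(np.abs(m) - np.abs(m.T))[off]
        assert np.nanmax(diffs) > 1e-3

    def test_max_abs_r_invariant_under_affine_ni_rescale(self, small_set, small_ni):
        dset = fod_transform(small_set, 0.3)
        m1 = correlation_map(dset, small_ni, "NDI").r_matrix
        scaled = NiTable(small_ni.sample_ids, 3.7 * small_ni.ni_mg_per_kg + 11.0)
        m2 = correlation_map(dset, scaled, "NDI").r_matrix
        assert np.nanmax(np.abs(m1)) == pytest.approx(np.nanmax(np.abs(m2)), abs=1e-12)

    def test_stride_subsamples_grid(self, small_set, small_ni):
        m = correlation_map(fod_transform(small_set, 0.0), small_ni, "DI", stride_nm=5)
        np.testing.assert_array_equal(m.wavelengths_nm, small_set.wavelengths_nm[::5])
        assert m.r_matrix.shape == (4, 4)


def _map(name, order, wl, r):
    return CorrelationMap(index_name=name, order_v=order,
                          wavelengths_nm=np.asarray(wl, float),
                          r_matrix=np.asarray(r, float), stride_nm=1,
                          n_samples_used=10)


class TestSelection:
    def test_planted_ranking_across_orders(self, rng):
        wl = 400.0 + 5 * np.arange(10)
        planted = [(0.5, 1, 7, 0.9), (1.0, 0, 3, -0.8), (0.5, 2, 9, 0.7),
                   (1.0, 4, 6, 0.6)]
        maps = {}
        for order in (0.5, 1.0):
            noise = rng.uniform(-0.29, 0.29, size=(10, 10))
            noise = (noise - noise.T) / 2  # antisymmetric like NDI
            maps[order] = noise
        for order, i, j, r in planted:
            maps[order][i, j] = r
            maps[order][j, i] = -r
        out = select_top_combos(
            [_map("NDI", o, wl, m) for o, m in maps.items()], k=4)
        got = [(c.order_v, c.lambda1_nm, c.lambda2_nm, round(abs(c.r), 6)) for c in out]
        assert got == [(0.5, wl[1], wl[7], 0.9), (1.0, wl[0], wl[3], 0.8),
                       (0.5, wl[2], wl[9], 0.7), (1.0, wl[4], wl[6], 0.6)]

    def test_mirror_pair_never_co_selected(self, rng):
        wl = 400.0 + np.arange(6)
        m = rng.uniform(-0.9, 0.9, size=(6, 6))
        m = (m - m.T) / 2
        out = select_top_combos([_map("NDI", 0.0, wl, m)], k=10)
        pairs = {(c.lambda1_nm, c.lambda2_nm) for c in out}
        assert all(l1 < l2 for l1, l2 in pairs)
        assert len(pairs) == len(out)

    def test_tie_break_prefers_lower_order_then_wavelengths(self):
        wl = [400.0, 401.0, 402.0]
        z = np.zeros((3, 3))
        a = z.copy(); a[0, 2] = 0.5
        b = z.copy(); b[0, 1] = 0.5
        out = select_top_combos([_map("PI", 1.0, wl, a), _map("PI", 0.5, wl, b)], k=2)
        assert (out[0].order_v, out[0].lambda1_nm, out[0].lambda2_nm) == (0.5, 400, 401)
        assert (out[1].order_v, out[1].lambda1_nm, out[1].lambda2_nm) == (1.0, 400, 402)

    def test_k_larger_than_available_warns_and_returns_all(self):
        wl = [400.0, 401.0]
        m = np.array([[np.nan, 0.4], [0.4, np.nan]])
        with pytest.warns(UserWarning, match="available"):
            out = select_top_combos([_map("PI", 0.0, wl, m)], k=5)
        assert len(out) == 1

    def test_rendering_layout(self):
        c = BandCombo("NDI", 1.9, 709.0, 1631.0, 0.803)
        assert render_combo(c) == "(R_709, R_1631) 1.9"


class TestFeatureTable:
    def test_columns_match_direct_recomputation(self, small_set, small_ni):
        dsets = [fod_transform(small_set, v) for v in (0.0, 0.5, 1.0)]
        combos = [
            BandCombo("NDI", 0.5, small_set.wavelengths_nm[2],
                      small_set.wavelengths_nm[11], 0.5),
            BandCombo("NDI", 1.0, small_set.wavelengths_nm[0],
                      small_set.wavelengths_nm[19], -0.4),
        ]
        ft = build_feature_table(combos, dsets, small_set.sample_ids)
        assert ft.values.shape == (5, 2)
        for j, c in enumerate(combos):
            d = next(x for x in dsets if x.derivative_order == c.order_v)
            direct = compute_index(
                c.index_name,
                d.reflectance[:, d.band_index(c.lambda1_nm)],
                d.reflectance[:, d.band_index(c.lambda2_nm)])
            np.testing.assert_array_equal(ft.values[:, j], direct)

    def test_missing_order_rejected(self, small_set):
        dsets = [fod_transform(small_set, 0.3)]
        combo = BandCombo("DI", 0.35, 400.0, 405.0, 0.1)
        with pytest.raises(KeyError, match="0.35"):
            build_feature_table([combo], dsets)

    def test_off_grid_wavelength_rejected(self, small_set):
        dsets = [fod_transform(small_set, 0.0)]
        combo = BandCombo("DI", 0.0, 400.5, 405.0, 0.1)
        with pytest.raises(KeyError, match="not on the grid"):
            build_feature_table([combo], dsets)


def test_long_format_export_round_trips_entries(small_set, small_ni):
    m = correlation_map(fod_transform(small_set, 0.0), small_ni, "SI", stride_nm=5)
    df = map_to_long_frame(m)
    assert len(df) == m.r_matrix.size
    back = df.pivot(index="lambda1_nm", columns="lambda2_nm", values="r").to_numpy()
    np.testing.assert_array_equal(back, m.r_matrix)
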