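"""GLCM and feature-map contracts, with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from braintexture.quantize import QuantizedVolume, equalize_histogram
from braintexture.synthetic import generate_brain_volume
from braintexture.texture import (DEFAULT_OFFSETS, FEATURE_NAMES, GLCM,
                                  glcm_2d, haralick_features, map_grid_starts,
                                  texture_feature_maps)


def brute_force_glcm(slice2d, offset, g, symmetric=True):
    """Exhaustive double-loop pair counter (independent oracle)."""
    dr, dc = offset
    h, w = slice2d.shape
    p = np.zeros((g, g))
    n = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                p[slice2d[r, c], slice2d[r2, c2]] += 1
                n += 1
    if symmetric:
        p = p + p.T
    if p.sum():
        p = p / p.sum()
    return p, n


def brute_force_features(p):
    """Direct-summation Haralick oracle."""
    g = p.shape[0]
    out = dict.fromkeys(FEATURE_NAMES, 0.0)
    psum = np.zeros(2 * g - 1)
    pdiff = np.zeros(g)
    for i in range(g):
        for j in range(g):
            v = p[i, j]
            out["energy"] += v * v
            out["entropy"] -= v * np.log(v) if v > 0 else 0.0
            out["contrast"] += (i - j) ** 2 * v
            out["homogeneity"] += v / (1 + abs(i - j))
            psum[i + j] += v
            pdiff[abs(i - j)] += v
    for k in psum:
        out["sum_entropy"] -= k * np.log(k) if k > 0 else 0.0
    for k in pdiff:
        out["difference_entropy"] -= k * np.log(k) if k > 0 else 0.0
    return out


class TestGLCM:
    def test_two_row_slice_counts_by_hand(self):
        g = glcm_2d(np.array([[0, 0], [1, 1]]), (0, 1), n_levels=2)
        assert g.p[0, 0] == pytest.approx(0.5)
        assert g.p[1, 1] == pytest.approx(0.5)
        assert g.p[0, 1] == g.p[1, 0] == 0.0
        assert g.n_pairs == 2

    def test_constant_slice_single_entry(self):
        for off in DEFAULT_OFFSETS:
            g = glcm_2d(np.full((4, 4), 2), off, n_levels=4)
            assert g.p[2, 2] == 1.0 and g.p.sum() == 1.0

    def test_slice_smaller_than_offset_flagged_empty(self):
        g = glcm_2d(np.array([[1]]), (0, 1), n_levels=2)
        assert g.n_pairs == 0 and np.all(g.p == 0)

    def test_random_slices_match_brute_force_exactly(self, rng):
        for _ in range(25):
            s = rng.integers(0, 8, size=(8, 8))
            for off in DEFAULT_OFFSETS:
                got = glcm_2d(s, off, n_levels=8)
                want_p, want_n = brute_force_glcm(s, off, 8)
                assert np.array_equal(got.p, want_p)
                assert got.n_pairs == want_n

    def test_out_of_range_levels_rejected(self):
        with pytest.raises(ValueError):
            glcm_2d(np.array([[0, 9]]), (0, 1), n_levels=4)


class TestHaralick:
    def test_single_entry_glcm_closed_forms(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = haralick_features(GLCM(p, (0, 1), True, 10))
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == 1.0
        assert f["sum_entropy"] == 0.0
        assert f["difference_entropy"] == 0.0

    def test_uniform_glcm_maximum_entropy_closed_form(self):
        p = np.full((4, 4), 1 / 16)
        f = haralick_features(GLCM(p, (0, 1), True, 16))
        assert f["energy"] == pytest.approx(1 / 16, abs=1e-15)
        assert f["entropy"] == pytest.approx(np.log(16), abs=1e-12)

    def test_diagonal_half_half_by_direct_summation(self):
        p = np.diag([0.5, 0.5])
        f = haralick_features(GLCM(p, (0, 1), True, 4))
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(np.log(2))
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == 1.0
        assert f["difference_entropy"] == 0.0
        # p_{x+y} puts 1/2 at 0 and 1/2 at 2
        assert f["sum_entropy"] == pytest.approx(np.log(2))

    def test_unnormalized_glcm_rejected(self):
        with pytest.raises(ValueError):
            haralick_features(GLCM(np.full((2, 2), 0.5), (0, 1), True, 4))
        with pytest.raises(ValueError):
            haralick_features(GLCM(np.zeros((2, 2)), (0, 1), True, 0))

    @settings(max_examples=40, deadline=None)
    @given(hnp.arrays(np.int64, (7, 7), elements=st.integers(0, 5)))
    def test_normalization_and_bounds_hold_for_any_slice(self, s):
        g = glcm_2d(s, (1, 1), n_levels=6)
        assert abs(g.p.sum() - 1.0) <= 1e-12
        f = haralick_features(g)
        assert 0 < f["energy"] <= 1
        assert 0 <= f["entropy"] <= 2 * np.log(6)
        assert 0 < f["homogeneity"] <= 1
        want = brute_force_features(g.p)
        for k in FEATURE_NAMES:
            assert f[k] == pytest.approx(want[k], abs=1e-12)


def _quantized_from_levels(levels, g, nonzero=None):
    levels = np.asarray(levels, dtype=np.int16)
    nz = levels > 0 if nonzero is None else nonzero
    return QuantizedVolume(levels=levels, n_levels=g,
                           source_mapping=(np.empty(0), np.empty(0)),
                           brain_mask=nz, nonzero_mask=nz)


class TestFeatureMaps:
    def test_all_background_volume_entirely_invalid(self):
        q = _quantized_from_levels(np.zeros((12, 12, 12)), 4)
        maps = texture_feature_maps(q, cube_size=4, stride=2)
        assert not maps["energy"].valid_mask.any()
        assert np.all(np.isnan(maps["energy"].values))

    def test_constant_nonzero_volume_is_perfectly_ordered(self):
        q = _quantized_from_levels(np.full((12, 12, 12), 3), 4)
        maps = texture_feature_maps(q, cube_size=4, stride=2)
        assert np.all(maps["energy"].values == 1.0)
        assert np.all(maps["entropy"].values == 0.0)
        assert np.all(maps["homogeneity"].values == 1.0)

    def test_every_position_matches_per_cube_oracle(self, rng):
        """Vectorized maps equal haralick(glcm) recomputed per cube, slice
        and offset, at a random sample of positions of a random volume."""
        levels = rng.integers(0, 6, size=(20, 20, 20))
        nz = rng.random((20, 20, 20)) > 0.2
        levels = levels * nz
        q = _quantized_from_levels(levels, 6, nonzero=levels > 0)
        cube, stride = 5, 1
        maps = texture_feature_maps(q, cube, stride)
        starts = map_grid_starts(20, cube, stride)
        for _ in range(40):
            iz, iy, ix = rng.integers(0, len(starts), 3)
            z0, y0, x0 = starts[iz], starts[iy], starts[ix]
            cube_arr = levels[z0:z0 + cube, y0:y0 + cube, x0:x0 + cube]
            if not (cube_arr > 0).any():
                assert not maps["energy"].valid_mask[iz, iy, ix]
                continue
            acc = dict.fromkeys(FEATURE_NAMES, 0.0)
            for zz in range(cube):
                for off in DEFAULT_OFFSETS:
                    f = haralick_features(glcm_2d(cube_arr[zz], off, 6))
                    for k in FEATURE_NAMES:
                        acc[k] += f[k]
            for k in FEATURE_NAMES:
                assert maps[k].values[iz, iy, ix] == pytest.approx(
                    acc[k] / (cube * len(DEFAULT_OFFSETS)), abs=1e-9)

    def test_translation_by_stride_shifts_valid_map(self):
        levels = np.zeros((16, 16, 16), dtype=int)
        levels[4:9, 4:9, 4:9] = 3
        q = _quantized_from_levels(levels, 4)
        shifted = np.roll(levels, 2, axis=0)
        q2 = _quantized_from_levels(shifted, 4)
        m1 = texture_feature_maps(q, 4, 2, features=("energy",))["energy"]
        m2 = texture_feature_maps(q2, 4, 2, features=("energy",))["energy"]
        assert np.array_equal(np.roll(m1.valid_mask, 1, axis=0), m2.valid_mask)

    def test_degenerate_parameters_rejected(self):
        q = _quantized_from_levels(np.ones((8, 8, 8)), 4)
        with pytest.raises(ValueError):
            texture_feature_maps(q, cube_size=1)
        with pytest.raises(ValueError):
            texture_feature_maps(q, cube_size=9)
        with pytest.raises(ValueError):
            texture_feature_maps(q, cube_size=4, stride=0)
        with pytest.raises(ValueError):
            texture_feature_maps(q, cube_size=4, features=("bogus",))


def test_energy_entropy_antagonism_across_smoothness():
    """Over increasing boundary smoothness the boundary-shell energy never
    falls and entropy never rises (10 seeds × 3 settings, sign test)."""
    from scipy.stats import binomtest
    from test_synthetic import shell_mean_feature

    shape = (40, 40, 40)
    n_monotone = 0
    seeds = range(10)
    for seed in seeds:
        es, hs = [], []
        for sm in (0.3, 0.9, 1.8):
            vol = generate_brain_volume(shape, sm, 2.0, 0.05, seed=40 + seed)
            q = equalize_histogram(vol, 16)
            maps = texture_feature_maps(q, 5, 2,
                                        features=("energy", "entropy"))
            es.append(shell_mean_feature(shape, maps["energy"]))
            hs.append(shell_mean_feature(shape, maps["entropy"]))
        if np.all(np.diff(es) >= 0) and np.all(np.diff(hs) <= 0):
            n_monotone += 1
    assert binomtest(n_monotone, len(list(seeds)), 0.5,
                     alternative="greater").pvalue < 0.05
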