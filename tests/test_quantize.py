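"""Histogram equalization and bin-count selection contracts."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braintexture.quantize import (equalize_histogram, candidate_grid,
                                   select_bin_count)
from braintexture.synthetic import RawVolume, generate_brain_volume


def _volume_from_values(values, shape=None):
    values = np.asarray(values, dtype=float)
    if shape is None:
        n = values.size
        values = np.pad(values, (0, 27 - n % 27 if n % 27 else 0))
        side = int(np.ceil(values.size ** (1 / 3)))
        values = np.pad(values, (0, side**3 - values.size))
        values = values.reshape(side, side, side)
    mask = values != 0
    return RawVolume(voxels=values, brain_mask=mask)


class TestEqualize:
    def test_constant_in_mask_volume_occupies_single_level(self, caplog):
        vox = np.zeros((4, 4, 4))
        vox[1:3, 1:3, 1:3] = 7.0
        vol = RawVolume(voxels=vox)
        with caplog.at_level(logging.WARNING):
            q = equalize_histogram(vol, 16)
        assert len(np.unique(q.levels[q.brain_mask])) == 1
        assert "constant" in caplog.text

    def test_uniform_sixteen_values_map_bijectively_flat(self):
        vals = np.repeat(np.arange(1.0, 17.0), 4)
        vol = _volume_from_values(vals)
        q = equalize_histogram(vol, 16)
        hist = np.bincount(q.levels[vol.brain_mask], minlength=16)
        assert np.all(hist == hist[0])
        # bijective: each distinct intensity owns one distinct level
        uniq, lev = q.source_mapping
        assert len(np.unique(lev)) == 16

    def test_lognormal_output_closer_to_uniform_than_input(self, rng):
        """Equalization must beat naive equal-width binning in Kolmogorov
        distance to the uniform level distribution (CDF-mapping oracle)."""
        vals = rng.lognormal(0.0, 0.7, size=1000) + 0.1
        vol = _volume_from_values(vals)
        g = 16
        q = equalize_histogram(vol, g)
        inmask = vol.brain_mask

        def ks_to_uniform(levels):
            h = np.bincount(levels, minlength=g) / levels.size
            return np.abs(np.cumsum(h) - np.arange(1, g + 1) / g).max()

        # independent oracle: empirical-CDF mapping computed from scratch
        sorted_vals = np.sort(vals)
        ecdf = np.searchsorted(sorted_vals, vol.voxels[inmask],
                               side="right") / vals.size
        oracle_levels = np.clip(np.ceil(ecdf * g) - 1, 0, g - 1).astype(int)
        assert np.array_equal(q.levels[inmask], oracle_levels)

        equal_width = np.clip(
            ((vol.voxels[inmask] - vals.min())
             / (vals.max() - vals.min() + 1e-12) * g).astype(int), 0, g - 1)
        assert ks_to_uniform(q.levels[inmask]) < ks_to_uniform(equal_width)

    def test_background_pinned_to_zero_and_excluded_from_cdf(self):
        vox = np.zeros((6, 6, 6))
        vox[2:5, 2:5, 2:5] = np.linspace(10, 20, 27).reshape(3, 3, 3)
        vol = RawVolume(voxels=vox)
        q_small = equalize_histogram(vol, 4)
        assert np.all(q_small.levels[~vol.brain_mask] == 0)
        # adding background voxels must not change in-mask levels
        vox_big = np.zeros((10, 10, 10))
        vox_big[2:5, 2:5, 2:5] = vox[2:5, 2:5, 2:5]
        q_big = equalize_histogram(RawVolume(voxels=vox_big), 4)
        assert np.array_equal(q_small.levels[2:5, 2:5, 2:5],
                              q_big.levels[2:5, 2:5, 2:5])

    def test_equalization_idempotent_at_same_level_count(self):
        vol = generate_brain_volume((24, 24, 24), 1.0, 1.0, 0.1, seed=3)
        q = equalize_histogram(vol, 16)
        q2 = equalize_histogram(
            RawVolume(voxels=q.levels.astype(float) + (q.levels > 0) * 0.5,
                      brain_mask=vol.brain_mask), 16)
        # occupied-level multiset unchanged: re-equalizing is a no-op
        requant = equalize_histogram(
            RawVolume(voxels=np.where(vol.brain_mask,
                                      q.levels.astype(float) + 1.0, 0.0),
                      brain_mask=vol.brain_mask), 16)
        assert np.array_equal(requant.levels[vol.brain_mask],
                              q.levels[vol.brain_mask])
        del q2

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.1, 100.0), min_size=20, max_size=200),
           st.integers(2, 32))
    def test_mapping_monotone_and_levels_in_range(self, values, g):
        vol = _volume_from_values(np.array(values))
        q = equalize_histogram(vol, g)
        inm = q.levels[vol.brain_mask]
        assert inm.min() >= 0 and inm.max() <= g - 1
        uniq, lev = q.source_mapping
        assert np.all(np.diff(lev) >= 0)  # monotone non-decreasing

    def test_invalid_level_counts_rejected(self):
        vol = generate_brain_volume((16, 16, 16), seed=0)
        with pytest.raises(ValueError):
            equalize_histogram(vol, 1)
        with pytest.raises(ValueError):
            equalize_histogram(vol, 300)


class TestSelectBinCount:
    def test_single_candidate_returned_without_search(self):
        assert select_bin_count([], [], [16], eval_fn=None) == 16

    def test_argmax_selection_matches_full_grid_oracle(self):
        vols = [generate_brain_volume((16, 16, 16), 0.5, 1.0, 0.05, seed=s)
                for s in range(4)]
        labels = [0, 0, 1, 1]
        candidates = [2, 4, 8, 16]
        scores = {2: 0.5, 4: 0.9, 8: 0.7, 16: 0.6}

        def eval_fn(quantized, labs):
            return scores[quantized[0].n_levels]

        chosen = select_bin_count(vols, labels, candidates, eval_fn)
        oracle = max(candidates, key=lambda g: scores[g])
        assert chosen == oracle == 4

    def test_ties_break_toward_smaller_count(self):
        vols = [generate_brain_volume((16, 16, 16), seed=s) for s in range(2)]
        assert select_bin_count(vols, [0, 1], [8, 16],
                                eval_fn=lambda q, y: 0.7) == 8

    def test_failing_candidate_skipped_with_warning(self, caplog):
        vols = [generate_brain_volume((16, 16, 16), seed=s) for s in range(2)]

        def eval_fn(quantized, labs):
            if quantized[0].n_levels == 4:
                raise RuntimeError("boom")
            return quantized[0].n_levels / 100

        with caplog.at_level(logging.WARNING):
            assert select_bin_count(vols, [0, 1], [4, 8, 16], eval_fn) == 16
        assert "skipped" in caplog.text

    def test_all_candidates_failing_is_an_error(self):
        vols = [generate_brain_volume((16, 16, 16), seed=s) for s in range(2)]

        def eval_fn(quantized, labs):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="every candidate"):
            select_bin_count(vols, [0, 1], [4, 8], eval_fn)

    def test_single_class_labels_rejected(self):
        vols = [generate_brain_volume((16, 16, 16), seed=s) for s in range(2)]
        with pytest.raises(ValueError, match="both classes"):
            select_bin_count(vols, [0, 0], [4, 8], eval_fn=lambda q, y: 1.0)


def test_candidate_grid_is_conventional_2_to_256_step_2():
    grid = candidate_grid()
    assert grid[0] == 2 and grid[-1] == 256 and len(grid) == 128
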