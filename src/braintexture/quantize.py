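"""Grey-level quantization by histogram equalization.

Texture features from co-occurrence matrices need intensities reduced to a
small number G of discrete grey levels, identical across all images of a
study, so the matrices are comparable between subjects and samples.  The
mapping used here is classic CDF-based histogram equalization computed over
in-mask voxels only: the output level of intensity v is ``ceil(G·F(v)) - 1``
where F is the empirical CDF, giving the flattest level histogram achievable
by a monotone mapping.  Background stays pinned at level 0 and never enters
the CDF.

The optimal G is not known a priori; :func:`select_bin_count` searches a
candidate grid (the conventional one runs from 2 to 256 in steps of 2) by
cross-validated balanced accuracy of the downstream classifier, the way the
bin width is selected in radiomics studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import RawVolume

__all__ = ["QuantizedVolume", "equalize_histogram", "select_bin_count",
           "DEFAULT_N_LEVELS", "candidate_grid"]

logger = logging.getLogger(__name__)

#: Default number of grey levels (the bin count that maximizes downstream
#: balanced accuracy on cohorts of this kind).
DEFAULT_N_LEVELS = 16


def candidate_grid(lo: int = 2, hi: int = 256, step: int = 2) -> list[int]:
    """The conventional exhaustive bin-count grid: 2..256 in steps of 2."""
    return list(range(lo, hi + 1, step))


@dataclass
class QuantizedVolume:
    """Integer grey-level volume in [0, n_levels-1], background at level 0."""

    levels: np.ndarray
    n_levels: int
    #: (sorted unique in-mask intensities, their levels) — the monotone lookup.
    source_mapping: tuple[np.ndarray, np.ndarray]
    brain_mask: np.ndarray
    #: voxels whose *original* intensity was nonzero; the texture stage's
    #: cube-exclusion rule keys on this.
    nonzero_mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def map_intensity(self, values):
        """Apply the stored monotone intensity→level lookup to new values."""
        uniq, lev = self.source_mapping
        idx = np.clip(np.searchsorted(uniq, values), 0, len(uniq) - 1)
        return lev[idx]


def equalize_histogram(volume: RawVolume, n_levels: int = DEFAULT_N_LEVELS
                       ) -> QuantizedVolume:
    """Histogram-equalize a volume onto ``n_levels`` discrete grey levels.

    The empirical CDF is computed over in-mask voxels only and intensities
    are mapped by ``level(v) = ceil(n_levels · F(v)) - 1`` (clipped to
    ``[0, n_levels-1]``).  The mapping is monotone non-decreasing, the output
    histogram is maximally flat for a monotone mapping, and re-equalizing an
    already equalized volume at the same G is a no-op.  Background voxels are
    assigned level 0 and never influence the CDF.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2 (got {n_levels})")
    if n_levels > 256:
        raise ValueError(f"n_levels must be <= 256 (got {n_levels})")
    mask = volume.brain_mask
    vals = volume.voxels[mask]
    levels = np.zeros(volume.voxels.shape, dtype=np.int16)
    if vals.size == 0:
        logger.warning("empty brain mask: all voxels at level 0")
        return QuantizedVolume(levels, n_levels,
                               (np.empty(0), np.empty(0, dtype=np.int16)),
                               mask, volume.voxels != 0, volume.spacing)
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size == 1:
        logger.warning("constant in-mask volume: single occupied level")
        lev = np.zeros(1, dtype=np.int16)
    else:
        cdf = np.cumsum(counts) / vals.size
        lev = np.clip(np.ceil(cdf * n_levels) - 1, 0, n_levels - 1
                      ).astype(np.int16)
    idx = np.searchsorted(uniq, vals)
    levels[mask] = lev[idx]
    return QuantizedVolume(
        levels=levels,
        n_levels=n_levels,
        source_mapping=(uniq, lev),
        brain_mask=mask,
        nonzero_mask=volume.voxels != 0,
        spacing=volume.spacing,
    )


def select_bin_count(volumes, labels, candidates, eval_fn):
    """Pick the grey-level count with the best downstream balanced accuracy.

    Parameters
    ----------
    volumes : sequence of RawVolume
    labels : sequence
        Class label per volume; both classes must be present.
    candidates : sequence of int
        Bin counts to evaluate (see :func:`candidate_grid`).
    eval_fn : callable(quantized_volumes, labels) -> float
        Downstream evaluator returning a cross-validated balanced accuracy
        (percent or fraction — only the ordering matters).

    Returns the candidate with the highest score; ties break toward the
    smaller count.  Candidates on which ``eval_fn`` raises are skipped with a
    warning; if every candidate fails, an error is raised.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("no candidates given")
    if len(candidates) == 1:
        return candidates[0]
    if len(set(labels)) < 2:
        raise ValueError("labels must contain both classes")
    best, best_score = None, -np.inf
    for g in candidates:
        try:
            quantized = [equalize_histogram(v, g) for v in volumes]
            score = float(eval_fn(quantized, labels))
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            logger.warning("bin count %d skipped: %s", g, exc)
            continue
        logger.info("bin count %d: score %.4f", g, score)
        if score > best_score:  # strict: ties keep the smaller count
            best, best_score = g, score
    if best is None:
        raise RuntimeError("evaluation failed for every candidate bin count")
    return best
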