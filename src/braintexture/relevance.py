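"""Layer-wise relevance propagation heatmaps and their summaries.

A trained network's prediction for one subject is explained by decomposing
the predicted-class output score into signed per-voxel relevance: starting
from the output layer, relevance is propagated backwards through every layer
with the ε-stabilized rule, conserving the score up to the small amount the
stabilizer absorbs.  Positive relevance marks voxels whose texture pushed
the decision toward the predicted class, negative relevance voxels that
spoke against it.

Two summaries feed the downstream analyses: the mean relevance over a brain
mask (the scalar correlated with clinical scores) and, for localization, the
fraction of each atlas region's voxels whose relevance exceeds a percentile
of the in-brain relevance distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import TextureClassifier
from .texture import TextureFeatureMap, map_grid_starts

__all__ = [
    "RelevanceHeatmap",
    "lrp_relevance",
    "mean_relevance",
    "significant_region_fractions",
    "atlas_on_map_grid",
]

logger = logging.getLogger(__name__)


@dataclass
class RelevanceHeatmap:
    """Signed per-voxel relevance for one subject's prediction."""

    relevance: np.ndarray
    subject_id: str
    predicted_class: int
    output_score: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.relevance)):
            raise ValueError("relevance contains non-finite values")


def lrp_relevance(model, input_map, subject_id="", eps=1e-6
                  ) -> RelevanceHeatmap:
    """ε-rule LRP heatmap of one subject's feature map under a model.

    ``model`` is a :class:`~braintexture.classify.TextureClassifier` (its
    standardization is applied first, and relevance lives on the network's
    input grid, which matches the feature-map grid) or a bare
    :class:`~braintexture.nn.Sequential`.  Relevance is initialized as the
    predicted-class output score and propagated back; layers without a
    propagation rule raise an error naming the layer.
    """
    if isinstance(input_map, TextureFeatureMap):
        x = np.where(input_map.valid_mask, input_map.values, 0.0)
    else:
        x = np.asarray(input_map, dtype=float)
    batch = x[None, None]
    if isinstance(model, TextureClassifier):
        net = model.net
        batch = model.standardized_input(batch)
    else:
        net = model
    logits = net.forward(batch)[0]
    pred = int(np.argmax(logits))
    score = float(logits[pred])
    r_out = np.zeros_like(logits)[None]
    r_out[0, pred] = score
    r_in = net.relprop(r_out, eps=eps)
    return RelevanceHeatmap(
        relevance=r_in[0, 0],
        subject_id=subject_id,
        predicted_class=pred,
        output_score=score,
    )


def mean_relevance(heatmap: RelevanceHeatmap, mask) -> float:
    """Arithmetic mean of relevance over a nonempty boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != heatmap.relevance.shape:
        raise ValueError("mask shape does not match heatmap")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(heatmap.relevance[mask].mean())


def significant_region_fractions(heatmap: RelevanceHeatmap, atlas,
                                 percentile=95.0, brain_mask=None
                                 ) -> dict[int, float]:
    """Per-region fraction of voxels with significant relevance.

    A voxel is significant when its relevance strictly exceeds the given
    percentile of the in-brain relevance distribution (at percentile 0 the
    comparison is ``>=``: exceeding the 0th percentile means lying in the
    support).  ``atlas`` holds integer region labels (0 = outside); regions
    with no voxels are omitted with a warning.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != heatmap.relevance.shape:
        raise ValueError("atlas shape does not match heatmap")
    if not 0 <= percentile < 100:
        raise ValueError("percentile must lie in [0, 100)")
    if brain_mask is None:
        brain_mask = atlas > 0
    rel = heatmap.relevance
    in_brain = rel[np.asarray(brain_mask, dtype=bool)]
    if in_brain.size == 0:
        raise ValueError("brain mask is empty")
    thr = np.percentile(in_brain, percentile)
    significant = rel >= thr if percentile == 0 else rel > thr
    fractions = {}
    for region in np.unique(atlas):
        if region == 0:
            continue
        sel = atlas == region
        n = int(sel.sum())
        if n == 0:  # pragma: no cover - unique() precludes this
            logger.warning("region %s has no voxels; omitted", region)
            continue
        fractions[int(region)] = float(significant[sel].sum() / n)
    return fractions


def atlas_on_map_grid(atlas, cube_size, stride) -> np.ndarray:
    """Resample a voxel-grid atlas onto the cube-centre grid of the texture
    feature maps (label at each cube's centre voxel)."""
    atlas = np.asarray(atlas)
    idx = [map_grid_starts(n, cube_size, stride) + cube_size // 2
           for n in atlas.shape]
    return atlas[np.ix_(*idx)]
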