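"""Grey-level co-occurrence matrices and Haralick texture feature maps.

The texture of a quantized volume is summarized locally: a cube slides over
the volume and, for every cube position, 2D co-occurrence matrices (GLCMs)
are computed on each axial slice of the cube for a set of in-plane offsets
(by default the four standard directions 0°, 45°, 90°, 135°, symmetric).
Each GLCM yields the six classic Haralick statistics

* energy        Σ p(i,j)²                (uniformity / order)
* entropy       −Σ p log p               (randomness / heterogeneity)
* contrast      Σ (i−j)² p(i,j)
* homogeneity   Σ p(i,j) / (1 + |i−j|)
* sum entropy   −Σ_k p_{x+y}(k) log p_{x+y}(k)
* diff entropy  −Σ_k p_{x−y}(k) log p_{x−y}(k)

and the feature-map value at a cube centre is the mean over the cube's
slices and offsets.  Cubes containing no nonzero-intensity voxel (pure
background) are excluded and marked invalid.  Natural logarithms throughout.

:func:`glcm_2d` and :func:`haralick_features` are the reference single-slice
path; :func:`texture_feature_maps` computes the same quantities for all cube
positions at once via windowed pair-code histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import xlogy

from .quantize import QuantizedVolume

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_OFFSETS",
    "GLCM",
    "TextureFeatureMap",
    "glcm_2d",
    "haralick_features",
    "texture_feature_maps",
    "map_grid_starts",
]

FEATURE_NAMES = (
    "energy",
    "entropy",
    "sum_entropy",
    "difference_entropy",
    "contrast",
    "homogeneity",
)

#: In-plane (row, col) displacements for 0°, 45°, 90°, 135°.
DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class GLCM:
    """A normalized grey-level co-occurrence matrix."""

    p: np.ndarray
    offset: tuple[int, int]
    symmetric: bool
    n_pairs: int


@dataclass
class TextureFeatureMap:
    """One Haralick feature evaluated at every cube centre of a volume.

    ``values`` lives on the cube-centre grid (one entry per cube position);
    invalid positions (all-background cubes) carry NaN and are flagged False
    in ``valid_mask``.  The extraction configuration is carried along so a
    model trained on maps from one configuration can refuse maps from
    another.
    """

    feature_name: str
    values: np.ndarray
    valid_mask: np.ndarray
    cube_size: int
    stride: int
    n_levels: int
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS

    @property
    def config(self) -> dict:
        return {
            "cube_size": self.cube_size,
            "stride": self.stride,
            "n_levels": self.n_levels,
            "offsets": tuple(tuple(o) for o in self.offsets),
        }


def glcm_2d(slice2d, offset, n_levels, symmetric=True) -> GLCM:
    """Co-occurrence matrix of one 2D integer-level image at one offset.

    Counts ordered pairs ``(v[r, c], v[r+dr, c+dc])`` over all in-bounds
    positions, optionally adds the transposed counts (symmetric GLCM), and
    normalizes to probabilities.  An image too small for the offset yields a
    zero matrix with ``n_pairs == 0``.
    """
    s = np.asarray(slice2d)
    if s.ndim != 2:
        raise ValueError("slice must be 2D")
    if s.size and (s.min() < 0 or s.max() >= n_levels):
        raise ValueError(f"slice values must lie in [0, {n_levels - 1}]")
    dr, dc = int(offset[0]), int(offset[1])
    h, w = s.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    p = np.zeros((n_levels, n_levels), dtype=np.float64)
    if r1 <= r0 or c1 <= c0:
        return GLCM(p=p, offset=(dr, dc), symmetric=symmetric, n_pairs=0)
    a = s[r0:r1, c0:c1].ravel()
    b = s[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    np.add.at(p, (a, b), 1.0)
    n_pairs = a.size
    if symmetric:
        p = p + p.T
    p /= p.sum()
    return GLCM(p=p, offset=(dr, dc), symmetric=symmetric, n_pairs=n_pairs)


def haralick_features(glcm: GLCM) -> dict[str, float]:
    """The six Haralick statistics of one normalized GLCM.

    ``0·log 0`` is taken as 0 in all entropies; logarithms are natural.
    """
    p = glcm.p
    if glcm.n_pairs <= 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("GLCM must be normalized with n_pairs > 0")
    g = p.shape[0]
    i, j = np.indices((g, g))
    p_sum = np.bincount((i + j).ravel(), weights=p.ravel(), minlength=2 * g - 1)
    p_diff = np.bincount(np.abs(i - j).ravel(), weights=p.ravel(), minlength=g)
    return {
        "energy": float((p**2).sum()),
        "entropy": float(-xlogy(p, p).sum()),
        "sum_entropy": float(-xlogy(p_sum, p_sum).sum()),
        "difference_entropy": float(-xlogy(p_diff, p_diff).sum()),
        "contrast": float(((i - j) ** 2 * p).sum()),
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
    }


def map_grid_starts(dim: int, cube_size: int, stride: int) -> np.ndarray:
    """Cube start indices along one axis: 0, stride, … ≤ dim − cube_size."""
    return np.arange(0, dim - cube_size + 1, stride)


def _feature_weights(n_levels):
    """Pair-code weight vectors and groupings shared by all windows."""
    g = n_levels
    i, j = np.indices((g, g))
    sum_idx = (i + j).ravel()
    diff_idx = np.abs(i - j).ravel()
    order_s = np.argsort(sum_idx, kind="stable")
    order_d = np.argsort(diff_idx, kind="stable")
    starts_s = np.searchsorted(sum_idx[order_s], np.arange(2 * g - 1))
    starts_d = np.searchsorted(diff_idx[order_d], np.arange(g))
    return {
        "contrast": ((i - j) ** 2).ravel().astype(np.float64),
        "homogeneity": (1.0 / (1.0 + np.abs(i - j))).ravel(),
        "order_s": order_s,
        "starts_s": starts_s,
        "order_d": order_d,
        "starts_d": starts_d,
        "transpose": (j * g + i).ravel(),
    }


def _count_entropy(counts, total, lut):
    """−Σ (c/T) ln(c/T) for integer count vectors via a c·ln c lookup."""
    return np.log(total) - lut[counts].sum(axis=1) / total


def _slice_features(counts, total, w, features):
    """Haralick statistics for a stack of integer GLCM count vectors.

    ``counts``: (n_windows, G²) co-occurrence counts, each summing to
    ``total``.  Integer counts keep the entropies exact (a small lookup
    table replaces per-entry logs).  Returns dict feature → (n_windows,).
    """
    lut = xlogy(np.arange(total + 1, dtype=np.float64),
                np.arange(total + 1, dtype=np.float64))
    out = {}
    if "energy" in features:
        out["energy"] = (counts.astype(np.int64) ** 2).sum(axis=1) / total**2
    if "entropy" in features:
        out["entropy"] = _count_entropy(counts, total, lut)
    if "contrast" in features:
        out["contrast"] = (counts @ w["contrast"]) / total
    if "homogeneity" in features:
        out["homogeneity"] = (counts @ w["homogeneity"]) / total
    if "sum_entropy" in features:
        ms = np.add.reduceat(counts[:, w["order_s"]], w["starts_s"], axis=1)
        out["sum_entropy"] = _count_entropy(ms, total, lut)
    if "difference_entropy" in features:
        md = np.add.reduceat(counts[:, w["order_d"]], w["starts_d"], axis=1)
        out["difference_entropy"] = _count_entropy(md, total, lut)
    return out


def texture_feature_maps(
    qvolume: QuantizedVolume,
    cube_size: int = 5,
    stride: int = 1,
    features=FEATURE_NAMES,
    offsets=DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> dict[str, TextureFeatureMap]:
    """Sliding-cube Haralick feature maps of a quantized volume.

    For every cube position the value of each feature is the mean of
    ``haralick_features(glcm_2d(axial slice of the cube, offset))`` over the
    cube's ``cube_size`` axial slices and all ``offsets``.  Cubes made up
    entirely of zero-intensity voxels are invalid (NaN value, False mask).

    Windowed pair-code histograms make this exactly equivalent to — but a few
    hundred times faster than — looping :func:`glcm_2d` over cubes.
    """
    features = tuple(features)
    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    if cube_size < 2:
        raise ValueError("cube_size must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    levels = qvolume.levels
    nz, ny, nx = levels.shape
    if cube_size > min(nz, ny, nx):
        raise ValueError(
            f"cube_size {cube_size} exceeds smallest volume dimension "
            f"{min(nz, ny, nx)}"
        )
    g = qvolume.n_levels
    zs = map_grid_starts(nz, cube_size, stride)
    ys = map_grid_starts(ny, cube_size, stride)
    xs = map_grid_starts(nx, cube_size, stride)
    grid_shape = (len(zs), len(ys), len(xs))
    w = _feature_weights(g)

    # Per-slice feature planes, then a mean over the cube's z-extent.
    # slice_feats[f][z, iy, ix] = mean over offsets of feature f of the GLCM
    # of the cube window at (iy, ix) in axial slice z.
    slice_feats = {f: np.zeros((nz, len(ys), len(xs))) for f in features}
    n_off = len(offsets)
    nyx = len(ys) * len(xs)
    z_chunk = max(1, int(2**22 // max(nyx * g * g, 1)) or 1)
    for dr, dc in offsets:
        adr, adc = abs(int(dr)), abs(int(dc))
        wh, ww = cube_size - adr, cube_size - adc
        total = 2 * wh * ww if symmetric else wh * ww
        r0, c0 = max(0, -dr), max(0, -dc)
        a = levels[:, r0:ny - max(0, dr), c0:nx - max(0, dc)]
        b = levels[:, r0 + dr:r0 + dr + a.shape[1],
                   c0 + dc:c0 + dc + a.shape[2]]
        # Pair codes g1·G+g2 per axial slice; a cube window starting at
        # (y0, x0) contains exactly the pairs whose anchor lies in the
        # (wh × ww) code sub-window at (y0, x0).
        codes = a.astype(np.int32) * g + b
        win = sliding_window_view(codes, (wh, ww), axis=(1, 2))
        win = win[:, ys][:, :, xs]  # (nz, ny_grid, nx_grid, wh, ww)
        for z0 in range(0, nz, z_chunk):
            z1 = min(z0 + z_chunk, nz)
            flat = win[z0:z1].reshape(-1, wh * ww)
            nwin = flat.shape[0]
            offs = (np.arange(nwin, dtype=np.int64) * (g * g))[:, None]
            counts = np.bincount((flat + offs).ravel(),
                                 minlength=nwin * g * g
                                 ).reshape(nwin, g * g).astype(np.int32)
            if symmetric:
                counts = counts + counts[:, w["transpose"]]
            sf = _slice_features(counts, total, w, features)
            for f in features:
                slice_feats[f][z0:z1] += (
                    sf[f].reshape(z1 - z0, len(ys), len(xs)) / n_off
                )

    # Mean over the cube's axial slices via a cumulative sum along z.
    maps = {}
    valid = _valid_cube_mask(qvolume.nonzero_mask, cube_size, zs, ys, xs)
    for f in features:
        cs = np.concatenate(
            [np.zeros((1,) + grid_shape[1:]), np.cumsum(slice_feats[f], axis=0)]
        )
        vals = (cs[zs + cube_size] - cs[zs]) / cube_size
        vals = np.where(valid, vals, np.nan)
        maps[f] = TextureFeatureMap(
            feature_name=f,
            values=vals,
            valid_mask=valid,
            cube_size=cube_size,
            stride=stride,
            n_levels=g,
            offsets=tuple(tuple(o) for o in offsets),
        )
    return maps


def _valid_cube_mask(nonzero_mask, cube_size, zs, ys, xs):
    """True where the cube holds at least one nonzero-intensity voxel."""
    nz_int = nonzero_mask.astype(np.float64)
    c = nz_int
    for ax in range(3):
        cs = np.cumsum(c, axis=ax)
        cs = np.concatenate([np.zeros_like(np.take(cs, [0], axis=ax)), cs],
                            axis=ax)
        starts = (zs, ys, xs)[ax]
        c = np.take(cs, starts + cube_size, axis=ax) - np.take(cs, starts,
                                                               axis=ax)
    return c > 0
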