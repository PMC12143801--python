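"""Volume-level segmentation metrics and signed surface distance maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging_io import BinaryMask, DegenerateInputError

__all__ = ["SegMetrics", "SurfaceDistanceMap", "seg_metrics",
           "surface_distance", "error_histogram", "surface_voxels"]


@dataclass
class SegMetrics:
    ds: float           # Dice in [0, 1]
    pr: float           # precision, percent
    re: float           # recall, percent
    n_pred: int
    n_gt: int
    n_intersection: int


@dataclass
class SurfaceDistanceMap:
    nodes: np.ndarray         # (n, 3) mm coordinates of predicted-surface voxels
    signed_error: np.ndarray  # mm; >0 outside GT (overestimation), <0 inside


def seg_metrics(pred: BinaryMask, gt: BinaryMask) -> SegMetrics:
    """Dice, precision and recall from exact voxel counts."""
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {gt.shape}")
    p = pred.voxels
    g = gt.voxels
    n_p = int(p.sum())
    n_g = int(g.sum())
    n_i = int((p & g).sum())
    if n_p == 0 and n_g == 0:
        raise DegenerateInputError("both masks empty: metrics undefined")
    ds = 2.0 * n_i / (n_p + n_g)
    pr = 100.0 * n_i / n_p if n_p else 0.0
    re = 100.0 * n_i / n_g if n_g else 0.0
    return SegMetrics(ds=ds, pr=pr, re=re,
                      n_pred=n_p, n_gt=n_g, n_intersection=n_i)


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Indices of foreground voxels with at least one background 6-neighbour."""
    fg = mask.voxels
    eroded = ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    return np.argwhere(fg & ~eroded)


def surface_distance(pred: BinaryMask, gt: BinaryMask) -> SurfaceDistanceMap:
    """Per predicted-surface node: mm distance to the nearest GT surface node.

    Sign is positive when the node lies outside the GT mask (overestimation),
    negative when inside (underestimation).
    """
    if pred.spacing != gt.spacing:
        raise ValueError("masks must share spacing")
    if not pred.voxels.any() or not gt.voxels.any():
        raise DegenerateInputError("empty mask")
    spacing = np.asarray(pred.spacing)
    p_idx = surface_voxels(pred)
    g_idx = surface_voxels(gt)
    tree = cKDTree(g_idx * spacing)
    dist, _ = tree.query(p_idx * spacing)
    inside = gt.voxels[tuple(p_idx.T)]
    signed = np.where(inside, -dist, dist)
    return SurfaceDistanceMap(nodes=p_idx * spacing, signed_error=signed)


def error_histogram(dmap: SurfaceDistanceMap, bin_width: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Counts of nodes per signed-error bin; counts sum to the node count."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if dmap.signed_error.size == 0:
        raise DegenerateInputError("empty distance map")
    e = dmap.signed_error
    lo = np.floor(e.min() / bin_width) * bin_width
    hi = np.ceil(e.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(e, bins=edges)
    return counts, edges
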