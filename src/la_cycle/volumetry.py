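"""Per-phase left-atrial volumes and the three rhythm features.

Features per patient:

* LAEI (expansion index)  = (LAVmax - LAVmin) / LAVmin * 100   [%]
* LAEF (emptying fraction) = (LAVmax - LAVmin) / LAVmax * 100  [%]
* AP diameter: at the maximal-volume phase, on the axial slice with the
  largest segmented area, the maximum pairwise distance (mm) between
  border pixels of the largest connected component.

LAVmax/LAVmin come from the ten raw per-phase volumes; the cubic spline
(periodic, the cycle wraps 90% -> 0%) is provided for curve inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .imaging_io import BinaryMask, DegenerateInputError
from .trainer import CANONICAL_PHASES

__all__ = ["VolumeCurve", "VolumetricFeatures", "mask_volume", "volume_curve",
           "expansion_index", "emptying_fraction", "ap_diameter",
           "extract_features"]


@dataclass
class VolumeCurve:
    phases: tuple[int, ...]
    lav: np.ndarray          # mL, one per phase
    lav_max: float
    lav_min: float
    spline: CubicSpline

    def __call__(self, phase_percent):
        return self.spline(np.mod(phase_percent, 100.0))


@dataclass
class VolumetricFeatures:
    laei: float   # percent
    laef: float   # percent
    ap: float     # mm


def mask_volume(mask: BinaryMask) -> float:
    """Voxel count times voxel volume, in mL."""
    return float(mask.voxels.sum()) * mask.voxel_volume_mm3() / 1000.0


def volume_curve(masks) -> VolumeCurve:
    """Ten phase-ordered masks -> per-phase volumes plus a periodic spline."""
    masks = list(masks)
    if len(masks) != len(CANONICAL_PHASES):
        raise ValueError(f"expected {len(CANONICAL_PHASES)} phase masks, "
                         f"got {len(masks)}")
    lav = np.array([mask_volume(m) for m in masks])
    # close the cycle: knot at 100% repeats phase 0
    x = np.array(list(CANONICAL_PHASES) + [100.0])
    y = np.append(lav, lav[0])
    spline = CubicSpline(x, y, bc_type="periodic")
    return VolumeCurve(phases=CANONICAL_PHASES, lav=lav,
                       lav_max=float(lav.max()), lav_min=float(lav.min()),
                       spline=spline)


def expansion_index(curve: VolumeCurve) -> float:
    if curve.lav_min <= 0:
        raise DegenerateInputError("LAVmin must be > 0")
    return (curve.lav_max - curve.lav_min) / curve.lav_min * 100.0


def emptying_fraction(curve: VolumeCurve) -> float:
    if curve.lav_max <= 0:
        raise DegenerateInputError("LAVmax must be > 0")
    return (curve.lav_max - curve.lav_min) / curve.lav_max * 100.0


def _border_pixels(slice2d: np.ndarray) -> np.ndarray:
    """Border pixels of the largest connected component of a 2D mask."""
    labels = measure.label(slice2d, connectivity=1)
    if labels.max() == 0:
        return np.empty((0, 2), dtype=int)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    comp = labels == largest
    interior = np.zeros_like(comp)
    interior[1:-1, 1:-1] = (comp[1:-1, 1:-1] & comp[:-2, 1:-1] & comp[2:, 1:-1]
                            & comp[1:-1, :-2] & comp[1:-1, 2:])
    return np.argwhere(comp & ~interior)


def _set_diameter(points_mm: np.ndarray) -> float:
    """Maximum pairwise distance; convex hull prunes when it helps."""
    if len(points_mm) < 2:
        return 0.0
    pts = points_mm
    if len(pts) > 10:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    return float(pdist(pts).max())


def ap_diameter(masks, axial_axis: int = 2) -> float:
    """AP diameter (mm) at the maximal-volume phase.

    ``axial_axis`` selects which voxel axis indexes axial slices; the two
    in-plane spacings are used for physical distances.
    """
    masks = list(masks)
    volumes = [mask_volume(m) for m in masks]
    best = masks[int(np.argmax(volumes))]
    if not best.voxels.any():
        raise DegenerateInputError("maximal-phase mask is empty")
    areas = best.voxels.sum(axis=tuple(a for a in range(3) if a != axial_axis))
    k = int(np.argmax(areas))
    slice2d = np.take(best.voxels, k, axis=axial_axis)
    inplane = [s for a, s in enumerate(best.spacing) if a != axial_axis]
    border = _border_pixels(slice2d)
    return _set_diameter(border * np.asarray(inplane))


def extract_features(masks, axial_axis: int = 2) -> tuple[VolumetricFeatures, VolumeCurve]:
    """The (LAEI, LAEF, AP) triple plus the volume curve for one patient."""
    curve = volume_curve(masks)
    return (VolumetricFeatures(laei=expansion_index(curve),
                               laef=emptying_fraction(curve),
                               ap=ap_diameter(masks, axial_axis=axial_axis)),
            curve)
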