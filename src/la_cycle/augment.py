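"""Online affine augmentation: rotation, shear, and scale.

Each augmented copy applies one composite transform (rotation in the
x-y, x-z and y-z planes, then shear, then uniform scale) about the
volume centre, with the same transform used for the image (trilinear)
and its mask (nearest-neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imaging_io import BinaryMask, ImageVolume

__all__ = ["AffineAugmentConfig", "shear_matrix", "rotation_matrix",
           "scale_matrix", "sample_transform", "augment_pair"]


@dataclass
class AffineAugmentConfig:
    rot_range: float = 0.2        # radians, per plane
    shear_range: float = 0.05     # unitless, per axis
    scale_range: float = 0.15     # fractional linear scale variation
    factor: int = 4               # augmented copies per volume
    seed: int = 0

    def __post_init__(self):
        if min(self.rot_range, self.shear_range, self.scale_range) < 0:
            raise ValueError("augmentation ranges must be >= 0")
        if self.factor < 0:
            raise ValueError("factor must be >= 0")


def shear_matrix(sx: float, sy: float, sz: float) -> np.ndarray:
    """Homogeneous shear: diagonal kept at 1, off-diagonals coupled pairwise."""
    return np.array([
        [1.0, sx, sx * sy, 0.0],
        [sy, 1.0, sy * sz, 0.0],
        [sz, sz * sx, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])


def rotation_matrix(theta_xy: float, theta_xz: float, theta_yz: float) -> np.ndarray:
    """Composite of in-plane rotations applied in x-y, then x-z, then y-z order."""
    def plane_rot(a, b, theta):
        m = np.eye(4)
        c, s = np.cos(theta), np.sin(theta)
        m[a, a] = c
        m[a, b] = -s
        m[b, a] = s
        m[b, b] = c
        return m

    return (plane_rot(1, 2, theta_yz)
            @ plane_rot(0, 2, theta_xz)
            @ plane_rot(0, 1, theta_xy))


def scale_matrix(s: float) -> np.ndarray:
    m = np.diag([s, s, s, 1.0])
    return m


def sample_transform(cfg: AffineAugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one composite rotation -> shear -> scale matrix."""
    thetas = rng.uniform(-cfg.rot_range, cfg.rot_range, size=3)
    shears = rng.uniform(-cfg.shear_range, cfg.shear_range, size=3)
    s = 1.0 + rng.uniform(-cfg.scale_range, cfg.scale_range)
    return scale_matrix(s) @ shear_matrix(*shears) @ rotation_matrix(*thetas)


def _apply_affine(field: np.ndarray, matrix: np.ndarray, order: int,
                  cval: float) -> np.ndarray:
    """Apply the forward homogeneous `matrix` about the volume centre."""
    inv = np.linalg.inv(matrix)[:3, :3]
    center = (np.array(field.shape) - 1) / 2.0
    offset = center - inv @ center
    return ndimage.affine_transform(field, inv, offset=offset, order=order,
                                    mode="constant", cval=cval)


def augment_pair(vol: ImageVolume, mask: BinaryMask,
                 cfg: AffineAugmentConfig,
                 rng: np.random.Generator | None = None
                 ) -> list[tuple[ImageVolume, BinaryMask]]:
    """Return ``cfg.factor`` jointly transformed (image, mask) pairs.

    The stream is reproducible: with no explicit ``rng`` a fresh generator is
    seeded from ``cfg.seed``, so two identical calls are bitwise identical.
    """
    if vol.shape != mask.shape or vol.spacing != mask.spacing:
        raise ValueError("image and mask must share geometry")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.factor):
        m = sample_transform(cfg, rng)
        v = _apply_affine(np.asarray(vol.voxels, dtype=np.float64), m,
                          order=1, cval=0.0)
        mk = _apply_affine(mask.voxels.astype(np.uint8), m, order=0,
                           cval=0) > 0
        out.append((replace(vol, voxels=v),
                    BinaryMask(voxels=mk, spacing=mask.spacing)))
    return out


def epoch_rng(seed: int, epoch: int, sample_index: int) -> np.random.Generator:
    """Deterministic per-(epoch, sample) stream for online augmentation."""
    return np.random.default_rng(np.random.SeedSequence((seed, epoch, sample_index)))
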