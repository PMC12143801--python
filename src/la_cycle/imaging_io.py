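"""NIfTI I/O, intensity/geometry preprocessing, and image SNR.

Volumes are 3D scalar fields in Hounsfield units (or normalized [0, 1])
with per-axis spacing in millimetres. Intensity preprocessing clips to a
fixed HU window and maps it affinely onto [0, 1]; geometry preprocessing
resamples to isotropic spacing and crops to the mask bounding box.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "IntensityState",
    "ImageVolume",
    "BinaryMask",
    "RoiSpec",
    "PreprocessConfig",
    "read_nifti",
    "read_nifti_mask",
    "write_nifti",
    "compute_snr",
    "clip_and_normalize",
    "resample_iso",
    "crop_to_mask",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported image payloads."""


class DegenerateInputError(ValueError):
    """Raised when an input is valid in form but degenerate in content."""


class IntensityState(str, enum.Enum):
    RAW_HU = "raw_hu"
    CLIPPED = "clipped"
    NORMALIZED = "normalized"


@dataclass
class ImageVolume:
    """A 3D scalar field with physical spacing and an optional phase tag."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    phase: int | None = None
    patient_id: str | None = None
    intensity_state: IntensityState = IntensityState.RAW_HU
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected 3D voxel data, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self):
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class BinaryMask:
    """A boolean field sharing the grid of its paired :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected 3D mask, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self):
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


class RoiRole(str, enum.Enum):
    SIGNAL = "signal"
    BACKGROUND = "background"


@dataclass
class RoiSpec:
    """Half-open per-axis index bounds of a rectangular region of interest."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    role: RoiRole = RoiRole.SIGNAL

    def extract(self, vol: ImageVolume) -> np.ndarray:
        for (lo, hi), n in zip(self.bounds, vol.shape):
            if not (0 <= lo < hi <= n):
                raise DegenerateInputError(
                    f"ROI bounds {self.bounds} outside grid {vol.shape}")
        (x0, x1), (y0, y1), (z0, z1) = self.bounds
        return vol.voxels[x0:x1, y0:y1, z0:z1]


@dataclass
class PreprocessConfig:
    clip_low: float = -350.0
    clip_high: float = 800.0
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    crop_margin: int = 0

    def __post_init__(self):
        if self.clip_low >= self.clip_high:
            raise ValueError("clip_low must be < clip_high")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")


def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_nifti(path) -> ImageVolume:
    """Load a 3D NIfTI volume; intensities are taken as raw HU."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D payload, got {data.ndim}D")
    spacing = _spacing_from_header(img)
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive spacing {spacing}")
    return ImageVolume(voxels=data, spacing=spacing,
                       intensity_state=IntensityState.RAW_HU,
                       affine=np.asarray(img.affine))


def read_nifti_mask(path) -> BinaryMask:
    vol = read_nifti(path)
    return BinaryMask(voxels=vol.voxels > 0.5, spacing=vol.spacing,
                      affine=vol.affine)


def write_nifti(obj: ImageVolume | BinaryMask, path) -> None:
    """Write a volume or mask; world coordinates from the affine are kept."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if obj.affine is not None:
        affine = obj.affine
    else:
        affine = np.diag(list(obj.spacing) + [1.0])
    data = obj.voxels.astype(np.uint8) if isinstance(obj, BinaryMask) \
        else np.asarray(obj.voxels, dtype=np.float64)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(obj.spacing)
    nib.save(img, str(path))


def compute_snr(vol: ImageVolume, signal_roi: RoiSpec, noise_roi: RoiSpec) -> float:
    """Mean of the signal ROI over the population std of the noise ROI."""
    if vol.intensity_state is not IntensityState.RAW_HU:
        raise ValueError("SNR is defined on raw HU intensities")
    s = signal_roi.extract(vol)
    n = noise_roi.extract(vol)
    sigma = float(n.std(ddof=0))  # population convention
    if sigma == 0.0:
        raise DegenerateInputError("noise ROI has zero standard deviation")
    return float(s.mean()) / sigma


def clip_and_normalize(vol: ImageVolume, cfg: PreprocessConfig | None = None) -> ImageVolume:
    """Clip to [clip_low, clip_high] HU then map that fixed window onto [0, 1]."""
    cfg = cfg or PreprocessConfig()
    if vol.intensity_state is not IntensityState.RAW_HU:
        raise ValueError("input must be raw HU")
    clipped = np.clip(vol.voxels, cfg.clip_low, cfg.clip_high)
    normalized = (clipped - cfg.clip_low) / (cfg.clip_high - cfg.clip_low)
    return replace(vol, voxels=normalized,
                   intensity_state=IntensityState.NORMALIZED)


def resample_iso(obj: ImageVolume | BinaryMask,
                 cfg: PreprocessConfig | None = None):
    """Resample to ``cfg.target_spacing`` (trilinear images, nearest masks)."""
    cfg = cfg or PreprocessConfig()
    if any(n < 2 for n in obj.shape):
        raise DegenerateInputError(f"cannot resample degenerate grid {obj.shape}")
    factors = tuple(s / t for s, t in zip(obj.spacing, cfg.target_spacing))
    if isinstance(obj, BinaryMask):
        out = ndimage.zoom(obj.voxels.astype(np.uint8), factors, order=0,
                           grid_mode=True, mode="grid-constant") > 0
        return BinaryMask(voxels=out, spacing=cfg.target_spacing,
                          affine=None)
    out = ndimage.zoom(obj.voxels, factors, order=1,
                       grid_mode=True, mode="nearest")
    return replace(obj, voxels=out, spacing=cfg.target_spacing, affine=None)


def crop_to_mask(vol: ImageVolume, mask: BinaryMask,
                 cfg: PreprocessConfig | None = None) -> tuple[ImageVolume, BinaryMask]:
    """Crop both fields to the mask bounding box plus ``crop_margin`` voxels."""
    cfg = cfg or PreprocessConfig()
    if vol.shape != mask.shape:
        raise ValueError(f"grid mismatch: {vol.shape} vs {mask.shape}")
    if not mask.voxels.any():
        raise DegenerateInputError("empty mask")
    slices = []
    for ax in range(3):
        proj = mask.voxels.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        lo = max(int(idx[0]) - cfg.crop_margin, 0)
        hi = min(int(idx[-1]) + 1 + cfg.crop_margin, mask.shape[ax])
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    return (replace(vol, voxels=vol.voxels[slices], affine=None),
            BinaryMask(voxels=mask.voxels[slices], spacing=mask.spacing))
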