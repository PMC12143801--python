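"""Synthetic ECG-gated 4D phantoms and synthetic rhythm feature tables.

A phantom cardiac phase is an ellipsoidal "atrium" with a half-ellipsoid
lobed protrusion (the appendage), scaled per phase so the analytic shape
volume follows a programmed volume curve. The image is a constant
blood-pool contrast over a soft-tissue background with additive
Gaussian noise whose sigma is solved from the target SNR (signal-ROI
mean over noise-ROI standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import BinaryMask, ImageVolume, IntensityState, RoiRole, RoiSpec
from .rhythm import AF, SR, FEATURE_NAMES, RhythmDataset
from .trainer import CANONICAL_PHASES

__all__ = ["PhantomConfig", "RhythmSimConfig", "sr_volume_program",
           "af_volume_program", "make_phase_series", "default_rois",
           "make_rhythm_table"]


def sr_volume_program(v_min: float = 90.0, v_max: float = 180.0) -> tuple[float, ...]:
    """Large-amplitude program peaking at phase 40% (mL per phase)."""
    p = np.asarray(CANONICAL_PHASES, dtype=float)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * (p + 10.0) / 100.0))
    return tuple(v_min + (v_max - v_min) * w)


def af_volume_program(v_min: float = 130.0, v_max: float = 150.0) -> tuple[float, ...]:
    """Attenuated-amplitude program (reduced contractility)."""
    return sr_volume_program(v_min, v_max)


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (112, 112, 112)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # base semi-axes (mm) at unit scale; the per-phase scale is solved from
    # the volume program
    atrium_semiaxes: tuple[float, float, float] = (34.0, 28.0, 24.0)
    appendage_semiaxes: tuple[float, float, float] = (8.0, 6.0, 6.0)
    volume_program: tuple[float, ...] = field(default_factory=sr_volume_program)
    contrast_hu: float = 260.0
    background_hu: float = 40.0
    target_snr: float = 0.79
    seed: int = 0

    def __post_init__(self):
        if len(self.volume_program) != len(CANONICAL_PHASES):
            raise ValueError("volume program must cover the 10 phases")
        if min(self.volume_program) <= 0:
            raise ValueError("volumes must be > 0")
        if self.target_snr <= 0:
            raise ValueError("target_snr must be > 0")


def _analytic_volume_ml(cfg: PhantomConfig, scale: float) -> float:
    a, b, c = (s * scale for s in cfg.atrium_semiaxes)
    al, bl, cl = (s * scale for s in cfg.appendage_semiaxes)
    # full ellipsoid + half-ellipsoid lobe, mm^3 -> mL
    return (4.0 / 3.0 * np.pi * a * b * c + 2.0 / 3.0 * np.pi * al * bl * cl) / 1000.0


def _digitize_shape(cfg: PhantomConfig, scale: float) -> np.ndarray:
    shape = cfg.shape
    sp = np.asarray(cfg.spacing)
    center = (np.asarray(shape) - 1) / 2.0 * sp
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, sp)),
                        indexing="ij")
    a, b, c = (s * scale for s in cfg.atrium_semiaxes)
    ell = (((grids[0] - center[0]) / a) ** 2
           + ((grids[1] - center[1]) / b) ** 2
           + ((grids[2] - center[2]) / c) ** 2) <= 1.0
    # lobed appendage: half-ellipsoid protruding along +x from the atrium tip
    al, bl, cl = (s * scale for s in cfg.appendage_semiaxes)
    lx = center[0] + a
    lobe = ((((grids[0] - lx) / al) ** 2
             + ((grids[1] - center[1]) / bl) ** 2
             + ((grids[2] - center[2]) / cl) ** 2) <= 1.0) & (grids[0] >= lx)
    return ell | lobe


def default_rois(cfg: PhantomConfig) -> tuple[RoiSpec, RoiSpec]:
    """Signal ROI: small box at the atrium centre; noise ROI: grid corner."""
    cx, cy, cz = (n // 2 for n in cfg.shape)
    h = 3
    signal = RoiSpec(bounds=((cx - h, cx + h), (cy - h, cy + h), (cz - h, cz + h)),
                     role=RoiRole.SIGNAL)
    w = max(2, min(12, min(cfg.shape) // 8))
    noise = RoiSpec(bounds=((0, w), (0, w), (0, w)), role=RoiRole.BACKGROUND)
    return signal, noise


def make_phase_series(cfg: PhantomConfig) -> list[tuple[ImageVolume, BinaryMask]]:
    """Ten (image, mask) pairs following the programmed volume curve."""
    rng = np.random.default_rng(cfg.seed)
    v_unit = _analytic_volume_ml(cfg, 1.0)
    sigma = (cfg.background_hu + cfg.contrast_hu) / cfg.target_snr
    out = []
    extent = [n * s for n, s in zip(cfg.shape, cfg.spacing)]
    for phase, v_target in zip(CANONICAL_PHASES, cfg.volume_program):
        scale = (v_target / v_unit) ** (1.0 / 3.0)
        # feasibility: scaled shape must fit; the lobe protrudes one-sided
        # along +x from the atrium centred on the grid
        half_x = (cfg.atrium_semiaxes[0] + cfg.appendage_semiaxes[0]) * scale
        if (half_x > extent[0] / 2
                or 2 * cfg.atrium_semiaxes[1] * scale > extent[1]
                or 2 * cfg.atrium_semiaxes[2] * scale > extent[2]):
            raise ValueError(
                f"volume program infeasible on grid: phase {phase} needs "
                f"scale {scale:.2f} on extent {extent}")
        mask = _digitize_shape(cfg, scale)
        img = np.full(cfg.shape, cfg.background_hu, dtype=float)
        img[mask] += cfg.contrast_hu
        img += rng.normal(0.0, sigma, size=cfg.shape)
        out.append((ImageVolume(voxels=img, spacing=cfg.spacing, phase=phase,
                                intensity_state=IntensityState.RAW_HU),
                    BinaryMask(voxels=mask, spacing=cfg.spacing)))
    return out


@dataclass
class RhythmSimConfig:
    n_af: int = 22
    n_sr: int = 11
    # class-conditional means for (laei %, laef %, ap mm); laef means follow
    # laef = 100 laei / (100 + laei)
    mean_af: tuple[float, float, float] = (15.0, 13.0, 85.0)
    mean_sr: tuple[float, float, float] = (70.0, 41.2, 60.0)
    cov_af: np.ndarray = field(default_factory=lambda: np.diag([16.0, 9.0, 25.0]))
    cov_sr: np.ndarray = field(default_factory=lambda: np.diag([100.0, 36.0, 25.0]))
    seed: int = 0

    def __post_init__(self):
        if min(self.n_af, self.n_sr) < 1:
            raise ValueError("class counts must be >= 1")
        for cov in (self.cov_af, self.cov_sr):
            if np.any(np.linalg.eigvalsh(np.asarray(cov, dtype=float)) < 0):
                raise ValueError("covariances must be positive semi-definite")


def make_rhythm_table(cfg: RhythmSimConfig) -> RhythmDataset:
    """Sample class-conditional Gaussian (LAEI, LAEF, AP) features with labels."""
    rng = np.random.default_rng(cfg.seed)
    rows, labels = [], []
    for label, n, mean, cov in ((AF, cfg.n_af, cfg.mean_af, cfg.cov_af),
                                (SR, cfg.n_sr, cfg.mean_sr, cfg.cov_sr)):
        need = n
        attempts = 0
        while need > 0:
            draw = rng.multivariate_normal(mean, cov, size=max(need * 2, 8),
                                           check_valid="ignore")
            ok = (draw[:, 0] >= 0) & (draw[:, 1] >= 0) & (draw[:, 1] < 100) \
                & (draw[:, 2] > 0)
            kept = draw[ok][:need]
            rows.extend(kept)
            labels.extend([label] * len(kept))
            need -= len(kept)
            attempts += 1
            if attempts > 100:
                raise ValueError("infeasible clamping: cannot draw valid samples")
    features = np.asarray(rows)
    labels = np.asarray(labels, dtype=object)
    ids = np.array([f"p{i:03d}" for i in range(len(labels))])
    return RhythmDataset(features=features, labels=labels, patient_ids=ids,
                         feature_names=FEATURE_NAMES)
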