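"""Two-class Dice loss, phase-stratified fold design, and the training loop.

The loss is implemented verbatim from the printed two-class form:

    L = 1 - (sum(p*r) + eps) / (sum(p + r) + eps)
          - (sum((1-p)*(1-r)) + eps) / (sum(2 - p - r) + eps)

It lacks the factor 2 of a conventional per-class soft Dice, so perfect
overlap gives ~0 and the degenerate both-empty case ~-0.5; a
conventional variant is available behind ``strict=False``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .augment import AffineAugmentConfig, augment_pair, epoch_rng
from .resunet import ResUNet3D

__all__ = [
    "TrainConfig",
    "FoldSpec",
    "TrainLog",
    "CANONICAL_PHASES",
    "dice_loss",
    "build_phase_folds",
    "split_patients",
    "train_fold",
]

CANONICAL_PHASES = tuple(range(0, 100, 10))


@dataclass
class TrainConfig:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs_max: int = 500
    patience: int = 20
    epsilon_dice: float = 1e-5
    augmentation_factor: int = 4
    seed: int = 0
    batch_size: int = 1
    shuffle: bool = True

    def __post_init__(self):
        if self.patience >= self.epochs_max:
            raise ValueError("patience must be < epochs_max")
        if self.epsilon_dice <= 0:
            raise ValueError("epsilon_dice must be > 0")


@dataclass
class FoldSpec:
    fold_index: int
    train_phases: frozenset
    val_phases: frozenset
    test_phases: frozenset
    train_patients: tuple = ()
    val_patients: tuple = ()
    test_patients: tuple = ()
    test_phase_assignment: dict = field(default_factory=dict)


@dataclass
class TrainLog:
    t_loss: list[float] = field(default_factory=list)   # per-epoch training loss
    v_score: list[float] = field(default_factory=list)  # per-epoch validation Dice
    v_loss: list[float] = field(default_factory=list)   # per-epoch validation loss
    best_epoch: int = 0                                  # 1-based
    stop_epoch: int = 0

    def to_csv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "t_loss", "v_loss", "v_score"])
            for i, (t, vl, vs) in enumerate(
                    zip(self.t_loss, self.v_loss, self.v_score), start=1):
                w.writerow([i, t, vl, vs])


def dice_loss(p, r, eps: float = 1e-5, strict: bool = True):
    """Two-class soft Dice loss.

    Accepts NumPy arrays or autograd Tensors (the expression only uses
    elementwise arithmetic and sums, so either works). ``strict`` keeps the
    printed form without the factor 2.
    """
    p_shape = p.shape
    r_shape = r.shape
    if p_shape != r_shape:
        raise ValueError(f"shape mismatch: {p_shape} vs {r_shape}")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if strict:
        fg = ((p * r).sum() + eps) / ((p + r).sum() + eps)
        bg = (((1.0 - p) * (1.0 - r)).sum() + eps) / ((2.0 - p - r).sum() + eps)
        return 1.0 - fg - bg
    # conventional per-class soft Dice (factor 2, both-empty -> 0)
    fg = (2.0 * (p * r).sum() + eps) / ((p + r).sum() + eps)
    bg = (2.0 * ((1.0 - p) * (1.0 - r)).sum() + eps) / ((2.0 - p - r).sum() + eps)
    return 1.0 - 0.5 * fg - 0.5 * bg


def build_phase_folds(phases=CANONICAL_PHASES, n_folds: int = 5) -> list[FoldSpec]:
    """Fold k tests {10(k-1), 10(k-1)+50}; validates on fold k-1's test phases."""
    if sorted(phases) != list(CANONICAL_PHASES):
        raise ValueError(f"expected the canonical phases {CANONICAL_PHASES}")
    if n_folds != 5:
        raise ValueError("the phase design is defined for 5 folds")
    folds = []
    all_phases = set(CANONICAL_PHASES)
    for k in range(1, n_folds + 1):
        test = {(k - 1) * 10, (k - 1) * 10 + 50}
        prev = {(k - 2) % n_folds * 10, (k - 2) % n_folds * 10 + 50}
        train = all_phases - test - prev
        folds.append(FoldSpec(fold_index=k,
                              train_phases=frozenset(train),
                              val_phases=frozenset(prev),
                              test_phases=frozenset(test)))
    return folds


def split_patients(patient_ids, fold: FoldSpec, seed: int = 0,
                   sizes: tuple[int, int, int] = (36, 12, 12)) -> FoldSpec:
    """Patient-level random split into train/val/test, six patients per test phase."""
    ids = list(patient_ids)
    n_train, n_val, n_test = sizes
    if len(ids) != sum(sizes):
        raise ValueError(
            f"expected {sum(sizes)} patient ids (got {len(ids)}); "
            "pass `sizes` for a different cohort")
    rng = np.random.default_rng(np.random.SeedSequence((seed, fold.fold_index)))
    perm = [ids[i] for i in rng.permutation(len(ids))]
    train = tuple(perm[:n_train])
    val = tuple(perm[n_train:n_train + n_val])
    test = tuple(perm[n_train + n_val:])
    phases = sorted(fold.test_phases)
    half = n_test // 2
    assignment = {pid: phases[0] for pid in test[:half]}
    assignment.update({pid: phases[1] for pid in test[half:]})
    return FoldSpec(fold_index=fold.fold_index,
                    train_phases=fold.train_phases,
                    val_phases=fold.val_phases,
                    test_phases=fold.test_phases,
                    train_patients=train, val_patients=val, test_patients=test,
                    test_phase_assignment=assignment)


def _epoch_pass(network: ResUNet3D, samples, cfg: TrainConfig, optimizer,
                epoch: int, rng: np.random.Generator):
    """One optimization epoch; returns the mean training loss."""
    order = rng.permutation(len(samples)) if cfg.shuffle else np.arange(len(samples))
    losses = []
    for idx in order:
        vol, mask = samples[idx]
        pairs = [(vol, mask)]
        if cfg.augmentation_factor > 0:
            aug_cfg = AffineAugmentConfig(factor=cfg.augmentation_factor,
                                          seed=cfg.seed)
            pairs += augment_pair(vol, mask, aug_cfg,
                                  rng=epoch_rng(cfg.seed, epoch, int(idx)))
        for v, m in pairs:
            x = nn.Tensor(np.asarray(v.voxels, dtype=np.float64)[None])
            p = network.forward(x)
            loss = dice_loss(p, np.asarray(m.voxels, dtype=np.float64)[None],
                             eps=cfg.epsilon_dice)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
    return float(np.mean(losses))


def _validate(network: ResUNet3D, samples, eps: float):
    """Mean validation loss (Eq.-style) and mean binarized Dice score."""
    from .seg_eval import seg_metrics
    from .imaging_io import BinaryMask
    v_losses, dices = [], []
    for vol, mask in samples:
        prob = network.predict(np.asarray(vol.voxels, dtype=np.float64))
        ref = np.asarray(mask.voxels, dtype=np.float64)
        v_losses.append(float(dice_loss(prob, ref, eps=eps)))
        pred = BinaryMask(voxels=prob > 0.5, spacing=mask.spacing)
        if pred.voxels.any() or mask.voxels.any():
            dices.append(seg_metrics(pred, mask).ds)
        else:
            dices.append(1.0)
    return float(np.mean(v_losses)), float(np.mean(dices))


def train_fold(network: ResUNet3D, train_samples, val_samples,
               cfg: TrainConfig | None = None,
               checkpoint_dir=None,
               stop_when=None) -> tuple[ResUNet3D, TrainLog]:
    """Adam + early stopping on validation loss; returns best-epoch weights.

    ``train_samples`` / ``val_samples`` are sequences of
    (ImageVolume, BinaryMask) pairs (normalized intensities).
    ``stop_when(log)``, if given, is checked after each epoch and ends
    training early when it returns True (e.g. a target-loss budget guard).
    """
    cfg = cfg or TrainConfig()
    if not train_samples:
        raise ValueError("empty training set")
    optimizer = nn.Adam(network.parameters(), lr=cfg.lr,
                        beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(cfg.seed)
    log = TrainLog()
    best_state, best_vloss, since_best = None, np.inf, 0
    for epoch in range(1, cfg.epochs_max + 1):
        t_loss = _epoch_pass(network, train_samples, cfg, optimizer, epoch, rng)
        v_loss, v_score = _validate(network, val_samples or train_samples,
                                    cfg.epsilon_dice)
        log.t_loss.append(t_loss)
        log.v_loss.append(v_loss)
        log.v_score.append(v_score)
        if checkpoint_dir is not None:
            from .resunet import save_checkpoint
            save_checkpoint(network, Path(checkpoint_dir) / f"epoch_{epoch:04d}.npz")
        if v_loss < best_vloss:
            best_vloss = v_loss
            best_state = network.state_dict()
            log.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        log.stop_epoch = epoch
        if since_best >= cfg.patience:
            break
        if stop_when is not None and stop_when(log):
            break
    if best_state is not None:
        network.load_state_dict(best_state)
    return network, log
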