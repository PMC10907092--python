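"""Subject-grouped cross-validation splits and the optimization protocol.

Splits are grouped at the subject level: every scan of a participant lands
in the same partition, and across the k folds each subject serves in the
test partition exactly once. This is the leakage guard repeat-scan
cohorts require — splitting scans instead of subjects lets a network
memorize a participant seen at another visit.

Optimization: Adam (beta1=0.9, beta2=0.999) on per-voxel mean squared
error, mini-batches of 2 scans, initial learning rate 1e-4, 150 epochs in
the full-size protocol. The learning rate halves when the validation error
has not improved for 7 epochs, with at least 10 epochs between successive
decays; a pure fixed schedule (halve every 10 epochs regardless of the
validation curve) is available as ``schedule="fixed"``. The best-validation
parameter set is retained and restored at the end of training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .net import DenseUNet
from .phantom import Cohort, ScanPair
from .prep import CropPadSpec, crop_pad, normalize_suvr
from .volio import ROIAtlas

__all__ = ["FoldSplit", "TrainConfig", "TrainResult", "make_folds", "fit", "prepare_arrays"]

PARTITIONS = ("train", "val", "test")


@dataclass
class FoldSplit:
    """Per-fold subject -> partition assignment for grouped k-fold CV."""

    k: int
    fractions: tuple[float, float, float]
    assignment: list[dict[str, str]]  # one {subject_id: partition} map per fold

    def subjects_in(self, fold: int, partition: str) -> list[str]:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return sorted(s for s, p in self.assignment[fold].items() if p == partition)

    def scans_in(self, cohort: Cohort, fold: int, partition: str) -> list[ScanPair]:
        wanted = set(self.subjects_in(fold, partition))
        return [sc for sc in cohort.scans if sc.subject_id in wanted]

    def check_no_leakage(self) -> None:
        """Raise if any subject appears in two partitions of one fold."""
        for fold, amap in enumerate(self.assignment):
            parts: dict[str, set[str]] = {p: set() for p in PARTITIONS}
            for s, p in amap.items():
                parts[p].add(s)
            for a in PARTITIONS:
                for b in PARTITIONS:
                    if a < b and parts[a] & parts[b]:
                        raise AssertionError(
                            f"fold {fold}: subjects {parts[a] & parts[b]} in both {a} and {b}"
                        )


def make_folds(
    cohort: Cohort,
    k: int = 5,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> FoldSplit:
    """Grouped k-fold split with train/val/test fractions.

    Subjects are shuffled once and partitioned into k groups; fold ``i``
    uses group ``i`` as test, the next group (cyclically) as validation and
    the remainder as training, so the union of test sets over folds covers
    every subject exactly once.
    """
    subjects = cohort.subject_ids
    if len(subjects) < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for {k} folds, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    groups = [list(g) for g in np.array_split(np.array(order, dtype=object), k)]
    n_val_groups = max(1, round(fractions[1] * k))
    assignment = []
    for fold in range(k):
        amap: dict[str, str] = {}
        val_ids = {(fold + 1 + j) % k for j in range(n_val_groups)}
        for gi, grp in enumerate(groups):
            part = "test" if gi == fold else ("val" if gi in val_ids else "train")
            for s in grp:
                amap[str(s)] = part
        assignment.append(amap)
    split = FoldSplit(k=k, fractions=fractions, assignment=assignment)
    split.check_no_leakage()
    return split


@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the full-size recipe."""

    lr0: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 150
    batch_size: int = 2
    lr_decay_factor: float = 2.0
    decay_every_epochs: int = 10
    plateau_patience_epochs: int = 7
    loss: str = "mse"
    seed: int = 0
    schedule: str = "plateau"  # "plateau" (patience-gated) or "fixed" (pure 10-epoch)

    def __post_init__(self) -> None:
        if min(self.lr0, self.epochs, self.batch_size, self.decay_every_epochs) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must exceed 1")
        if self.loss != "mse":
            raise ValueError("only the mean-squared-error loss is supported")
        if self.schedule not in ("plateau", "fixed"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


def lr_at_epoch_fixed(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate of 1-based ``epoch`` under the pure fixed schedule."""
    return cfg.lr0 / cfg.lr_decay_factor ** ((epoch - 1) // cfg.decay_every_epochs)


@dataclass
class TrainResult:
    model: DenseUNet
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_loss: float = float("inf")


def prepare_arrays(
    scans: list[ScanPair],
    atlas: ROIAtlas,
    croppad: CropPadSpec | None = None,
    normalize: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """SUVR-normalize source/target pairs and move them to network space.

    Returns float32 ``(x, y)`` arrays of shape (1, S, S, S) per scan. Pass
    ``croppad=None`` for volumes already on a network-compatible grid.
    """
    out = []
    for sc in scans:
        src, tgt = sc.source, sc.target
        if normalize:
            src = normalize_suvr(src, atlas)
            tgt = normalize_suvr(tgt, atlas)
        if croppad is not None:
            src = crop_pad(src, croppad)
            tgt = crop_pad(tgt, croppad)
        out.append(
            (
                src.values[None].astype(np.float32),
                tgt.values[None].astype(np.float32),
            )
        )
    return out


def _mean_val_loss(model: DenseUNet, pairs) -> float:
    losses = []
    for x, y in pairs:
        pred = model.forward(x).data
        losses.append(float(np.mean((pred.astype(np.float64) - y) ** 2)))
    return float(np.mean(losses))


def fit(
    model: DenseUNet,
    cohort: Cohort,
    split: FoldSplit,
    fold: int,
    cfg: TrainConfig,
    atlas: ROIAtlas,
    croppad: CropPadSpec | None = None,
) -> TrainResult:
    """Train one fold; returns the model with best-validation weights restored.

    Only train-partition scans update the weights; model selection uses the
    validation partition exclusively. Per-epoch train/val MSE (per-voxel)
    and the learning-rate trajectory are recorded.
    """
    train_scans = split.scans_in(cohort, fold, "train")
    val_scans = split.scans_in(cohort, fold, "val")
    if not train_scans or not val_scans:
        raise ValueError(
            f"fold {fold}: empty partition (train={len(train_scans)}, val={len(val_scans)})"
        )
    train_pairs = prepare_arrays(train_scans, atlas, croppad)
    val_pairs = prepare_arrays(val_scans, atlas, croppad)

    opt = Adam(model.params, lr=cfg.lr0, beta1=cfg.beta1, beta2=cfg.beta2)
    result = TrainResult(model=model)
    rng = np.random.default_rng(cfg.seed)
    best_params = {k: v.copy() for k, v in model.params.items()}
    epochs_since_improve = 0
    epochs_since_decay = 0
    lr = cfg.lr0

    for epoch in range(1, cfg.epochs + 1):
        if cfg.schedule == "fixed":
            lr = lr_at_epoch_fixed(cfg, epoch)
        opt.lr = lr
        order = rng.permutation(len(train_pairs))
        batch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            acc: dict[str, np.ndarray] | None = None
            for i in idx:
                x, y = train_pairs[i]
                loss, grads = model.loss_and_grads(x, y)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} (lr={lr:g}); aborting"
                    )
                batch_losses.append(loss)
                if acc is None:
                    acc = grads
                else:
                    for k in acc:
                        acc[k] += grads[k]
            assert acc is not None
            for k in acc:
                acc[k] /= len(idx)
            opt.step(acc)

        val = _mean_val_loss(model, val_pairs)
        result.train_loss.append(float(np.mean(batch_losses)))
        result.val_loss.append(val)
        result.lr_history.append(lr)

        if val < result.best_val_loss:
            result.best_val_loss = val
            result.best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
        epochs_since_decay += 1
        if (
            cfg.schedule == "plateau"
            and epochs_since_improve >= cfg.plateau_patience_epochs
            and epochs_since_decay >= cfg.decay_every_epochs
        ):
            lr /= cfg.lr_decay_factor
            epochs_since_decay = 0
            epochs_since_improve = 0

    model.params.update(best_params)
    return result
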