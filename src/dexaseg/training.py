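"""Training loop, learning-rate schedule and subject-level five-fold CV.

Protocol: Adam (framework defaults beyond the learning rate), initial
learning rate 1e-3 multiplied by 0.98 every five epochs, mini-batches of
16 with the training set reshuffled each epoch (last partial batch
kept), Generalized Dice loss on softmax probabilities, 500 epochs by
default. After every epoch the mean validation Dice (ulna and radius
Dice averaged over images) is recorded and the checkpoint with the
highest validation Dice is kept — ties resolve to the earliest epoch.

Cross-validation splits subjects (never individual images, so the
low/high pair of a subject always shares a partition) into five
near-equal folds; rotation r tests on fold r, validates on fold
(r+1) mod 5 and trains on the remaining three folds — the 3/1/1 split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import augment as aug
from .dataio import one_hot
from .loss import gdl_value_and_grad
from .metrics import dice_class
from .network import SegNet
from .nn import Adam


@dataclass
class FoldSplit:
    """Subject-level partition for one CV rotation."""

    rotation: int
    train_subjects: list[str]
    val_subjects: list[str]
    test_subjects: list[str]

    def __post_init__(self):
        parts = [set(self.train_subjects), set(self.val_subjects), set(self.test_subjects)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("fold partitions overlap")


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 16
    lr0: float = 0.001
    lr_decay: float = 0.98
    decay_every: int = 5
    seed: int = 0
    augment: bool = True
    loss_eps: float = 1e-8

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr0 <= 0 or not (0 < self.lr_decay <= 1):
            raise ValueError("lr0 must be > 0 and 0 < lr_decay <= 1")


def make_folds(subjects: list[str], k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Shuffle subjects by seed and cut into k near-equal folds.

    Returns one FoldSplit per rotation; every subject appears in the
    test partition exactly once across rotations.
    """
    subjects = list(subjects)
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    folds = [list(f) for f in np.array_split(shuffled, k)]
    splits = []
    for r in range(k):
        test = folds[r]
        val = folds[(r + 1) % k]
        train = [s for i in range(k) if i not in (r, (r + 1) % k) for s in folds[i]]
        splits.append(FoldSplit(r, train, val, test))
    return splits


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step-decay schedule: lr0 * decay^floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.decay_every)


def _mean_val_dice(model: SegNet, images: np.ndarray, labels: np.ndarray,
                   batch: int = 16) -> float:
    """Mean over images of the per-image average ulna/radius Dice."""
    scores = []
    for i in range(0, len(images), batch):
        probs = model.forward(images[i : i + batch][:, None], train=False)
        preds = probs.argmax(axis=1)
        for p, t in zip(preds, labels[i : i + batch]):
            scores.append(0.5 * (dice_class(p, t, 1) + dice_class(p, t, 2)))
    return float(np.mean(scores))


def train(model: SegNet, train_images: np.ndarray, train_labels: np.ndarray,
          val_images: np.ndarray | None = None, val_labels: np.ndarray | None = None,
          cfg: TrainConfig | None = None):
    """Train a segmentation network; returns (model, history DataFrame).

    ``train_images`` is (N, H, W) in [0, 1]; ``train_labels`` is
    (N, H, W) with values in {0, 1, 2}. The model is left holding the
    best-validation-Dice parameters (final parameters when no validation
    set is given). History has one row per epoch: epoch, lr, loss,
    val_dice.
    """
    cfg = cfg or TrainConfig()
    n = len(train_images)
    if n == 0:
        raise ValueError("empty training set")
    if train_images.shape != train_labels.shape:
        raise ValueError("train images/labels shape mismatch")

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters())
    history = []
    best = {"dice": -np.inf, "epoch": -1, "state": None}

    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if cfg.augment:
                ims, labs = [], []
                for i in idx:
                    params = aug.sample_params(rng)
                    im, lab = aug.apply_arrays(train_images[i], train_labels[i], params)
                    ims.append(im)
                    labs.append(lab)
                batch_x = np.stack(ims)[:, None].astype(np.float32)
                batch_t = np.stack([one_hot(lab) for lab in labs])
            else:
                batch_x = train_images[idx][:, None].astype(np.float32)
                batch_t = np.stack([one_hot(train_labels[i]) for i in idx])
            probs = model.forward(batch_x, train=True)
            loss, dprobs = gdl_value_and_grad(probs, batch_t, eps=cfg.loss_eps)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss}")
            optimizer.zero_grad()
            model.backward(dprobs.astype(np.float32))
            optimizer.step(lr)
            epoch_losses.append(loss)

        mean_loss = float(np.mean(epoch_losses))
        if val_images is not None and len(val_images):
            val_dice = _mean_val_dice(model, val_images, val_labels)
            if val_dice > best["dice"]:
                best = {"dice": val_dice, "epoch": epoch,
                        "state": {k: v.copy() for k, v in model.state_arrays().items()}}
        else:
            val_dice = np.nan
        history.append({"epoch": epoch, "lr": lr, "loss": mean_loss, "val_dice": val_dice})

    if best["state"] is not None:
        model.load_state_arrays(best["state"])
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best["epoch"]
    hist.attrs["best_val_dice"] = best["dice"]
    return model, hist


def select_best_epoch(history: pd.DataFrame) -> int:
    """Best-checkpoint rule, reproducible from the history alone:
    highest val_dice, ties to the earliest epoch."""
    vd = history["val_dice"].to_numpy()
    if np.all(np.isnan(vd)):
        return int(history["epoch"].iloc[-1])
    return int(history["epoch"].iloc[int(np.nanargmax(vd))])
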