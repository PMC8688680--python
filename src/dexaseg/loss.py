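"""Generalized Dice Loss over softmax probabilities.

For a C-class prediction P (probabilities) and one-hot ground truth G on
M pixels,

    Loss = 1 - 2 * sum_c w_c sum_m P_cm G_cm
               / sum_c w_c sum_m (P_cm^2 + G_cm^2),

with inverse-squared-volume class weights w_c = 1 / ((sum_m G_cm)^2 + eps).
Weighting each class by the inverse square of its ground-truth area makes
small structures (here the two bones against a dominant background) count
as much as large ones. The eps in the weight denominator is the single
regularization point: it keeps the weight of a class absent from the
ground truth finite; no eps is added to the main fraction.

Weights are computed per image; the loss of a batch is the arithmetic
mean of per-image losses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gdl_weights", "generalized_dice_loss", "gdl_value_and_grad"]


def gdl_weights(truth_onehot: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-class weights w_c = 1/((pixel count of class c)^2 + eps).

    ``truth_onehot`` has shape (C, H, W); returns shape (C,).
    """
    counts = np.asarray(truth_onehot, dtype=np.float64).sum(axis=(1, 2))
    return 1.0 / (counts**2 + eps)


def _check_probs(pred: np.ndarray) -> None:
    sums = pred.sum(axis=-3)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("pred is not a probability map: channel sums deviate from 1")
    if pred.min() < -1e-7 or pred.max() > 1 + 1e-7:
        raise ValueError("pred entries must lie in [0, 1]")


def gdl_value_and_grad(pred: np.ndarray, truth_onehot: np.ndarray, eps: float = 1e-8):
    """Loss and dLoss/dpred for (C, H, W) or batched (N, C, H, W) input.

    Batched input returns the mean of per-image losses and the matching
    gradient (each image's gradient divided by the batch size).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth_onehot, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    batched = pred.ndim == 4
    if not batched:
        pred, truth = pred[None], truth[None]
    n = pred.shape[0]
    counts = truth.sum(axis=(2, 3))  # (N, C)
    w = 1.0 / (counts**2 + eps)
    inter = (pred * truth).sum(axis=(2, 3))  # (N, C)
    sq = (pred**2 + truth**2).sum(axis=(2, 3))
    num = 2.0 * (w * inter).sum(axis=1)  # (N,)
    den = (w * sq).sum(axis=1)
    loss = 1.0 - num / den
    # d/dP_cm [1 - num/den] = (num * 2 w_c P_cm - 2 w_c G_cm * den) / den^2
    wb = w[:, :, None, None]
    grad = (num[:, None, None, None] * 2.0 * wb * pred - 2.0 * wb * truth * den[:, None, None, None]) / (
        den[:, None, None, None] ** 2
    )
    grad /= n
    if not batched:
        return float(loss[0]), grad[0]
    return float(loss.mean()), grad


def generalized_dice_loss(pred: np.ndarray, truth_onehot: np.ndarray, eps: float = 1e-8) -> float:
    """Generalized Dice Loss in [0, 1]; 0 iff pred equals the one-hot truth.

    ``pred`` must be a valid probability map (channels summing to 1);
    shapes (C, H, W) or (N, C, H, W), matching ``truth_onehot``.
    """
    _check_probs(np.asarray(pred))
    loss, _ = gdl_value_and_grad(pred, truth_onehot, eps=eps)
    return loss
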