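"""Stochastic training-time augmentation: joint affine + image gamma.

Each draw samples, independently and uniformly,

* translation tx, ty in [-60, 60] px,
* scaling sx, sy in [0.9, 1.1],
* rotation theta in [-20, 20] degrees,
* gamma exponent in [0.5, 1.5],

and applies one composed affine map — rotate about the image center,
then scale, then translate — to the image (bilinear) and the label map
(nearest-neighbor, so labels stay in {0, 1, 2}). Out-of-bounds pixels
are filled with 0: background intensity and background class. The gamma
power is applied to the image only; intensities in [0, 1] stay in [0, 1].

Augmentation is drawn fresh per sample per epoch, and the low- and
high-energy images of a subject are augmented independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import Sample

RANGES = {
    "translate_px": (-60.0, 60.0),
    "scale": (0.9, 1.1),
    "rotate_deg": (-20.0, 20.0),
    "gamma": (0.5, 1.5),
}


@dataclass
class AugmentParams:
    tx: float
    ty: float
    sx: float
    sy: float
    theta: float
    gamma: float

    def __post_init__(self):
        lo, hi = RANGES["translate_px"]
        if not (lo <= self.tx <= hi and lo <= self.ty <= hi):
            raise ValueError(f"translation out of [{lo}, {hi}]")
        lo, hi = RANGES["scale"]
        if not (lo <= self.sx <= hi and lo <= self.sy <= hi):
            raise ValueError(f"scale out of [{lo}, {hi}]")
        lo, hi = RANGES["rotate_deg"]
        if not (lo <= self.theta <= hi):
            raise ValueError(f"rotation out of [{lo}, {hi}]")
        lo, hi = RANGES["gamma"]
        if not (lo <= self.gamma <= hi):
            raise ValueError(f"gamma out of [{lo}, {hi}]")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(0.0, 0.0, 1.0, 1.0, 0.0, 1.0)


def sample_params(rng: np.random.Generator) -> AugmentParams:
    """Draw one parameter set, each field uniform over its interval."""
    t_lo, t_hi = RANGES["translate_px"]
    s_lo, s_hi = RANGES["scale"]
    r_lo, r_hi = RANGES["rotate_deg"]
    g_lo, g_hi = RANGES["gamma"]
    return AugmentParams(
        tx=rng.uniform(t_lo, t_hi),
        ty=rng.uniform(t_lo, t_hi),
        sx=rng.uniform(s_lo, s_hi),
        sy=rng.uniform(s_lo, s_hi),
        theta=rng.uniform(r_lo, r_hi),
        gamma=rng.uniform(g_lo, g_hi),
    )


def _inverse_affine(params: AugmentParams, shape):
    """Matrix and offset mapping output (row, col) to input coordinates.

    Forward map: rotate by theta about the center, scale (sy, sx), then
    translate (ty, tx). scipy's affine_transform wants the inverse.
    """
    h, w = shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    th = np.deg2rad(params.theta)
    # rotation in (row, col) coordinates
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    scale = np.diag([params.sy, params.sx])
    fwd = scale @ rot
    t = np.array([params.ty, params.tx])
    inv = np.linalg.inv(fwd)
    # x_in = inv @ (x_out - t - c) + c
    offset = c - inv @ (c + t)
    return inv, offset


def apply(sample: Sample, params: AugmentParams) -> Sample:
    """Apply the affine jointly to image and labels, then gamma to the image."""
    if sample.image.shape != sample.labels.shape:
        raise ValueError("image/label shape mismatch")
    matrix, offset = _inverse_affine(params, sample.image.shape)
    image = ndimage.affine_transform(
        sample.image.astype(np.float64), matrix, offset=offset, order=1,
        mode="constant", cval=0.0)
    labels = ndimage.affine_transform(
        sample.labels, matrix, offset=offset, order=0, mode="constant", cval=0)
    image = np.clip(image, 0.0, 1.0) ** params.gamma
    return Sample(sample.subject_id, sample.energy, image.astype(np.float32), labels)


def apply_arrays(image: np.ndarray, labels: np.ndarray, params: AugmentParams):
    """Array-level variant of :func:`apply` used by the training loop."""
    s = apply(Sample("_", "low", np.asarray(image, dtype=np.float32),
                     np.asarray(labels, dtype=np.uint8)), params)
    return s.image, s.labels
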