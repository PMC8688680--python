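"""Synthetic dual-energy forearm phantoms with ground-truth bone masks.

Each phantom subject is a portrait radiograph pair (low/high energy) of
two elongated "bones" on a soft-tissue background, built from a simple
projection model: a cylindrical thickness map t(x, y) per bone, a smooth
soft-tissue column, and Beer-Lambert attenuation

    I(x, y) = exp(-mu_soft * t_soft - mu_bone(E) * t_bone) + noise,

clipped to [0, 1]. The low-energy attenuation coefficient exceeds the
high-energy one, so bone pixels are darker in the low-energy image —
the contrast DEXA exploits. Higher attenuation always means a darker
pixel (no radiographic negative).

The radius is modeled as the thicker, tapered capsule; the ulna as a
thinner capsule carrying a half-disc bump at its distal end standing in
for the styloid process, the anatomically hardest sub-structure. Bone
supports are disjoint by construction with a guaranteed gap, the label
map (0 background, 1 ulna, 2 radius) is shared by both energies, and
every subject is a pure function of (seed, subject_index).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import Sample, write_image, write_labelmap, write_manifest, MANIFEST_COLUMNS


@dataclass
class PhantomParams:
    """Geometry, attenuation and noise settings for phantom generation.

    Defaults give a 128x96 desk-scale canvas (divisible by 16, as the
    segmentation network requires); height=768, width=576 mimics the
    study geometry. Attenuation coefficients are dimensionless products
    mu*t with thickness normalized to [0, 1].
    """

    height: int = 128
    width: int = 96
    n_subjects: int = 10
    seed: int = 0
    mu_bone_low: float = 2.5
    mu_bone_high: float = 1.4
    mu_soft: float = 0.3
    thickness_scale: float = 1.0
    noise_sigma: float = 0.01
    rotation_jitter_deg: float = 4.0
    translation_jitter_px: float = 3.0

    def __post_init__(self):
        if self.height % 16 or self.width % 16:
            raise ValueError("height and width must be divisible by 16")
        if not (self.mu_bone_low > self.mu_bone_high > self.mu_soft >= 0):
            raise ValueError("attenuation ordering mu_bone_low > mu_bone_high > mu_soft >= 0 violated")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class PhantomSubject:
    """A low/high-energy sample pair sharing one ground-truth label map."""

    low: Sample
    high: Sample
    labels: np.ndarray = field(repr=False)


def _capsule_thickness(yy, xx, cx0, slope, half_width, h):
    """Projected thickness of a slanted cylindrical capsule.

    Centerline x = cx0 + slope*(y - h/2); half-width tapers linearly
    toward the distal (top) end. Returns (thickness in [0,1], support).
    """
    cx = cx0 + slope * (yy - h / 2.0)
    taper = 0.75 + 0.25 * (yy / h)  # distal (top) end 75% as wide
    r = half_width * taper
    d = np.abs(xx - cx)
    t = np.sqrt(np.maximum(r**2 - d**2, 0.0)) / half_width
    return t, t > 0


def _styloid_bump(yy, xx, cy, cx, radius):
    """Half-disc thickness bump at the ulna's distal tip, lateral side."""
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    t = np.sqrt(np.maximum(radius**2 - d2, 0.0)) / radius
    t[yy > cy] = 0.0  # keep the bump on the distal half
    return t


def generate_subject(params: PhantomParams, subject_index: int) -> PhantomSubject:
    """Generate one phantom subject, deterministic in (seed, subject_index)."""
    h, w = params.height, params.width
    rng = np.random.default_rng([params.seed, subject_index])
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    scale = w / 96.0  # geometry expressed at the 96-px-wide reference canvas
    tx = rng.uniform(-params.translation_jitter_px, params.translation_jitter_px) * scale
    slope = np.tan(np.deg2rad(rng.uniform(-params.rotation_jitter_deg, params.rotation_jitter_deg)))

    # radius: thicker, medial (left); ulna: thinner, lateral (right)
    cx_radius = 0.33 * w + tx
    cx_ulna = 0.64 * w + tx
    hw_radius = rng.uniform(6.0, 8.0) * scale
    hw_ulna = rng.uniform(3.5, 4.5) * scale

    t_rad, sup_rad = _capsule_thickness(yy, xx, cx_radius, slope, hw_radius, h)
    t_uln, sup_uln = _capsule_thickness(yy, xx, cx_ulna, slope, hw_ulna, h)

    # styloid process: half-disc on the ulna's distal tip, away from the radius
    tip_y = 0.08 * h + rng.uniform(0.0, 0.04 * h)
    tip_cx = cx_ulna + slope * (tip_y - h / 2.0) + hw_ulna * 0.5
    r_styloid = rng.uniform(2.5, 3.5) * scale
    t_sty = _styloid_bump(yy, xx, tip_y, tip_cx, r_styloid)
    t_uln = np.maximum(t_uln, t_sty)
    sup_uln = t_uln > 0

    if (sup_rad & sup_uln).any():
        raise RuntimeError("phantom bone supports overlap; geometry parameters inconsistent")

    labels = np.zeros((h, w), dtype=np.uint8)
    labels[sup_uln] = 1
    labels[sup_rad] = 2

    # soft-tissue column spanning most of the frame, elliptical chord profile
    chord = 1.0 - ((xx - w / 2.0 - tx) / (0.46 * w)) ** 2
    t_soft = np.sqrt(np.maximum(chord, 0.0))

    t_bone = (t_rad + t_uln) * params.thickness_scale
    images = {}
    for energy, mu in (("low", params.mu_bone_low), ("high", params.mu_bone_high)):
        img = np.exp(-params.mu_soft * t_soft - mu * t_bone)
        if params.noise_sigma > 0:
            img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
        images[energy] = np.clip(img, 0.0, 1.0).astype(np.float32)

    sid = f"S{subject_index:03d}"
    return PhantomSubject(
        low=Sample(sid, "low", images["low"], labels),
        high=Sample(sid, "high", images["high"], labels),
        labels=labels,
    )


def generate_dataset(params: PhantomParams, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write a phantom dataset (images, masks, manifest CSV) to out_dir.

    Produces n_subjects*2 16-bit PNG images, n_subjects 8-bit PNG masks
    and a manifest with n_subjects*2 rows; returns the manifest frame.
    Paths in the manifest are relative to out_dir.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for idx in range(params.n_subjects):
        subj = generate_subject(params, idx)
        sid = subj.low.subject_id
        mask_path = f"{sid}_mask.png"
        write_labelmap(os.path.join(out_dir, mask_path), subj.labels)
        for sample in (subj.low, subj.high):
            img_path = f"{sid}_{sample.energy}.png"
            write_image(os.path.join(out_dir, img_path), sample.image, bits=16)
            rows.append({"subject_id": sid, "energy": sample.energy,
                         "image_path": img_path, "label_path": mask_path})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest


def generate_arrays(params: PhantomParams):
    """In-memory dataset: (images (2n, H, W), labels (2n, H, W), subject_ids, energies).

    Row order is (subject 0 low, subject 0 high, subject 1 low, ...).
    """
    images, labels, sids, energies = [], [], [], []
    for idx in range(params.n_subjects):
        subj = generate_subject(params, idx)
        for sample in (subj.low, subj.high):
            images.append(sample.image)
            labels.append(sample.labels)
            sids.append(sample.subject_id)
            energies.append(sample.energy)
    return np.stack(images), np.stack(labels), sids, energies
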