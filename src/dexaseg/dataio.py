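"""Data model and I/O for dual-energy forearm image/label datasets.

A dataset is a directory of grayscale radiographs (PNG or TIFF, 8- or
16-bit) in low/high-energy pairs, single-channel label masks with pixel
codes {0 = background, 1 = ulna, 2 = radius}, and a CSV manifest binding
subject ID, energy tag and file paths together.

Conventions
-----------
* Intensities are normalized by the dtype maximum (255 or 65535), never
  per-image min/max, so the physical contrast between the low- and
  high-energy image of a subject survives loading.
* Arrays are row-major: axis 0 is the image row (y), pixel (0, 0) is the
  top-left corner, and sizes are reported height x width. The study
  geometry is portrait: height 768, width 576.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

VALID_LABELS = frozenset({0, 1, 2})
CLASS_NAMES = {0: "background", 1: "ulna", 2: "radius"}
ENERGIES = ("low", "high")

MANIFEST_COLUMNS = ["subject_id", "energy", "image_path", "label_path"]


class InvalidLabelError(ValueError):
    """A label mask contains a pixel value outside {0, 1, 2}."""


class ManifestError(ValueError):
    """A manifest violates the dataset contract."""


@dataclass
class Sample:
    """One grayscale image with its label map, subject ID and energy tag."""

    subject_id: str
    energy: str
    image: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if self.energy not in ENERGIES:
            raise ValueError(f"energy must be one of {ENERGIES}, got {self.energy!r}")
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image shape {self.image.shape} != label shape {self.labels.shape}"
            )
        validate_labelmap(self.labels)


def validate_labelmap(labels: np.ndarray) -> np.ndarray:
    """Check that every value is in the closed codebook {0, 1, 2}."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), sorted(VALID_LABELS))
    if bad.size:
        raise InvalidLabelError(f"label map contains invalid value(s) {bad.tolist()}; allowed: 0, 1, 2")
    return labels.astype(np.uint8, copy=False)


def read_image(path: str | os.PathLike, allow_color: bool = False) -> np.ndarray:
    """Read a grayscale raster and normalize intensities into [0, 1].

    Scaling divides by the dtype maximum, so an 8-bit pixel of 255 and a
    16-bit pixel of 65535 both map to 1.0 and zero maps to 0.0.

    Parameters
    ----------
    path
        PNG or TIFF file, single channel unless ``allow_color``.
    allow_color
        If True, multi-channel input is averaged to grayscale before
        normalization; otherwise it is an error.
    """
    arr = iio.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: expected an integer raster, got {arr.dtype}")
    maxval = float(np.iinfo(arr.dtype).max)
    if arr.ndim == 3:
        if not allow_color:
            raise ValueError(f"{path}: multi-channel image; pass allow_color=True to average to grayscale")
        arr = arr.mean(axis=-1)
    return (arr.astype(np.float64) / maxval).astype(np.float32)


def write_image(path: str | os.PathLike, image: np.ndarray, bits: int = 16) -> None:
    """Write a [0, 1] intensity array as an 8- or 16-bit grayscale PNG/TIFF."""
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bits == 8:
        iio.imwrite(path, np.round(image * 255).astype(np.uint8))
    elif bits == 16:
        iio.imwrite(path, np.round(image * 65535).astype(np.uint16))
    else:
        raise ValueError("bits must be 8 or 16")


def read_labelmap(path: str | os.PathLike) -> np.ndarray:
    """Read a label mask; values must lie in {0, 1, 2}."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: label mask must be single-channel")
    return validate_labelmap(arr)


def write_labelmap(path: str | os.PathLike, labels: np.ndarray) -> None:
    """Write a label map as an 8-bit PNG with raw codes 0/1/2."""
    iio.imwrite(path, validate_labelmap(labels))


def one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Encode a label map as per-class indicator channels, shape (C, H, W).

    Channel c is 1 exactly where the label equals c, so channel sums are
    the class pixel counts and argmax over channels recovers the input.
    """
    labels = np.asarray(labels)
    if labels.size and labels.max() >= n_classes:
        raise ValueError(f"n_classes={n_classes} too small for label {labels.max()}")
    eye = np.eye(n_classes, dtype=np.float32)
    return np.moveaxis(eye[labels], -1, 0)


def load_manifest(path: str | os.PathLike, require_pairs: bool = True) -> pd.DataFrame:
    """Load and validate a dataset manifest CSV.

    Columns: subject_id, energy, image_path, label_path, optional fold.
    By default every subject must appear with exactly the two energies
    "low" and "high"; set ``require_pairs=False`` for single-energy data.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {missing}")
    bad_energy = set(df["energy"]) - set(ENERGIES)
    if bad_energy:
        raise ManifestError(f"unknown energy tag(s): {sorted(bad_energy)}")
    if require_pairs:
        for sid, grp in df.groupby("subject_id"):
            if sorted(grp["energy"]) != ["high", "low"]:
                raise ManifestError(
                    f"subject {sid!r} must have exactly one low and one high energy row, "
                    f"got {sorted(grp['energy'])}"
                )
    return df


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a manifest CSV (round-trips bit-exactly through load_manifest)."""
    manifest.to_csv(path, index=False)


def load_samples(manifest: pd.DataFrame, root: str | os.PathLike = ".") -> list[Sample]:
    """Materialize every manifest row into a Sample (paths relative to root)."""
    samples = []
    for row in manifest.itertuples(index=False):
        img = read_image(os.path.join(root, row.image_path))
        lab = read_labelmap(os.path.join(root, row.label_path))
        samples.append(Sample(str(row.subject_id), row.energy, img, lab))
    return samples
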