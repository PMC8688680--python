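"""Per-class Dice and Jaccard overlap metrics with mean +/- std tables.

Dice = 2|P_c & G_c| / (|P_c| + |G_c|) and Jaccard = |P_c & G_c| / |P_c | G_c|
are computed per image on hard (argmax) class masks for the two bone
classes (1 = ulna, 2 = radius). The two are algebraically linked by
J = D / (2 - D). When a class is absent from both prediction and ground
truth the 0/0 case is scored 1.0 — absent-class agreement is perfect
agreement; ``strict_empty=True`` drops such records instead.

Aggregation reports the sample (n-1) standard deviation and formats
"mean +/- std" to four decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_LABELS = {1: "ulna", 2: "radius"}


@dataclass
class MetricsRecord:
    subject_id: str
    energy: str
    class_name: str
    dice: float
    jaccard: float
    both_empty: bool = False


def _class_masks(pred, truth, cls):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if cls not in CLASS_LABELS:
        raise ValueError(f"cls must be 1 (ulna) or 2 (radius), got {cls}")
    return pred == cls, truth == cls


def dice_class(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    """Dice coefficient of class ``cls`` between two label maps."""
    p, g = _class_masks(pred, truth, cls)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def jaccard_class(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    """Jaccard index of class ``cls`` between two label maps."""
    p, g = _class_masks(pred, truth, cls)
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def evaluate_pair(pred: np.ndarray, truth: np.ndarray, subject_id: str = "",
                  energy: str = "low") -> list[MetricsRecord]:
    """Dice/Jaccard records for both bone classes of one prediction."""
    records = []
    for cls, name in CLASS_LABELS.items():
        empty = not ((np.asarray(pred) == cls).any() or (np.asarray(truth) == cls).any())
        records.append(
            MetricsRecord(subject_id, energy, name, dice_class(pred, truth, cls),
                          jaccard_class(pred, truth, cls), both_empty=empty)
        )
    return records


def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    """Long-form table: subject_id, energy, class, dice, jaccard."""
    return pd.DataFrame(
        [(r.subject_id, r.energy, r.class_name, r.dice, r.jaccard, r.both_empty)
         for r in records],
        columns=["subject_id", "energy", "class", "dice", "jaccard", "both_empty"],
    )


def aggregate(records, strict_empty: bool = False) -> pd.DataFrame:
    """Mean +/- sample std per (class, metric).

    Accepts a list of MetricsRecord or a long-form DataFrame. Returns one
    row per (class, metric) with columns mean, std and a formatted
    "m +/- s" string to 4 decimals. ``strict_empty`` drops records whose
    class was absent from both prediction and ground truth instead of
    scoring them 1.0.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if strict_empty and "both_empty" in df.columns:
        df = df[~df["both_empty"].astype(bool)]
    if df.empty:
        raise ValueError("cannot aggregate an empty metrics table")
    rows = []
    for cls_name, grp in df.groupby("class", sort=True):
        for metric in ("dice", "jaccard"):
            vals = grp[metric].to_numpy(dtype=float)
            mean = float(vals.mean())
            std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append({"class": cls_name, "metric": metric, "mean": mean, "std": std,
                         "formatted": f"{mean:.4f} ± {std:.4f}"})
    return pd.DataFrame(rows)
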