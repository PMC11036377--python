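"""Quantitative evaluation: dice, surface distance, volume correlation,
age-binned summaries, outlier flagging and between-model consistency.

Dice is reported as a similarity in [0, 1] (tables multiply by 100 at
report time only). The average surface distance is symmetric: the mean,
pooled over the boundary voxels of both masks, of the Euclidean distance to
the other mask's boundary, in mm (boundaries are 6-connectivity surfaces).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import LabelMap

AGE_BIN_EDGES: tuple[float, ...] = (26.0, 32.0, 36.0, 40.0, 45.0)


@dataclass
class EvalRecord:
    """One per-subject, per-structure measurement for one model."""

    subject_id: str
    model_id: str
    structure: str
    dice: float
    asd_mm: float | None = None
    volume_mm3: float | None = None
    age_weeks: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError("dice must lie in [0, 1]")
        if self.asd_mm is not None and self.asd_mm < 0:
            raise ValueError("asd must be >= 0")
        if self.volume_mm3 is not None and self.volume_mm3 < 0:
            raise ValueError("volume must be >= 0")


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def dice_score(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """2|X∩Y| / (|X| + |Y|); both-empty -> 1, one-empty -> 0."""
    pred_mask = np.asarray(pred_mask, bool)
    gt_mask = np.asarray(gt_mask, bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"mask grids differ: {pred_mask.shape} vs "
                         f"{gt_mask.shape}")
    total = int(pred_mask.sum()) + int(gt_mask.sum())
    if total == 0:
        return 1.0
    inter = int((pred_mask & gt_mask).sum())
    return 2.0 * inter / total


def consistency_dice(pred_model1: np.ndarray | LabelMap,
                     pred_model2: np.ndarray | LabelMap,
                     structure: int | str) -> float:
    """Dice between the predictions of two models (no ground truth):
    measures how consistent the two trainings are."""
    def mask(pred):
        if isinstance(pred, LabelMap):
            return pred.mask(structure)
        return np.asarray(pred, bool)
    return dice_score(mask(pred_model1), mask(pred_model2))


def merge_for_eval(label_map: LabelMap) -> LabelMap:
    """Collapse ventricles into CSF (evaluation-only merge); idempotent.

    The merged class keeps the CSF id under the name ``csf+ventricles``.
    """
    try:
        csf = label_map.id_of("csf")
    except KeyError:
        csf = label_map.id_of("csf+ventricles")
    voxels = label_map.voxels.copy()
    palette = dict(label_map.palette)
    try:
        vent = label_map.id_of("ventricles")
    except KeyError:
        vent = None
    if vent is not None:
        voxels[voxels == vent] = csf
        del palette[vent]
    palette[csf] = "csf+ventricles"
    return label_map.with_voxels(voxels, palette)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """6-connectivity surface voxels of a binary mask."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure,
                                    border_value=0)
    return mask & ~eroded


def average_surface_distance(pred_mask: np.ndarray, gt_mask: np.ndarray,
                             voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Symmetric average surface distance in mm.

    Mean, pooled over the boundary voxels of both masks, of the Euclidean
    distance to the nearest boundary voxel of the other mask. Undefined for
    empty masks (raises; callers report it as missing).
    """
    pred_mask = np.asarray(pred_mask, bool)
    gt_mask = np.asarray(gt_mask, bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask grids differ")
    if not pred_mask.any() or not gt_mask.any():
        raise ValueError("average surface distance is undefined for an "
                         "empty mask")
    b_pred = _boundary(pred_mask)
    b_gt = _boundary(gt_mask)
    d_to_gt = ndimage.distance_transform_edt(~b_gt, sampling=voxel_size)
    d_to_pred = ndimage.distance_transform_edt(~b_pred, sampling=voxel_size)
    dists = np.concatenate([d_to_gt[b_pred], d_to_pred[b_gt]])
    return float(dists.mean())


def volume_correlation(volumes_a, volumes_b) -> tuple[float, float]:
    """Pearson r and least-squares slope of b on a across paired subjects.

    Used to compare per-tissue volumes predicted from two contrasts of the
    same subjects; an ideal contrast-independent model gives r close to 1.
    """
    a = np.asarray(volumes_a, float)
    b = np.asarray(volumes_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1D volume vectors required")
    if len(a) < 3:
        raise ValueError("volume correlation needs >= 3 paired subjects")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("volume correlation undefined for zero variance")
    r = float(stats.pearsonr(a, b).statistic)
    slope = float(np.polyfit(a, b, 1)[0])
    return r, slope


def age_binned_summary(records, bin_edges=AGE_BIN_EDGES) -> pd.DataFrame:
    """Distribution of the structure-averaged dice in age bins.

    Bins are closed on the left; the last bin is closed on both ends (an
    age equal to an inner edge goes to the upper bin). Ages outside the
    range are excluded with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    edges = list(bin_edges)
    per_subject = (df.groupby(["subject_id", "model_id"])
                   .agg(dice=("dice", "mean"), age=("age_weeks", "first"))
                   .reset_index())
    out_of_range = per_subject[(per_subject.age < edges[0])
                               | (per_subject.age > edges[-1])]
    if len(out_of_range):
        warnings.warn(f"excluding {len(out_of_range)} subjects with age "
                      f"outside [{edges[0]}, {edges[-1]}]", RuntimeWarning,
                      stacklevel=2)
        per_subject = per_subject.drop(out_of_range.index)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        sel = per_subject[(per_subject.age >= lo)
                          & ((per_subject.age <= hi) if last
                             else (per_subject.age < hi))]
        rows.append({
            "bin": f"[{lo:g}, {hi:g}{']' if last else ')'}",
            "age_lo": lo, "age_hi": hi, "n": len(sel),
            "mean_dice": sel.dice.mean() if len(sel) else np.nan,
            "q25": sel.dice.quantile(0.25) if len(sel) else np.nan,
            "median": sel.dice.median() if len(sel) else np.nan,
            "q75": sel.dice.quantile(0.75) if len(sel) else np.nan,
        })
    return pd.DataFrame(rows)


def flag_outliers(records, k: float = 3.0) -> list[str]:
    """Subjects whose structure-averaged dice deviates from the cohort mean
    by more than ``k`` standard deviations."""
    df = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    per_subject = df.groupby("subject_id").dice.mean()
    if len(per_subject) < 5:
        raise ValueError("outlier flagging needs >= 5 records")
    mu = per_subject.mean()
    sd = per_subject.std(ddof=0)
    if sd == 0 or not np.isfinite(k):
        return []
    return sorted(per_subject[(per_subject - mu).abs() > k * sd].index)
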