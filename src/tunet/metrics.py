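"""Segmentation evaluation: Dice, precision, recall, and surface distances.

Overlap metrics are computed on binarized masks from the standard confusion
counts.  Surface metrics operate on boundary point sets: a boundary pixel is
a foreground pixel with at least one 4-connected background neighbour (the
image border counts as background), taken at pixel centres and scaled by the
pixel spacing to millimetres.  The Hausdorff distance (HD) is the exact
maximum of the two directed max–min Euclidean distances; the average
symmetric surface distance (ASD) sums every point's nearest-surface distance
in both directions and divides by the total boundary point count.

Degenerate masks are flagged rather than silently propagated: if both masks
are empty the pair counts as perfect agreement (Dice 1) with distances
undefined; if exactly one is empty the Dice is 0 and distances are likewise
undefined, to be tallied separately by the aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "MetricRecord", "binarize", "confusion_counts", "precision_recall",
    "extract_surface", "hausdorff", "asd", "evaluate_pair",
    "aggregate_records", "records_to_frame",
]


@dataclass
class MetricRecord:
    """Per-image evaluation result (distances in mm; NaN when undefined)."""

    dice: float
    precision: float
    recall: float
    hd: float
    asd: float
    degenerate_flag: str = "none"  # none | both_empty | one_empty
    image_id: str = ""


def binarize(probs, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to a {0,1} mask (strictly greater-than)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} not in (0, 1)")
    return (np.asarray(probs) > threshold).astype(np.uint8)


def confusion_counts(pred, gt) -> tuple:
    """(TP, FP, FN, TN) pixel counts."""
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return tp, fp, fn, tn


def precision_recall(counts) -> tuple:
    """precision = TP/(TP+FP), recall = TP/(TP+FN); 0/0 -> 0."""
    tp, fp, fn = counts[0], counts[1], counts[2]
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def extract_surface(mask, spacing: float = 1.0) -> np.ndarray:
    """Boundary points of a binary mask, in mm.

    Returns an (n, 2) array of (row, col) coordinates scaled by ``spacing``.
    A foreground pixel is on the surface if any of its 4-neighbours is
    background; pixels on the image border always qualify.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1] &
                padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = m & ~interior
    pts = np.argwhere(boundary).astype(np.float64)
    return pts * float(spacing)


def _directed_nn(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point of ``a`` to its nearest neighbour in ``b``."""
    return cKDTree(b).query(a)[0]


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Exact symmetric Hausdorff distance between two point sets (mm)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("hausdorff undefined for empty point sets")
    return float(max(_directed_nn(a, b).max(), _directed_nn(b, a).max()))


def asd(a: np.ndarray, b: np.ndarray) -> float:
    """Average symmetric surface distance between two point sets (mm)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("asd undefined for empty point sets")
    total = _directed_nn(a, b).sum() + _directed_nn(b, a).sum()
    return float(total / (len(a) + len(b)))


def evaluate_pair(probs, gt, spacing: float = 1.0, threshold: float = 0.5,
                  image_id: str = "") -> MetricRecord:
    """Full per-image record for a probability map against a binary mask."""
    pred = binarize(probs, threshold)
    g = np.asarray(gt)
    if pred.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {g.shape}")
    tp, fp, fn, tn = confusion_counts(pred, g)
    pred_empty = tp + fp == 0
    gt_empty = tp + fn == 0
    if pred_empty and gt_empty:
        return MetricRecord(1.0, 1.0, 1.0, np.nan, np.nan, "both_empty", image_id)
    if pred_empty or gt_empty:
        prec, rec = precision_recall((tp, fp, fn, tn))
        return MetricRecord(0.0, prec, rec, np.nan, np.nan, "one_empty", image_id)
    dice = 2 * tp / (2 * tp + fp + fn)
    prec, rec = precision_recall((tp, fp, fn, tn))
    sa = extract_surface(pred, spacing)
    sb = extract_surface(g, spacing)
    return MetricRecord(dice, prec, rec, hausdorff(sa, sb), asd(sa, sb),
                        "none", image_id)


def records_to_frame(records) -> pd.DataFrame:
    """Per-image records as a tidy DataFrame."""
    return pd.DataFrame([{
        "image_id": r.image_id, "dice": r.dice, "precision": r.precision,
        "recall": r.recall, "hd": r.hd, "asd": r.asd,
        "degenerate_flag": r.degenerate_flag,
    } for r in records])


def aggregate_records(records) -> pd.DataFrame:
    """Mean ± std summary over records.

    Overlap metrics average over all images; distance metrics average over
    non-degenerate records only, with the exclusion counts reported.
    """
    df = records_to_frame(records)
    rows = []
    for metric in ("dice", "precision", "recall"):
        vals = df[metric].to_numpy(dtype=float)
        rows.append({"metric": metric, "mean": vals.mean() if len(vals) else np.nan,
                     "std": vals.std() if len(vals) else np.nan,
                     "n": len(vals), "n_excluded": 0})
    for metric in ("hd", "asd"):
        vals = df[metric].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        rows.append({"metric": metric,
                     "mean": vals[ok].mean() if ok.any() else np.nan,
                     "std": vals[ok].std() if ok.any() else np.nan,
                     "n": int(ok.sum()), "n_excluded": int((~ok).sum())})
    return pd.DataFrame(rows)
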