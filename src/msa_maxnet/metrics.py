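"""Segmentation evaluation: Dice, IoU and the 95th-percentile Hausdorff
distance, reported per foreground class and macro-averaged.

Overlap metrics operate on binary class masks:

    DSC = 2|X n Y| / (|X| + |Y|),    IoU = |X n Y| / |X u Y|

with both defined as 1 when both masks are empty (a class absent from
both prediction and truth is a perfect agreement).

HD95 is a surface distance: boundaries are the mask pixels with at least
one 4-neighbour outside the mask; distances from every boundary pixel of
one mask to the nearest boundary pixel of the other are pooled over both
directions and the 95th percentile (linear interpolation) is taken,
which discards the largest 5% of surface errors. Distances are computed
with a Euclidean distance transform. When either mask is empty the
distance is undefined; the sentinel is NaN by default, or the grid
diagonal if preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt

__all__ = ["dsc", "iou", "hd95", "boundary", "evaluate", "MetricReport"]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _check_pair(x, y):
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    return x, y


def dsc(x, y) -> float:
    """Dice similarity coefficient of two binary masks."""
    x, y = _check_pair(x, y)
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(x, y).sum() / denom)


def iou(x, y) -> float:
    """Jaccard overlap of two binary masks."""
    x, y = _check_pair(x, y)
    union = np.logical_or(x, y).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(x, y).sum() / union)


def boundary(mask) -> np.ndarray:
    """Mask pixels with at least one 4-neighbour outside the mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return mask
    interior = binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~interior


def hd95(x, y, spacing: float = 1.0, empty: str = "nan") -> float:
    """95th percentile of pooled boundary-to-boundary distances (both directions).

    ``empty`` selects the sentinel when either mask has no pixels:
    ``"nan"`` (undefined) or ``"diagonal"`` (the grid diagonal).
    """
    x, y = _check_pair(x, y)
    if not x.any() or not y.any():
        if empty == "diagonal":
            return float(spacing * np.hypot(*x.shape))
        return float("nan")
    bx, by = boundary(x), boundary(y)
    # distance from every pixel to the nearest boundary pixel of the other mask
    dist_to_by = distance_transform_edt(~by)
    dist_to_bx = distance_transform_edt(~bx)
    pooled = np.concatenate([dist_to_by[bx], dist_to_bx[by]]) * spacing
    return float(np.percentile(pooled, 95, method="linear"))


@dataclass
class MetricReport:
    """Per-foreground-class and macro-averaged DSC / IoU / HD95."""

    per_class: dict[int, dict[str, float]]
    macro: dict[str, float]

    @classmethod
    def compute(cls, pred, truth, n_classes: int, spacing: float = 1.0,
                empty: str = "nan") -> "MetricReport":
        return evaluate(pred, truth, n_classes, spacing=spacing, empty=empty)

    def as_rows(self):
        """(class, dsc, iou, hd95) rows, macro last with class 'macro'."""
        rows = [(str(c), m["dsc"], m["iou"], m["hd95"])
                for c, m in sorted(self.per_class.items())]
        rows.append(("macro", self.macro["dsc"], self.macro["iou"], self.macro["hd95"]))
        return rows

    def to_text(self) -> str:
        lines = [f"{'class':>8s} {'DSC':>8s} {'IoU':>8s} {'HD95':>8s}"]
        for name, d, i, h in self.as_rows():
            lines.append(f"{name:>8s} {d:8.4f} {i:8.4f} {h:8.3f}")
        return "\n".join(lines)


def evaluate(pred, truth, n_classes: int, spacing: float = 1.0,
             empty: str = "nan") -> MetricReport:
    """One-vs-rest metrics for every foreground class (background = 0 excluded).

    Macro values are unweighted means over foreground classes; classes with
    an undefined HD95 are excluded from the HD95 macro.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"label map shapes differ: {pred.shape} vs {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    per_class = {}
    for c in range(1, n_classes):
        pm, tm = pred == c, truth == c
        per_class[c] = {
            "dsc": dsc(pm, tm),
            "iou": iou(pm, tm),
            "hd95": hd95(pm, tm, spacing=spacing, empty=empty),
        }
    macro = {
        "dsc": float(np.mean([m["dsc"] for m in per_class.values()])),
        "iou": float(np.mean([m["iou"] for m in per_class.values()])),
        "hd95": float(np.nanmean([m["hd95"] for m in per_class.values()]))
        if per_class and not all(np.isnan(m["hd95"]) for m in per_class.values())
        else float("nan"),
    }
    return MetricReport(per_class=per_class, macro=macro)
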