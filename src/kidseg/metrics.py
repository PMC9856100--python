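"""Segmentation overlap and boundary-distance metrics: Dice, IoU, 95HD."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class MetricReport:
    dice: float
    iou: float
    hd95: float


class EmptyMaskError(ValueError):
    """Boundary-distance metrics are undefined for empty masks."""


def _as_bool(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1)."""
    a, b = _as_bool(a, b)
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / total


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """|A∩B| / |A∪B|; two empty masks give 1."""
    a, b = _as_bool(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return np.logical_and(a, b).sum() / union


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (row, col) of 4-connectivity edge pixels of the mask."""
    mask = np.asarray(mask).astype(bool)
    eroded = binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~eroded)


def hd95(a: np.ndarray, b: np.ndarray) -> float:
    """95th percentile of pooled directed boundary-to-boundary distances.

    Both directed distance sets (each boundary pixel of A to the nearest of B,
    and vice versa) are pooled before taking the percentile; distances are in
    pixel units.
    """
    a, b = _as_bool(a, b)
    if not a.any() or not b.any():
        raise EmptyMaskError("hd95 requires two nonempty masks")
    pa = boundary_pixels(a).astype(float)
    pb = boundary_pixels(b).astype(float)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def evaluate_pair(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    return MetricReport(dice=dice(pred, truth), iou=iou(pred, truth), hd95=hd95(pred, truth))
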