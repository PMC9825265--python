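"""Segmentation-quality metrics and duplicate-prediction pruning.

The two error metrics validate any upstream instance segmenter against a
human-annotated ground truth:

* binary error   e_binary = |A_gt − A_pred| / A_gt   (foreground areas)
* object error   e_object = |N_gt − N_pred| / N_gt   (cell counts)

Both are 0 for a perfect prediction and scale-invariant. Duplicate masks
produced by an instance segmenter are pruned by greedy non-maximum
suppression on mask IoU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LabelImage


@dataclass
class SegEvalResult:
    e_binary: float | None  # None when A_gt == 0 (undefined)
    e_object: float | None  # None when N_gt == 0
    area_gt_um2: float
    area_pred_um2: float
    n_gt: int
    n_pred: int


def evaluate_segmentation(gt: LabelImage, pred: LabelImage) -> SegEvalResult:
    """Compare a predicted label image against ground truth."""
    if gt.pixels.shape != pred.pixels.shape:
        raise ValueError("ground truth and prediction must share dimensions")
    if gt.pixel_size != pred.pixel_size:
        raise ValueError("ground truth and prediction must share pixel size")
    px2 = gt.pixel_size ** 2
    a_gt = float(np.count_nonzero(gt.pixels)) * px2
    a_pred = float(np.count_nonzero(pred.pixels)) * px2
    n_gt, n_pred = gt.n_cells, pred.n_cells
    return SegEvalResult(
        e_binary=None if a_gt == 0 else abs(a_gt - a_pred) / a_gt,
        e_object=None if n_gt == 0 else abs(n_gt - n_pred) / n_gt,
        area_gt_um2=a_gt,
        area_pred_um2=a_pred,
        n_gt=n_gt,
        n_pred=n_pred,
    )


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def prune_duplicates(masks: list[tuple[np.ndarray, float]],
                     iou_threshold: float = 0.5) -> list[tuple[np.ndarray, float]]:
    """Greedy non-maximum suppression over predicted cell masks.

    Masks are visited in descending confidence (ties broken by smaller
    input index); a mask is dropped when its IoU with any already-kept
    mask exceeds ``iou_threshold``. Deterministic and idempotent.
    """
    if not masks:
        return []
    shapes = {np.asarray(m).shape for m, _ in masks}
    if len(shapes) > 1:
        raise ValueError("all masks must share dimensions")
    for _, score in masks:
        if not (0 <= score <= 1):
            raise ValueError("confidence scores must lie in [0, 1]")
    order = sorted(range(len(masks)), key=lambda i: (-masks[i][1], i))
    kept: list[int] = []
    for i in order:
        mask_i = np.asarray(masks[i][0], dtype=bool)
        if all(mask_iou(mask_i, np.asarray(masks[j][0], dtype=bool)) <= iou_threshold
               for j in kept):
            kept.append(i)
    return [(np.asarray(masks[i][0], dtype=bool), masks[i][1]) for i in kept]
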