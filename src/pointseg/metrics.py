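"""Evaluation metrics: per-class IoU / mIoU, counting MAE and GAME(L).

IoU is micro-averaged: TP/FP/FN pixel counts are pooled over the whole
evaluation set before the ratio, and mIoU is the mean of the background and
foreground IoUs.  A class absent from both prediction and truth (0/0) scores
1 — vacuously perfect, relevant only for degenerate toy sets.

Counting uses 8-connected components of the predicted foreground; MAE is the
mean absolute per-image count error.  GAME(L) splits each image into a
2^L x 2^L grid of cells and sums per-cell absolute count errors, so a count
placed in the wrong part of the image is penalised even when the totals
match; GAME(0) equals MAE and GAME is non-decreasing in L.  Predicted blobs
are assigned to cells by their pixel centroid, annotation points by their
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .data_model import STRUCT8

__all__ = [
    "MetricReport",
    "iou_accumulate",
    "count_predictions",
    "mae",
    "game",
    "evaluate_set",
]


@dataclass
class MetricReport:
    tp: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    fp: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    fn: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    mae: float | None = None
    game: dict[int, float] = field(default_factory=dict)

    def _iou(self, c: int) -> float:
        denom = self.tp[c] + self.fp[c] + self.fn[c]
        return 1.0 if denom == 0 else float(self.tp[c]) / float(denom)

    @property
    def iou_background(self) -> float:
        return self._iou(0)

    @property
    def iou_foreground(self) -> float:
        return self._iou(1)

    @property
    def miou(self) -> float:
        return 0.5 * (self.iou_background + self.iou_foreground)

    def as_dict(self) -> dict:
        out = {
            "tp": self.tp.tolist(),
            "fp": self.fp.tolist(),
            "fn": self.fn.tolist(),
            "iou_background": self.iou_background,
            "iou_foreground": self.iou_foreground,
            "miou": self.miou,
        }
        if self.mae is not None:
            out["mae"] = self.mae
        if self.game:
            out["game"] = {str(k): v for k, v in self.game.items()}
        return out


def iou_accumulate(pred_masks: list[np.ndarray], true_masks: list[np.ndarray],
                   report: MetricReport | None = None) -> MetricReport:
    """Pool per-class TP/FP/FN over the set (micro-average)."""
    report = report or MetricReport()
    for pred, true in zip(pred_masks, true_masks, strict=True):
        pred = np.asarray(pred).astype(bool)
        true = np.asarray(true).astype(bool)
        if pred.shape != true.shape:
            raise ValueError("prediction/truth shape mismatch")
        for c, (p, t) in enumerate(((~pred, ~true), (pred, true))):
            report.tp[c] += int((p & t).sum())
            report.fp[c] += int((p & ~t).sum())
            report.fn[c] += int((~p & t).sum())
    return report


def count_predictions(pred_mask: np.ndarray) -> int:
    """Number of 8-connected foreground components."""
    _, n = ndi.label(np.asarray(pred_mask) > 0, structure=STRUCT8)
    return int(n)


def mae(counts_pred: list[float], counts_true: list[float]) -> float:
    if len(counts_pred) != len(counts_true):
        raise ValueError("count lists must have equal length")
    if not counts_pred:
        return 0.0
    a = np.asarray(counts_pred, dtype=float)
    b = np.asarray(counts_true, dtype=float)
    return float(np.mean(np.abs(a - b)))


def _cell_edges(size: int, k: int) -> np.ndarray:
    # deterministic partition for sizes not divisible by 2^L
    return np.array([(size * i) // k for i in range(k + 1)], dtype=int)


def _cell_of(coord: float, edges: np.ndarray) -> int:
    return int(np.clip(np.searchsorted(edges, coord, side="right") - 1,
                       0, len(edges) - 2))


def blob_centroids(pred_mask: np.ndarray) -> list[tuple[float, float]]:
    labels, n = ndi.label(np.asarray(pred_mask) > 0, structure=STRUCT8)
    cents = ndi.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    return [(float(r), float(c)) for r, c in cents]


def game(preds: list, true_points: list[list[tuple[int, int]]], L: int,
         image_shape: tuple[int, int]) -> float:
    """Grid Average Mean absolute Error at level ``L``.

    ``preds`` may be binary masks (blob centroids are computed) or lists of
    centroid coordinates.  ``4**L`` cells per image.
    """
    if L < 0:
        raise ValueError("GAME level must be >= 0")
    k = 2 ** L
    h, w = image_shape
    redges = _cell_edges(h, k)
    cedges = _cell_edges(w, k)
    total = 0.0
    n_img = len(preds)
    for pred, pts in zip(preds, true_points, strict=True):
        if isinstance(pred, np.ndarray) and pred.ndim == 2:
            cents = blob_centroids(pred)
        else:
            cents = [(float(r), float(c)) for r, c in pred]
        pc = np.zeros((k, k), dtype=int)
        tc = np.zeros((k, k), dtype=int)
        for r, c in cents:
            pc[_cell_of(r, redges), _cell_of(c, cedges)] += 1
        for r, c in pts:
            tc[_cell_of(r, redges), _cell_of(c, cedges)] += 1
        total += float(np.abs(pc - tc).sum())
    return total / n_img if n_img else 0.0


def evaluate_set(pred_masks: list[np.ndarray],
                 true_masks: list[np.ndarray] | None,
                 true_points: list[list[tuple[int, int]]],
                 game_levels: tuple[int, ...] = (0, 1, 2, 4)) -> MetricReport:
    """Full report over a split: IoU (when masks exist), MAE and GAME."""
    report = MetricReport()
    if true_masks is not None:
        iou_accumulate(pred_masks, true_masks, report)
    counts_pred = [count_predictions(m) for m in pred_masks]
    counts_true = [len(p) for p in true_points]
    report.mae = mae(counts_pred, counts_true)
    if pred_masks:
        shape = np.asarray(pred_masks[0]).shape
        for L in game_levels:
            report.game[L] = game(pred_masks, true_points, L, shape)
    return report
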