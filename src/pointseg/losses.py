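"""The four-term LCFCN objective on per-pixel probabilities and point labels.

    L = L_I + L_P + L_S + L_F

* image-level L_I: the most-confident pixel must say "fish" when the image
  contains at least one click, "background" when it contains none;
* point-level L_P: cross-entropy for the fish class at every click;
* split-level L_S: blobs containing two or more clicks are carved by a
  watershed seeded at the clicks (topography = negative fish probability);
  the separating ridge pixels are pushed towards background, weighted by the
  number of clicks in the blob;
* false-positive L_F: every pixel of a blob containing no click is pushed
  towards background.

Together the terms drive the model towards exactly one blob per annotated
instance.  Blob structure (connected components, watershed basins) is
recomputed every step and treated as a constant: gradients flow only through
the per-pixel -log probability terms.  All -log arguments are clamped at
1e-8 for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .autodiff import Tensor
from .data_model import STRUCT8
from .network import ProbMap

__all__ = [
    "BlobSet",
    "LossReport",
    "find_blobs",
    "image_level_loss",
    "point_level_loss",
    "split_level_loss",
    "false_positive_loss",
    "lcfcn_loss",
    "PROB_FLOOR",
]

PROB_FLOOR = 1e-8


@dataclass
class Blob:
    blob_id: int
    pixel_count: int
    contained_points: list[tuple[int, int]]


@dataclass
class BlobSet:
    """8-connected components of the predicted foreground."""

    labels: np.ndarray  # H x W int, 0 = background
    blobs: dict[int, Blob] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.blobs)

    @property
    def count(self) -> int:
        return len(self.blobs)


def _neg_log(p: Tensor) -> Tensor:
    return -(p.clamp_min(PROB_FLOOR).log())


def find_blobs(probs: ProbMap, points: list[tuple[int, int]]) -> BlobSet:
    """Label predicted-foreground components and assign clicks to blobs."""
    scores = probs.values.data
    fg = scores[1] > scores[0]
    labels, n = ndi.label(fg, structure=STRUCT8)
    blobs: dict[int, Blob] = {}
    for k in range(1, n + 1):
        blobs[k] = Blob(k, int((labels == k).sum()), [])
    for r, c in points:
        k = int(labels[r, c])
        if k > 0:
            blobs[k].contained_points.append((r, c))
    return BlobSet(labels, blobs)


def image_level_loss(probs: ProbMap, points: list[tuple[int, int]]) -> Tensor:
    fg_max = probs.foreground.max()
    if len(points) > 0:
        return _neg_log(fg_max)
    return _neg_log(1.0 - fg_max)


def point_level_loss(probs: ProbMap, points: list[tuple[int, int]]) -> Tensor:
    if not points:
        return Tensor(np.zeros((), dtype=probs.values.dtype))
    h, w = probs.values.shape[1:]
    flat = np.array([r * w + c for r, c in points], dtype=np.intp)
    return _neg_log(probs.foreground.take(flat)).sum()


def _watershed_ridge(fg_prob: np.ndarray, blob_mask: np.ndarray,
                     pts: list[tuple[int, int]]) -> np.ndarray:
    """Flat indices of the watershed line separating the blob's clicks."""
    markers = np.zeros(fg_prob.shape, dtype=np.int32)
    for i, (r, c) in enumerate(pts, start=1):
        markers[r, c] = i
    basins = watershed(-fg_prob, markers=markers, mask=blob_mask,
                       connectivity=2, watershed_line=True)
    ridge = blob_mask & (basins == 0)
    return np.flatnonzero(ridge.ravel())


def split_level_loss(probs: ProbMap, blobs: BlobSet) -> Tensor:
    fg_prob = probs.values.data[1]
    total = Tensor(np.zeros((), dtype=probs.values.dtype))
    for blob in blobs.blobs.values():
        n_b = len(blob.contained_points)
        if n_b < 2:
            continue
        mask = blobs.labels == blob.blob_id
        ridge = _watershed_ridge(fg_prob, mask, blob.contained_points)
        if ridge.size == 0:
            continue
        total = total + float(n_b) * _neg_log(probs.background.take(ridge)).sum()
    return total


def false_positive_loss(probs: ProbMap, blobs: BlobSet) -> Tensor:
    unannotated = [b.blob_id for b in blobs.blobs.values()
                   if not b.contained_points]
    if not unannotated:
        return Tensor(np.zeros((), dtype=probs.values.dtype))
    pix = np.flatnonzero(np.isin(blobs.labels, unannotated).ravel())
    return _neg_log(probs.background.take(pix)).sum()


@dataclass
class LossReport:
    total: Tensor
    image_level: float
    point_level: float
    split_level: float
    false_positive: float

    def as_dict(self) -> dict[str, float]:
        return {
            "total": float(self.total.data),
            "image_level": self.image_level,
            "point_level": self.point_level,
            "split_level": self.split_level,
            "false_positive": self.false_positive,
        }


def lcfcn_loss(probs: ProbMap, points: list[tuple[int, int]]) -> LossReport:
    """Full objective; ``report.total`` stays on the tape for backprop."""
    blobs = find_blobs(probs, points)
    l_i = image_level_loss(probs, points)
    l_p = point_level_loss(probs, points)
    l_s = split_level_loss(probs, blobs)
    l_f = false_positive_loss(probs, blobs)
    total = l_i + l_p + l_s + l_f
    return LossReport(total, float(l_i.data), float(l_p.data),
                      float(l_s.data), float(l_f.data))
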