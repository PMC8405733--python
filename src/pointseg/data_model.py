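"""Core data types and dataset I/O.

Datasets follow a simple folder layout (one folder per annotation kind, one
sub-folder per split, plus a listing file per split)::

    root/
      train.txt  val.txt  test.txt          # one scene id per line
      images/<split>/<id>.png               # RGB image
      points/<split>/<id>.png               # single channel, non-zero at clicks
      masks/<split>/<id>.png                # single channel, {0,255}

Point annotations mark each fish with one click; when only full masks are
available, :func:`derive_points_from_mask` produces the click at each
component's deepest interior pixel (maximal Euclidean distance transform),
which is the convention used to turn segmentation masks into point labels.

All coordinates are 0-based ``(row, col)``; conversion to/from image (x, y)
happens only at file boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "Scene",
    "DatasetManifest",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "load_manifest",
    "derive_points_from_mask",
    "write_mask",
    "read_mask",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

SPLITS = ("train", "val", "test")

#: 8-connectivity structuring element shared by every component operation.
STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Scene:
    """One image with its point annotations and optional ground-truth mask."""

    id: str
    image: np.ndarray  # H x W x 3 float in [0, 1]
    points: list[tuple[int, int]] = field(default_factory=list)
    mask: np.ndarray | None = None  # H x W in {0, 1}
    split: str = "train"

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        seen = set()
        for r, c in self.points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"scene {self.id}: point ({r},{c}) outside {h}x{w}")
            if (r, c) in seen:
                raise ValueError(f"scene {self.id}: duplicate point ({r},{c})")
            seen.add((r, c))
        if self.mask is not None:
            if self.mask.shape != (h, w):
                raise ValueError(f"scene {self.id}: mask shape mismatch")
            for r, c in self.points:
                if self.mask[r, c] != 1:
                    warnings.warn(
                        f"scene {self.id}: point ({r},{c}) off the mask foreground",
                        stacklevel=2,
                    )

    @property
    def count(self) -> int:
        """Number of annotated instances."""
        return len(self.points)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class DatasetManifest:
    scenes: list[Scene]
    resize_target: tuple[int, int] | None = None
    normalization: tuple[tuple[float, ...], tuple[float, ...]] = (
        IMAGENET_MEAN,
        IMAGENET_STD,
    )

    def split(self, name: str) -> list[Scene]:
        return [s for s in self.scenes if s.split == name]

    def __len__(self) -> int:
        return len(self.scenes)


# ----------------------------------------------------------------- loading
def _read_image(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.float64) / 255.0


def read_mask(path: Path) -> np.ndarray:
    """Read a single-channel mask; {0,255} or {0,1} on disk become {0,1}."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a {0,255} single-channel PNG (lossless)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.astype(np.uint8) * 255), extension=".png")


def _points_from_map(point_map: np.ndarray) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(point_map)
    return [(int(r), int(c)) for r, c in zip(rows, cols)]


def _scale_point(p: tuple[int, int], sr: float, sc: float,
                 shape: tuple[int, int]) -> tuple[int, int]:
    # round-half-down keeps scaled clicks inside the body they annotate
    r = int(np.ceil(p[0] * sr - 0.5))
    c = int(np.ceil(p[1] * sc - 0.5))
    return (min(max(r, 0), shape[0] - 1), min(max(c, 0), shape[1] - 1))


def _resize_image(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    return resize(img, target, order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)


def _resize_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    out = resize(mask.astype(float), target, order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def _find_file(folder: Path, scene_id: str) -> Path | None:
    for ext in (".png", ".jpg", ".jpeg"):
        cand = folder / f"{scene_id}{ext}"
        if cand.exists():
            return cand
    return None


def load_manifest(
    root_path: str | Path,
    resize_target: tuple[int, int] | None = None,
    normalization: tuple = (IMAGENET_MEAN, IMAGENET_STD),
) -> DatasetManifest:
    """Load every listed scene under ``root_path``.

    Raises ``FileNotFoundError`` naming the missing file when a listed image
    is absent.  A point falling outside the mask foreground produces a
    warning (the point is kept): real click annotations occasionally miss
    thin bodies after resizing.
    """
    root = Path(root_path)
    scenes: list[Scene] = []
    for split in SPLITS:
        listing = root / f"{split}.txt"
        if not listing.exists():
            continue
        ids = [ln.strip() for ln in listing.read_text().splitlines() if ln.strip()]
        for scene_id in ids:
            img_path = _find_file(root / "images" / split, scene_id)
            if img_path is None:
                raise FileNotFoundError(
                    f"missing image for scene '{scene_id}' under "
                    f"{root / 'images' / split}"
                )
            image = _read_image(img_path)
            orig_shape = image.shape[:2]

            points: list[tuple[int, int]] = []
            pt_path = _find_file(root / "points" / split, scene_id)
            if pt_path is not None:
                points = _points_from_map(read_mask(pt_path))

            mask = None
            mask_path = _find_file(root / "masks" / split, scene_id)
            if mask_path is not None:
                mask = read_mask(mask_path)

            if resize_target is not None and tuple(orig_shape) != tuple(resize_target):
                sr = resize_target[0] / orig_shape[0]
                sc = resize_target[1] / orig_shape[1]
                image = _resize_image(image, resize_target)
                if mask is not None:
                    mask = _resize_mask(mask, resize_target)
                points = [_scale_point(p, sr, sc, resize_target) for p in points]
                # distinct clicks can collapse onto one pixel after scaling
                points = list(dict.fromkeys(points))

            scenes.append(Scene(scene_id, image, points, mask, split))
    return DatasetManifest(scenes, resize_target, normalization)


# ------------------------------------------------------- point derivation
def derive_points_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """One click per connected component, at its deepest interior pixel.

    The click is the component pixel with the maximal Euclidean distance to
    the nearest background pixel; everything outside the image counts as
    background, so a component touching the border still gets an interior
    click.  Ties break deterministically by smallest row then smallest
    column.  Components use 8-connectivity.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if mask.sum() == 0:
        return []
    labels, n = ndi.label(mask, structure=STRUCT8)
    # foreground of one component never shrinks another component's distance:
    # distance is to the nearest *zero* pixel, so one global EDT suffices
    dist = ndi.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    points: list[tuple[int, int]] = []
    for k in range(1, n + 1):
        inside = labels == k
        d = np.where(inside, dist, -np.inf)
        flat = int(np.argmax(d))  # argmax scans row-major -> row, then col
        points.append(np.unravel_index(flat, mask.shape))
    return [(int(r), int(c)) for r, c in points]
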