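"""Synthetic underwater-style scenes for desk-scale experiments.

Real fish-monitoring imagery is hard for segmentation for two reasons this
generator reproduces: the contrast between a fish body and the water behind
it is small, and backgrounds are textured (debris, vegetation, caustics).
Each scene is a smoothed-noise background with 0-3 deformable elliptical
"fish" (random rotation, aspect and a sinusoidal boundary perturbation)
added at a configurable intensity offset.  Ground truth comes for free: the
instance masks, their count, and point annotations placed at each
component's maximal-distance-transform pixel — the same convention used to
derive clicks from real masks.

What it does *not* emulate: photorealistic water optics, species-specific
shapes and fin detail, motion blur, and the heavy class imbalance of long
camera deployments.  Tests passing on these scenes exercise the machinery
(losses, refinement, metrics, training loop), not field-readiness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .data_model import (
    DatasetManifest,
    Scene,
    derive_points_from_mask,
    load_manifest,
    write_mask,
)

__all__ = ["SceneSpec", "EASY", "DEFAULT", "generate_scene", "generate_split"]


@dataclass(frozen=True)
class SceneSpec:
    """Generation parameters for one family of scenes.

    ``contrast`` is the intensity offset of a fish body over the local
    background (in [0,1] image units); ``texture_strength`` scales the
    background noise amplitude; ``occlusion_prob`` is the chance a fish is
    allowed to overlap an already placed one.
    """

    height: int = 96
    width: int = 96
    n_fish_range: tuple[int, int] = (0, 3)
    fish_scale_range: tuple[int, int] = (9, 16)  # semi-major axis, px
    contrast: float = 0.25
    texture_strength: float = 0.5
    occlusion_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish_range[0] > self.n_fish_range[1]:
            raise ValueError("n_fish_range must be (min, max) with min <= max")
        if self.fish_scale_range[0] > self.fish_scale_range[1]:
            raise ValueError("fish_scale_range must be (min, max)")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")
        if not 0 <= self.occlusion_prob <= 1:
            raise ValueError("occlusion_prob must lie in [0, 1]")
        if self.texture_strength < 0:
            raise ValueError("texture_strength must be >= 0")


#: Low-contrast default emulating the difficulty of real footage.
DEFAULT = SceneSpec()
#: High-contrast preset for fast mechanism checks and acceptance runs.
EASY = SceneSpec(contrast=0.8, texture_strength=0.3, occlusion_prob=0.0)


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((spec.height, spec.width))
    smooth = ndi.gaussian_filter(noise, sigma=3.0)
    smooth /= max(np.abs(smooth).max(), 1e-9)
    return 0.35 + 0.15 * spec.texture_strength * smooth


def _fish_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one randomly deformed, rotated ellipse anywhere that fits."""
    h, w = spec.height, spec.width
    a = rng.uniform(*spec.fish_scale_range)
    b = a * rng.uniform(0.35, 0.6)
    angle = rng.uniform(0, np.pi)
    amp = rng.uniform(0.05, 0.2)
    k = rng.integers(2, 5)
    phase = rng.uniform(0, 2 * np.pi)
    margin = int(np.ceil(a * 1.3))
    cr = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
    cc = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2

    rr, cc_grid = np.mgrid[0:h, 0:w]
    dr, dc = rr - cr, cc_grid - cc
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dc + sa * dr
    v = -sa * dc + ca * dr
    radial = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    theta = np.arctan2(v / b, u / a)
    boundary = 1.0 + amp * np.sin(k * theta + phase)
    return radial <= boundary


def generate_scene(spec: SceneSpec, rng: np.random.Generator,
                   scene_id: str = "scene", split: str = "train") -> Scene:
    """One scene with mask, derived points and count within the spec range."""
    h, w = spec.height, spec.width
    n_fish = int(rng.integers(spec.n_fish_range[0], spec.n_fish_range[1] + 1))
    mask = np.zeros((h, w), dtype=np.uint8)
    fish_layers: list[np.ndarray] = []
    for _ in range(n_fish):
        allow_overlap = rng.uniform() < spec.occlusion_prob
        placed = None
        for _attempt in range(200):
            cand = _fish_mask(spec, rng)
            if allow_overlap:
                placed = cand
                break
            # separation by a 1-cell dilation keeps components 8-disjoint
            grown = ndi.binary_dilation(cand, structure=np.ones((5, 5)))
            if not (grown & (mask > 0)).any():
                placed = cand
                break
        if placed is None:  # crowded frame: fall back to overlap
            placed = cand
        mask |= placed.astype(np.uint8)
        fish_layers.append(placed)

    image = _background(spec, rng)
    for layer in fish_layers:
        depth = rng.uniform(0.9, 1.0)  # slight per-fish brightness variation
        image = np.where(layer, image + spec.contrast * depth, image)
    image = image + 0.02 * rng.standard_normal((h, w))
    image = np.clip(image, 0.0, 1.0)
    image3 = np.repeat(image[:, :, None], 3, axis=2)

    points = derive_points_from_mask(mask)
    return Scene(scene_id, image3, points, mask, split)


def generate_split(spec: SceneSpec, n_train: int, n_val: int, n_test: int,
                   seed: int, root: str | Path) -> DatasetManifest:
    """Write a dataset in the standard folder layout and load it back."""
    import imageio.v3 as iio

    root = Path(root)
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    seq = np.random.SeedSequence(seed)
    streams = dict(zip(sizes, seq.spawn(len(sizes))))
    for split, n in sizes.items():
        rng = np.random.default_rng(streams[split])
        ids = []
        for i in range(n):
            scene_id = f"{split}_{i:04d}"
            scene = generate_scene(spec, rng, scene_id, split)
            img_path = root / "images" / split / f"{scene_id}.png"
            img_path.parent.mkdir(parents=True, exist_ok=True)
            iio.imwrite(img_path,
                        np.round(scene.image * 255).astype(np.uint8),
                        extension=".png")
            point_map = np.zeros((spec.height, spec.width), dtype=np.uint8)
            for r, c in scene.points:
                point_map[r, c] = 1
            write_mask(point_map, root / "points" / split / f"{scene_id}.png")
            write_mask(scene.mask, root / "masks" / split / f"{scene_id}.png")
            ids.append(scene_id)
        (root / f"{split}.txt").write_text("\n".join(ids) + ("\n" if ids else ""))
    return load_manifest(root)


def in_memory_split(spec: SceneSpec, n_train: int, n_val: int, n_test: int,
                    seed: int) -> DatasetManifest:
    """Same split without touching the filesystem (fast path for training)."""
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    seq = np.random.SeedSequence(seed)
    streams = dict(zip(sizes, seq.spawn(len(sizes))))
    scenes: list[Scene] = []
    for split, n in sizes.items():
        rng = np.random.default_rng(streams[split])
        for i in range(n):
            scenes.append(generate_scene(spec, rng, f"{split}_{i:04d}", split))
    return DatasetManifest(scenes)
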