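"""Segmentation network: shared backbone, activation and affinity branches.

One fully convolutional backbone feeds two heads:

* the activation branch, a single 1x1 convolution with 2 output channels
  (background / fish scores) on the deepest feature map;
* the affinity branch, per-level 1x1 convolutions with 64, 128 and 256
  channels applied to three backbone depths, resampled bilinearly to the
  deepest grid, concatenated (448 channels) and merged by a final 1x1
  convolution into 448-dimensional affinity features.

The affinity features define a local pairwise graph whose row-normalised
transition operator refines the raw activations by a random walk; the
refined scores are bilinearly upsampled to image resolution and squashed by
a softmax into per-pixel class probabilities.  Setting
``affinity_enabled=False`` bypasses refinement entirely (plain LCFCN mode);
every other code path is shared, which is what makes the affinity ablation a
one-flag experiment.

Backbones are pluggable behind a three-level feature contract.  The default
"small" backbone is a compact strided CNN (strides 2/4/8) with randomly
initialised weights, suitable for desk-scale synthetic scenes; "deep" is a
wider/deeper variant at the same strides; "toy" keeps full resolution and
exists for gradient checks on tiny inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor, concat, conv2d, resize_bilinear
from .affinity import (
    AffinityFeatureMap,
    NeighborGraph,
    ScoreMap,
    build_affinity_graph,
    build_transition,
    random_walk_refine,
)

__all__ = [
    "BackboneFeatures",
    "ModelConfig",
    "ProbMap",
    "SegModel",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class BackboneFeatures:
    """Three feature grids from increasing backbone depths."""

    levels: list[Tensor]  # each (C_l, h_l, w_l)
    last: Tensor

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError("backbone must expose exactly 3 feature levels")


@dataclass
class ProbMap:
    """Per-pixel class probabilities, shape ``(2, H, W)``, channels sum to 1."""

    values: Tensor

    def __post_init__(self) -> None:
        self.values = ad.as_tensor(self.values)
        s = self.values.data.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-6):
            raise ValueError("probability channels must sum to 1 per pixel")

    @property
    def foreground(self) -> Tensor:
        return self.values[1]

    @property
    def background(self) -> Tensor:
        return self.values[0]

    def numpy(self) -> np.ndarray:
        return self.values.data


@dataclass
class ModelConfig:
    backbone_name: str = "small"
    affinity_enabled: bool = True
    affinity_channels: tuple[int, int, int] = (64, 128, 256)
    merged_channels: int = 448
    num_classes: int = 2
    affinity_radius: float = 5.0
    affinity_beta: float = 8.0
    affinity_iterations: int = 8
    #: weight scale of the affinity merge conv.  Affinity distances are L1
    #: over 448 dimensions, so unit-scale random features would start with
    #: W = exp(-L1) underflowing to 0 and a dead (gradient-free) branch;
    #: a small gain starts the walk near, but not at, the identity.
    affinity_init_gain: float = 0.01
    #: initial background-vs-fish logit margin of the activation head
    foreground_prior_logit: float = 2.2
    normalization: tuple = ((0.485, 0.456, 0.406), (0.229, 0.224, 0.225))
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.merged_channels != sum(self.affinity_channels):
            raise ValueError("merged_channels must equal the sum of "
                             "affinity_channels")


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, pad=None, dtype=np.float32):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, k, k), c_in * k * k, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class SmallBackbone(Module):
    """Three strided stages; feature levels at strides 2, 4 and 8."""

    strides = (2, 4, 8)
    channels = (8, 16, 32)

    def __init__(self, rng, dtype=np.float32):
        c1, c2, c3 = self.channels
        self.conv1 = Conv(rng, 3, c1, stride=2, dtype=dtype)
        self.conv2 = Conv(rng, c1, c2, stride=2, dtype=dtype)
        self.conv3 = Conv(rng, c2, c3, stride=2, dtype=dtype)

    def __call__(self, x: Tensor) -> BackboneFeatures:
        l1 = self.conv1(x).relu()
        l2 = self.conv2(l1).relu()
        l3 = self.conv3(l2).relu()
        return BackboneFeatures([l1, l2, l3], l3)


class DeepBackbone(Module):
    """Two convolutions per stage, wider channels, same stride layout."""

    strides = (2, 4, 8)
    channels = (16, 32, 64)

    def __init__(self, rng, dtype=np.float32):
        c1, c2, c3 = self.channels
        self.conv1a = Conv(rng, 3, c1, stride=2, dtype=dtype)
        self.conv1b = Conv(rng, c1, c1, dtype=dtype)
        self.conv2a = Conv(rng, c1, c2, stride=2, dtype=dtype)
        self.conv2b = Conv(rng, c2, c2, dtype=dtype)
        self.conv3a = Conv(rng, c2, c3, stride=2, dtype=dtype)
        self.conv3b = Conv(rng, c3, c3, dtype=dtype)

    def __call__(self, x: Tensor) -> BackboneFeatures:
        l1 = self.conv1b(self.conv1a(x).relu()).relu()
        l2 = self.conv2b(self.conv2a(l1).relu()).relu()
        l3 = self.conv3b(self.conv3a(l2).relu()).relu()
        return BackboneFeatures([l1, l2, l3], l3)


class ToyBackbone(Module):
    """Full-resolution stages for finite-difference gradient checks."""

    strides = (1, 1, 1)
    channels = (4, 4, 4)

    def __init__(self, rng, dtype=np.float64):
        c1, c2, c3 = self.channels
        self.conv1 = Conv(rng, 3, c1, dtype=dtype)
        self.conv2 = Conv(rng, c1, c2, dtype=dtype)
        self.conv3 = Conv(rng, c2, c3, dtype=dtype)

    def __call__(self, x: Tensor) -> BackboneFeatures:
        l1 = self.conv1(x).relu()
        l2 = self.conv2(l1).relu()
        l3 = self.conv3(l2).relu()
        return BackboneFeatures([l1, l2, l3], l3)


class FineBackbone(Module):
    """Stride-4 deepest grid (strides 2/4/4): finer blobs on small images."""

    strides = (2, 4, 4)
    channels = (8, 16, 32)

    def __init__(self, rng, dtype=np.float32):
        c1, c2, c3 = self.channels
        self.conv1 = Conv(rng, 3, c1, stride=2, dtype=dtype)
        self.conv2 = Conv(rng, c1, c2, stride=2, dtype=dtype)
        self.conv3 = Conv(rng, c2, c3, stride=1, dtype=dtype)

    def __call__(self, x: Tensor) -> BackboneFeatures:
        l1 = self.conv1(x).relu()
        l2 = self.conv2(l1).relu()
        l3 = self.conv3(l2).relu()
        return BackboneFeatures([l1, l2, l3], l3)


_BACKBONES = {"small": SmallBackbone, "deep": DeepBackbone,
              "fine": FineBackbone, "toy": ToyBackbone}


@dataclass
class ForwardResult:
    probs: ProbMap                 # (2, H, W) at image resolution
    refined: ScoreMap              # (2, h, w) at feature resolution
    graph: NeighborGraph | None    # None when affinity is disabled
    raw: ScoreMap = None           # pre-refinement activations


class SegModel(Module):
    """Shared-backbone segmentation model with optional affinity refinement."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.backbone_name not in _BACKBONES:
            raise ValueError(f"unknown backbone '{config.backbone_name}'")
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(seed)
        self.backbone = _BACKBONES[config.backbone_name](rng, dtype=dtype)
        c_levels = self.backbone.channels
        # activation branch: one 1x1 conv, 2 channels, on the deepest map
        self.act_head = Conv(rng, c_levels[-1], config.num_classes, k=1, pad=0,
                             dtype=dtype)
        # background-favouring prior: start with an empty foreground so the
        # point/image terms grow blobs from the clicks outward instead of
        # first fighting the false-positive term over random blobs
        self.act_head.bias.data[1] = -abs(config.foreground_prior_logit)
        # affinity branch: per-level 1x1 convs -> resample -> concat -> merge
        self.aff_convs = [
            Conv(rng, c_in, c_out, k=1, pad=0, dtype=dtype)
            for c_in, c_out in zip(c_levels, config.affinity_channels)
        ]
        self.aff_merge = Conv(rng, sum(config.affinity_channels),
                              config.merged_channels, k=1, pad=0, dtype=dtype)
        self.aff_merge.weight.data *= config.affinity_init_gain

    # ----------------------------------------------------------- pieces
    def backbone_forward(self, image: Tensor | np.ndarray) -> BackboneFeatures:
        x = ad.as_tensor(image)
        if x.ndim != 3 or x.shape[0] != 3:
            raise ValueError("expected a normalized (3, H, W) image")
        return self.backbone(x)

    def activation_branch(self, features: BackboneFeatures) -> ScoreMap:
        return ScoreMap(self.act_head(features.last), "feature")

    def affinity_branch(self, features: BackboneFeatures) -> AffinityFeatureMap:
        if len(features.levels) < 3:
            raise ValueError("affinity branch needs 3 feature levels")
        target = features.last.shape[1:]
        mapped = []
        for conv, level in zip(self.aff_convs, features.levels):
            y = conv(level)
            if y.shape[1:] != target:
                y = resize_bilinear(y, target)
            mapped.append(y)
        merged = self.aff_merge(concat(mapped, axis=0))
        return AffinityFeatureMap(merged)

    def normalize(self, image_hw3: np.ndarray) -> np.ndarray:
        mean, std = self.config.normalization
        mean = np.asarray(mean, dtype=np.float64)
        std = np.asarray(std, dtype=np.float64)
        out = (image_hw3 - mean) / std
        return out.transpose(2, 0, 1).astype(self.config.dtype)

    # ---------------------------------------------------------- forward
    def forward(self, image_hw3: np.ndarray) -> ForwardResult:
        """Full pass from an un-normalized H x W x 3 image in [0, 1]."""
        cfg = self.config
        h_img, w_img = image_hw3.shape[:2]
        x = Tensor(self.normalize(image_hw3))
        feats = self.backbone_forward(x)
        raw = self.activation_branch(feats)
        graph = None
        refined = raw
        if cfg.affinity_enabled:
            aff = self.affinity_branch(feats)
            graph = build_affinity_graph(aff, cfg.affinity_radius)
            operator = build_transition(graph, cfg.affinity_beta)
            refined = random_walk_refine(raw, operator, cfg.affinity_iterations)
        upsampled = resize_bilinear(refined.values, (h_img, w_img))
        probs = ProbMap(upsampled.softmax(axis=0))
        return ForwardResult(probs, refined, graph, raw)

    __call__ = forward

    def predict_mask(self, image_hw3: np.ndarray) -> np.ndarray:
        """Hard {0,1} segmentation (argmax; ties resolve to background)."""
        res = self.forward(image_hw3)
        scores = res.probs.values.data
        return (scores[1] > scores[0]).astype(np.uint8)


def build_model(config: ModelConfig, seed: int = 0) -> SegModel:
    return SegModel(config, seed=seed)


def save_checkpoint(model: SegModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())


def load_checkpoint(model: SegModel, path: str | Path) -> SegModel:
    with np.load(Path(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
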