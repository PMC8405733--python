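"""Pairwise-affinity graph and differentiable random-walk refinement.

Given an affinity feature map ``f`` (d x h x w), the semantic affinity
between two grid cells i, j is

    W_ij = exp(-||f_i - f_j||_1),

restricted to local pairs within Euclidean grid radius gamma.  The graph is
turned into a random-walk transition operator by an element-wise (Hadamard)
power followed by row normalisation,

    T = D^-1 W^beta,   D_ii = sum_j W_ij^beta,

and class-score channels are refined by t applications of T.  A larger beta
makes the propagation more conservative (small feature differences are
suppressed harder); more iterations diffuse scores further, but always as
convex combinations of neighbour scores, so refinement can never push a
channel outside its original [min, max] range.

Everything here is differentiable with respect to the affinity features and
the activations, which is what allows the affinity branch to be trained from
point annotations alone, without explicit pair labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse as sp

from .autodiff import Tensor, as_tensor, concat, sparse_matmul

__all__ = [
    "AffinityFeatureMap",
    "NeighborGraph",
    "TransitionOperator",
    "ScoreMap",
    "build_affinity_graph",
    "build_transition",
    "random_walk_refine",
]


@dataclass
class AffinityFeatureMap:
    """Per-cell feature vectors, shape ``(d, h, w)``."""

    values: Tensor

    def __post_init__(self) -> None:
        self.values = as_tensor(self.values)
        if not np.isfinite(self.values.data).all():
            raise ValueError("affinity features must be finite")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass
class ScoreMap:
    """Per-class raw activations, shape ``(C, h, w)``."""

    values: Tensor
    resolution_tag: str = "feature"  # "feature" or "image"

    def __post_init__(self) -> None:
        self.values = as_tensor(self.values)
        if not np.isfinite(self.values.data).all():
            raise ValueError("score map must be finite")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    def numpy(self) -> np.ndarray:
        return self.values.data


def _selection(rows: np.ndarray, n_cols: int) -> sp.csr_matrix:
    m = rows.size
    return sp.csr_matrix(
        (np.ones(m, dtype=np.float32), (np.arange(m), rows)), shape=(m, n_cols)
    )


@lru_cache(maxsize=16)
def _grid_structure(h: int, w: int, radius: float):
    """Directed neighbour pairs of an h x w grid within Euclidean ``radius``.

    Returns (idx_i, idx_j, gather_j, scatter_i, half_i, half_j, half_map)
    where the gather matrix selects per-pair target rows, ``scatter_i`` sums
    per-pair values into their source row, the ``half_*`` arrays enumerate
    each unordered pair (i < j) once, and ``half_map`` maps every directed
    pair either to its unordered index or — for self pairs — to the sentinel
    slot ``len(half_i)`` (weight exp(0) = 1).  Memory scales with the number
    of pairs, not (hw)^2.
    """
    r_int = int(np.floor(radius))
    offs = [
        (dr, dc)
        for dr in range(-r_int, r_int + 1)
        for dc in range(-r_int, r_int + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    idx_i_parts, idx_j_parts = [], []
    base = (rows * w + cols).ravel()
    for dr, dc in offs:
        r2 = rows + dr
        c2 = cols + dc
        valid = ((r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)).ravel()
        tgt = (r2 * w + c2).ravel()
        idx_i_parts.append(base[valid])
        idx_j_parts.append(tgt[valid])
    idx_i = np.concatenate(idx_i_parts)
    idx_j = np.concatenate(idx_j_parts)
    order = np.lexsort((idx_j, idx_i))
    idx_i, idx_j = idx_i[order], idx_j[order]
    n = h * w
    gather_j = _selection(idx_j, n)
    scatter_i = _selection(idx_i, n).T.tocsr()

    upper = idx_i < idx_j
    half_i, half_j = idx_i[upper], idx_j[upper]
    # key unordered pairs so both (i,j) and (j,i) resolve to the same slot
    keys = half_i * n + half_j
    lookup = {int(k): p for p, k in enumerate(keys)}
    half_map = np.empty(idx_i.size, dtype=np.intp)
    for p, (a, b) in enumerate(zip(idx_i, idx_j)):
        if a == b:
            half_map[p] = half_i.size  # sentinel: zero L1 distance
        else:
            key = (a * n + b) if a < b else (b * n + a)
            half_map[p] = lookup[int(key)]
    return idx_i, idx_j, gather_j, scatter_i, half_i, half_j, half_map


def _pairwise_l1(feats: Tensor, half_i: np.ndarray, half_j: np.ndarray,
                 n_nodes: int) -> Tensor:
    """Fused per-pair L1 feature distance with a single-op backward.

    ``feats`` has shape (n, d); the result has one entry per unordered pair.
    Fusing avoids taping the (pairs x d) intermediates, which dominate the
    cost of a training step.
    """
    gi = _selection(half_i, n_nodes)
    gj = _selection(half_j, n_nodes)
    fi = gi @ feats.data
    fj = gj @ feats.data
    diff = fi - fj
    sign = np.sign(diff)
    out = np.abs(diff, out=diff).sum(axis=1)

    def bwd(g):
        contrib = sign * g[:, None]
        return ((feats, gi.T @ contrib - gj.T @ contrib),)

    return Tensor(out, _backward=bwd, _parents=(feats,))


@dataclass
class NeighborGraph:
    """Sparse symmetric affinity graph over an ``h x w`` grid.

    ``weights[p]`` is W_{idx_i[p], idx_j[p]}; every unordered pair appears in
    both directions and every node carries a self pair with weight 1.
    """

    grid_shape: tuple[int, int]
    idx_i: np.ndarray
    idx_j: np.ndarray
    weights: Tensor
    radius: float

    @property
    def n_nodes(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def to_sparse(self) -> sp.csr_matrix:
        """Materialise W as scipy CSR (detached from the tape)."""
        n = self.n_nodes
        return sp.csr_matrix(
            (self.weights.data, (self.idx_i, self.idx_j)), shape=(n, n)
        )

    def validate(self) -> None:
        w = self.weights.data
        if not ((w > 0).all() and (w <= 1.0 + 1e-12).all()):
            raise ValueError("affinity weights must lie in (0, 1]")
        mat = self.to_sparse()
        if (abs(mat - mat.T) > 1e-9).nnz:
            raise ValueError("affinity graph must be symmetric")
        if not np.allclose(mat.diagonal(), 1.0):
            raise ValueError("self-affinities must equal 1")


@dataclass
class TransitionOperator:
    """Row-stochastic random-walk operator ``T = D^-1 W^beta``."""

    grid_shape: tuple[int, int]
    idx_i: np.ndarray
    idx_j: np.ndarray
    values: Tensor  # per-pair T_ij, taped
    beta: float
    degree: np.ndarray  # D_ii, detached

    @property
    def n_nodes(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def to_sparse(self) -> sp.csr_matrix:
        n = self.n_nodes
        return sp.csr_matrix(
            (self.values.data, (self.idx_i, self.idx_j)), shape=(n, n)
        )

    def apply(self, v: Tensor) -> Tensor:
        """One walk step on stacked channel columns ``v`` of shape (n, C)."""
        _, _, gather_j, scatter_i, *_ = _grid_structure(
            *self.grid_shape, self.radius_key
        )
        vj = sparse_matmul(gather_j, v)
        vals = self.values.reshape(-1, 1)
        return sparse_matmul(scatter_i, vals * vj)

    # kept so apply() can recover the cached structure matrices
    radius_key: float = 0.0


def build_affinity_graph(features: AffinityFeatureMap | Tensor | np.ndarray,
                         radius: float) -> NeighborGraph:
    """Affinity weights ``exp(-L1 feature distance)`` over local pairs."""
    if radius < 1:
        raise ValueError("neighborhood radius must be >= 1")
    if not isinstance(features, AffinityFeatureMap):
        features = AffinityFeatureMap(as_tensor(features))
    d, h, w = features.values.shape
    idx_i, idx_j, _, _, half_i, half_j, half_map = _grid_structure(h, w, radius)
    feats = features.values.reshape(d, h * w).T  # (n, d)
    l1_half = _pairwise_l1(feats, half_i, half_j, h * w)
    w_half = (-l1_half).exp()
    # mirror each unordered weight onto both directions; sentinel slot = 1
    ones = Tensor(np.ones(1, dtype=w_half.dtype))
    weights = concat([w_half, ones]).take(half_map)
    return NeighborGraph((h, w), idx_i, idx_j, weights, radius)


def build_transition(graph: NeighborGraph, beta: float) -> TransitionOperator:
    """Hadamard power then row normalisation (``T = D^-1 W^beta``)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    wb = graph.weights ** float(beta)
    _, _, _, scatter_i, *_ = _grid_structure(*graph.grid_shape, graph.radius)
    degree = sparse_matmul(scatter_i, wb)  # (n,) row sums of W^beta
    if (degree.data <= 0).any():
        raise RuntimeError("zero row degree in transition operator")
    tvals = wb / degree.take(graph.idx_i)
    op = TransitionOperator(
        graph.grid_shape, graph.idx_i, graph.idx_j, tvals, float(beta),
        degree.data.copy(),
    )
    op.radius_key = graph.radius
    return op


def random_walk_refine(activations: ScoreMap, operator: TransitionOperator,
                       iterations: int) -> ScoreMap:
    """Apply ``T^t`` to every class channel of the activation map."""
    if iterations < 0:
        raise ValueError("iteration count must be >= 0")
    c, h, w = activations.values.shape
    if (h, w) != operator.grid_shape:
        raise ValueError(
            f"activation grid {h}x{w} does not match operator grid "
            f"{operator.grid_shape[0]}x{operator.grid_shape[1]}"
        )
    if iterations == 0:
        return ScoreMap(activations.values, activations.resolution_tag)
    v = activations.values.reshape(c, h * w).T  # (n, C)
    for _ in range(iterations):
        v = operator.apply(v)
    out = v.T.reshape(c, h, w)
    return ScoreMap(out, activations.resolution_tag)
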