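"""Multi-hop graph attention (MGA) on convolutional feature maps.

The module turns a 4-D feature map (C × H × W × D) into a graph whose nodes
are pooled descriptors of spatial patches, propagates edge strengths over
``m`` Markov hops via the Chapman–Kolmogorov recursion, prunes weak edges
with a data-driven threshold, applies masked graph self-attention, and
reassembles the attended patches into a feature map of the original size.

This file provides the *functional*, single-map numpy implementation: it is
the readable reference for the mathematics, used directly by analysis code
and tests.  The trainable, batched implementation inside the network
(:mod:`brainmga.backbone`) shares the same geometry helpers and is checked
against this one in the test suite.

Pipeline per branch (split ratio γ)::

    extract_patches → aggregate_nodes → edge_scores → row_normalize
      → multi_hop_edges → compute_threshold → threshold_edges
      → masked_attention → update_patches → reassemble

``k`` branches with different γ run in parallel and their outputs are
averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidSplitError",
    "InvalidConfigError",
    "PatchGeometry",
    "PatchSet",
    "MGAParams",
    "MGAConfig",
    "grid_offsets",
    "extract_patches",
    "patch_flat_index",
    "aggregate_nodes",
    "edge_scores",
    "row_normalize",
    "multi_hop_edges",
    "compute_threshold",
    "threshold_edges",
    "masked_attention",
    "update_patches",
    "reassemble",
    "mga_forward",
    "init_params",
]

#: distances are clipped here before exponentiation so that a row of the raw
#: edge matrix can never underflow to all-zeros off the diagonal
DISTANCE_CLIP = 50.0

#: negative-region slope of the LeakyReLU in the attention logits
DEFAULT_LEAKY_SLOPE = 0.2


class InvalidSplitError(ValueError):
    """A spatial extent is too small for the requested split ratio."""


class InvalidConfigError(ValueError):
    """An MGA hyperparameter is outside its valid range."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchGeometry:
    """Where the patches of one split ratio sit inside a feature map.

    ``placements`` enumerates spatial offsets on a regular grid, ordered
    row-major over (H, W, D) — D varies fastest — which fixes the node
    numbering that the edge threshold's superdiagonal refers to.
    """

    gamma: int
    channels: int
    map_extent: tuple  # (H, W, D)
    patch_extent: tuple  # (h_p, w_p, d_p)
    stride: int
    placements: tuple  # ((oh, ow, od), ...)

    @property
    def n_patches(self) -> int:
        return len(self.placements)

    @property
    def patch_size(self) -> int:
        h, w, d = self.patch_extent
        return self.channels * h * w * d


@dataclass
class PatchSet:
    """Vectorized patches (one per row) plus the geometry to invert them."""

    patches: np.ndarray  # (N_p, S)
    geometry: PatchGeometry


@dataclass
class MGAParams:
    """Learnable parameters of one attention branch.

    ``V`` embeds the 2-vector node descriptors; ``a`` scores a concatenated
    pair of embeddings, logit(i, j) = aᵀ[V h_i ‖ V h_j].  Each branch owns
    an independent (V, a) pair.
    """

    V: np.ndarray  # (2, 2)
    a: np.ndarray  # (4,)

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.V.shape != (2, 2) or self.a.shape != (4,):
            raise InvalidConfigError("V must be 2x2 and a length-4")
        if not (np.all(np.isfinite(self.V)) and np.all(np.isfinite(self.a))):
            raise InvalidConfigError("MGA parameters must be finite")


@dataclass
class MGAConfig:
    """Hyperparameters of the MGA module.

    Defaults follow the fine-tuned setting of the published model:
    m = 3 hops, k = 2 branches with split ratios γ = {2, 4}, hop weight
    β = 0.8.
    """

    m: int = 3
    k: int = 2
    gammas: Sequence[int] = (2, 4)
    beta: float = 0.8
    leaky_slope: float = DEFAULT_LEAKY_SLOPE
    drop_path_rate: float = 0.1

    def __post_init__(self):
        self.gammas = tuple(int(g) for g in self.gammas)
        if self.m < 1:
            raise InvalidConfigError(f"hop count m must be >= 1, got {self.m}")
        if self.k < 1:
            raise InvalidConfigError(f"branch count k must be >= 1, got {self.k}")
        if len(self.gammas) != self.k:
            raise InvalidConfigError(
                f"need one split ratio per branch: k={self.k}, gammas={self.gammas}"
            )
        if any(g < 1 for g in self.gammas):
            raise InvalidConfigError("split ratios must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise InvalidConfigError(f"beta must be in (0, 1], got {self.beta}")
        if not (0.0 <= self.drop_path_rate < 1.0):
            raise InvalidConfigError("drop_path_rate must be in [0, 1)")


def grid_offsets(extent: int, patch: int, stride: int) -> tuple:
    """Patch start offsets along one axis under the full-coverage rule.

    Offsets march at ``stride`` while a patch still fits; if the final
    regular placement leaves trailing voxels uncovered, one extra placement
    anchored at ``extent - patch`` is appended so every voxel is covered.
    """
    offsets = list(range(0, extent - patch + 1, stride))
    if offsets[-1] + patch < extent:
        offsets.append(extent - patch)
    return tuple(offsets)


def _geometry(shape: tuple, gamma: int) -> PatchGeometry:
    C, H, W, D = shape
    names = ("H", "W", "D")
    for name, ext in zip(names, (H, W, D)):
        if ext // gamma < 1:
            raise InvalidSplitError(
                f"axis {name} (extent {ext}) cannot be split by gamma={gamma}"
            )
    hp, wp, dp = H // gamma, W // gamma, D // gamma
    stride = min(hp, wp, dp)
    placements = tuple(
        (oh, ow, od)
        for oh in grid_offsets(H, hp, stride)
        for ow in grid_offsets(W, wp, stride)
        for od in grid_offsets(D, dp, stride)
    )
    return PatchGeometry(gamma, C, (H, W, D), (hp, wp, dp), stride, placements)


def patch_flat_index(geom: PatchGeometry) -> np.ndarray:
    """(N_p, S) flat indices into a raveled (C, H, W, D) array.

    Row i lists, in C-order of the patch block, the positions of patch i's
    voxels; shared by patch extraction (gather) and reassembly (scatter).
    """
    C = geom.channels
    H, W, D = geom.map_extent
    hp, wp, dp = geom.patch_extent
    c, h, w, d = np.meshgrid(
        np.arange(C), np.arange(hp), np.arange(wp), np.arange(dp), indexing="ij"
    )
    base = (((c * H) + h) * W + w) * D + d  # flat index of patch block at origin
    base = base.reshape(-1)
    offs = np.array(
        [((oh * W) + ow) * D + od for (oh, ow, od) in geom.placements], dtype=np.int64
    )
    return offs[:, None] + base[None, :]


def extract_patches(fmap: np.ndarray, gamma: int) -> PatchSet:
    """Split a (C, H, W, D) feature map into a grid of vectorized patches.

    The patch extent is C × H//γ × W//γ × D//γ with stride
    min(H//γ, W//γ, D//γ); overlapping placements arise on axes whose patch
    extent exceeds the stride, and a clipped final placement guarantees
    full coverage on non-divisible extents.
    """
    fmap = np.asarray(fmap)
    if fmap.ndim != 4:
        raise ValueError(f"feature map must be 4-D (C,H,W,D), got {fmap.shape}")
    geom = _geometry(fmap.shape, gamma)
    idx = patch_flat_index(geom)
    return PatchSet(fmap.reshape(-1)[idx], geom)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def aggregate_nodes(patches: PatchSet | np.ndarray) -> np.ndarray:
    """Node descriptors (N_p, 2): per-patch global average and max pooling."""
    P = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    if P.ndim != 2 or P.shape[1] < 1:
        raise ValueError("patch matrix must be (N_p, S) with S >= 1")
    return np.stack([P.mean(axis=1), P.max(axis=1)], axis=1)


def edge_scores(nodes: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Raw similarity edges e_ij = 1 / exp(‖V h_i − V h_j‖₂).

    Symmetric with unit diagonal: a node's similarity to itself is exactly
    1, so every node can attend to itself.  Distances are clipped at
    ``DISTANCE_CLIP`` before exponentiation so no row underflows to zero.
    """
    nodes = np.asarray(nodes, dtype=float)
    V = np.asarray(V, dtype=float)
    if not (np.all(np.isfinite(nodes)) and np.all(np.isfinite(V))):
        raise ValueError("nodes and V must be finite")
    z = nodes @ V.T  # (N_p, 2) embedded nodes
    diff = z[:, None, :] - z[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    E = np.exp(-np.minimum(dist, DISTANCE_CLIP))
    np.fill_diagonal(E, 1.0)
    return E


def row_normalize(E: np.ndarray) -> np.ndarray:
    """Row-stochastic normalization Ẽ = D⁻¹E with d_ii = Σ_j e_ij."""
    E = np.asarray(E, dtype=float)
    deg = E.sum(axis=1, keepdims=True)
    return E / deg


def multi_hop_edges(E_tilde: np.ndarray, m: int, beta: float) -> np.ndarray:
    """β-weighted sum of hop powers, symmetrized.

    E∀m = Σ_{j=1..m} β^{j−1} Ẽ^j (Chapman–Kolmogorov: Ẽ^j is the j-hop
    transition matrix), then (E∀m + E∀mᵀ)/2 to restore the undirected-graph
    symmetry.  Powers are built by iterated multiplication.
    """
    if m < 1:
        raise InvalidConfigError(f"hop count m must be >= 1, got {m}")
    if not (0.0 < beta <= 1.0):
        raise InvalidConfigError(f"beta must be in (0, 1], got {beta}")
    E_tilde = np.asarray(E_tilde, dtype=float)
    power = E_tilde.copy()
    acc = E_tilde.copy()
    for j in range(1, m):
        power = power @ E_tilde
        acc = acc + beta**j * power
    return (acc + acc.T) / 2.0


def compute_threshold(E_all: np.ndarray) -> float:
    """Edge-pruning threshold θ: mean superdiagonal strength.

    The superdiagonal entries (i, i+1) are the edges between consecutively
    numbered nodes — the kind of direct link a conventional one-hop graph
    network would use — so their average calibrates which multi-hop edges
    count as "connected".  A single-node graph has no such entries and gets
    θ = 0.
    """
    E_all = np.asarray(E_all)
    n = E_all.shape[0]
    if n < 2:
        return 0.0
    return float(np.diagonal(E_all, offset=1).mean())


def threshold_edges(E_all: np.ndarray, theta: float) -> np.ndarray:
    """Binary adjacency: strictly greater-than-θ, self-loops forced on."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    A = (np.asarray(E_all) > theta).astype(float)
    np.fill_diagonal(A, 1.0)
    return A


# ---------------------------------------------------------------------------
# attention and update
# ---------------------------------------------------------------------------


def masked_attention(
    nodes: np.ndarray,
    adjacency: np.ndarray,
    params: MGAParams,
    leaky_slope: float = DEFAULT_LEAKY_SLOPE,
) -> np.ndarray:
    """Masked graph self-attention coefficients α (N_p × N_p).

    logit(i, j) = aᵀ[V h_i ‖ V h_j] through a LeakyReLU, soft-maxed over
    each node's binary neighborhood; α is exactly zero outside it and each
    row sums to 1 (the forced self-loop keeps every neighborhood nonempty).
    """
    nodes = np.asarray(nodes, dtype=float)
    adjacency = np.asarray(adjacency)
    z = nodes @ params.V.T
    li = z @ params.a[:2]
    lj = z @ params.a[2:]
    logits = li[:, None] + lj[None, :]
    logits = np.where(logits >= 0, logits, leaky_slope * logits)
    neg_inf = np.full_like(logits, -np.inf)
    masked = np.where(adjacency > 0, logits, neg_inf)
    masked = masked - masked.max(axis=1, keepdims=True)
    ex = np.exp(masked)
    return ex / ex.sum(axis=1, keepdims=True)


def update_patches(patches: PatchSet, alpha: np.ndarray) -> PatchSet:
    """Attention-weighted patch update P′ = αP; geometry unchanged."""
    alpha = np.asarray(alpha)
    if alpha.shape[0] != patches.patches.shape[0]:
        raise ValueError(
            f"attention is {alpha.shape} but patch set has {patches.patches.shape[0]} rows"
        )
    return PatchSet(alpha @ patches.patches, patches.geometry)


def reassemble(patches: PatchSet) -> np.ndarray:
    """Put patches back into a (C, H, W, D) map; overlaps are averaged.

    Every voxel is covered by at least one patch (coverage rule), so the
    voxelwise mean over covering patches is always defined and the
    extract → reassemble round trip with untouched patches is exact.
    """
    geom = patches.geometry
    idx = patch_flat_index(geom)
    size = geom.channels * int(np.prod(geom.map_extent))
    total = np.bincount(idx.reshape(-1), weights=patches.patches.reshape(-1), minlength=size)
    count = np.bincount(idx.reshape(-1), minlength=size)
    return (total / count).reshape((geom.channels,) + geom.map_extent)


# ---------------------------------------------------------------------------
# full module forward
# ---------------------------------------------------------------------------


def init_params(rng: np.random.Generator, scale: float = 0.5) -> MGAParams:
    """Independent Gaussian init of one branch's (V, a)."""
    return MGAParams(V=rng.normal(0.0, scale, (2, 2)), a=rng.normal(0.0, scale, 4))


def branch_forward(
    fmap: np.ndarray,
    gamma: int,
    params: MGAParams,
    m: int,
    beta: float,
    leaky_slope: float = DEFAULT_LEAKY_SLOPE,
) -> np.ndarray:
    """One attention branch: full patch → graph → attention → map pipeline."""
    pset = extract_patches(fmap, gamma)
    nodes = aggregate_nodes(pset)
    E = edge_scores(nodes, params.V)
    E_tilde = row_normalize(E)
    E_all = multi_hop_edges(E_tilde, m, beta)
    theta = compute_threshold(E_all)
    A = threshold_edges(E_all, theta)
    alpha = masked_attention(nodes, A, params, leaky_slope)
    updated = update_patches(pset, alpha)
    return reassemble(updated)


def mga_forward(
    fmap: np.ndarray,
    config: MGAConfig,
    params: Sequence[MGAParams],
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> np.ndarray:
    """Run all k branches and average their updated feature maps.

    During training each branch is independently dropped with probability
    ``config.drop_path_rate`` (drop path); surviving branches are averaged.
    If every branch is dropped the input map passes through unchanged.
    Output extents always equal input extents.
    """
    if len(params) != config.k:
        raise InvalidConfigError(
            f"expected {config.k} parameter sets, got {len(params)}"
        )
    fmap = np.asarray(fmap, dtype=float)
    outputs = []
    for gamma, p in zip(config.gammas, params):
        if training and rng is not None and rng.random() < config.drop_path_rate:
            continue
        outputs.append(
            branch_forward(fmap, gamma, p, config.m, config.beta, config.leaky_slope)
        )
    if not outputs:
        return fmap.copy()
    return np.mean(outputs, axis=0)
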