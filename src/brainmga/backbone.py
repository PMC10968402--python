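"""MGA-sSE-ResNet18: a 3D residual network for brain-age regression.

Architecture (8 residual units total, two per stage)::

    stem:   7×7×7 conv, 64, stride 2  →  3×3×3 max pool, stride 2
    stage1: 2 × [conv3–conv3, 64]   + sSE ∥ MGA
    stage2: 2 × [conv3–conv3, 128]  + sSE ∥ MGA   (entry stride 2)
    stage3: 2 × [conv3–conv3, 256]  + sSE ∥ MGA   (entry stride 2)
    stage4: 2 × [conv3–conv3, 512]  + sSE ∥ MGA   (entry stride 2)
    head:   global average pool → [optional sex one-hot ‖] → linear(1)

Each residual unit computes ``y = relu(bn(conv(relu(bn(conv(x))))) + skip(x))``
and then ``z = y + mean(sSE(y), MGA(y))`` — an inner skip across the two
convolutions and an outer skip across the parallel attention/excitation
pair.  Either module can be toggled off; with both off the unit is a plain
ResNet basic block.

Every stride-2 operation halves each spatial extent exactly as ``n // 2``
(parity-aware padding), which reproduces the published size ladder
101×101×121 → 50×50×60 → 25×25×30 → 12×12×15 → 6×6×7 → global pool.

The MGA layer here is the batched, trainable counterpart of the functional
pipeline in :mod:`brainmga.mga`; both share the same patch geometry and are
cross-checked in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .mga import (
    DISTANCE_CLIP,
    InvalidConfigError,
    MGAConfig,
    PatchGeometry,
    _geometry,
    patch_flat_index,
)

__all__ = [
    "ModelSpec",
    "SpatialSE",
    "MGALayer",
    "ResidualUnit",
    "MGASSEResNet18",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1

#: minimal spatial extent: five stride-2 halvings must leave at least 1 voxel
MIN_EXTENT = 32

STAGE_MULTIPLIERS = (1, 2, 4, 8)
BLOCKS_PER_STAGE = 2


@dataclass
class ModelSpec:
    """Configuration of the regression network.

    ``base_width`` scales the channel ladder (64 → 128 → 256 → 512 at the
    published width 64); desk-scale runs use 16 (quarter width).  ``use_sse``
    / ``use_mga`` toggle the parallel modules; disabling both yields plain
    ResNet18.  ``with_sex`` appends a 2-dim one-hot sex vector to the pooled
    features before the regression head.
    """

    base_width: int = 64
    use_sse: bool = True
    use_mga: bool = True
    mga: MGAConfig = field(default_factory=MGAConfig)
    with_sex: bool = False
    in_channels: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if isinstance(d.get("mga"), dict):
            d["mga"] = MGAConfig(**d["mga"])
        return cls(**d)


def _halving_padding(extent: int, kernel: int) -> int:
    """Padding p with (extent + 2p − kernel)//2 + 1 == extent // 2."""
    for p in range(kernel):
        if (extent + 2 * p - kernel) // 2 + 1 == extent // 2:
            return p
    raise ValueError(f"no halving padding for extent {extent}, kernel {kernel}")


class _HalvingConv(nn.Module):
    """Stride-2 conv whose per-axis padding is chosen so output = input // 2."""

    def __init__(self, cin, cout, kernel, rng, bias=False):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, kernel, stride=2, padding=0, bias=bias, rng=rng)
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        if self.kernel == 1:
            # a 1×1×1 stride-2 map floor-halves by dropping the first voxel
            # of each axis and sampling every other one
            x = x[:, :, 1:, 1:, 1:]
            return self.conv(x)
        pads = [(_halving_padding(e, self.kernel),) * 2 for e in x.shape[2:]]
        x = ad.pad_nd(x, ((0, 0), (0, 0)) + tuple(pads))
        return self.conv(x)


class _HalvingMaxPool(nn.Module):
    def __init__(self, kernel=3):
        super().__init__()
        self.kernel = kernel
        self.pool = nn.MaxPool3d(kernel, stride=2, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        pads = [(_halving_padding(e, self.kernel),) * 2 for e in x.shape[2:]]
        x = ad.pad_nd(x, ((0, 0), (0, 0)) + tuple(pads), value=-1e30)
        return self.pool(x)


class SpatialSE(nn.Module):
    """Spatial squeeze-and-excitation: channel squeeze, spatial excitation.

    All channels are projected to a single spatial gate through a 1×1×1
    convolution and a sigmoid; the input map is rescaled voxelwise by the
    gate, broadcast over channels.  Shape preserving.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv3d(channels, 1, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        gate = ad.sigmoid(self.proj(x))
        return x * gate


class _BranchParams(nn.Module):
    """Learnable (V, a) of one MGA branch; independent per branch."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.V = nn.Parameter(rng.normal(0.0, 0.5, (2, 2)))
        self.a = nn.Parameter(rng.normal(0.0, 0.5, 4))


class MGALayer(nn.Module):
    """Batched multi-hop graph attention over a (N, C, H, W, D) tensor.

    Mirrors the functional pipeline in :mod:`brainmga.mga` per sample and
    branch; the edge threshold θ and the binary neighborhood are recomputed
    each forward pass from the current edge values but treated as constants
    under differentiation (gradients flow through the attention logits and
    the patch values only).

    Branches whose split ratio exceeds the smallest spatial extent of the
    incoming map are clamped to it, so the layer stays valid in the deepest
    stages of small desk-scale volumes (γ_eff = 1 degenerates to a single
    whole-map patch and an identity update).

    During training, drop path disables each branch independently with
    probability ``config.drop_path_rate``; surviving branches are averaged
    and a forward with every branch dropped is an identity.
    """

    _geom_cache: dict = {}

    def __init__(self, config: MGAConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        self.branches = nn.ModuleList([_BranchParams(rng) for _ in range(config.k)])
        self._droprng = drop_rng or np.random.default_rng(0)

    # -- geometry -----------------------------------------------------------

    @classmethod
    def _indices(cls, shape: tuple, gamma: int):
        key = (shape, gamma)
        hit = cls._geom_cache.get(key)
        if hit is not None:
            return hit
        geom = _geometry(shape, gamma)
        idx = patch_flat_index(geom)
        count = np.bincount(idx.reshape(-1), minlength=int(np.prod(shape)))
        offdiag = (1.0 - np.eye(geom.n_patches)).astype(nn.DTYPE)
        out = (geom, idx, count.astype(nn.DTYPE), offdiag)
        cls._geom_cache[key] = out
        return out

    # -- forward ------------------------------------------------------------

    def _branch_forward(self, x: Tensor, branch: _BranchParams, gamma: int) -> Tensor:
        N, C, H, W, D = x.shape
        gamma_eff = max(1, min(gamma, H, W, D))
        geom, idx, count, offdiag = self._indices((C, H, W, D), gamma_eff)
        npatch = geom.n_patches
        item = C * H * W * D
        bidx = nn._batched_index(idx, N, item)

        P = ad.take_flat(x, bidx)  # (N, N_p, S)
        gap = P.mean(axis=2)
        gmp = P.max(axis=2)
        nodes = ad.concatenate(
            [gap.reshape((N, npatch, 1)), gmp.reshape((N, npatch, 1))], axis=2
        )

        z = ad.matmul(nodes, branch.V.swapaxes(0, 1))  # (N, N_p, 2)
        diff = z.reshape((N, npatch, 1, 2)) - z.reshape((N, 1, npatch, 2))
        sq = (diff * diff).sum(axis=3)
        # eps keeps sqrt differentiable at coincident embeddings; the exact
        # unit diagonal is restored by masking
        dist = ad.sqrt(sq + 1e-12) * offdiag
        E = ad.exp(-ad.clip_max(dist, DISTANCE_CLIP))

        E_tilde = E / E.sum(axis=2, keepdims=True)
        acc = E_tilde
        power = E_tilde
        for j in range(1, self.config.m):
            power = ad.matmul(power, E_tilde)
            acc = acc + (self.config.beta**j) * power
        E_all = (acc + acc.transpose((0, 2, 1))) * 0.5

        # θ and the adjacency are data-driven constants (non-differentiable)
        ea = E_all.data
        if npatch >= 2:
            sup = np.stack([np.diagonal(ea[i], offset=1) for i in range(N)])
            theta = sup.mean(axis=1)[:, None, None]
        else:
            theta = np.zeros((N, 1, 1), dtype=ea.dtype)
        adj = (ea > theta).astype(nn.DTYPE)
        eye = np.eye(npatch, dtype=nn.DTYPE)
        adj = np.maximum(adj, eye)

        li = ad.matmul(z, branch.a[:2])  # (N, N_p)
        lj = ad.matmul(z, branch.a[2:])
        logits = li.reshape((N, npatch, 1)) + lj.reshape((N, 1, npatch))
        logits = ad.leaky_relu(logits, self.config.leaky_slope)
        rowmax = np.where(adj > 0, logits.data, -np.inf).max(axis=2, keepdims=True)
        ex = ad.exp(logits - rowmax) * adj
        alpha = ex / ex.sum(axis=2, keepdims=True)

        updated = ad.matmul(alpha, P)
        flat = ad.scatter_add_flat(updated, bidx, N * item)
        out = flat.reshape((N, C, H, W, D)) / count.reshape((1, C, H, W, D))
        return out

    def forward(self, x: Tensor) -> Tensor:
        outs = []
        for branch, gamma in zip(self.branches, self.config.gammas):
            if (
                self.training
                and self.config.drop_path_rate > 0
                and self._droprng.random() < self.config.drop_path_rate
            ):
                continue
            outs.append(self._branch_forward(x, branch, gamma))
        if not outs:
            return x
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        return acc * (1.0 / len(outs))


class ResidualUnit(nn.Module):
    """conv–bn–relu–conv–bn + inner skip, then parallel sSE ∥ MGA + outer skip."""

    def __init__(self, cin, cout, downsample, use_sse, use_mga, mga_config,
                 seed=(0,)):
        super().__init__()
        # independent streams per component: toggling sSE/MGA must not shift
        # the initialisation of anything else (exact ablation parity)
        seed = (seed,) if np.isscalar(seed) else tuple(seed)
        conv_rng = np.random.default_rng((*seed, 0))
        sse_rng = np.random.default_rng((*seed, 1))
        mga_rng = np.random.default_rng((*seed, 2))
        drop_rng = np.random.default_rng((*seed, 3))
        if downsample:
            self.conv1 = _HalvingConv(cin, cout, 3, conv_rng)
        else:
            if cin != cout:
                raise InvalidConfigError(
                    f"channel mismatch without downsampling: {cin} -> {cout}"
                )
            self.conv1 = nn.Conv3d(cin, cout, 3, stride=1, padding=1, bias=False,
                                   rng=conv_rng)
        self.bn1 = nn.BatchNorm3d(cout)
        self.conv2 = nn.Conv3d(cout, cout, 3, stride=1, padding=1, bias=False,
                               rng=conv_rng)
        self.bn2 = nn.BatchNorm3d(cout)
        self.downsample = downsample
        if downsample:
            self.skip_conv = _HalvingConv(cin, cout, 1, conv_rng)
            self.skip_bn = nn.BatchNorm3d(cout)
        self.sse = SpatialSE(cout, sse_rng) if use_sse else None
        self.mga = MGALayer(mga_config, mga_rng, drop_rng) if use_mga else None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        skip = self.skip_bn(self.skip_conv(x)) if self.downsample else x
        y = ad.relu(out + skip)
        parts = []
        if self.sse is not None:
            parts.append(self.sse(y))
        if self.mga is not None:
            parts.append(self.mga(y))
        if not parts:
            return y
        acc = parts[0]
        for p in parts[1:]:
            acc = acc + p
        return y + acc * (1.0 / len(parts))


class MGASSEResNet18(nn.Module):
    """The full brain-age regression network."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        self.seed = seed
        w = spec.base_width
        self.stem_conv = _HalvingConv(
            spec.in_channels, w, 7, np.random.default_rng((seed, 100)), bias=False
        )
        self.stem_bn = nn.BatchNorm3d(w)
        self.stem_pool = _HalvingMaxPool(3)
        units = []
        cin = w
        unit_index = 0
        for si, mult in enumerate(STAGE_MULTIPLIERS):
            cout = w * mult
            for bi in range(BLOCKS_PER_STAGE):
                downsample = si > 0 and bi == 0
                units.append(
                    ResidualUnit(
                        cin, cout, downsample, spec.use_sse, spec.use_mga,
                        spec.mga, seed=(seed, 10 + unit_index),
                    )
                )
                cin = cout
                unit_index += 1
        self.units = nn.ModuleList(units)
        head_in = w * STAGE_MULTIPLIERS[-1] + (2 if spec.with_sex else 0)
        self.head = nn.Linear(head_in, 1, rng=np.random.default_rng((seed, 200)))

    # -- introspection -------------------------------------------------------

    @property
    def n_residual_units(self) -> int:
        return len(self.units)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward -------------------------------------------------------------

    def forward(self, x: Tensor, sex: Tensor | None = None) -> Tensor:
        """x: (N, C, H, W, D) → (N,) predicted ages in years."""
        for e in x.shape[2:]:
            if e < MIN_EXTENT:
                raise ValueError(
                    f"spatial extent {e} < minimum {MIN_EXTENT}: "
                    "five stride-2 halvings would leave no voxels"
                )
        h = ad.relu(self.stem_bn(self.stem_conv(x)))
        h = self.stem_pool(h)
        for unit in self.units:
            h = unit(h)
        feats = nn.global_avg_pool(h)  # (N, C_last)
        if self.spec.with_sex:
            if sex is None:
                raise ValueError("model was built with_sex=True; pass a sex one-hot")
            feats = ad.concatenate([feats, Tensor._coerce(sex)], axis=1)
        return self.head(feats).reshape((x.shape[0],))

    def predict(self, volume: np.ndarray, sex: np.ndarray | None = None) -> float:
        """Predict age (years) for one volume (H,W,D) or (C,H,W,D)."""
        vol = np.asarray(volume, dtype=nn.DTYPE)
        if vol.ndim == 3:
            vol = vol[None]
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                s = None
                if sex is not None:
                    s = np.asarray(sex, dtype=nn.DTYPE).reshape(1, 2)
                out = self.forward(Tensor(vol[None]), s)
        finally:
            self.train(was_training)
        return float(out.data[0])


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> MGASSEResNet18:
    """Deterministically construct the network from a spec and seed."""
    return MGASSEResNet18(spec or ModelSpec(), seed=seed)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: MGASSEResNet18, extra: dict | None = None) -> None:
    """Self-describing archive: parameters + buffers + spec + version."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "spec": model.spec.to_dict(),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple:
    """Returns (model, extra-dict)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('version')!r}"
            )
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec = ModelSpec.from_dict(meta["spec"])
    model = MGASSEResNet18(spec)
    model.load_state_dict(state)
    return model, meta.get("extra", {})
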