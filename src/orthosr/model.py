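"""The two-input densely connected 3D super-resolution network.

The network follows the mDCSRN pattern: an initial 3x3x3 convolution, a chain
of dense blocks whose units (norm -> ELU -> 3x3x3 conv, each emitting
``growth_rate`` features) see the concatenation of every earlier feature in
the block, a 1x1x1 compression convolution after each block, and a final
1x1x1 convolution down to one channel.  The free wiring constants are fixed so
that the reference configuration (growth 8, 8 blocks, 4 units, 2 input
channels) has 248K trainable parameters: the initial convolution emits
``8 x growth`` features and each compression reduces to ``2 x growth``.
A parameter-free global residual adds the mean of the two input channels to
the network output, so the convolutional path predicts the correction to the
linearly fused input (residual learning, standard in super-resolution; it
leaves the parameter count untouched and makes small-budget training viable).

Spatial size is preserved everywhere, so the network is fully convolutional:
it trains on 40^3 patches and runs on any patch size.  Whole volumes are
reconstructed by tiling overlapping patches and averaging with per-voxel
normalised weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import ELU, BatchNorm3d, Conv3d
from .volumes import VolumeGrid, resample_to_grid

__all__ = [
    "ModelConfig",
    "MDCSRN",
    "ChannelMeanNet",
    "build_mdcsrn",
    "count_parameters",
    "upsample_concat",
    "PatchLayout",
    "make_patch_layout",
    "predict_patch",
    "reconstruct_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``init_features`` and ``compress_to`` default to ``8 x growth`` and
    ``2 x growth`` respectively — the wiring constants that reproduce the
    reference 248K parameter count.
    """

    growth_rate: int = 8
    num_blocks: int = 8
    units_per_block: int = 4
    in_channels: int = 2
    patch_size_mm: int = 40
    init_features: int | None = None
    compress_to: int | None = None

    def __post_init__(self) -> None:
        if self.init_features is None:
            self.init_features = 8 * self.growth_rate
        if self.compress_to is None:
            self.compress_to = 2 * self.growth_rate
        for v in (self.growth_rate, self.num_blocks, self.units_per_block,
                  self.in_channels, self.patch_size_mm,
                  self.init_features, self.compress_to):
            if int(v) != v or v <= 0:
                raise ValueError("all ModelConfig fields must be positive integers")


class _DenseUnit:
    """norm -> ELU -> 3^3 conv emitting growth_rate features."""

    def __init__(self, in_channels: int, growth: int, rng):
        self.bn = BatchNorm3d(in_channels)
        self.act = ELU()
        self.conv = Conv3d(in_channels, growth, 3, rng)

    def forward(self, x, train=False):
        return self.conv.forward(self.act.forward(self.bn.forward(x, train), train),
                                 train)

    def backward(self, dout):
        return self.bn.backward(self.act.backward(self.conv.backward(dout)))

    @property
    def n_params(self):
        return self.bn.n_params + self.conv.n_params


class MDCSRN:
    """Densely connected super-resolution network (numpy implementation)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        k, n0, nc = config.growth_rate, config.init_features, config.compress_to
        self.conv0 = Conv3d(config.in_channels, n0, 3, rng)
        self.blocks: list[list[_DenseUnit]] = []
        self.compressors: list[Conv3d] = []
        cur = n0
        for _ in range(config.num_blocks):
            units = []
            c = cur
            for _ in range(config.units_per_block):
                units.append(_DenseUnit(c, k, rng))
                c += k
            self.blocks.append(units)
            self.compressors.append(Conv3d(c, nc, 1, rng))
            cur = nc
        self.final = Conv3d(cur, 1, 1, rng, scale=1e-2)
        self._cache = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, in_channels, D, H, W) -> (N, 1, D, H, W).

        The output is the mean of the input channels (the linearly fused
        volume) plus the convolutional correction — a parameter-free global
        residual, so the network learns the *difference* between interpolation
        fusion and the HR target rather than the identity map.  With the final
        convolution zeroed the network reduces exactly to linear fusion.
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}")
        skip = x.mean(axis=1, keepdims=True)
        feats_sizes = []
        h = self.conv0.forward(x, train)
        for units, comp in zip(self.blocks, self.compressors):
            feats = [h]
            for unit in units:
                cat = np.concatenate(feats, axis=1)
                feats.append(unit.forward(cat, train))
            cat = np.concatenate(feats, axis=1)
            h = comp.forward(cat, train)
            feats_sizes.append([f.shape[1] for f in feats])
        out = self.final.forward(h, train) + skip
        if train:
            self._cache = feats_sizes
        return out

    def backward(self, dout: np.ndarray) -> None:
        feats_sizes = self._cache
        dh = self.final.backward(dout)
        for units, comp, sizes in zip(reversed(self.blocks),
                                      reversed(self.compressors),
                                      reversed(feats_sizes)):
            dcat = comp.backward(dh)
            # split the concat gradient back onto the block's feature list
            splits = np.cumsum(sizes)[:-1]
            dfeats = list(np.split(dcat, splits, axis=1))
            for i in range(len(units) - 1, -1, -1):
                dunit_in = units[i].backward(dfeats[i + 1])
                dparts = np.split(dunit_in, np.cumsum(sizes[: i + 1])[:-1], axis=1)
                for j, dp in enumerate(dparts):
                    dfeats[j] = dfeats[j] + dp
            dh = dfeats[0]
        self.conv0.backward(dh)

    # -- parameters ---------------------------------------------------------

    def _layers(self):
        yield self.conv0
        for units, comp in zip(self.blocks, self.compressors):
            for u in units:
                yield u.bn
                yield u.conv
            yield comp
        yield self.final

    def param_grads(self):
        out = []
        for layer in self._layers():
            if isinstance(layer, Conv3d):
                out.append((layer.W, layer.dW))
                out.append((layer.b, layer.db))
            elif isinstance(layer, BatchNorm3d):
                out.append((layer.gamma, layer.dgamma))
                out.append((layer.beta, layer.dbeta))
        return out

    def state_arrays(self):
        """All arrays defining the model state (params + BN running stats)."""
        out = []
        for layer in self._layers():
            if isinstance(layer, Conv3d):
                out += [layer.W, layer.b]
            elif isinstance(layer, BatchNorm3d):
                out += [layer.gamma, layer.beta,
                        layer.running_mean, layer.running_var]
        return out

    def get_state(self):
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state):
        for a, s in zip(self.state_arrays(), state):
            a[...] = s

    def zero_grad(self):
        for _, g in self.param_grads():
            g[...] = 0.0


class ChannelMeanNet:
    """Surrogate network whose output is the mean of the input channels.

    Used as an analytic oracle: reconstructing a volume with this network must
    reproduce the linearly fused (channel-averaged) volume exactly, which
    isolates the patch-aggregation arithmetic from the learned weights.
    """

    def __init__(self, in_channels: int = 2):
        self.config = ModelConfig(in_channels=in_channels)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        return x.mean(axis=1, keepdims=True)


def build_mdcsrn(config: ModelConfig | None = None, seed: int = 0) -> MDCSRN:
    """Instantiate the network from a configuration."""
    return MDCSRN(config or ModelConfig(), seed=seed)


def count_parameters(network) -> int:
    """Exact number of trainable scalars in the network."""
    if isinstance(network, ChannelMeanNet):
        return 0
    return int(sum(p.size for p, _ in network.param_grads()))


# ---------------------------------------------------------------------------
# Upsample + concatenate front end


def upsample_concat(X1: VolumeGrid, X2: VolumeGrid,
                    grid: tuple | None = None,
                    target_spacing: float = 1.0,
                    method: str = "linear"):
    """Resample both views to a common isotropic grid and stack as channels.

    If *grid* (shape, spacing, origin) is not given, the target covers the
    union of the two views' voxel-center extents at ``target_spacing``.
    Returns ``(channels, grid)`` with ``channels`` of shape (2, D, H, W).
    """
    if grid is None:
        lo = [min(a, b) for a, b in zip(X1.origin, X2.origin)]
        hi = [max(a, b) for a, b in zip(*[
            [o + e for o, e in zip(v.origin, v.extent_mm())] for v in (X1, X2)])]
        shape = tuple(int(np.floor((h - l) / target_spacing + 1e-6)) + 1
                      for l, h in zip(lo, hi))
        grid = (shape, (target_spacing,) * 3, tuple(lo))
    shape, spacing, origin = grid
    chans = [
        resample_to_grid(v, shape, spacing, origin, method).values
        for v in (X1, X2)
    ]
    return np.stack(chans).astype(np.float32), grid


# ---------------------------------------------------------------------------
# Patch tiling and aggregation


@dataclass
class PatchLayout:
    """Overlapping patch origins plus normalised aggregation weights."""

    shape: tuple[int, int, int]
    patch: int
    stride: int
    origins: list[tuple[int, int, int]]

    def __iter__(self):
        return iter(self.origins)


def _axis_origins(dim: int, patch: int, stride: int) -> list[int]:
    if dim <= patch:
        return [0]
    starts = list(range(0, dim - patch, stride))
    starts.append(dim - patch)
    return starts


def make_patch_layout(shape, patch: int = 40, stride: int = 20) -> PatchLayout:
    """Tile *shape* with overlapping cubes of edge *patch* at *stride*."""
    if stride <= 0 or patch <= 0:
        raise ValueError("patch and stride must be positive")
    per_axis = [_axis_origins(n, patch, stride) for n in shape]
    origins = [(i, j, k) for i in per_axis[0] for j in per_axis[1]
               for k in per_axis[2]]
    return PatchLayout(tuple(shape), patch, stride, origins)


def predict_patch(network, patch: np.ndarray) -> np.ndarray:
    """Deterministic forward pass on one two-channel patch -> (D, H, W)."""
    out = network.forward(np.asarray(patch, dtype=np.float32), train=False)
    return out[0, 0]


def reconstruct_volume(network, X1: VolumeGrid, X2: VolumeGrid,
                       stride: int = 20, grid: tuple | None = None,
                       out_spacing=None) -> VolumeGrid:
    """Patchwise whole-volume inference.

    Upsamples and concatenates the two views onto the 1 mm grid, runs the
    network on overlapping ``patch_size`` cubes, and averages overlaps with
    per-voxel weights that sum to one.  Volumes smaller than one patch are
    reflect-padded and cropped back.  If *out_spacing* is given (native
    in-plane spacing finer than 1 mm), the output is resampled onto it.
    """
    channels, grid = upsample_concat(X1, X2, grid=grid)
    shape, spacing, origin = channels.shape[1:], grid[1], grid[2]
    if min(shape) == 0:
        raise ValueError("empty volume")
    p = network.config.patch_size_mm
    pad = [(0, max(p - n, 0)) for n in shape]
    work = np.pad(channels, [(0, 0)] + pad, mode="reflect") \
        if any(b for _, b in pad) else channels
    wshape = work.shape[1:]
    layout = make_patch_layout(wshape, p, stride)
    acc = np.zeros(wshape, dtype=np.float64)
    wsum = np.zeros(wshape, dtype=np.float64)
    for (i, j, k) in layout:
        sl = (slice(i, i + p), slice(j, j + p), slice(k, k + p))
        pred = predict_patch(network, work[(slice(None),) + sl])
        acc[sl] += pred
        wsum[sl] += 1.0
    out = (acc / wsum)[: shape[0], : shape[1], : shape[2]]
    vol = VolumeGrid(out, spacing, origin, X1.axes)
    if out_spacing is not None:
        from .volumes import resample
        vol = resample(vol, out_spacing, method="linear")
    return vol


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(network: MDCSRN, path) -> None:
    """Persist model state with the config embedded."""
    arrays = {f"a{i}": a for i, a in enumerate(network.state_arrays())}
    with open(path, "wb") as fh:  # keep the exact path (np.savez renames)
        np.savez(fh, config=json.dumps(asdict(network.config)), **arrays)


def load_checkpoint(path) -> MDCSRN:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["config"])))
        net = MDCSRN(config, seed=0)
        n = len(net.state_arrays())
        net.set_state([data[f"a{i}"] for i in range(n)])
    return net
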