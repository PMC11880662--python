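"""Patch corpus construction, the minimum-L1 multi-target loss, and training.

The trainer scores a prediction against the *closest* of the four HR targets
(one per simulated rigid frame): because the two input stacks are misregistered
against each other, no single frame is the canonical ground truth, and taking
the minimum lets the network commit to whichever frame it reconstructs instead
of averaging them into blur.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .degrade import ArtifactConfig, simulate_pair
from .model import MDCSRN, upsample_concat
from .nn import Adam
from .volumes import VolumeGrid

__all__ = [
    "TrainingExample",
    "TrainConfig",
    "rotation24",
    "make_training_set",
    "min_l1_loss",
    "train",
]


@dataclass
class TrainingExample:
    """One input pair (as a 2-channel patch) and its four HR targets."""

    x: np.ndarray              # (2, p, p, p) upsampled LR views
    targets: np.ndarray        # (4, p, p, p) HR frames
    provenance: dict = field(default_factory=dict)


@dataclass
class TrainConfig:
    patches_per_image: int = 256
    batch_size: int = 8
    epochs: int = 10
    learning_rate: float = 1e-4
    seed: int = 0
    val_fraction: float = 0.1
    patch_size: int = 40

    def __post_init__(self) -> None:
        if (self.patches_per_image <= 0 or self.batch_size <= 0
                or self.epochs < 0 or self.patch_size <= 0):
            raise ValueError("TrainConfig fields must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


# The 24 orientation-preserving right-angle rotations of a cube, encoded as
# (axis permutation, per-axis flips) with determinant +1.
_ROT24 = [
    (perm, flips)
    for perm in itertools.permutations(range(3))
    for flips in itertools.product((1, -1), repeat=3)
    if np.linalg.det(np.eye(3)[list(perm)] * np.asarray(flips)[:, None]) > 0
]
assert len(_ROT24) == 24


def rotation24(values: np.ndarray, index: int) -> np.ndarray:
    """Apply the *index*-th right-angle rotation (0..23) to a cubic array."""
    perm, flips = _ROT24[index % 24]
    out = np.transpose(values, perm)
    for ax, f in enumerate(flips):
        if f < 0:
            out = np.flip(out, axis=ax)
    return out


def make_training_set(hr_volumes, cfg: TrainConfig, rng: np.random.Generator,
                      artifacts: ArtifactConfig | None = None,
                      dtype=np.float32) -> list[TrainingExample]:
    """Sample ``cfg.patches_per_image`` random patches per HR volume.

    Each patch is cropped at a random position, given a random right-angle
    orientation (arbitrary-angle rotation would break the perpendicular
    slice-stack geometry), degraded into two LR views, and the views upsampled
    back onto the patch grid as the 2-channel network input.
    """
    p = cfg.patch_size
    out: list[TrainingExample] = []
    for vid, vol in enumerate(hr_volumes):
        if any(abs(s - 1.0) > 1e-6 for s in vol.spacing):
            raise ValueError("training volumes must be 1 mm isotropic")
        if min(vol.shape) < p:
            raise ValueError(f"volume {vid} smaller than the {p}^3 patch")
        for pid in range(cfg.patches_per_image):
            corner = [int(rng.integers(0, n - p + 1)) for n in vol.shape]
            rot = int(rng.integers(0, 24))
            cube = vol.values[corner[0]:corner[0] + p,
                              corner[1]:corner[1] + p,
                              corner[2]:corner[2] + p]
            cube = np.ascontiguousarray(rotation24(cube, rot))
            hr = VolumeGrid(cube, (1.0, 1.0, 1.0))
            pair = simulate_pair(hr, rng, artifacts)
            grid = ((p, p, p), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
            x, _ = upsample_concat(pair.X1, pair.X2, grid=grid)
            targets = np.stack([t.values for t in pair.targets])
            out.append(TrainingExample(
                x=x.astype(dtype),
                targets=targets.astype(dtype),
                provenance=dict(volume=vid, patch=pid, corner=corner,
                                rotation=rot,
                                params=pair.params.to_dict(),
                                masked_view=pair.masked_view),
            ))
    return out


def min_l1_loss(pred: np.ndarray, targets: np.ndarray,
                return_grad: bool = False):
    """Minimum-L1 multi-target loss.

    ``pred`` has shape (N, p, p, p) (a leading channel axis of size 1 is
    squeezed) and ``targets`` (N, K, p, p, p).  The per-example loss is the
    minimum over the K targets of the mean absolute difference; the batch loss
    is the mean over examples.
    """
    pred = np.asarray(pred)
    targets = np.asarray(targets)
    if pred.ndim == targets.ndim and pred.shape[1] == 1:
        pred = pred[:, 0]
    if pred.ndim == targets.ndim - 2:      # unbatched single example
        pred, targets = pred[None], targets[None]
    if pred.shape != targets.shape[:1] + targets.shape[2:]:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs targets {targets.shape}")
    diff = pred[:, None] - targets                      # (N, K, ...)
    per_k = np.abs(diff).mean(axis=tuple(range(2, diff.ndim)))
    best = per_k.argmin(axis=1)
    loss = float(per_k[np.arange(len(best)), best].mean())
    if not return_grad:
        return loss
    n = len(best)
    nvox = int(np.prod(targets.shape[2:]))
    grad = np.sign(diff[np.arange(n), best]) / (nvox * n)
    return loss, grad.astype(np.float32)


def _batches(order, batch_size):
    for i in range(0, len(order), batch_size):
        yield order[i:i + batch_size]


def train(network: MDCSRN, corpus, cfg: TrainConfig):
    """Adam training with the minimum-L1 loss; keeps the best-validation state.

    Returns ``(network, history)`` where history holds per-epoch training and
    validation losses.  Fully reproducible for a fixed ``cfg.seed``.
    """
    if len(corpus) == 0:
        raise ValueError("empty training corpus")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(corpus))
    n_val = int(round(cfg.val_fraction * len(corpus)))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training examples")

    opt = Adam(network.param_grads(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, network.get_state())

    def eval_loss(indices):
        if len(indices) == 0:
            return float("nan")
        losses = []
        for b in np.array_split(indices, max(1, len(indices) // cfg.batch_size)):
            x = np.stack([corpus[i].x for i in b]).astype(np.float32)
            y = np.stack([corpus[i].targets for i in b]).astype(np.float32)
            pred = network.forward(x, train=False)
            losses.append(min_l1_loss(pred, y) * len(b))
        return float(np.sum(losses) / len(indices))

    # One deterministic shuffle; the batch order is fixed across epochs so a
    # run is reproducible and a zero learning rate provably changes nothing.
    order = rng.permutation(len(train_idx))
    for epoch in range(cfg.epochs):
        # cosine learning-rate decay from cfg.learning_rate to ~0
        opt.lr = cfg.learning_rate * 0.5 * (
            1.0 + np.cos(np.pi * epoch / max(cfg.epochs, 1)))
        epoch_losses = []
        for b in _batches(order, cfg.batch_size):
            sel = train_idx[b]
            x = np.stack([corpus[i].x for i in sel]).astype(np.float32)
            y = np.stack([corpus[i].targets for i in sel]).astype(np.float32)
            opt.zero_grad()
            pred = network.forward(x, train=True)
            loss, grad = min_l1_loss(pred, y, return_grad=True)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            network.backward(grad[:, None])
            opt.step()
            epoch_losses.append(loss * len(sel))
        train_loss = float(np.sum(epoch_losses) / len(train_idx))
        val_loss = eval_loss(val_idx) if n_val else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, network.get_state())

    if np.isfinite(best[0]):
        network.set_state(best[1])
    return network, history
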