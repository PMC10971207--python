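"""Segmentation model definition, training protocol and whole-section inference.

The training protocol follows the fixed recipe: Adam (learning rate 2e-4,
weight decay 1e-5), per-pixel cross-entropy ignoring background, a step
learning-rate schedule halving every 5 epochs, random affine augmentation of
every patch in every iteration, early stopping on validation loss, and three
replicate runs (seeds seed, seed+1, seed+2) from which metric mean and SD are
reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .nn import Adam, SegmentationNet, StepLR, build_network, masked_cross_entropy, softmax
from .patches import DatasetManifest, Patch
from .preprocess import ChannelStats, LabelMap, MultimodalStack, ParameterError

__all__ = [
    "ModalityConfig",
    "TrainConfig",
    "AugmentRanges",
    "TrainedModel",
    "build_model",
    "augment_affine",
    "apply_affine",
    "train",
    "predict_section",
]

#: stack channel order is (r1238, r1546, df)
_MODALITY_CHANNELS = {"DF": (2,), "IR": (0, 1), "COMBINED": (0, 1, 2)}


@dataclass(frozen=True)
class ModalityConfig:
    """Which stack channels feed the network: darkfield only, the two IR
    band-ratio channels, or their concatenation."""

    name: str

    def __post_init__(self):
        if self.name not in _MODALITY_CHANNELS:
            raise ParameterError(f"modality must be one of {sorted(_MODALITY_CHANNELS)}")

    @property
    def channel_selector(self) -> tuple[int, ...]:
        return _MODALITY_CHANNELS[self.name]

    @property
    def n_channels(self) -> int:
        return len(self.channel_selector)


@dataclass(frozen=True)
class AugmentRanges:
    """Random affine augmentation magnitudes (disabled when all are zero)."""

    rotation_deg: float = 30.0
    translate_frac: float = 0.10
    scale_min: float = 0.9
    scale_max: float = 1.1
    shear_deg: float = 5.0

    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0
            and self.translate_frac == 0
            and self.scale_min == 1.0
            and self.scale_max == 1.0
            and self.shear_deg == 0
        )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    weight_decay: float = 1e-5
    scheduler_step_epochs: int = 5
    scheduler_gamma: float = 0.5
    max_epochs: int = 40
    early_stopping_patience: int = 10
    early_stopping_min_delta: float = 1e-4
    batch_size: int = 8
    augment: AugmentRanges = field(default_factory=AugmentRanges)
    n_replicates: int = 3
    seed: int = 0
    backbone: str = "resnet50"
    class_weighting: bool = False  # optional counter to the ~10:1 class imbalance

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ParameterError("rates must be positive")
        if not (0.0 < self.scheduler_gamma < 1.0):
            raise ParameterError("scheduler_gamma must be in (0, 1)")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


@dataclass
class TrainedModel:
    network: SegmentationNet
    modality: ModalityConfig
    train_config: TrainConfig
    stats: ChannelStats
    history: list[dict]  # per-epoch {epoch, lr, train_loss, val_loss}
    replicate: int

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, **self.network.state_arrays())
        meta = {
            "modality": self.modality.name,
            "backbone": self.network.backbone,
            "replicate": self.replicate,
            "history": self.history,
            "stats_mean": [float(x) for x in self.stats.mean],
            "stats_sd": [float(x) for x in self.stats.sd],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def build_model(
    modality: ModalityConfig,
    n_classes: int = 3,
    backbone: str = "resnet50",
    seed: int = 0,
) -> SegmentationNet:
    """Instantiate the FCN with its first layer sized to the modality."""
    rng = np.random.default_rng(seed)
    return build_network(modality.n_channels, n_classes, backbone=backbone, rng=rng)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_affine(patch: Patch, rng: np.random.Generator, ranges: AugmentRanges | None = None) -> Patch:
    """Random affine transform of a patch: channels bilinear, labels/mask
    nearest-neighbor with the identical transform; exposed regions fill with
    background (label 0, channel 0), which the loss ignores."""
    r = ranges or AugmentRanges()
    if r.is_identity():
        return replace_patch(patch, patch.channels.copy(), patch.labels.copy(), patch.mask.copy())
    theta = rng.uniform(-r.rotation_deg, r.rotation_deg)
    shear = rng.uniform(-r.shear_deg, r.shear_deg)
    scale = rng.uniform(r.scale_min, r.scale_max)
    t_max = r.translate_frac * patch.size
    ty, tx = rng.uniform(-t_max, t_max, size=2)
    return apply_affine(patch, rotation_deg=theta, shear_deg=shear, scale=scale, translate=(ty, tx))


def apply_affine(
    patch: Patch,
    rotation_deg: float = 0.0,
    shear_deg: float = 0.0,
    scale: float = 1.0,
    translate: tuple[float, float] = (0.0, 0.0),
) -> Patch:
    """Deterministic affine transform of a patch about its center."""
    theta = np.deg2rad(rotation_deg)
    shear = np.deg2rad(shear_deg)
    size = patch.size
    ty, tx = translate

    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    sh = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    fwd = scale * (rot @ sh)  # forward map: x_out = fwd @ (x_in - ctr) + ctr + t
    inv = np.linalg.inv(fwd)
    center = (size - 1) / 2.0
    ctr = np.array([center, center])
    t = np.array([ty, tx])
    # affine_transform maps output -> input: x_in = inv @ x_out + offset
    offset = ctr - inv @ (ctr + t)
    # snap near-integer entries so right-angle rotations stay exact
    # index permutations instead of leaking edge pixels out of frame
    inv = np.where(np.abs(inv - np.round(inv)) < 1e-9, np.round(inv), inv)
    offset = np.where(np.abs(offset - np.round(offset)) < 1e-6, np.round(offset), offset)

    chans = np.stack(
        [
            ndimage.affine_transform(ch, inv, offset=offset, order=1, mode="constant", cval=0.0)
            for ch in patch.channels
        ]
    ).astype(np.float32)
    labels = ndimage.affine_transform(
        patch.labels, inv, offset=offset, order=0, mode="constant", cval=0
    )
    mask = ndimage.affine_transform(
        patch.mask.astype(np.uint8), inv, offset=offset, order=0, mode="constant", cval=0
    ).astype(bool)
    return replace_patch(patch, chans, labels, mask)


def replace_patch(patch: Patch, channels, labels, mask) -> Patch:
    return Patch(
        channels=channels,
        labels=labels,
        mask=mask,
        section_id=patch.section_id,
        origin=patch.origin,
        tissue_frac=float(np.asarray(mask).mean()),
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_arrays(
    patches: list[Patch], idx: np.ndarray, selector: tuple[int, ...], stats: ChannelStats,
    rng: np.random.Generator | None, ranges: AugmentRanges,
):
    mean = stats.mean.astype(np.float32)[list(selector), None, None]
    sd = stats.sd.astype(np.float32)[list(selector), None, None]
    xs, ys, ms = [], [], []
    for i in idx:
        p = patches[i]
        if rng is not None:
            p = augment_affine(p, rng, ranges)
        xs.append((p.channels[list(selector)] - mean) / sd)
        ys.append(p.labels)
        ms.append(p.mask)
    return (
        np.stack(xs).astype(np.float32),
        np.stack(ys),
        np.stack(ms),
    )


def _epoch_loss(net: SegmentationNet, patches, selector, stats, batch_size) -> float:
    """Mean loss over a split without updating weights (eval mode)."""
    net.train(False)
    tot, n = 0.0, 0
    for start in range(0, len(patches), batch_size):
        idx = np.arange(start, min(start + batch_size, len(patches)))
        x, y, m = _batch_arrays(patches, idx, selector, stats, None, AugmentRanges())
        logits = net.forward(x)
        loss, _ = masked_cross_entropy(logits, y, m)
        tot += loss * len(idx)
        n += len(idx)
    return tot / max(n, 1)


def train(
    manifest: DatasetManifest,
    modality: ModalityConfig,
    config: TrainConfig,
    verbose: bool = False,
) -> list[TrainedModel]:
    """Train ``n_replicates`` models (replicate r seeded with seed + r).

    Early stopping monitors validation loss with the configured patience and
    minimum improvement; the best-validation weights are retained.  When the
    manifest has no ``val`` split the ``test`` split is used for monitoring,
    reproducing the two-way design in which the held-out sections serve both
    validation and blind testing.
    """
    train_patches = manifest.split_patches("train")
    val_split = "val" if manifest.section_ids("val") else "test"
    val_patches = manifest.split_patches(val_split)
    if not train_patches or not val_patches:
        raise ParameterError("train() needs non-empty train and validation splits")
    if manifest.stats is None:
        raise ParameterError("manifest has no channel standardization stats")
    stats = manifest.stats
    selector = modality.channel_selector

    models: list[TrainedModel] = []
    for rep in range(config.n_replicates):
        seed = config.seed + rep
        rng = np.random.default_rng(seed)
        net = build_model(modality, n_classes=3, backbone=config.backbone, seed=seed)
        opt = Adam(
            net.parameters(),
            lr=config.learning_rate,
            weight_decay=config.weight_decay,
        )
        sched = StepLR(opt, config.scheduler_step_epochs, config.scheduler_gamma,
                       base_lr=config.learning_rate)
        history: list[dict] = []
        best_val = np.inf
        best_state = net.copy_state()
        since_improve = 0
        for epoch in range(config.max_epochs):
            lr = sched.set_epoch(epoch)
            net.train(True)
            order = rng.permutation(len(train_patches))
            losses = []
            for start in range(0, len(order), config.batch_size):
                idx = order[start:start + config.batch_size]
                x, y, m = _batch_arrays(
                    train_patches, idx, selector, stats, rng, config.augment
                )
                logits = net.forward(x)
                loss, grad = masked_cross_entropy(logits, y, m)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch} (replicate {rep})"
                    )
                opt.zero_grad()
                net.backward(grad)
                opt.step()
                losses.append(loss)
            val_loss = _epoch_loss(net, val_patches, selector, stats, config.batch_size)
            history.append(
                {"epoch": epoch, "lr": lr,
                 "train_loss": float(np.mean(losses)), "val_loss": float(val_loss)}
            )
            if verbose:
                print(f"[rep {rep}] epoch {epoch}: lr={lr:.2e} "
                      f"train={history[-1]['train_loss']:.4f} val={val_loss:.4f}")
            if val_loss < best_val - config.early_stopping_min_delta:
                best_val = val_loss
                best_state = net.copy_state()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= config.early_stopping_patience:
                    break
        net.load_state_arrays(best_state)
        net.train(False)
        models.append(
            TrainedModel(
                network=net,
                modality=modality,
                train_config=config,
                stats=stats,
                history=history,
                replicate=rep,
            )
        )
    return models


# ---------------------------------------------------------------------------
# whole-section inference
# ---------------------------------------------------------------------------

def predict_section(
    model: TrainedModel,
    stack: MultimodalStack,
    tile: int = 256,
    overlap: int = 32,
) -> LabelMap:
    """Tile-and-stitch inference over a whole section.

    Per-tile class probabilities are averaged where tiles overlap, then
    argmaxed; pixels outside the tissue mask are forced to background.
    """
    net = model.network
    if tile < net.stride_product or tile % net.stride_product:
        raise ParameterError(
            f"tile must be a multiple of the network stride product {net.stride_product}"
        )
    if overlap < 0 or overlap >= tile:
        raise ParameterError("overlap must be in [0, tile)")
    h, w = stack.grid_shape
    selector = model.modality.channel_selector
    mean = model.stats.mean.astype(np.float32)[list(selector), None, None]
    sd = model.stats.sd.astype(np.float32)[list(selector), None, None]
    x = (stack.channels[list(selector)] - mean) / sd

    step = tile - overlap
    starts_r = _tile_starts(h, tile, step)
    starts_c = _tile_starts(w, tile, step)
    scores = np.zeros((net.n_classes, h, w), dtype=np.float64)
    weight = np.zeros((h, w), dtype=np.float64)
    net.train(False)
    for r0 in starts_r:
        for c0 in starts_c:
            win = (slice(r0, r0 + tile), slice(c0, c0 + tile))
            logits = net.forward(x[(slice(None),) + win][None])
            probs = softmax(logits.astype(np.float64), axis=1)[0]
            scores[(slice(None),) + win] += probs
            weight[win] += 1.0
    scores /= weight[None]
    pred = (scores.argmax(axis=0) + 1).astype(np.uint8)
    pred[~stack.tissue_mask] = 0
    return LabelMap(pred)


def _tile_starts(extent: int, tile: int, step: int) -> list[int]:
    if tile > extent:
        raise ParameterError(f"tile {tile} larger than section extent {extent}")
    starts = list(range(0, extent - tile + 1, step))
    if starts[-1] != extent - tile:
        starts.append(extent - tile)  # clamp the last tile inside the frame
    return starts
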