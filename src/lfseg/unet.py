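"""Three-class U-Nets mapping normalized reflectance to class probabilities.

The 2D and 3D networks share one architecture family: encoder depth 4 with
64 first-layer filters and complete up-convolutional expansion, trained with
cross-entropy on patches (256x256 in 2D, 64x64x64 in 3D) under zero-center
normalization with x/y reflection and rotation augmentation.  The published
training schedules are available as the ``published2d`` (``ffpe=True`` for
the longer formalin-fixed schedule) and ``published3d`` presets; the
``tiny`` / ``tiny3d`` presets are reduced profiles
(depth 2, few filters, small patches) sized for CPU-scale runs and used
throughout the test-suite.

Probability maps are arrays of shape ``(3, *spatial)`` over
{background, nuclei, cytoskeleton}, summing to 1 per pixel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from lfseg.nn import Adam, SGDMomentum, UNet, softmax_cross_entropy
from lfseg.nn.optim import step_decay_lr
from lfseg.types import NormalizedImage, check_same_shape

OPTIMIZERS = ("sgdm", "adam")


@dataclass(frozen=True)
class UNetSpec:
    """Architecture of a three-class U-Net."""

    dims: int = 2
    n_classes: int = 3
    encoder_depth: int = 4
    first_layer_filters: int = 64

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        if self.encoder_depth < 1 or self.first_layer_filters < 1:
            raise ValueError("encoder_depth and first_layer_filters must be positive")

    @property
    def encoder_filters(self) -> list[int]:
        """Filter counts per encoder level (doubling per level)."""
        return [self.first_layer_filters * 2**d for d in range(self.encoder_depth)]

    @property
    def bottleneck_filters(self) -> int:
        return self.first_layer_filters * 2**self.encoder_depth


@dataclass(frozen=True)
class TrainingConfig:
    """Training schedule for a U-Net.

    Defaults follow the published 2D frozen-section schedule; use the
    preset constructors for the other profiles.
    """

    patch_shape: tuple[int, ...] = (256, 256)
    batch_size: int = 12
    epochs: int = 50
    optimizer: str = "sgdm"
    initial_lr: float = 0.05
    lr_drop_period: int = 10
    lr_drop_factor: float = 0.1
    momentum: float = 0.9
    l2_regularization: float = 1e-4
    loss: str = "cross_entropy"
    normalization: str = "zero_center"
    augment: bool = True
    shuffle_each_epoch: bool = True
    patches_per_epoch: int = 64
    #: optional per-class loss weights (background, nuclei, cytoskeleton);
    #: None = plain unweighted cross-entropy
    class_weights: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if min(self.initial_lr, self.lr_drop_factor) <= 0 or self.batch_size < 1:
            raise ValueError("rates must be positive and batch_size >= 1")
        if len(self.patch_shape) not in (2, 3):
            raise ValueError("patch_shape must be 2D or 3D")


def published2d(ffpe: bool = False) -> TrainingConfig:
    """Published 2D schedule: SGD + momentum, 50 epochs (150 for FFPE)."""
    return TrainingConfig(
        patch_shape=(256, 256),
        batch_size=12,
        epochs=150 if ffpe else 50,
        optimizer="sgdm",
        initial_lr=0.05,
        lr_drop_period=10,
        lr_drop_factor=0.1,
        momentum=0.9,
        l2_regularization=1e-4,
    )


def published3d() -> TrainingConfig:
    """Published 3D schedule: Adam, 150 epochs, 64^3 patches."""
    return TrainingConfig(
        patch_shape=(64, 64, 64),
        batch_size=8,
        epochs=150,
        optimizer="adam",
        initial_lr=5e-4,
        lr_drop_period=5,
        lr_drop_factor=0.95,
        l2_regularization=1e-4,
    )


def tiny(seed: int = 0) -> tuple[UNetSpec, TrainingConfig]:
    """Reduced 2D profile for CPU-scale runs: depth 2, 8 filters, 64^2 patches."""
    spec = UNetSpec(dims=2, encoder_depth=2, first_layer_filters=8)
    config = TrainingConfig(
        patch_shape=(64, 64),
        batch_size=4,
        epochs=15,
        optimizer="adam",
        initial_lr=2e-3,
        lr_drop_period=6,
        lr_drop_factor=0.5,
        l2_regularization=1e-4,
        patches_per_epoch=64,
        seed=seed,
    )
    return spec, config


def tiny3d(seed: int = 0) -> tuple[UNetSpec, TrainingConfig]:
    """Reduced 3D profile: depth 2, 8 filters, 32^3 patches."""
    spec = UNetSpec(dims=3, encoder_depth=2, first_layer_filters=8)
    config = TrainingConfig(
        patch_shape=(32, 32, 32),
        batch_size=2,
        epochs=24,
        optimizer="adam",
        initial_lr=3e-3,
        lr_drop_period=6,
        lr_drop_factor=0.5,
        l2_regularization=1e-4,
        patches_per_epoch=40,
        seed=seed,
    )
    return spec, config


PRESETS = {"published2d": published2d, "published3d": published3d, "tiny": tiny, "tiny3d": tiny3d}


class UNetModel:
    """A built (possibly trained) U-Net plus its input normalization state."""

    def __init__(self, spec: UNetSpec, seed: int = 0, dtype=np.float32) -> None:
        self.spec = spec
        self.seed = int(seed)
        self.net = UNet(
            ndim=spec.dims,
            n_classes=spec.n_classes,
            depth=spec.encoder_depth,
            base_filters=spec.first_layer_filters,
            in_channels=1,
            seed=seed,
            dtype=dtype,
        )
        self.input_mean: float = 0.0
        self.trained: bool = False

    @property
    def dims(self) -> int:
        return self.spec.dims


def build_model(spec: UNetSpec, seed: int = 0, dtype=np.float32) -> UNetModel:
    """Instantiate a U-Net from its architecture spec (untrained)."""
    return UNetModel(spec, seed=seed, dtype=dtype)


# -- patch sampling --------------------------------------------------------


def _dihedral(arr: np.ndarray, code: int) -> np.ndarray:
    """Apply one of the 8 axis-aligned symmetries of the (y, x) plane.

    Rotations are 90-degree multiples in the last two axes, optionally
    composed with a flip of the last axis; in 3D the z axis is untouched
    (augmentation is x/y reflection and rotation only).
    """
    rot, flip = code % 4, code // 4
    out = np.rot90(arr, k=rot, axes=(-2, -1))
    if flip:
        out = np.flip(out, axis=-1)
    return out


class PatchSampler:
    """Seeded stream of augmented (patch, label-patch) training pairs.

    Iteration yields pairs indefinitely; every ``config.patches_per_epoch``
    draws form one epoch, re-drawn (shuffled) each epoch when
    ``config.shuffle_each_epoch`` is set.  Images smaller than the patch in
    any dimension are reflect-padded, never an error.  Square patches only
    in the rotated plane (the y/x rotation must preserve shape).
    """

    def __init__(
        self, image: NormalizedImage | np.ndarray, labels: np.ndarray, config: TrainingConfig
    ) -> None:
        pixels = image.pixels if isinstance(image, NormalizedImage) else np.asarray(image)
        labels = np.asarray(labels)
        check_same_shape(pixels, labels)
        patch = tuple(int(p) for p in config.patch_shape)
        if len(patch) != pixels.ndim:
            raise ValueError(
                f"patch_shape {patch} does not match image dimensionality {pixels.ndim}"
            )
        if config.augment and patch[-1] != patch[-2]:
            raise ValueError("augmentation by y/x rotation requires square patches")
        pads = [(0, max(0, p - s)) for p, s in zip(patch, pixels.shape)]
        if any(p[1] for p in pads):
            pixels = np.pad(pixels, pads, mode="reflect")
            labels = np.pad(labels, pads, mode="reflect")
        self.pixels = pixels
        self.labels = labels
        self.patch = patch
        self.config = config
        #: training-set mean used for zero-center normalization
        self.input_mean = float(pixels.mean())

    def _epoch_draws(self, rng: np.random.Generator):
        cfg = self.config
        maxoff = [s - p for s, p in zip(self.pixels.shape, self.patch)]
        offsets = np.column_stack(
            [rng.integers(0, m + 1, size=cfg.patches_per_epoch) for m in maxoff]
        )
        codes = (
            rng.integers(0, 8, size=cfg.patches_per_epoch)
            if cfg.augment
            else np.zeros(cfg.patches_per_epoch, dtype=int)
        )
        return offsets, codes

    def __iter__(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        offsets, codes = self._epoch_draws(rng)
        while True:
            for off, code in zip(offsets, codes):
                sl = tuple(slice(o, o + p) for o, p in zip(off, self.patch))
                patch = _dihedral(self.pixels[sl], int(code))
                label = _dihedral(self.labels[sl], int(code))
                yield patch.copy(), label.copy()
            if cfg.shuffle_each_epoch:
                offsets, codes = self._epoch_draws(rng)


def sample_patches(
    image: NormalizedImage | np.ndarray, labels: np.ndarray, config: TrainingConfig
) -> PatchSampler:
    """Build the seeded augmented patch stream for training."""
    return PatchSampler(image, labels, config)


# -- training --------------------------------------------------------------


def train(
    model: UNetModel, pairs: PatchSampler, config: TrainingConfig
) -> tuple[UNetModel, list[float]]:
    """Train in place on the patch stream; returns (model, per-epoch loss).

    Runs the configured schedule: step-decay learning rate, L2 weight
    decay, SGD-with-momentum or Adam.  Aborts with a diagnostic if the loss
    turns non-finite.
    """
    if config.normalization == "zero_center":
        model.input_mean = float(getattr(pairs, "input_mean", 0.0))
    params = model.net.parameter_arrays()
    if config.optimizer == "sgdm":
        opt = SGDMomentum(
            params, config.initial_lr, config.momentum, config.l2_regularization
        )
    else:
        opt = Adam(params, config.initial_lr, weight_decay=config.l2_regularization)

    stream = iter(pairs)
    history: list[float] = []
    weights = np.asarray(config.class_weights) if config.class_weights else None
    n_batches = max(1, config.patches_per_epoch // config.batch_size)
    for epoch in range(config.epochs):
        opt.lr = step_decay_lr(
            config.initial_lr, epoch, config.lr_drop_period, config.lr_drop_factor
        )
        epoch_loss = 0.0
        for b in range(n_batches):
            xs, ys = [], []
            for _ in range(config.batch_size):
                patch, label = next(stream)
                xs.append(patch - model.input_mean)
                ys.append(label)
            x = np.stack(xs)[:, None].astype(model.net.dtype)
            y = np.stack(ys).astype(np.int64)
            logits = model.net.forward(x)
            loss, dlogits = softmax_cross_entropy(logits, y, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}, batch {b + 1}"
                )
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss
        history.append(epoch_loss / n_batches)
    model.trained = True
    return model, history


# -- inference -------------------------------------------------------------


def _predict_tile(model: UNetModel, tile: np.ndarray) -> np.ndarray:
    """Class probabilities (3, *tile) for one tile, padding to the U-Net grid."""
    d = 2**model.spec.encoder_depth
    pads = [((0, (-s) % d)) for s in tile.shape]
    padded = np.pad(tile, pads, mode="reflect") if any(p[1] for p in pads) else tile
    x = padded[None, None].astype(model.net.dtype)
    probs = model.net.predict_proba(x)[0]
    crop = (slice(None),) + tuple(slice(0, s) for s in tile.shape)
    return np.asarray(probs[crop], dtype=np.float64)


def _feather_weights(tile_shape: tuple[int, ...], overlap: tuple[int, ...]) -> np.ndarray:
    """Separable blending weights: 1 in the tile core, ~0 at tile edges.

    A tile's outermost pixels are predicted from truncated context the full
    image does not have, and that contamination reaches as far as the
    network's receptive field.  The outer half of each overlap is therefore
    a zero-weight halo (floored at a tiny epsilon so pixels with no other
    contributor — the image borders — still get a value), with a linear
    ramp to 1 over the inner half.  With tile step ``t − o`` the clean
    cores (``halo = o/2`` trimmed per side) tile the image exactly, so
    every interior pixel has a full-context contributor.
    """
    eps = 1e-6
    ramps = []
    for t, o in zip(tile_shape, overlap):
        halo = o // 2
        i = np.arange(t, dtype=np.float64)
        d = np.minimum(i, t - 1 - i)
        ramp = (d - halo + 1) / max(o - halo + 1, 1)
        ramps.append(np.clip(ramp, eps, 1.0))
    w = ramps[0]
    for r in ramps[1:]:
        w = np.multiply.outer(w, r)
    return w


def predict_probability_map(
    model: UNetModel,
    reflectance: NormalizedImage | np.ndarray,
    tile_shape: tuple[int, ...] | None = None,
    overlap_fraction: float = 0.25,
) -> np.ndarray:
    """Class probability map ``(3, *spatial)`` for a whole image.

    Large images are processed as overlapping tiles whose softmax outputs
    are blended by linear feathering; the result is renormalized to sum to
    1 per pixel.  With ``tile_shape=None`` (or an image no larger than one
    tile) the whole image goes through in a single pass.

    Tile shapes and origins are snapped to the network's ``2**depth``
    stride grid: the strided transposed-convolution upsampling makes the
    output translation-invariant only modulo that grid, so unaligned tiles
    would disagree with whole-image inference by the phase of that pattern.
    """
    pixels = reflectance.pixels if isinstance(reflectance, NormalizedImage) else np.asarray(reflectance)
    if pixels.ndim != model.dims:
        raise ValueError(
            f"model is {model.dims}D but image has {pixels.ndim} dimensions"
        )
    if not 0 <= overlap_fraction < 0.5:
        raise ValueError("overlap_fraction must lie in [0, 0.5)")
    x = pixels.astype(np.float64) - model.input_mean
    grid = 2**model.spec.encoder_depth

    if tile_shape is None or all(s <= t for s, t in zip(x.shape, tile_shape)):
        probs = _predict_tile(model, x)
    else:
        pads = [(0, (-s) % grid) for s in x.shape]
        xp = np.pad(x, pads, mode="reflect") if any(p[1] for p in pads) else x
        tile = tuple(
            min(-(-t // grid) * grid, s) for t, s in zip(tile_shape, xp.shape)
        )
        overlap = tuple(
            (int(round(overlap_fraction * t)) // grid) * grid for t in tile
        )
        origins_per_axis = []
        for s, t, o in zip(xp.shape, tile, overlap):
            step = max(grid, t - o)
            origins = list(range(0, max(s - t, 0) + 1, step))
            if origins[-1] + t < s:
                origins.append(s - t)  # grid-aligned: s and t are multiples
            origins_per_axis.append(origins)
        weight = _feather_weights(tile, overlap)
        acc = np.zeros((model.spec.n_classes,) + xp.shape)
        norm = np.zeros(xp.shape)
        grids = np.meshgrid(*origins_per_axis, indexing="ij")
        for origin in zip(*(g.ravel() for g in grids)):
            sl = tuple(slice(o, o + t) for o, t in zip(origin, tile))
            acc[(slice(None),) + sl] += _predict_tile(model, xp[sl]) * weight
            norm[sl] += weight
        crop = (slice(None),) + tuple(slice(0, s) for s in x.shape)
        probs = (acc / norm)[crop]
    return probs / probs.sum(axis=0, keepdims=True)


# -- checkpoints -----------------------------------------------------------


def save_model(model: UNetModel, path: str | Path, config: TrainingConfig | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar with spec, seed and state."""
    path = Path(path)
    np.savez(path, **model.net.state_dict())
    sidecar = {
        "spec": asdict(model.spec),
        "seed": model.seed,
        "input_mean": model.input_mean,
        "trained": model.trained,
        "training_config": asdict(config) if config is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> UNetModel:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = dict(meta["spec"])
    spec = UNetSpec(**spec_d)
    model = UNetModel(spec, seed=meta["seed"])
    weight_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(weight_path) as data:
        model.net.load_state_dict(dict(data))
    model.input_mean = float(meta["input_mean"])
    model.trained = bool(meta["trained"])
    return model
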