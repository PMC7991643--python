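"""Paired image-to-image translation: phase contrast -> virtual fluorescence.

The generator is a U-Net — an encoder/decoder with skip connections at
matching resolutions — trained against an L1 pixel reconstruction loss
and, optionally, a least-squares adversarial loss from a patch-level
discriminator that scores the concatenation of the phase input and a
(real or predicted) fluorescence image.  With
``adversarial_loss_weight = 0`` training degrades exactly to supervised
U-Net regression: the discriminator is never built and the generator
update path is identical.

Architecture (depth d, base channels c), all convolutions zero-padded:

* entry: 3x3 conv (1 -> c), leaky-ReLU
* encoder level i = 1..d: 4x4 stride-2 conv (c 2^{i-1} -> c 2^i), leaky-ReLU
* decoder level i = d..1: nearest 2x upsample, 3x3 conv (c 2^i -> c 2^{i-1}),
  leaky-ReLU, concat skip from the encoder at that resolution,
  3x3 conv (c 2^i -> c 2^{i-1}), leaky-ReLU
* exit: 3x3 conv (c -> 1), linear output (clipped to the model
  range at inference; a saturating output nonlinearity would make the
  all-background constant a gradient-dead attractor under the L1 loss)

Discriminator: 4x4 stride-2 conv (2 -> c), leaky-ReLU, 4x4 stride-2
conv (c -> 2c), leaky-ReLU, 3x3 conv (2c -> 1); the output is an
(H/4, W/4) grid of patch realism scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from virtustain import metrics
from virtustain.errors import (
    FormatError,
    ShapeError,
    TrainingDivergenceError,
    UndefinedStatisticError,
    ValidationError,
)
from virtustain import nn
from virtustain.nn import Adam, Parameter, Tensor, he_init

__all__ = [
    "TranslatorConfig",
    "TrainedTranslator",
    "TrainingLog",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "train",
    "predict",
    "predict_tiles",
    "save_model",
    "load_model",
    "normalize_image",
]

CHECKPOINT_VERSION = "virtustain-ckpt-1"

#: percentile window used to normalize each image to [0, 1]
NORM_PERCENTILES = (0.1, 99.9)


@dataclass
class TranslatorConfig:
    depth: int = 3
    base_channels: int = 16
    pixel_loss_weight: float = 100.0
    adversarial_loss_weight: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 4
    iterations: int = 2000
    seed: int = 0
    input_size: int = 64
    val_interval: int = 200

    def __post_init__(self):
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.input_size % (2**self.depth) != 0:
            raise ValidationError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.pixel_loss_weight < 0 or self.adversarial_loss_weight < 0:
            raise ValidationError("loss weights must be >= 0")
        if self.pixel_loss_weight == 0 and self.adversarial_loss_weight == 0:
            raise ValidationError("at least one loss weight must be > 0")
        if self.batch_size < 1 or self.iterations < 0:
            raise ValidationError("batch_size >= 1 and iterations >= 0 required")


@dataclass
class TrainingLog:
    iterations: list[int] = field(default_factory=list)
    generator_loss: list[float] = field(default_factory=list)
    discriminator_loss: list[float] = field(default_factory=list)
    validation: list[tuple[int, float]] = field(default_factory=list)


class _ConvNet:
    """Common parameter bookkeeping for the two networks."""

    def __init__(self):
        self._params: list[Parameter] = []

    def _conv(self, rng, c_in, c_out, k):
        w = he_init(rng, (c_out, c_in, k, k), fan_in=c_in * k * k)
        b = Parameter(np.zeros(c_out, dtype=nn.DTYPE))
        self._params += [w, b]
        return w, b

    def parameters(self) -> list[Parameter]:
        return self._params

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self._params)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self._params]

    def load_arrays(self, arrays) -> None:
        if len(arrays) != len(self._params):
            raise FormatError("parameter count mismatch when loading checkpoint")
        for p, a in zip(self._params, arrays):
            if p.data.shape != a.shape:
                raise FormatError("parameter shape mismatch when loading checkpoint")
            p.data = np.asarray(a, dtype=nn.DTYPE)


class UNetGenerator(_ConvNet):
    """Single-channel-in, single-channel-out U-Net."""

    def __init__(self, config: TranslatorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c, d = config.base_channels, config.depth
        self.entry = self._conv(rng, 1, c, 3)
        self.downs = [
            self._conv(rng, c * 2**i, c * 2 ** (i + 1), 4) for i in range(d)
        ]
        self.ups = []
        for i in range(d, 0, -1):
            ci, co = c * 2**i, c * 2 ** (i - 1)
            self.ups.append(
                (self._conv(rng, ci, co, 3), self._conv(rng, 2 * co, co, 3))
            )
        self.exit = self._conv(rng, c, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        h = x.conv2d(*self.entry, stride=1, pad=1).leaky_relu()
        skips = [h]
        for i, (w, b) in enumerate(self.downs):
            h = h.conv2d(w, b, stride=2, pad=1).leaky_relu()
            if i < len(self.downs) - 1:
                skips.append(h)
        for (wu, bu), (wm, bm) in self.ups:
            h = h.upsample2().conv2d(wu, bu, stride=1, pad=1).leaky_relu()
            h = h.concat(skips.pop())
            h = h.conv2d(wm, bm, stride=1, pad=1).leaky_relu()
        return h.conv2d(*self.exit, stride=1, pad=1)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Inference on a raw (N, 1, H, W) array in [-1, 1]."""
        return self.forward(Tensor(x)).data


class PatchDiscriminator(_ConvNet):
    """Patch-level realism scorer on a (phase, fluorescence) pair."""

    def __init__(self, config: TranslatorConfig, rng: np.random.Generator):
        super().__init__()
        c = config.base_channels
        self.c1 = self._conv(rng, 2, c, 4)
        self.c2 = self._conv(rng, c, 2 * c, 4)
        self.c3 = self._conv(rng, 2 * c, 1, 3)

    def forward(self, xy: Tensor) -> Tensor:
        if xy.data.shape[1] != 2:
            raise ShapeError(
                f"discriminator expects a 2-channel input, got {xy.data.shape[1]}"
            )
        h = xy.conv2d(*self.c1, stride=2, pad=1).leaky_relu()
        h = h.conv2d(*self.c2, stride=2, pad=1).leaky_relu()
        return h.conv2d(*self.c3, stride=1, pad=1)

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(xy)).data


def build_generator(config: TranslatorConfig) -> UNetGenerator:
    return UNetGenerator(config, np.random.default_rng(config.seed))


def build_discriminator(config: TranslatorConfig) -> PatchDiscriminator:
    return PatchDiscriminator(config, np.random.default_rng(config.seed + 1))


# ---------------------------------------------------------------------------
# normalization

def normalize_image(img: np.ndarray, percentiles=NORM_PERCENTILES) -> np.ndarray:
    """Robust per-image scaling to [0, 1] by percentile window."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = np.percentile(img, percentiles)
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _to_model(img01: np.ndarray) -> np.ndarray:
    return img01 * 2.0 - 1.0


def _from_model(out: np.ndarray) -> np.ndarray:
    return (np.clip(out, -1.0, 1.0) + 1.0) / 2.0


@dataclass
class TrainedTranslator:
    """A trained generator plus the normalization convention.

    Inputs are percentile-normalized per image to [0, 1] and shifted to
    [-1, 1]; the generator output in [-1, 1] is mapped back to the
    [0, 1] intensity scale (offset -1, scale 2, inverted on output).
    """

    generator: UNetGenerator
    config: TranslatorConfig
    normalization: dict = field(
        default_factory=lambda: {
            "input_percentiles": list(NORM_PERCENTILES),
            "model_range": [-1.0, 1.0],
            "output_range": [0.0, 1.0],
        }
    )

    def predict(self, phase: np.ndarray) -> np.ndarray:
        return predict(self, phase)


# ---------------------------------------------------------------------------
# training

def _prepare(pairs) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) == 0:
        raise ValidationError("empty training set")
    shapes = {p.phase.shape for p in pairs} | {p.fluorescence.shape for p in pairs}
    if len(shapes) != 1:
        raise ShapeError(f"all training pairs must share one shape, got {shapes}")
    xs = np.stack([_to_model(normalize_image(p.phase)) for p in pairs])[:, None]
    ys = np.stack([_to_model(normalize_image(p.fluorescence)) for p in pairs])[:, None]
    return xs.astype(nn.DTYPE), ys.astype(nn.DTYPE)


def train(
    pairs,
    config: TranslatorConfig,
    validation=(),
) -> tuple[TrainedTranslator, TrainingLog]:
    """Adversarial (or purely supervised) training on paired images.

    Alternates a discriminator update minimizing the least-squares GAN
    loss (real pair -> 1, fake pair -> 0) with a generator update
    minimizing the least-squares loss towards 1 plus
    ``pixel_loss_weight`` times the mean absolute pixel error.  Fully
    deterministic for a fixed (data, config, seed).
    """
    xs, ys = _prepare(pairs)
    h, w = xs.shape[2], xs.shape[3]
    if h % 2**config.depth or w % 2**config.depth:
        raise ValidationError("training image size must be divisible by 2^depth")

    rng = np.random.default_rng(config.seed)
    gen = UNetGenerator(config, rng)
    adversarial = config.adversarial_loss_weight > 0
    disc = PatchDiscriminator(config, rng) if adversarial else None
    opt_g = Adam(gen.parameters(), lr=config.learning_rate)
    opt_d = Adam(disc.parameters(), lr=config.learning_rate) if adversarial else None

    n = xs.shape[0]
    log = TrainingLog()
    val_pairs = list(validation)

    for it in range(config.iterations):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        xb, yb = xs[idx], ys[idx]
        x_t = Tensor(xb)

        d_loss_val = math.nan
        if adversarial:
            fake = gen.forward(x_t).data  # detached for the D step
            opt_d.zero_grad()
            d_real = disc.forward(Tensor(np.concatenate([xb, yb], axis=1)))
            d_fake = disc.forward(Tensor(np.concatenate([xb, fake], axis=1)))
            d_loss = ((d_real - 1.0).mean_sq() + d_fake.mean_sq()).scale(0.5)
            d_loss.backward()
            opt_d.step()
            d_loss_val = float(d_loss.data)

        opt_g.zero_grad()
        pred = gen.forward(x_t)
        g_loss = (pred - Tensor(yb)).mean_abs().scale(config.pixel_loss_weight)
        if adversarial:
            d_on_fake = disc.forward(x_t.concat(pred))
            g_loss = g_loss + (d_on_fake - 1.0).mean_sq().scale(
                0.5 * config.adversarial_loss_weight
            )
        g_loss.backward()
        opt_g.step()
        g_loss_val = float(g_loss.data)

        if not math.isfinite(g_loss_val) or (
            adversarial and not math.isfinite(d_loss_val)
        ):
            raise TrainingDivergenceError(it)

        log.iterations.append(it)
        log.generator_loss.append(g_loss_val)
        log.discriminator_loss.append(d_loss_val)

        if val_pairs and (it + 1) % config.val_interval == 0:
            model = TrainedTranslator(generator=gen, config=config)
            rs = []
            for p in val_pairs:
                try:
                    rs.append(
                        metrics.pearson_source(
                            normalize_image(p.fluorescence), model.predict(p.phase)
                        )
                    )
                except UndefinedStatisticError:
                    rs.append(math.nan)  # collapsed (constant) prediction
            log.validation.append((it, float(np.nanmean(rs) if rs else math.nan)))

    return TrainedTranslator(generator=gen, config=config), log


# ---------------------------------------------------------------------------
# prediction

def predict(model: TrainedTranslator, phase: np.ndarray) -> np.ndarray:
    """Virtual fluorescence image for one phase-contrast frame.

    The input is percentile-normalized, reflect-padded up to the next
    multiple of 2^depth, translated, cropped back and mapped to the
    [0, 1] output intensity scale.  Deterministic.
    """
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim != 2:
        raise ShapeError(f"predict expects a 2-D image, got ndim={phase.ndim}")
    mult = 2**model.config.depth
    h, w = phase.shape
    ph = (mult - h % mult) % mult
    pw = (mult - w % mult) % mult
    x = _to_model(normalize_image(phase)).astype(nn.DTYPE)
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
    out = model.generator(x[None, None])[0, 0]
    return _from_model(out[:h, :w]).astype(np.float64)


def predict_tiles(model: TrainedTranslator, tiles, overlap: int = 0) -> np.ndarray:
    """Predict a grid of tiles and stitch them into one mosaic.

    Overlapping regions are blended with linear feathering ramps whose
    weights sum to one everywhere, so constant fields survive blending
    unchanged.  For an R x C grid of (th, tw) tiles the mosaic is
    (R*th - (R-1)*overlap, C*tw - (C-1)*overlap).
    """
    if overlap < 0:
        raise ValidationError("overlap must be >= 0")
    grid = [[np.asarray(t, dtype=np.float64) for t in row] for row in tiles]
    if not grid or not grid[0]:
        raise ValidationError("empty tile grid")
    th, tw = grid[0][0].shape
    if any(t.shape != (th, tw) for row in grid for t in row):
        raise ShapeError("all tiles must share one shape")
    nr, nc = len(grid), len(grid[0])
    if overlap >= min(th, tw):
        raise ValidationError("overlap must be smaller than the tile size")
    hh = nr * th - (nr - 1) * overlap
    ww = nc * tw - (nc - 1) * overlap
    acc = np.zeros((hh, ww))
    wacc = np.zeros((hh, ww))

    def ramp(n_tiles, idx, size):
        wt = np.ones(size)
        if overlap > 0:
            up = (np.arange(overlap) + 1.0) / (overlap + 1.0)
            if idx > 0:
                wt[:overlap] = up
            if idx < n_tiles - 1:
                wt[-overlap:] = up[::-1]
        return wt

    for r, row in enumerate(grid):
        for c, tile in enumerate(row):
            pred = predict(model, tile)
            wt = np.outer(ramp(nr, r, th), ramp(nc, c, tw))
            r0, c0 = r * (th - overlap), c * (tw - overlap)
            acc[r0 : r0 + th, c0 : c0 + tw] += pred * wt
            wacc[r0 : r0 + th, c0 : c0 + tw] += wt
    return acc / wacc


# ---------------------------------------------------------------------------
# persistence

def save_model(model: TrainedTranslator, path) -> None:
    """Single-file checkpoint: parameters + config + normalization."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "normalization": model.normalization,
    }
    arrays = {
        f"param_{i:03d}": a for i, a in enumerate(model.generator.state_arrays())
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> TrainedTranslator:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise FormatError(
                f"unsupported checkpoint version {meta.get('version')!r}; "
                f"expected {CHECKPOINT_VERSION!r}"
            )
        config = TranslatorConfig(**meta["config"])
        gen = build_generator(config)
        keys = sorted(k for k in z.files if k.startswith("param_"))
        gen.load_arrays([z[k] for k in keys])
    return TrainedTranslator(
        generator=gen, config=config, normalization=meta["normalization"]
    )
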