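"""Conditional-GAN architecture: U-Net generator, PatchGAN discriminator.

The generator is an encoder-decoder with skip connections between
mirrored resolution levels; each encoder level halves the spatial size
(4x4 conv, stride 2), each decoder level doubles it (nearest upsample +
3x3 conv).  The output activation is tanh, so generated images never
leave [-1, 1].  The discriminator is conditional: it scores the
channel-concatenated (input, candidate) pair and emits a 2D grid of
patch logits rather than a single scalar, so the adversarial signal
targets local high-frequency structure.

The training objective is the pix2pix one: binary cross-entropy on the
patch grid (labels 1 = real, 0 = fake; non-saturating generator term)
plus an L1 reconstruction term weighted by lambda (default 100).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import DTYPE, bce_with_logits, l1_loss


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net generator hyperparameters.

    ``depth`` is the number of 2x downsamplings (6 halves 64-256 px
    inputs down to a 1-4 px bottleneck); ``base_width`` is the feature
    count of the first level, doubling per level and capped at 8x.
    """

    in_channels: int = 1
    depth: int = 6
    base_width: int = 64
    seed: int = 0


@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN discriminator hyperparameters.

    ``n_strided`` strided blocks plus a two-conv head give roughly a
    70-px receptive field at the default 3; input is the 2-channel
    (condition, candidate) concatenation.
    """

    in_channels: int = 2
    n_strided: int = 3
    base_width: int = 64
    seed: int = 0


@dataclass(frozen=True)
class LossWeights:
    """Objective weights: total G loss = adv * BCE + l1 * L1."""

    adversarial: float = 1.0
    l1: float = 100.0
    real_label: float = 1.0
    fake_label: float = 0.0

    def __post_init__(self):
        if self.l1 < 0:
            raise ValueError("l1 weight must be >= 0")


def _channels(width: int, depth: int) -> list[int]:
    return [min(width * 2 ** i, 8 * width) for i in range(depth)]


class UNetGenerator:
    """U-Net image-to-image generator with tanh output in [-1, 1]."""

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = _channels(spec.base_width, spec.depth)
        d = spec.depth

        self.enc: list[nn.Sequential] = []
        prev = spec.in_channels
        for i in range(d):
            layers: list[nn.Layer] = [nn.Conv2d(prev, ch[i], 4, 2, 1, rng=rng)]
            if i > 0:
                layers.append(nn.InstanceNorm2d(ch[i]))
            layers.append(nn.LeakyReLU(0.2))
            self.enc.append(nn.Sequential(*layers))
            prev = ch[i]

        self.dec: list[nn.Sequential] = []
        self._dec_prev_ch: list[int] = []
        prev = ch[d - 1]
        for i in range(d):
            in_ch = prev if i == 0 else prev + ch[d - 1 - i]
            self._dec_prev_ch.append(prev)
            if i < d - 1:
                out_ch = ch[d - 2 - i]
                self.dec.append(nn.Sequential(
                    nn.UpsampleNearest(),
                    nn.Conv2d(in_ch, out_ch, 3, 1, 1, rng=rng),
                    nn.InstanceNorm2d(out_ch),
                    nn.ReLU(),
                ))
            else:
                out_ch = spec.in_channels
                self.dec.append(nn.Sequential(
                    nn.UpsampleNearest(),
                    nn.Conv2d(in_ch, out_ch, 3, 1, 1, rng=rng),
                    nn.Tanh(),
                ))
            prev = out_ch

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 4:
            raise ValueError("expected NCHW input")
        h, w = x.shape[2:]
        div = 2 ** self.spec.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial size {(h, w)} not divisible by 2^depth = {div}")
        skips = []
        out = x
        for blk in self.enc:
            out = blk.forward(out)
            skips.append(out)
        self._skips = skips
        d = out
        for i, blk in enumerate(self.dec):
            inp = d if i == 0 else np.concatenate([d, skips[len(self.enc) - 1 - i]], axis=1)
            d = blk.forward(inp)
        return d

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        depth = len(self.enc)
        gskips = [None] * depth
        g = gy
        for i in reversed(range(depth)):
            ginp = self.dec[i].backward(g)
            if i == 0:
                g = ginp
            else:
                split = self._dec_prev_ch[i]
                g = ginp[:, :split]
                s = depth - 1 - i
                gskips[s] = ginp[:, split:] if gskips[s] is None else gskips[s] + ginp[:, split:]
        for i in reversed(range(depth)):
            if gskips[i] is not None:
                g = g + gskips[i]
            g = self.enc[i].backward(g)
        return g

    # -- bookkeeping --------------------------------------------------------
    def named_params(self):
        for j, blk in enumerate(self.enc):
            yield from blk.named_params(f"enc{j}.")
        for j, blk in enumerate(self.dec):
            yield from blk.named_params(f"dec{j}.")

    def zero_grad(self) -> None:
        for blk in (*self.enc, *self.dec):
            blk.zero_grad()


class PatchDiscriminator:
    """Conditional PatchGAN: (x, y) pairs -> 2D grid of patch logits."""

    def __init__(self, spec: DiscriminatorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = _channels(spec.base_width, spec.n_strided + 1)
        layers: list[nn.Layer] = []
        prev = spec.in_channels
        for i in range(spec.n_strided):
            layers.append(nn.Conv2d(prev, ch[i], 4, 2, 1, rng=rng))
            if i > 0:
                layers.append(nn.InstanceNorm2d(ch[i]))
            layers.append(nn.LeakyReLU(0.2))
            prev = ch[i]
        layers += [
            nn.Conv2d(prev, ch[-1], 4, 1, 1, rng=rng),
            nn.InstanceNorm2d(ch[-1]),
            nn.LeakyReLU(0.2),
            nn.Conv2d(ch[-1], 1, 4, 1, 1, rng=rng),
        ]
        self.net = nn.Sequential(*layers)

    def forward(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        pair = np.concatenate([np.asarray(x, dtype=DTYPE),
                               np.asarray(y, dtype=DTYPE)], axis=1)
        self._n_cond = x.shape[1]
        return self.net.forward(pair)

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Returns the gradient w.r.t. the *candidate* channels only."""
        gpair = self.net.backward(gy)
        return gpair[:, self._n_cond:]

    def named_params(self):
        yield from self.net.named_params()

    def zero_grad(self) -> None:
        self.net.zero_grad()


def build_generator(spec: GeneratorSpec, image_size: int | None = None) -> UNetGenerator:
    """Build a seeded U-Net generator; optionally pre-check divisibility."""
    if image_size is not None and image_size % 2 ** spec.depth:
        raise ValueError(
            f"image size {image_size} not divisible by 2^depth = {2 ** spec.depth}")
    return UNetGenerator(spec)


def build_discriminator(spec: DiscriminatorSpec,
                        image_size: int | None = None) -> PatchDiscriminator:
    if image_size is not None and image_size % 2 ** spec.n_strided:
        raise ValueError(
            f"image size {image_size} not divisible by 2^{spec.n_strided}")
    return PatchDiscriminator(spec)


def cgan_losses(d_real: np.ndarray, d_fake: np.ndarray, y: np.ndarray,
                g_out: np.ndarray, w: LossWeights = LossWeights()
                ) -> tuple[float, float]:
    """The conditional-GAN objective values for one batch.

    discriminator loss = mean of the two BCE terms pushing real patches
    to the real label and fake patches to the fake label; generator loss
    = adversarial BCE (fake patches toward the real label,
    non-saturating) + lambda * mean absolute error.
    """
    if d_real.shape != d_fake.shape:
        raise ValueError("patch grids must share a shape")
    if np.shape(y) != np.shape(g_out):
        raise ValueError("target and generated images must share a shape")
    d_loss = 0.5 * (bce_with_logits(d_real, w.real_label)
                    + bce_with_logits(d_fake, w.fake_label))
    g_loss = (w.adversarial * bce_with_logits(d_fake, w.real_label)
              + w.l1 * l1_loss(y, g_out))
    return g_loss, d_loss


def checksum(model) -> str:
    """SHA-256 over the model's parameters, for determinism checks."""
    h = hashlib.sha256()
    for name, layer, k in sorted(model.named_params(), key=lambda t: t[0]):
        h.update(name.encode())
        h.update(np.ascontiguousarray(layer.params[k]).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stub generators (baselines and closure tests)
# ---------------------------------------------------------------------------

class IdentityGenerator:
    """Returns its input unchanged (method-1 copy baseline)."""

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=DTYPE)


class ConstantGenerator:
    """Returns a constant image (value 0 = method-2 copy baseline)."""

    def __init__(self, value: float = 0.0):
        self.value = value

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(x, dtype=DTYPE), self.value)


class OracleGenerator:
    """Looks up the ground-truth target for each input it was built from.

    Keyed on the input image bytes; raises on unseen inputs.  Used to
    close the loop between pairing, inference, and assembly without any
    learned model in between.
    """

    def __init__(self, examples):
        self._table = {
            np.asarray(ex.input, dtype=DTYPE).tobytes(): np.asarray(ex.target, dtype=DTYPE)
            for ex in examples
        }

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        out = np.empty_like(x)
        for i in range(x.shape[0]):
            key = x[i, 0].tobytes()
            if key not in self._table:
                raise KeyError("input not in oracle table")
            out[i, 0] = self._table[key]
        return out
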