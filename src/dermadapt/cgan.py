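"""Conditional GAN for class-conditional synthesis of lesion-like images.

Generator: six transposed-convolution layers; layers 1–5 are each followed
by batch normalisation and ReLU, the final layer by ReLU alone (its output
is clamped to [0, 1] to define pixel semantics — the ReLU output head is
nonstandard relative to tanh but is the architecture this package
implements faithfully).  Class labels are embedded and concatenated to the
noise vector.

Discriminator: six convolution layers; the first is followed by LeakyReLU,
layers 2–5 by batch normalisation and LeakyReLU, the sixth by a sigmoid
real/fake score.  The label enters as an extra learned per-class input
channel map.

Training: alternating discriminator/generator updates with binary
cross-entropy adversarial losses, Adam (lr 2e-4, β1 = 0.5), default 30
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Adam, ForwardContext, Tensor
from .nn import functional as F
from .nn.layers import seed_rng

__all__ = ["CGANSpec", "Generator", "Discriminator", "build_cgan",
           "generate", "train_cgan", "CGANHistory"]


@dataclass(frozen=True)
class CGANSpec:
    """Architecture and optimisation settings for the conditional GAN."""

    noise_dim: int = 100
    n_classes: int = 2
    image_size: int = 64
    base_channels: int = 512   # widest generator layer; halves upward
    label_embed_dim: int = 16
    lr: float = 2e-4
    beta1: float = 0.5
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32 or (self.image_size & (self.image_size - 1)):
            raise ValueError("image_size must be a power of two >= 32")
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")


def _widths(base: int) -> list[int]:
    """Geometric halving from ``base`` over five stages, floored at 8 so
    scaled-down test configurations keep usable capacity."""
    return [max(base // (2 ** i), 8) for i in range(5)]


class Generator(nn.Module):
    """(noise ⊕ label embedding) -> (n, 3, s, s) image batch in [0, 1].

    Six transposed-conv layers: one projection from 1x1 to s/16, four
    stride-2 doublings, and a final same-size refinement layer.
    """

    def __init__(self, spec: CGANSpec):
        super().__init__("gen")
        self.spec = spec
        seed = spec.seed
        s0 = spec.image_size // 16
        cw = _widths(spec.base_channels)  # e.g. 512..32
        zin = spec.noise_dim + spec.label_embed_dim
        rng = seed_rng(seed, "gen.embed")
        # unit-scale embedding: the label must be as loud as the noise it
        # is concatenated with
        self.label_table = self.add_param(
            "label_embed", rng.normal(0.0, 1.0,
                                      (spec.n_classes, spec.label_embed_dim)))
        defs = [
            ("l1", zin, cw[0], s0, 1, 0, True),
            ("l2", cw[0], cw[1], 4, 2, 1, True),
            ("l3", cw[1], cw[2], 4, 2, 1, True),
            ("l4", cw[2], cw[3], 4, 2, 1, True),
            ("l5", cw[3], cw[4], 4, 2, 1, True),
            ("l6", cw[4], 3, 3, 1, 1, False),
        ]
        self.blocks = []
        for name, ci, co, k, st, pad, bn in defs[:-1]:
            layers = [nn.ConvTranspose2d(f"gen.{name}.convT", ci, co, k, seed,
                                         stride=st, pad=pad)]
            if bn:
                layers.append(nn.BatchNorm(f"gen.{name}.bn", co))
            layers.append(nn.ReLU(f"gen.{name}.relu"))
            block = nn.Sequential(f"gen.{name}", layers)
            self.add_child(block)
            self.blocks.append(block)
        # output head: rectified-and-saturated [0, 1] pixels.  The forward
        # value equals ReLU followed by the [0, 1] clamp; the backward is
        # straight-through, because a one-sided-dead output head lets the
        # generator drift to black and freeze there.
        name, ci, co, k, st, pad, _ = defs[-1]
        head = nn.Sequential(f"gen.{name}", [
            nn.ConvTranspose2d(f"gen.{name}.convT", ci, co, k, seed,
                               stride=st, pad=pad)])
        self.add_child(head)
        self.blocks.append(head)
        head.layers[0].bias.data[:] = 0.5  # start at mid-grey

    def forward(self, z_and_label: Tensor, ctx):
        x = z_and_label  # (n, 1, 1, zin) channels-last
        for block in self.blocks:
            x = block(x, ctx)
        return F.clip01_straight_through(x)  # (n, s, s, 3) in [0, 1]

    def synthesize(self, class_labels, seed: int, ctx=None) -> np.ndarray:
        """Deterministic class-conditional sampling -> (n, 3, s, s) in [0,1]."""
        labels = np.asarray(class_labels, dtype=np.int64)
        if labels.ndim != 1 or not np.isin(labels, range(self.spec.n_classes)).all():
            raise ValueError(f"labels must be a 1-D sequence over "
                             f"{{0..{self.spec.n_classes - 1}}}")
        rng = seed_rng(seed, "gen.noise")
        z = rng.normal(0.0, 1.0, (labels.size, self.spec.noise_dim)) \
            .astype(np.float32)
        emb = self.label_table.data[labels]
        zin = np.concatenate([z, emb], axis=1)[:, None, None, :]
        ctx = ctx or ForwardContext(train=False)
        out = self.forward(Tensor(zin), ctx)
        return np.ascontiguousarray(out.data.transpose(0, 3, 1, 2))


class Discriminator(nn.Module):
    """(image, label map) -> real/fake probability per image."""

    def __init__(self, spec: CGANSpec):
        super().__init__("disc")
        self.spec = spec
        seed = spec.seed
        s = spec.image_size
        cw = _widths(spec.base_channels)[::-1]  # narrow -> wide
        # one learned s*s map per class, appended as a fourth input channel;
        # initialised to distinct constants so the label is trivially
        # readable from the start
        init_maps = np.linspace(0.0, 1.0, spec.n_classes)[:, None] \
            * np.ones((1, s * s))
        self.label_map = self.add_param("label_map", init_maps)
        defs = [("l1", 4, cw[0], False), ("l2", cw[0], cw[1], True),
                ("l3", cw[1], cw[2], True), ("l4", cw[2], cw[3], True),
                ("l5", cw[3], cw[4], True)]
        self.blocks = []
        for name, ci, co, bn in defs:
            layers = [nn.Conv2d(f"disc.{name}.conv", ci, co, 4, seed,
                                stride=2, pad=1)]
            if bn:
                layers.append(nn.BatchNorm(f"disc.{name}.bn", co))
            layers.append(nn.LeakyReLU(f"disc.{name}.lrelu", 0.2))
            block = nn.Sequential(f"disc.{name}", layers)
            self.add_child(block)
            self.blocks.append(block)
        self.final = self.add_child(
            nn.Conv2d("disc.l6.conv", cw[4], 1, s // 32, seed, stride=1,
                      pad=0))

    def forward(self, images_nhwc: Tensor, ctx, class_labels=None):
        labels = np.asarray(class_labels, dtype=np.int64)
        maps = F.embedding(
            self._params["label_map"], labels)
        maps = F.reshape(maps, (labels.size, self.spec.image_size,
                                self.spec.image_size, 1))
        x = F.concat([images_nhwc, maps], axis=3)
        for block in self.blocks:
            x = block(x, ctx)
        score = self.final(x, ctx)          # (n, 1, 1, 1)
        return F.sigmoid(F.reshape(score, (labels.size, 1)))


def build_cgan(spec: CGANSpec) -> tuple[Generator, Discriminator]:
    return Generator(spec), Discriminator(spec)


def generate(generator: Generator, class_labels, seed: int) -> np.ndarray:
    """Class-conditional image synthesis; bit-reproducible given the seed."""
    return generator.synthesize(class_labels, seed)


@dataclass
class CGANHistory:
    d_loss: list
    g_loss: list


def train_cgan(images, labels, spec: CGANSpec):
    """Adversarial training on (n, 3, s, s) images in [0, 1] with 0/1 labels.

    Alternates one discriminator update (real batch + fake batch, BCE toward
    1/0) with one generator update (BCE toward 1 through the frozen-D graph)
    per step.  Returns (generator, discriminator, history).
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if images.ndim != 4 or images.shape[1] != 3 \
            or images.shape[2] != spec.image_size:
        raise ValueError(f"expected (n, 3, {spec.image_size}, "
                         f"{spec.image_size}) images, got {images.shape}")
    counts = np.bincount(labels, minlength=spec.n_classes)
    if (counts < 2).any():
        raise ValueError("conditioning degenerate: need >= 2 images per class")

    gen, disc = build_cgan(spec)
    opt_g = Adam(gen.parameters(), lr=spec.lr, betas=(spec.beta1, 0.999))
    opt_d = Adam(disc.parameters(), lr=spec.lr, betas=(spec.beta1, 0.999))
    n = images.shape[0]
    batch = min(spec.batch_size, n)
    nhwc = np.ascontiguousarray(images.transpose(0, 2, 3, 1))
    history = CGANHistory([], [])
    noise_rng = seed_rng(spec.seed, "cgan.noise")
    step = 0
    for epoch in range(spec.epochs):
        order = seed_rng(spec.seed, "cgan.order", epoch).permutation(n)
        d_sum = g_sum = 0.0
        nb = 0
        for start in range(0, n - batch + 1, batch):
            idx = order[start:start + batch]
            real = Tensor(nhwc[idx])
            y = labels[idx]
            bs = len(idx)
            ctx = ForwardContext(True, spec.seed, step, tag=0)

            # --- discriminator update ---------------------------------
            z = noise_rng.normal(0.0, 1.0, (bs, spec.noise_dim)) \
                .astype(np.float32)
            fake_y = noise_rng.integers(0, spec.n_classes, bs)
            emb = gen._params["label_embed"].data[fake_y]
            zin = Tensor(np.concatenate([z, emb], 1)[:, None, None, :])
            fake = gen.forward(zin, ctx)
            p_real = disc.forward(real, ctx, y)
            # same-step D pass on fakes reuses the real batch's BN scale
            ctx_f = ForwardContext(True, spec.seed, step, tag=1,
                                   bn_stats="reuse")
            fake_const = Tensor(np.clip(fake.data, 0.0, 1.0))  # detached
            p_fake = disc.forward(fake_const, ctx_f, fake_y)
            d_loss = F.add(F.binary_cross_entropy(p_real, np.ones((bs, 1))),
                           F.binary_cross_entropy(p_fake, np.zeros((bs, 1))))
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # --- generator update -------------------------------------
            step += 1
            ctx2 = ForwardContext(True, spec.seed, step, tag=0)
            # D is evaluated under the real batch's BN anchoring here too,
            # so G is scored in the same normalisation regime as D trains in
            ctx2_d = ForwardContext(True, spec.seed, step, tag=0,
                                    bn_stats="reuse")
            z2 = noise_rng.normal(0.0, 1.0, (bs, spec.noise_dim)) \
                .astype(np.float32)
            gy = noise_rng.integers(0, spec.n_classes, bs)
            emb2 = F.embedding(gen._params["label_embed"], gy)
            zin2 = F.reshape(
                F.concat([Tensor(z2), emb2], axis=1),
                (bs, 1, 1, spec.noise_dim + spec.label_embed_dim))
            fake2 = gen.forward(zin2, ctx2)
            p_gen = disc.forward(fake2, ctx2_d, gy)
            g_loss = F.binary_cross_entropy(p_gen, np.ones((bs, 1)))
            opt_g.zero_grad()
            # D's parameters also collect gradients here; only G steps
            g_loss.backward()
            opt_g.step()
            step += 1

            d_sum += d_loss.item()
            g_sum += g_loss.item()
            nb += 1
        history.d_loss.append(d_sum / nb)
        history.g_loss.append(g_sum / nb)
    return gen, disc, history
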