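"""Residual 3D U-Net generator, conditional 3D PatchGAN, and training loop.

The generator maps a multi-channel condition volume (image, appearance
prior, shape prior — or fewer channels in ablated configurations) to a
single-channel logit volume of the same spatial shape. Its encoder doubles
feature channels per level (base 64 up to a 512 cap in the full preset;
8 up to 64 in the tiny CPU preset) with anisotropic stride (1, 2, 2), so
the slice axis is never downsampled; the decoder restores resolution with
trilinear upsampling and residual decoding blocks fed by skip connections.

The discriminator is a conditional PatchGAN: it sees the mask concatenated
with the condition volume and emits a spatial grid of patch logits rather
than one scalar, judging local realism everywhere.

Losses (binary cross-entropy with logits, 1/0 grids matching the patch
output):

    L_D = 1/2 [ BCE(D(y, c), 1) + BCE(D(ŷ, c), 0) ]
    L_G = BCE(D(ŷ, c), 1) + λ_rec · mean |ŷ − y|,   λ_rec = 200

with ŷ the generator's sigmoid output; the predicted mask at inference is
sigmoid(logit) ≥ 0.5, i.e. logit ≥ 0 (ties to foreground). Training
alternates one discriminator and one generator step per sample at batch
size 1 (Adam, lr 4e-4, betas (0.5, 0.999)); a fixed seed reproduces the
full loss history on the same backend.
"""

from __future__ import annotations

import copy
import pickle
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import BinaryMask
from .metrics import dice
from .nn import (
    Adam,
    Conv3d,
    ConvBlock,
    Module,
    Param,
    ResBlock,
    UpsampleInPlane2x,
    bce_with_logits,
    l1_loss,
    sigmoid,
)

__all__ = [
    "ConditionVolume",
    "GeneratorConfig",
    "DiscriminatorConfig",
    "TrainConfig",
    "ResidualUNet3D",
    "PatchGAN3D",
    "loss_discriminator",
    "loss_generator",
    "train",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
    "TINY_GENERATOR",
    "TINY_DISCRIMINATOR",
]


@dataclass
class ConditionVolume:
    """Ordered condition channels on one lattice.

    The full configuration stacks (c1, c2, c3) = (image in [0,1],
    appearance map, shape prior); ablated configurations carry one or three
    channels. Channels are stored as one (C, D, H, W) float32 array.
    """

    channels: np.ndarray
    names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.channels = np.ascontiguousarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4:
            raise ValueError(f"expected (C, D, H, W), got shape {self.channels.shape}")
        if not self.names:
            self.names = tuple(f"c{i + 1}" for i in range(self.channels.shape[0]))
        if len(self.names) != self.channels.shape[0]:
            raise ValueError("one name per channel required")

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return self.channels.shape[1:]  # type: ignore[return-value]


@dataclass
class GeneratorConfig:
    in_channels: int = 3
    base_channels: int = 64
    max_channels: int = 512
    n_levels: int = 4
    stride: Tuple[int, int, int] = (1, 2, 2)

    def channel_sequence(self) -> List[int]:
        return [min(self.base_channels * 2**i, self.max_channels) for i in range(self.n_levels)]


@dataclass
class DiscriminatorConfig:
    cond_channels: int = 3
    base_channels: int = 64
    max_channels: int = 256
    n_blocks: int = 3
    stride: Tuple[int, int, int] = (1, 2, 2)

    def channel_sequence(self) -> List[int]:
        return [min(self.base_channels * 2**i, self.max_channels) for i in range(self.n_blocks)]


@dataclass
class TrainConfig:
    epochs: int = 200
    lr: float = 4e-4
    batch_size: int = 1
    lambda_rec: float = 200.0
    betas: Tuple[float, float] = (0.5, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_rec < 0:
            raise ValueError("lambda_rec must be >= 0")
        if self.batch_size != 1:
            raise ValueError("training operates at batch size 1")


TINY_GENERATOR = GeneratorConfig(base_channels=8, max_channels=64)
TINY_DISCRIMINATOR = DiscriminatorConfig(base_channels=8, max_channels=32)


class ResidualUNet3D(Module):
    """Encoder-decoder generator with skip connections and residual decoding."""

    def __init__(self, cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        ch = cfg.channel_sequence()
        self.stem = ConvBlock(cfg.in_channels, ch[0], rng=rng)
        self.downs = [
            ConvBlock(ch[i - 1], ch[i], stride=cfg.stride, rng=rng)
            for i in range(1, cfg.n_levels)
        ]
        self.bottleneck = ResBlock(ch[-1], ch[-1], rng=rng)
        self.ups = [UpsampleInPlane2x() for _ in range(cfg.n_levels - 1)]
        self.dec = [
            ResBlock(ch[i + 1] + ch[i], ch[i], rng=rng)
            for i in reversed(range(cfg.n_levels - 1))
        ]
        self.head = Conv3d(ch[0], 1, kernel=1, rng=rng)

    def params(self) -> List[Param]:
        out = self.stem.params()
        for d in self.downs:
            out += d.params()
        out += self.bottleneck.params()
        for d in self.dec:
            out += d.params()
        out += self.head.params()
        return out

    def buffers(self) -> List[np.ndarray]:
        out = self.stem.buffers()
        for d in self.downs:
            out += d.buffers()
        out += self.bottleneck.buffers()
        for d in self.dec:
            out += d.buffers()
        return out

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected ({self.cfg.in_channels}, D, H, W) input, got {x.shape}"
            )
        div = 2 ** (self.cfg.n_levels - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"H and W must be multiples of {div} for {self.cfg.n_levels} levels, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_input(x)
        skips = [self.stem.forward(x, train)]
        for down in self.downs:
            skips.append(down.forward(skips[-1], train))
        y = self.bottleneck.forward(skips[-1], train)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips[:-1])):
            y = up.forward(y, train)
            self._skip_channels.append(y.shape[0])
            y = dec.forward(np.concatenate([y, skip], axis=0), train)
        return self.head.forward(y, train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.head.backward(gout)
        # decoder stage j consumed skips[n_levels-2-j]; walking the stages in
        # reverse therefore yields skip gradients in stem-first order, so
        # gskips[i] is the direct gradient w.r.t. skips[i].
        gskips: List[np.ndarray] = []
        for up, dec, c_up in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            gcat = dec.backward(g)
            gskips.append(gcat[c_up:].copy())
            g = up.backward(np.ascontiguousarray(gcat[:c_up]))
        g = self.bottleneck.backward(g)  # now grad w.r.t. skips[-1]
        for i in range(len(self.downs) - 1, -1, -1):
            g = self.downs[i].backward(g) + gskips[i]
        return self.stem.backward(g)


class PatchGAN3D(Module):
    """Conditional PatchGAN: mask+condition concat in, spatial logit grid out."""

    def __init__(self, cfg: DiscriminatorConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        ch = cfg.channel_sequence()
        c_in = cfg.cond_channels + 1
        self.blocks: List[ConvBlock] = []
        prev = c_in
        for i, c in enumerate(ch):
            # first block keeps pix2pix convention: no normalization
            self.blocks.append(
                ConvBlock(prev, c, stride=cfg.stride, act="lrelu", norm=(i > 0), rng=rng)
            )
            prev = c
        self.head = Conv3d(prev, 1, kernel=3, rng=rng)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for b in self.blocks:
            out += b.params()
        return out + self.head.params()

    def buffers(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for b in self.blocks:
            out += b.buffers()
        return out

    def forward(self, mask_channel: np.ndarray, cond: np.ndarray, train: bool = True) -> np.ndarray:
        if mask_channel.shape[1:] != cond.shape[1:]:
            raise ValueError(
                f"mask/condition spatial mismatch: {mask_channel.shape[1:]} vs {cond.shape[1:]}"
            )
        if cond.shape[0] != self.cfg.cond_channels:
            raise ValueError(
                f"expected {self.cfg.cond_channels} condition channels, got {cond.shape[0]}"
            )
        y = np.concatenate([mask_channel, cond], axis=0).astype(np.float32)
        for b in self.blocks:
            y = b.forward(y, train)
        return self.head.forward(y, train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.head.backward(gout)
        for b in reversed(self.blocks):
            g = b.backward(g)
        return g  # gradient w.r.t. the (mask ++ cond) concatenation


def loss_discriminator(
    disc: PatchGAN3D,
    real_mask: np.ndarray,
    fake_mask: np.ndarray,
    cond: np.ndarray,
    accumulate: bool = True,
) -> float:
    """L_D = 1/2 [BCE(D(y,c), 1) + BCE(D(ŷ,c), 0)], grads accumulated in place.

    ``fake_mask`` must already be detached from the generator (a plain
    array); each term's gradient is scaled by 1/2 and backpropagated right
    after its forward pass so layer caches stay consistent.
    """
    logit_real = disc.forward(real_mask, cond, train=accumulate)
    loss_real, g_real = bce_with_logits(logit_real, 1.0)
    if accumulate:
        disc.backward(0.5 * g_real)
    logit_fake = disc.forward(fake_mask, cond, train=accumulate)
    loss_fake, g_fake = bce_with_logits(logit_fake, 0.0)
    if accumulate:
        disc.backward(0.5 * g_fake)
    return 0.5 * (loss_real + loss_fake)


def loss_generator(
    disc: PatchGAN3D,
    fake_prob: np.ndarray,
    real_mask: np.ndarray,
    cond: np.ndarray,
    lambda_rec: float = 200.0,
    want_grad: bool = True,
) -> tuple[float, float, Optional[np.ndarray]]:
    """L_G = BCE(D(ŷ,c), 1) + λ_rec · mean|ŷ − y|.

    Returns (adversarial term, l1 term, gradient w.r.t. ŷ). ŷ is the
    generator's sigmoid output. Discriminator parameter gradients touched
    here are discarded by the caller (the discriminator is re-zeroed before
    its own step).
    """
    logit_fake = disc.forward(fake_prob, cond, train=want_grad)
    adv, g_logit = bce_with_logits(logit_fake, 1.0)
    l1, g_l1 = l1_loss(fake_prob, real_mask)
    if not want_grad:
        return adv, l1, None
    g_concat = disc.backward(g_logit)
    g_fake = g_concat[: fake_prob.shape[0]] + lambda_rec * g_l1
    return adv, l1, g_fake


def predict_mask(gen: ResidualUNet3D, cond: ConditionVolume) -> BinaryMask:
    """Deterministic thresholded inference: sigmoid(logit) ≥ 0.5 ⇔ logit ≥ 0."""
    logit = gen.forward(cond.channels, train=False)
    return BinaryMask(data=(logit[0] >= 0.0).astype(np.uint8))


def _clone_state(net) -> List[np.ndarray]:
    """Snapshot of weights plus normalization running moments."""
    return [p.data.copy() for p in net.params()] + [b.copy() for b in net.buffers()]


def _restore_state(net, saved: Sequence[np.ndarray]) -> None:
    params = net.params()
    for p, s in zip(params, saved):
        p.data[...] = s
    for b, s in zip(net.buffers(), saved[len(params):]):
        b[...] = s


def train(
    pairs: Sequence[Tuple[ConditionVolume, BinaryMask]],
    cfg: TrainConfig,
    gen_cfg: Optional[GeneratorConfig] = None,
    disc_cfg: Optional[DiscriminatorConfig] = None,
    val_pairs: Sequence[Tuple[ConditionVolume, BinaryMask]] = (),
) -> tuple[ResidualUNet3D, pd.DataFrame]:
    """Alternating D/G optimization at batch size 1.

    Per sample: one discriminator step on (real, detached fake), then one
    generator step through the frozen-for-this-step discriminator. When
    validation pairs are given, the epoch with the best mean validation
    Dice is kept and its weights restored at the end (checkpoint
    selection); otherwise the final weights are returned. Aborts on
    non-finite losses with the offending epoch/sample.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    n_cond = pairs[0][0].channels.shape[0]
    gen_cfg = gen_cfg or GeneratorConfig(in_channels=n_cond)
    disc_cfg = disc_cfg or DiscriminatorConfig(cond_channels=n_cond)
    if gen_cfg.in_channels != n_cond:
        gen_cfg = GeneratorConfig(
            in_channels=n_cond,
            base_channels=gen_cfg.base_channels,
            max_channels=gen_cfg.max_channels,
            n_levels=gen_cfg.n_levels,
            stride=gen_cfg.stride,
        )
    if disc_cfg.cond_channels != n_cond:
        disc_cfg = DiscriminatorConfig(
            cond_channels=n_cond,
            base_channels=disc_cfg.base_channels,
            max_channels=disc_cfg.max_channels,
            n_blocks=disc_cfg.n_blocks,
            stride=disc_cfg.stride,
        )

    rng = np.random.default_rng(cfg.seed)
    gen = ResidualUNet3D(gen_cfg, rng=rng)
    disc = PatchGAN3D(disc_cfg, rng=rng)
    opt_g = Adam(gen.params(), lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(disc.params(), lr=cfg.lr, betas=cfg.betas)

    history = []
    best_val = -1.0
    best_weights: Optional[List[np.ndarray]] = None
    best_epoch = -1

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        d_losses, adv_losses, l1_losses = [], [], []
        for idx in order:
            cond, mask = pairs[idx]
            x = cond.channels
            y = mask.data[None].astype(np.float32)

            fake_logit = gen.forward(x, train=True)
            fake_prob = sigmoid(fake_logit)

            opt_d.zero_grad()
            ld = loss_discriminator(disc, y, fake_prob, x)
            opt_d.step()

            disc.zero_grad()
            adv, l1, g_fake = loss_generator(
                disc, fake_prob, y, x, lambda_rec=cfg.lambda_rec
            )
            # chain through the sigmoid: dL/dlogit = dL/dŷ · ŷ(1−ŷ)
            g_logit = g_fake * fake_prob * (1.0 - fake_prob)
            opt_g.zero_grad()
            gen.backward(g_logit.astype(np.float32))
            opt_g.step()

            lg = adv + cfg.lambda_rec * l1
            if not (np.isfinite(ld) and np.isfinite(lg)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample {int(idx)}: "
                    f"L_D={ld}, L_G={lg}"
                )
            d_losses.append(ld)
            adv_losses.append(adv)
            l1_losses.append(l1)

        row = {
            "epoch": epoch,
            "loss_d": float(np.mean(d_losses)),
            "loss_g_adv": float(np.mean(adv_losses)),
            "loss_g_l1": float(np.mean(l1_losses)),
        }
        if len(val_pairs) > 0:
            val_dice = float(
                np.mean([dice(predict_mask(gen, c), m) for c, m in val_pairs])
            )
            row["val_dice"] = val_dice
            if val_dice > best_val:
                best_val = val_dice
                best_weights = _clone_state(gen)
                best_epoch = epoch
        history.append(row)

    if best_weights is not None:
        _restore_state(gen, best_weights)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return gen, hist


def save_checkpoint(path, gen: ResidualUNet3D, train_cfg: Optional[TrainConfig] = None) -> None:
    """Serialize generator weights + normalization state + configs."""
    payload = {
        "gen_cfg": gen.cfg,
        "train_cfg": train_cfg,
        "state": _clone_state(gen),
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path) -> tuple[ResidualUNet3D, Optional[TrainConfig]]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    gen = ResidualUNet3D(payload["gen_cfg"])
    _restore_state(gen, payload["state"])
    return gen, payload["train_cfg"]


def checkpoint_bytes(gen: ResidualUNet3D) -> bytes:
    """Canonical byte serialization of the generator state (audit helper)."""
    return pickle.dumps([a.tobytes() for a in _clone_state(gen)])
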