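"""Dual-headed volumetric encoder-decoder network for joint inner-ear
segmentation and landmark-heatmap regression.

One shared encoder distills context from a CT chunk; two structurally
identical decoders consume the bottleneck features and the (optionally
attention-gated) encoder skips. The segmentation head ends in a single
sigmoid channel (foreground pseudo-probability), the heatmap head in three
linear channels, one per landmark (helicotrema, oval window, round window).

The basic building block is a double-convolution module: twice the sequence
normalization -> 3x3x3 convolution -> nonlinearity. Downsampling uses
stride-2 kernel-2 convolutions, upsampling stride-2 kernel-2 transposed
convolutions; the channel count is held constant across a level transition.
Optional deep supervision attaches auxiliary 1x1x1 output heads to the
intermediate decoder levels (terminals t1..t(levels-1) at 1/2, 1/4, ...
resolution, terminal t0 being the full-resolution output).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Activation, Conv3d, ConvTranspose3d, Module, Tensor, concat, make_norm

ATTENTION_MODES = ("none", "seg_head", "heatmap_head", "global")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters (the ablation axes are all here)."""

    levels: int = 4
    channels: tuple[int, ...] = (32, 64, 128, 256, 320)
    norm: str = "instance"
    activation: str = "leaky_relu"
    activation_slope: float = 0.025
    attention: str = "none"
    deep_supervision: bool = True
    tasks: str = "both"  # "both" | "segmentation" | "heatmap" (single-task ablation)
    seg_channels: int = 1
    heatmap_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != self.levels + 1:
            raise ValueError(
                f"channels must have levels+1={self.levels + 1} entries, "
                f"got {len(self.channels)}"
            )
        if self.attention not in ATTENTION_MODES:
            raise ValueError(f"attention must be one of {ATTENTION_MODES}")
        if self.seg_channels != 1:
            raise ValueError("segmentation head is single-channel")
        if self.heatmap_channels != 3:
            raise ValueError("heatmap head carries exactly three landmark channels")
        if self.activation not in Activation.NAMES:
            raise ValueError(f"activation must be one of {Activation.NAMES}")
        if self.norm not in ("instance", "batch"):
            raise ValueError("norm must be 'instance' or 'batch'")
        if self.tasks not in ("both", "segmentation", "heatmap"):
            raise ValueError("tasks must be 'both', 'segmentation' or 'heatmap'")

    def validate_chunk(self, edge: int):
        if edge % (2**self.levels) != 0:
            raise ValueError(
                f"chunk edge {edge} not divisible by 2^levels = {2**self.levels}"
            )


@dataclass
class PredictionBundle:
    """Outputs of one forward pass on a chunk.

    ``seg``: (1, D, H, W) sigmoid probabilities; ``heatmaps``: (3, D, H, W)
    unbounded; ``aux``: deep-supervision (seg, heatmaps) pairs at 1/2^i
    resolution for i = 1..levels-1, or None.
    """

    seg: Tensor | None
    heatmaps: Tensor | None
    aux: list[tuple[Tensor | None, Tensor | None]] | None = None


class DoubleConv(Module):
    """(norm -> conv3 -> act) twice."""

    def __init__(self, cin, cout, cfg: NetworkConfig, rng):
        super().__init__()
        self.n1 = make_norm(cfg.norm, cin)
        self.c1 = Conv3d(cin, cout, 3, rng)
        self.a1 = Activation(cfg.activation, rng, cfg.activation_slope)
        self.n2 = make_norm(cfg.norm, cout)
        self.c2 = Conv3d(cout, cout, 3, rng)
        self.a2 = Activation(cfg.activation, rng, cfg.activation_slope)

    def __call__(self, x):
        x = self.a1(self.c1(self.n1(x)))
        return self.a2(self.c2(self.n2(x)))


class AttentionGate(Module):
    """Additive attention over a skip connection.

    The gating signal is the decoder feature already upsampled to the skip's
    resolution. Both inputs are projected to ``cin // 2`` channels by 1x1x1
    convolutions, summed, rectified, projected to one channel and squashed
    to [0, 1]; the coefficient multiplies the skip features voxel-wise.
    """

    def __init__(self, cin: int, rng):
        super().__init__()
        inter = max(1, cin // 2)
        self.theta = Conv3d(cin, inter, 1, rng)
        self.phi = Conv3d(cin, inter, 1, rng)
        self.psi = Conv3d(inter, 1, 1, rng)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        return self.psi((self.theta(skip) + self.phi(gate)).relu()).sigmoid()

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        return skip * self.coefficients(skip, gate)


class Decoder(Module):
    def __init__(self, cfg: NetworkConfig, out_channels: int, gated: bool, rng):
        super().__init__()
        self.levels = cfg.levels
        self.gated = gated
        c = cfg.channels
        for i in reversed(range(cfg.levels)):
            self.register_child(f"up{i}", ConvTranspose3d(c[i + 1], c[i], rng))
            if gated:
                self.register_child(f"gate{i}", AttentionGate(c[i], rng))
            self.register_child(f"block{i}", DoubleConv(2 * c[i], c[i], cfg, rng))
            if cfg.deep_supervision and i >= 1:
                self.register_child(f"aux{i}", Conv3d(c[i], out_channels, 1, rng))
        self.head = Conv3d(c[0], out_channels, 1, rng)
        self.deep_supervision = cfg.deep_supervision

    def __call__(self, x: Tensor, skips: list[Tensor]):
        aux: list[Tensor] = []
        for i in reversed(range(self.levels)):
            x = getattr(self, f"up{i}")(x)
            s = skips[i]
            if self.gated:
                s = getattr(self, f"gate{i}")(s, x)
            x = getattr(self, f"block{i}")(concat([s, x], axis=0))
            if self.deep_supervision and i >= 1:
                aux.append(getattr(self, f"aux{i}")(x))
        aux.reverse()  # finest-first: t1, t2, ... coarsest-last
        return self.head(x), aux


class DualHeadUNet(Module):
    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.channels
        self.register_child("enc0", DoubleConv(1, c[0], config, rng))
        for i in range(config.levels):
            self.register_child(f"down{i}", Conv3d(c[i], c[i + 1], 2, rng))
            if i < config.levels - 1:
                self.register_child(f"enc{i + 1}", DoubleConv(c[i + 1], c[i + 1], config, rng))
        self.register_child("bottleneck", DoubleConv(c[-1], c[-1], config, rng))
        if config.tasks in ("both", "segmentation"):
            self.register_child(
                "seg_decoder",
                Decoder(config, config.seg_channels,
                        config.attention in ("seg_head", "global"), rng),
            )
        if config.tasks in ("both", "heatmap"):
            self.register_child(
                "heatmap_decoder",
                Decoder(config, config.heatmap_channels,
                        config.attention in ("heatmap_head", "global"), rng),
            )

    # -- encoder -----------------------------------------------------------

    def encode(self, x: Tensor):
        """Run the encoder; returns (skips, bottleneck features).

        ``skips[i]`` has ``channels[i]`` feature maps at 1/2^i resolution.
        """
        skips = []
        h = self.enc0(x)
        skips.append(h)
        for i in range(self.config.levels):
            h = getattr(self, f"down{i}")(h)
            if i < self.config.levels - 1:
                h = getattr(self, f"enc{i + 1}")(h)
                skips.append(h)
        h = self.bottleneck(h)
        return skips, h

    def encoder_feature_shapes(self, chunk_edge: int):
        """Per-level (channels, spatial_edge) of the encoder cascade,
        full-resolution block first, bottleneck last."""
        self.config.validate_chunk(chunk_edge)
        return [
            (c, chunk_edge // 2**i) for i, c in enumerate(self.config.channels)
        ]

    # -- full forward -------------------------------------------------------

    def __call__(self, chunk) -> PredictionBundle:
        x = chunk if isinstance(chunk, Tensor) else Tensor(chunk)
        if x.data.ndim == 3:
            x = x.reshape(1, *x.shape)
        edge = x.shape[1]
        for e in x.shape[1:]:
            self.config.validate_chunk(e)
        skips, h = self.encode(x)
        seg = hm = None
        seg_aux = hm_aux = None
        if self.config.tasks in ("both", "segmentation"):
            seg_logits, seg_aux = self.seg_decoder(h, skips)
            seg = seg_logits.sigmoid()
            seg_aux = [sa.sigmoid() for sa in seg_aux]
        if self.config.tasks in ("both", "heatmap"):
            hm, hm_aux = self.heatmap_decoder(h, skips)
        aux = None
        if self.config.deep_supervision:
            n = len(seg_aux) if seg_aux is not None else len(hm_aux)
            aux = [
                (seg_aux[i] if seg_aux is not None else None,
                 hm_aux[i] if hm_aux is not None else None)
                for i in range(n)
            ]
        return PredictionBundle(seg=seg, heatmaps=hm, aux=aux)


def build(config: NetworkConfig) -> DualHeadUNet:
    """Construct the network; deterministic in (config, config.seed)."""
    return DualHeadUNet(config)


def tiny_config(**overrides) -> NetworkConfig:
    """A desk-scale configuration used in tests and the scaled-down study."""
    base = dict(levels=2, channels=(8, 16, 24), deep_supervision=False,
                attention="none", norm="instance", activation="leaky_relu")
    base.update(overrides)
    return NetworkConfig(**base)
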