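"""Custom U-Net lesion segmenter and its ablation variants.

The architecture family mirrors a standard ablation design for attention /
multi-scale additions to U-Net on breast ultrasound:

* ``baseline``   — plain encoder/decoder U-Net (conv blocks with batch norm
  and dropout, max-pool downsampling, bilinear upsampling with skip
  concatenation, sigmoid output).
* ``baseline-M`` — baseline plus atrous spatial pyramid pooling (ASPP) at the
  bottleneck, capturing multi-scale context for lesions of very different
  sizes.
* ``baseline-A`` — baseline plus a concurrent spatial/channel
  squeeze-and-excitation (SCSE) attention block after every convolution
  block, steering capacity toward suspicious regions.
* ``full``       — both additions.

The modules are strictly additive, so removing ASPP from ``full`` yields
``baseline-A``'s architecture and removing SCSE yields ``baseline-M``'s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .nn import ASPP, ConvBlock, Module, SCSE, Tensor, concat, maxpool2x, upsample2x

VARIANTS = ("baseline", "baseline-M", "baseline-A", "full")


@dataclass
class SegModelConfig:
    """Hyperparameters of a segmentation network variant.

    ``input_size`` is (height, width) and must be divisible by ``2**depth``
    so the pooling pyramid closes.
    """

    variant: str = "full"
    depth: int = 4
    base_channels: int = 32
    dropout_rate: float = 0.1
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    scse_reduction: int = 8
    input_size: tuple[int, int] = (448, 384)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")
        f = 2**self.depth
        h, w = self.input_size
        if h % f or w % f:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2**depth = {f}")

    @property
    def has_aspp(self) -> bool:
        return self.variant in ("baseline-M", "full")

    @property
    def has_scse(self) -> bool:
        return self.variant in ("baseline-A", "full")


class SegmentationNetwork(Module):
    """U-Net over a single grayscale channel, emitting a lesion probability map."""

    def __init__(self, config: SegModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = [config.base_channels * 2**i for i in range(config.depth + 1)]
        d = config.dropout_rate

        self.enc = [self.add_module(ConvBlock(1 if i == 0 else ch[i - 1], ch[i], d, rng))
                    for i in range(config.depth)]
        self.bottleneck = self.add_module(ConvBlock(ch[-2], ch[-1], d, rng))
        self.dec = [self.add_module(ConvBlock(ch[i + 1] + ch[i], ch[i], d, rng))
                    for i in reversed(range(config.depth))]

        if config.has_scse:
            self.enc_att = [self.add_module(SCSE(ch[i], config.scse_reduction, rng))
                            for i in range(config.depth)]
            self.bot_att = self.add_module(SCSE(ch[-1], config.scse_reduction, rng))
            self.dec_att = [self.add_module(SCSE(ch[i], config.scse_reduction, rng))
                            for i in reversed(range(config.depth))]
        else:
            self.enc_att = self.bot_att = self.dec_att = None

        self.aspp = (self.add_module(ASPP(ch[-1], config.aspp_rates, rng))
                     if config.has_aspp else None)
        from .nn import Conv2d
        self.head = self.add_module(Conv2d(ch[0], 1, kernel=1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[2], x.data.shape[3]
        f = 2**self.config.depth
        if h % f or w % f:
            raise ValueError(f"input {h}x{w} not divisible by 2**depth = {f}")
        skips = []
        for i, block in enumerate(self.enc):
            x = block(x)
            if self.enc_att is not None:
                x = self.enc_att[i](x)
            skips.append(x)
            x = maxpool2x(x)
        x = self.bottleneck(x)
        if self.bot_att is not None:
            x = self.bot_att(x)
        if self.aspp is not None:
            x = self.aspp(x)
        for i, block in enumerate(self.dec):
            x = concat([upsample2x(x), skips[-1 - i]], axis=1)
            x = block(x)
            if self.dec_att is not None:
                x = self.dec_att[i](x)
        return self.head(x).sigmoid()


def build_model(config: SegModelConfig) -> SegmentationNetwork:
    """Instantiate the variant described by ``config`` (weights seeded)."""
    return SegmentationNetwork(config)


def predict_mask(network: SegmentationNetwork, image, threshold: float = 0.5,
                 px_per_cm: float | None = None):
    """Segment one grayscale image at its native resolution.

    The image is rescaled to the network's configured input size, passed
    through the network, and the probability map is resized back with
    bilinear interpolation before thresholding, so downstream geometry is
    measured in the original pixel grid.

    Returns ``(probability_map, binary_mask)`` as 2-D float/uint8 arrays.
    """
    from .training import preprocess  # local import to avoid a cycle

    pixels = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("expected a single-channel grayscale image")
    net_in = preprocess(pixels, input_size=network.config.input_size)
    was_training = network.training
    network.eval()
    prob = network(Tensor(net_in[None, None].astype(np.float32))).data[0, 0]
    network.train(was_training)
    prob_full = resize(prob.astype(np.float64), pixels.shape, order=1,
                       mode="edge", anti_aliasing=False)
    prob_full = np.clip(prob_full, 0.0, 1.0)
    mask = (prob_full >= threshold).astype(np.uint8)
    return prob_full, mask
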