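"""The translation generator: encoder -> residual transformer -> decoder.

The generator maps a multichannel label-free image to a 3-channel virtual
H&E image of the same spatial size. The encoder is three convolutions (a 7x7
stem followed by two stride-2 3x3 convolutions, quadrupling the channel
width), the transformer a cascade of residual blocks, and the decoder two
upsampling convolutions plus a final 7x7 projection with a bounded (tanh)
output nonlinearity mapped onto [0, L].

The same encoder also exposes the intermediate activations used as patch
features by the contrastive loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .imagedata import MultichannelImage, StainedImage


@dataclass
class GeneratorConfig:
    in_channels: int = 3
    out_channels: int = 3
    base_width: int = 64
    n_res_blocks: int = 9
    norm: str = "instance"
    #: encoder levels exposed as contrastive features: 0 = raw input pixels,
    #: 1..3 = the three encoder convolutions, 4 = the first residual block.
    chosen_layers: tuple[int, ...] = (0, 1, 2, 3, 4)
    seed: int = 0

    def __post_init__(self):
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")
        if any(l < 0 or l > 4 for l in self.chosen_layers):
            raise ValueError("chosen_layers indices must be in 0..4")
        if self.norm != "instance":
            raise ValueError("only instance normalization is supported")


class ResnetGenerator(nn.Module):
    """Encoder/transformer/decoder translation network."""

    DOWN_FACTOR = 4  # two stride-2 encoder stages

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_width
        self.enc1 = nn.Sequential(
            nn.Conv2d(cfg.in_channels, w, 7, rng, padding=3, pad_mode="reflect"),
            nn.InstanceNorm2d(w), nn.ReLU())
        self.enc2 = nn.Sequential(
            nn.Conv2d(w, 2 * w, 3, rng, stride=2, padding=1),
            nn.InstanceNorm2d(2 * w), nn.ReLU())
        self.enc3 = nn.Sequential(
            nn.Conv2d(2 * w, 4 * w, 3, rng, stride=2, padding=1),
            nn.InstanceNorm2d(4 * w), nn.ReLU())
        self.res_blocks = [nn.ResnetBlock(4 * w, rng)
                           for _ in range(cfg.n_res_blocks)]
        self.dec1 = nn.Sequential(
            nn.Conv2d(4 * w, 2 * w, 3, rng, padding=1),
            nn.InstanceNorm2d(2 * w), nn.ReLU())
        self.dec2 = nn.Sequential(
            nn.Conv2d(2 * w, w, 3, rng, padding=1),
            nn.InstanceNorm2d(w), nn.ReLU())
        self.out_conv = nn.Conv2d(w, cfg.out_channels, 7, rng, padding=3,
                                  pad_mode="reflect")

    # -- forward passes -----------------------------------------------------
    def encode(self, x: nn.Tensor) -> list[nn.Tensor]:
        """Return activations [input, enc1, enc2, enc3, res1]."""
        h1 = self.enc1(x)
        h2 = self.enc2(h1)
        h3 = self.enc3(h2)
        h4 = self.res_blocks[0](h3)
        return [x, h1, h2, h3, h4]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.forward_with_features(x)[0]

    def forward_with_features(self, x: nn.Tensor, chosen_layers=None):
        """Translate and return the encoder activations of the same pass, so
        the contrastive loss reuses rather than recomputes them."""
        layers = self.cfg.chosen_layers if chosen_layers is None else chosen_layers
        acts = self.encode(x)
        h = acts[4]
        for blk in self.res_blocks[1:]:
            h = blk(h)
        h = self.dec1(nn.upsample_nearest2x(h))
        h = self.dec2(nn.upsample_nearest2x(h))
        return nn.tanh(self.out_conv(h)), [acts[l] for l in layers]

    def features(self, x: nn.Tensor, chosen_layers=None) -> list[nn.Tensor]:
        layers = self.cfg.chosen_layers if chosen_layers is None else chosen_layers
        acts = self.encode(x)
        return [acts[l] for l in layers]


# ---------------------------------------------------------------------------
# Array <-> tensor plumbing
# ---------------------------------------------------------------------------

def to_input_tensor(img: MultichannelImage | StainedImage,
                    requires_grad: bool = False) -> nn.Tensor:
    """H x W x C image in [0, L] -> (1, C, H, W) tensor in [-1, 1]."""
    arr = img.pixels / img.dynamic_range_L * 2.0 - 1.0
    return nn.Tensor(np.moveaxis(arr, -1, 0)[None], requires_grad=requires_grad)


def from_output_tensor(t: nn.Tensor, L: float, pixel_size_um: float) -> StainedImage:
    """(1, 3, H, W) tanh output in [-1, 1] -> StainedImage in [0, L]."""
    arr = (np.moveaxis(t.data[0], 0, -1) + 1.0) / 2.0 * L
    return StainedImage(np.clip(arr, 0.0, L), dynamic_range_L=L,
                        pixel_size_um=pixel_size_um, provenance="virtual_NOCH")


def _pad_to_multiple(t: nn.Tensor, mult: int) -> tuple[nn.Tensor, tuple[int, int]]:
    _, _, H, W = t.shape
    ph = (-H) % mult
    pw = (-W) % mult
    if ph or pw:
        t = nn.pad2d(t, (0, ph, 0, pw), mode="reflect")
    return t, (H, W)


def translate(x: MultichannelImage, model: ResnetGenerator) -> StainedImage:
    """Produce the virtual H&E rendering of a label-free image.

    Spatial dims not divisible by the downsampling factor are reflection-
    padded and the output is cropped back, so output H x W always equals
    input H x W. Deterministic given (model weights, x).
    """
    if x.pixels.shape[2] != model.cfg.in_channels:
        raise ValueError(
            f"input has {x.pixels.shape[2]} channels, generator expects "
            f"{model.cfg.in_channels}")
    t, (H, W) = _pad_to_multiple(to_input_tensor(x), ResnetGenerator.DOWN_FACTOR)
    out = model(t)
    out = nn.Tensor(out.data[:, :, :H, :W])
    return from_output_tensor(out, x.dynamic_range_L, x.pixel_size_um)


def extract_features(img, model: ResnetGenerator, chosen_layers=None):
    """Encoder feature stack at the chosen layers for a domain image.

    Identical to the activations computed during translation of the same
    input under the same weights.
    """
    if img.pixels.shape[2] != model.cfg.in_channels:
        raise ValueError("channel count does not match generator config")
    t, _ = _pad_to_multiple(to_input_tensor(img), ResnetGenerator.DOWN_FACTOR)
    return model.features(t, chosen_layers)
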