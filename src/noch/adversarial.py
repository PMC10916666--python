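"""Markovian patch discriminator, adversarial loss and total objective.

The discriminator classifies overlapping receptive-field patches (a grid of
logits, not one scalar), so realism is judged locally — appropriate for
texture-level style transfer. The adversarial objective is the logarithmic
GAN form; a least-squares variant is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class DiscriminatorConfig:
    in_channels: int = 3
    base_width: int = 64
    n_layers: int = 3      # stride-2 stages; 3 gives a ~70-px receptive field
    norm: str = "instance"
    seed: int = 0


@dataclass
class LossWeights:
    lambda_gan: float = 1.0
    lambda_X: float = 1.0
    lambda_Y: float = 1.0

    def __post_init__(self):
        if min(self.lambda_gan, self.lambda_X, self.lambda_Y) < 0:
            raise ValueError("loss weights must be nonnegative")


class PatchDiscriminator(nn.Module):
    """PatchGAN: cascaded stride-2 4x4 convolutions ending in a logit grid."""

    def __init__(self, cfg: DiscriminatorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_width
        layers = [nn.Conv2d(cfg.in_channels, w, 4, rng, stride=2, padding=1),
                  nn.LeakyReLU(0.2)]
        mult = 1
        for i in range(1, cfg.n_layers):
            prev, mult = mult, min(2 ** i, 8)
            layers += [nn.Conv2d(w * prev, w * mult, 4, rng, stride=2, padding=1),
                       nn.InstanceNorm2d(w * mult), nn.LeakyReLU(0.2)]
        prev, mult = mult, min(2 ** cfg.n_layers, 8)
        layers += [nn.Conv2d(w * prev, w * mult, 4, rng, stride=1, padding=1),
                   nn.InstanceNorm2d(w * mult), nn.LeakyReLU(0.2),
                   nn.Conv2d(w * mult, 1, 4, rng, stride=1, padding=1)]
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(x)


def gan_loss(d_real_logits, d_fake_logits, side: str,
             variant: str = "logistic") -> nn.Tensor:
    """Adversarial objective over a grid of patch logits.

    ``side='discriminator'`` returns the value the discriminator maximises,
    E[log D(y)] + E[log(1 - D(G(x)))] (so the training step minimises its
    negation); ``side='generator'`` returns the non-saturating generator
    objective -E[log D(G(x))], to be minimised. D(.) = sigmoid(logits);
    expectations are means over the patch grid.
    """
    real = nn.as_tensor(d_real_logits) if d_real_logits is not None else None
    fake = nn.as_tensor(d_fake_logits)
    for t in (real, fake):
        if t is not None and not np.isfinite(t.data).all():
            raise ValueError("non-finite discriminator logits")
    if variant == "logistic":
        if side == "discriminator":
            # log D(y) = logsigmoid(real); log(1 - D(fake)) = logsigmoid(-fake)
            return nn.logsigmoid(real).mean() + nn.logsigmoid(-fake).mean()
        if side == "generator":
            return -nn.logsigmoid(fake).mean()
    elif variant == "least_squares":
        if side == "discriminator":
            return -0.5 * (((real - 1.0) ** 2.0).mean() + (fake ** 2.0).mean())
        if side == "generator":
            return 0.5 * ((fake - 1.0) ** 2.0).mean()
    else:
        raise ValueError(f"unknown gan loss variant {variant!r}")
    raise ValueError(f"side must be 'generator' or 'discriminator', got {side!r}")


def total_loss(gan, contrast_X, contrast_Y, w: LossWeights = LossWeights()):
    """Weighted sum of the adversarial and the two contrastive components."""
    return w.lambda_gan * gan + w.lambda_X * contrast_X + w.lambda_Y * contrast_Y
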