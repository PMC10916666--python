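"""Optimisation loop for the contrastive translation network.

Alternates discriminator and generator+projector Adam updates (lr 2e-4,
betas 0.5/0.999, batch size 1 in the instance-norm regime) on randomly
cropped, flip/rot90-augmented tiles. Supports paired presentation (the
corresponding unstained/stained tiles in the same step) and unpaired domain
sampling, self-contrastive negatives or cross-contrastive negatives from a
momentum-encoder bank. Checkpoints are snapshotted at the validation cadence
and the final model is the checkpoint with the best quantitative validation
score (PatchNCE on validation patches, plus pixel error against ground-truth
pseudo-H&E when the dataset is synthetic and paired).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .adversarial import (DiscriminatorConfig, LossWeights, PatchDiscriminator,
                          gan_loss, total_loss)
from .contrastive import (FeatureProjector, NegativeBank, ProjectorConfig,
                          momentum_update, patchnce_from_features,
                          project_and_sample)
from .generator import GeneratorConfig, ResnetGenerator
from .imagedata import MultichannelImage, StainedImage, as_rgb, invert_channels


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    iterations: int = 2000
    tile_size: int = 64
    batch_size: int = 1
    split_mode: str = "paired"              # {"paired", "unpaired"}
    mode: str = "self_contrastive"          # or "cross_contrastive"
    augment: bool = True
    validation_every: int = 250
    n_val_patches: int = 4
    n_locations: int = 64
    tau: float = 0.07
    #: within-layer aggregation of the patch NCE over sampled locations.
    #: "mean" keeps the contrastive terms on the adversarial loss's scale so
    #: the lambda = 1 weighting is meaningful; "sum" is the loss as printed.
    nce_reduction: str = "mean"
    gan_variant: str = "logistic"
    weights: LossWeights = field(default_factory=LossWeights)
    gen_base_width: int = 16
    n_res_blocks: int = 2
    disc_base_width: int = 16
    disc_n_layers: int = 2
    projector_dim: int = 64
    projector_hidden: int = 64
    bank_capacity: int = 1024
    momentum_m: float = 0.999
    lr_decay: bool = True
    dtype: str = "float32"       # training precision; oracles use float64
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.adam_beta1 < 1 and 0 < self.adam_beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.split_mode not in ("paired", "unpaired"):
            raise ValueError("split_mode must be 'paired' or 'unpaired'")
        if self.mode not in ("self_contrastive", "cross_contrastive"):
            raise ValueError("mode must be self_ or cross_contrastive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    config_hash: str
    seed: int
    log: list = field(default_factory=list)          # per-iteration components
    validations: list = field(default_factory=list)  # snapshots + scores
    selected_checkpoint: int | None = None
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.log:
                fh.write(json.dumps(row) + "\n")


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

def split_dataset(items: list, ratio_test_train: tuple[int, int],
                  seed: int = 0):
    """Disjoint random test/train partition at the given test:train ratio.

    The test share is round(n * test / (test + train)), at least 1. Validation
    patches are drawn from the train set at run time, never from test; the
    returned policy string documents this.
    """
    n = len(items)
    t, r = ratio_test_train
    if n < 2:
        raise ValueError("need at least 2 items to split into test and train")
    n_test = max(1, int(round(n * t / (t + r))))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test = [items[i] for i in order[:n_test]]
    train = [items[i] for i in order[n_test:]]
    policy = "validation patches are sampled from the train partition only"
    return train, test, policy


# ---------------------------------------------------------------------------
# Trainer
# ---------------------------------------------------------------------------

def prepare_input(img: MultichannelImage) -> MultichannelImage:
    """Standard X-domain preprocessing: invert against the dynamic range
    (dark-field -> bright-field background) and render to 3 colour channels
    so the encoder can ingest both domains."""
    return as_rgb(invert_channels(img))


class Trainer:
    def __init__(self, x_images: list[MultichannelImage],
                 y_images: list[StainedImage], cfg: TrainConfig):
        if not x_images or not y_images:
            raise ValueError("need at least one image in each domain")
        if cfg.split_mode == "paired" and len(x_images) != len(y_images):
            raise ValueError("paired mode requires equal-length domains")
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self._dtype = np.dtype(cfg.dtype)
        self.x_arrays = [prepare_input(x).pixels / x.dynamic_range_L * 2 - 1
                         for x in x_images]
        self.y_arrays = [y.pixels / y.dynamic_range_L * 2 - 1
                         for y in y_images]
        with nn.default_dtype(self._dtype):
            self._build()

    def _build(self):
        cfg = self.cfg
        gcfg = GeneratorConfig(in_channels=3, base_width=cfg.gen_base_width,
                               n_res_blocks=cfg.n_res_blocks, seed=cfg.seed)
        self.G = ResnetGenerator(gcfg)
        self.D = PatchDiscriminator(DiscriminatorConfig(
            base_width=cfg.disc_base_width, n_layers=cfg.disc_n_layers,
            seed=cfg.seed + 1))
        self.projector = FeatureProjector(ProjectorConfig(
            K=cfg.projector_dim, hidden_width=cfg.projector_hidden,
            seed=cfg.seed + 2))
        self.opt_G = nn.Adam(self.G.parameters(), lr=cfg.learning_rate,
                             beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        self.opt_D = nn.Adam(self.D.parameters(), lr=cfg.learning_rate,
                             beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        self._projector_registered = False
        self.record = RunRecord(config_hash=cfg.config_hash(), seed=cfg.seed)
        # cross-contrastive state
        self.bank = NegativeBank(cfg.bank_capacity, cfg.momentum_m) \
            if cfg.mode == "cross_contrastive" else None
        self.aux_G = ResnetGenerator(gcfg) if self.bank is not None else None
        if self.aux_G is not None:
            self.aux_G.load_state_dict(self.G.state_dict())
        self.aux_projector = None
        # fixed validation patches from the train images only
        self.val_patches = [self._sample_tiles(self.rng)
                            for _ in range(cfg.n_val_patches)]

    # -- data sampling ------------------------------------------------------
    def _crop(self, arr: np.ndarray, rng, r=None, c=None):
        ts = self.cfg.tile_size
        H, W = arr.shape[:2]
        if H < ts or W < ts:
            raise ValueError("tile_size larger than training image")
        if r is None:
            r = int(rng.integers(0, H - ts + 1))
            c = int(rng.integers(0, W - ts + 1))
        return arr[r:r + ts, c:c + ts], (r, c)

    @staticmethod
    def _augment(arr: np.ndarray, k: int, flip: bool) -> np.ndarray:
        out = np.rot90(arr, k, axes=(0, 1))
        if flip:
            out = out[:, ::-1]
        return np.ascontiguousarray(out)

    def _sample_tiles(self, rng):
        cfg = self.cfg
        if cfg.split_mode == "paired":
            i = int(rng.integers(len(self.x_arrays)))
            x, pos = self._crop(self.x_arrays[i], rng)
            y, _ = self._crop(self.y_arrays[i], rng, *pos)
            if cfg.augment:
                k, fl = int(rng.integers(4)), bool(rng.integers(2))
                x, y = self._augment(x, k, fl), self._augment(y, k, fl)
        else:
            i = int(rng.integers(len(self.x_arrays)))
            j = int(rng.integers(len(self.y_arrays)))
            x, _ = self._crop(self.x_arrays[i], rng)
            y, _ = self._crop(self.y_arrays[j], rng)
            if cfg.augment:
                k, fl = int(rng.integers(4)), bool(rng.integers(2))
                x = self._augment(x, k, fl)
                k, fl = int(rng.integers(4)), bool(rng.integers(2))
                y = self._augment(y, k, fl)
        to_t = lambda a: nn.Tensor(np.moveaxis(a, -1, 0)[None])
        return to_t(x), to_t(y)

    # -- losses --------------------------------------------------------------
    def _contrastive_pair(self, feats_ref, gen_t, query_side: str,
                          use_bank: bool):
        feats_gen = self.G.features(gen_t)
        fs = project_and_sample(feats_ref, feats_gen, self.projector,
                                self.cfg.n_locations, self.rng,
                                layer_ids=list(self.G.cfg.chosen_layers))
        bank = self.bank if (use_bank and self.bank is not None) else None
        return patchnce_from_features(fs, self.cfg.tau, bank, query_side,
                                      reduction=self.cfg.nce_reduction)

    def _momentum_step(self, x_t):
        """Push momentum-encoded features of the current image and update the
        auxiliary weights toward the main ones."""
        cfg = self.cfg
        if not self.projector.mlps:
            return    # no contrastive features yet (e.g. zero loss weights)
        if self.aux_projector is None and self.projector.mlps:
            self.aux_projector = FeatureProjector(self.projector.cfg)
            for lid, mlp in self.projector.mlps.items():
                aux = self.aux_projector._mlp(lid, mlp.layers[0].weight.shape[0])
                aux.load_state_dict(mlp.state_dict())
        feats = self.aux_G.features(x_t)
        for lid, f in zip(self.G.cfg.chosen_layers, feats):
            S = f.shape[2] * f.shape[3]
            take = min(cfg.n_locations, S)
            idx = self.rng.choice(S, size=take, replace=False)
            from .contrastive import _gather_locations
            vecs = self.aux_projector.project(lid, _gather_locations(
                nn.Tensor(f.data), idx))
            self.bank.push(lid, vecs.data)
        momentum_update(self.G, self.aux_G, cfg.momentum_m)
        if self.aux_projector is not None:
            momentum_update(self.projector, self.aux_projector, cfg.momentum_m)

    def _lr_at(self, it: int) -> float:
        cfg = self.cfg
        if not cfg.lr_decay or it < cfg.iterations // 2:
            return cfg.learning_rate
        half = cfg.iterations - cfg.iterations // 2
        frac = (it - cfg.iterations // 2 + 1) / (half + 1)
        return cfg.learning_rate * max(1e-3, 1.0 - frac)

    # -- validation -----------------------------------------------------------
    def validation_scores(self) -> dict:
        """Quantitative stand-in for the qualitative checkpoint criterion:
        mean PatchNCE(X) and, in paired mode, mean absolute pixel error of the
        translation against the paired target tile (both on fixed validation
        patches from the train set)."""
        rng = np.random.default_rng(self.cfg.seed + 9999)
        nce_vals, mae_vals = [], []
        for x_t, y_t in self.val_patches:
            fake, feats_ref = self.G.forward_with_features(x_t)
            feats_gen = self.G.features(fake)
            fs = project_and_sample(feats_ref, feats_gen, self.projector,
                                    self.cfg.n_locations, rng,
                                    layer_ids=list(self.G.cfg.chosen_layers))
            nce_vals.append(float(patchnce_from_features(
                fs, self.cfg.tau, reduction=self.cfg.nce_reduction).data))
            if self.cfg.split_mode == "paired":
                mae_vals.append(float(np.abs(fake.data - y_t.data).mean()))
        out = {"val_patchnce_X": float(np.mean(nce_vals))}
        if mae_vals:
            out["val_pixel_mae"] = float(np.mean(mae_vals))
        return out

    # -- main loop -------------------------------------------------------------
    def run(self) -> RunRecord:
        with nn.default_dtype(self._dtype):
            return self._run()

    def _run(self) -> RunRecord:
        cfg = self.cfg
        for it in range(cfg.iterations):
            lr = self._lr_at(it)
            self.opt_G.lr = self.opt_D.lr = lr
            x_t, y_t = self._sample_tiles(self.rng)
            fake, feats_x = self.G.forward_with_features(x_t)

            # discriminator update (maximise Eq. 4 <=> minimise its negation)
            d_obj = gan_loss(self.D(y_t), self.D(fake.detach()),
                             side="discriminator", variant=cfg.gan_variant)
            self.opt_D.zero_grad()
            (-d_obj).backward()
            self.opt_D.step()

            # generator + projector update
            g_gan = gan_loss(None, self.D(fake), side="generator",
                             variant=cfg.gan_variant)
            if cfg.weights.lambda_X > 0:
                loss_X = self._contrastive_pair(feats_x, fake, "z_hat",
                                                use_bank=True)
            else:
                loss_X = nn.Tensor(0.0)
            if cfg.weights.lambda_Y > 0:
                idt, feats_y = self.G.forward_with_features(y_t)
                loss_Y = self._contrastive_pair(feats_y, idt, "z",
                                                use_bank=False)
            else:
                loss_Y = nn.Tensor(0.0)
            total = total_loss(g_gan, loss_X, loss_Y, cfg.weights)
            if not self._projector_registered and self.projector.mlps:
                self.opt_G.add_params(self.projector.parameters())
                self._projector_registered = True
            self.opt_G.zero_grad()
            if isinstance(total, nn.Tensor):
                total.backward()
            self.opt_G.step()

            if self.bank is not None:
                self._momentum_step(x_t)

            row = {"iteration": it, "lr": lr,
                   "L_GAN": float(g_gan.data), "L_D": float(d_obj.data),
                   "L_contrast_X": float(loss_X.data),
                   "L_contrast_Y": float(loss_Y.data),
                   "total": float(total.data) if isinstance(total, nn.Tensor)
                            else float(total)}
            if not np.isfinite(row["total"]):
                self.record.log.append(row)
                raise RuntimeError(
                    f"training diverged at iteration {it}: {row}")
            self.record.log.append(row)

            if (it + 1) % cfg.validation_every == 0 or it + 1 == cfg.iterations:
                scores = self.validation_scores()
                self.record.validations.append({
                    "iteration": it,
                    "scores": scores,
                    "state_G": self.G.state_dict(),
                    "state_proj": self.projector.state_dict()})

        self._select_checkpoint()
        return self.record

    def _select_checkpoint(self) -> None:
        if not self.record.validations:
            return
        key = ("val_pixel_mae"
               if "val_pixel_mae" in self.record.validations[0]["scores"]
               else "val_patchnce_X")
        best = min(self.record.validations, key=lambda v: v["scores"][key])
        self.G.load_state_dict(best["state_G"])
        if best["state_proj"]:
            self.projector.load_state_dict(best["state_proj"])
        self.record.selected_checkpoint = best["iteration"]


def train(x_images, y_images, cfg: TrainConfig):
    """Train a translation network; returns (generator, projector, record)."""
    tr = Trainer(x_images, y_images, cfg)
    record = tr.run()
    return tr.G, tr.projector, record


def save_checkpoint(path, model: ResnetGenerator, cfg: TrainConfig | None = None):
    path = Path(path)
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"generator_config": asdict(model.cfg)}
    if cfg is not None:
        meta["train_config"] = asdict(cfg)
    np.savez(path, __meta__=json.dumps(meta, default=str), **state)


def load_checkpoint(path) -> ResnetGenerator:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    gcfg = meta["generator_config"]
    gcfg["chosen_layers"] = tuple(gcfg["chosen_layers"])
    model = ResnetGenerator(GeneratorConfig(**gcfg))
    model.load_state_dict({k[len("param/"):]: data[k]
                           for k in data.files if k.startswith("param/")})
    return model
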