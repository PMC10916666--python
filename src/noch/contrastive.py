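"""Patch-wise contrastive (InfoNCE) machinery.

Mutual information between corresponding patches of the input and the
translated image is maximised by an (N+1)-way classification: a query patch
feature must pick out its positive counterpart against N negative patches.
Features are encoder activations at several depths, passed through a
per-layer two-layer MLP and normalised onto the unit sphere. Negatives come
from other locations of the same image (self-contrastive) and, optionally,
from a FIFO bank of features of other images produced by a momentum encoder
(cross-contrastive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .generator import ResnetGenerator, extract_features

DEFAULT_TAU = 0.07          # temperature scaling the patch logits
DEFAULT_N_LOCATIONS = 256   # sampled patches per layer -> N = 255 negatives


@dataclass
class ProjectorConfig:
    K: int = 256
    hidden_width: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.hidden_width < 1:
            raise ValueError("projection dims must be >= 1")


def l2_normalize(t: nn.Tensor, eps: float = 1e-12) -> nn.Tensor:
    """Row-normalise (n, K) feature vectors onto the unit sphere."""
    sq = (t ** 2.0).sum(axis=1, keepdims=True)
    return t * (sq + eps) ** -0.5


class FeatureProjector(nn.Module):
    """One two-layer MLP per chosen encoder layer, built lazily once the
    per-layer channel dimension is known."""

    def __init__(self, cfg: ProjectorConfig):
        self.cfg = cfg
        self.mlps: dict[int, nn.Sequential] = {}
        self._rng = np.random.default_rng(cfg.seed)

    def named_parameters(self, prefix: str = ""):
        for lid in sorted(self.mlps):
            yield from self.mlps[lid].named_parameters(prefix=f"{prefix}mlp{lid}.")

    def _mlp(self, layer_id: int, in_dim: int) -> nn.Sequential:
        mlp = self.mlps.get(layer_id)
        if mlp is None:
            mlp = nn.Sequential(
                nn.Linear(in_dim, self.cfg.hidden_width, self._rng),
                nn.ReLU(),
                nn.Linear(self.cfg.hidden_width, self.cfg.K, self._rng))
            self.mlps[layer_id] = mlp
        return mlp

    def project(self, layer_id: int, vectors: nn.Tensor) -> nn.Tensor:
        """(n, C_l) sampled feature vectors -> unit-norm (n, K)."""
        return l2_normalize(self._mlp(layer_id, vectors.shape[1])(vectors))


@dataclass
class PatchFeatureSet:
    """Paired, unit-norm projected patch features sampled per layer."""

    layer_ids: list[int]
    locations: list[np.ndarray]       # flat spatial indices, one array per layer
    z: list[nn.Tensor]                # (n, K) from the reference image
    z_hat: list[nn.Tensor]            # (n, K) from the translated image

    def norms(self) -> list[np.ndarray]:
        return [np.linalg.norm(t.data, axis=1) for t in self.z + self.z_hat]


def _gather_locations(fmap: nn.Tensor, flat_idx: np.ndarray) -> nn.Tensor:
    """(1, C, H, W) feature map -> (n, C) vectors at flat spatial indices."""
    _, C, H, W = fmap.shape
    flat = fmap.reshape(C, H * W).transpose(1, 0)  # (S, C)
    return nn.index_take(flat, flat_idx, axis=0)


def sample_locations(feats: list[nn.Tensor], n_locations: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    locs = []
    for f in feats:
        S = f.shape[2] * f.shape[3]
        if n_locations > S:
            raise ValueError(
                f"cannot sample {n_locations} locations from a layer with "
                f"{S} spatial positions")
        locs.append(np.sort(rng.choice(S, size=n_locations, replace=False)))
    return locs


def project_and_sample(feats_x: list[nn.Tensor], feats_y: list[nn.Tensor],
                       projector: FeatureProjector, n_locations: int,
                       rng: np.random.Generator,
                       layer_ids: list[int] | None = None) -> PatchFeatureSet:
    """Sample identical random locations in both feature stacks and project
    the feature vectors through the per-layer MLPs onto the unit sphere."""
    if len(feats_x) != len(feats_y):
        raise ValueError("feature stacks must come from the same chosen layers")
    if layer_ids is None:
        layer_ids = list(range(len(feats_x)))
    locs = sample_locations(feats_x, n_locations, rng)
    z, z_hat = [], []
    for lid, fx, fy, idx in zip(layer_ids, feats_x, feats_y, locs):
        z.append(projector.project(lid, _gather_locations(fx, idx)))
        z_hat.append(projector.project(lid, _gather_locations(fy, idx)))
    return PatchFeatureSet(list(layer_ids), locs, z, z_hat)


# ---------------------------------------------------------------------------
# NCE losses
# ---------------------------------------------------------------------------

def nce_loss(query, positive, negatives, tau: float = DEFAULT_TAU) -> nn.Tensor:
    """(N+1)-way noise-contrastive cross-entropy for a single query.

    -log[ exp(q.p/tau) / (exp(q.p/tau) + sum_n exp(q.v_n/tau)) ], computed
    with a max-subtracted log-sum-exp. Accepts arrays or tensors; returns a
    scalar tensor (use float() for the value).
    """
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    q = nn.as_tensor(query)
    p = nn.as_tensor(positive)
    v = nn.as_tensor(negatives)
    if not (np.isfinite(q.data).all() and np.isfinite(p.data).all()
            and np.isfinite(v.data).all()):
        raise ValueError("non-finite inputs to nce_loss")
    K = q.shape[-1]
    keys = nn.concat([p.reshape(1, K), v.reshape(-1, K)], axis=0)
    logits = (keys @ q.reshape(K, 1)).reshape(-1) * (1.0 / tau)
    return nn.logsumexp(logits, axis=0) - nn.index_take(logits, [0], axis=0).sum()


def _nce_matrix_loss(q: nn.Tensor, k: nn.Tensor, tau: float,
                     external: np.ndarray | None = None,
                     reduction: str = "sum") -> nn.Tensor:
    """Per-row NCE losses where row s of q matches row s of k and all other
    rows of k (plus optional external bank vectors) are negatives, reduced by
    sum or mean over the rows."""
    logits = (q @ k.transpose(1, 0)) * (1.0 / tau)           # (n, n)
    pos = (q * k).sum(axis=1) * (1.0 / tau)                  # (n,)
    if external is not None and len(external):
        ext = (q @ nn.Tensor(external.T)) * (1.0 / tau)      # (n, B)
        logits = nn.concat([logits, ext], axis=1)
    per_row = nn.logsumexp(logits, axis=1) - pos
    return per_row.sum() if reduction == "sum" else per_row.mean()


def patchnce_from_features(fs: PatchFeatureSet, tau: float = DEFAULT_TAU,
                           bank: "NegativeBank | None" = None,
                           query_side: str = "z_hat",
                           reduction: str = "sum") -> nn.Tensor:
    """PatchNCE over all layers of a sampled feature set.

    ``query_side='z_hat'`` matches translated-image queries against
    reference-image keys (the X-domain loss); ``'z'`` swaps the roles (the
    identity-pass Y-domain loss). ``reduction`` controls the within-layer
    aggregation over sampled locations: ``'sum'`` follows the printed loss
    definition; ``'mean'`` keeps the contrastive term on the same scale as
    the adversarial term and is what training uses by default.
    """
    queries = fs.z_hat if query_side == "z_hat" else fs.z
    keys = fs.z if query_side == "z_hat" else fs.z_hat
    total = nn.Tensor(0.0)
    for lid, q, k in zip(fs.layer_ids, queries, keys):
        ext = bank.negatives(lid) if bank is not None else None
        total = total + _nce_matrix_loss(q, k, tau, ext, reduction)
    return total


def patchnce_loss_X(x, model: ResnetGenerator, projector: FeatureProjector,
                    rng: np.random.Generator, y_hat=None,
                    n_locations: int = DEFAULT_N_LOCATIONS,
                    tau: float = DEFAULT_TAU,
                    bank: "NegativeBank | None" = None,
                    reduction: str = "sum") -> nn.Tensor:
    """Contrastive loss matching input patches to translated-output patches.

    Queries are projected features of y_hat = G(x); positives/negatives are
    features of x at the same/other sampled locations.
    """
    from .generator import translate
    if y_hat is None:
        y_hat = translate(x, model)
    feats_x = extract_features(x, model)
    feats_y = extract_features(y_hat, model)
    fs = project_and_sample(feats_x, feats_y, projector, n_locations, rng,
                            layer_ids=list(model.cfg.chosen_layers))
    return patchnce_from_features(fs, tau, bank, query_side="z_hat",
                                  reduction=reduction)


def patchnce_loss_Y(y, model: ResnetGenerator, projector: FeatureProjector,
                    rng: np.random.Generator,
                    n_locations: int = DEFAULT_N_LOCATIONS,
                    tau: float = DEFAULT_TAU,
                    reduction: str = "sum") -> nn.Tensor:
    """Identity-pass contrastive loss on the target domain.

    The H&E image y is passed through the generator; queries are features of
    y itself and keys are features of G(y) (roles mirrored relative to the
    X-domain loss). Requires the generator to ingest 3-channel images.
    """
    from .generator import translate
    if y.pixels.shape[2] != model.cfg.in_channels:
        raise ValueError(
            "target-domain identity pass needs generator in_channels == 3; "
            "render 2-channel inputs to RGB (imagedata.as_rgb) for training")
    y_idt = translate(y, model)
    feats_y = extract_features(y, model)
    feats_idt = extract_features(y_idt, model)
    fs = project_and_sample(feats_y, feats_idt, projector, n_locations, rng,
                            layer_ids=list(model.cfg.chosen_layers))
    return patchnce_from_features(fs, tau, query_side="z",
                                  reduction=reduction)


# ---------------------------------------------------------------------------
# Cross-contrastive: momentum encoder + external negative bank
# ---------------------------------------------------------------------------

class NegativeBank:
    """Per-layer FIFO queues of unit-norm feature vectors from other images."""

    def __init__(self, capacity: int = 1024, momentum_m: float = 0.999):
        if not (0 < momentum_m <= 1):
            raise ValueError("momentum must lie in (0, 1]")
        self.capacity = capacity
        self.momentum_m = momentum_m
        self._queues: dict[int, np.ndarray] = {}

    def negatives(self, layer_id: int) -> np.ndarray | None:
        q = self._queues.get(layer_id)
        return None if q is None or len(q) == 0 else q

    def size(self, layer_id: int) -> int:
        q = self._queues.get(layer_id)
        return 0 if q is None else len(q)

    def push(self, layer_id: int, vectors: np.ndarray) -> None:
        vecs = np.asarray(vectors, dtype=np.float64)
        q = self._queues.get(layer_id)
        q = vecs.copy() if q is None else np.concatenate([q, vecs], axis=0)
        if len(q) > self.capacity:
            q = q[len(q) - self.capacity:]  # drop oldest entries first
        self._queues[layer_id] = q


def cross_contrastive_negatives(bank: NegativeBank,
                                current: PatchFeatureSet) -> dict[int, np.ndarray | None]:
    """Fetch the external negatives for every layer of ``current``, then push
    the current reference-side features into the bank (FIFO). On the first
    iterations the bank is empty and the loss falls back to self-contrastive
    negatives only (warm-up)."""
    external = {lid: bank.negatives(lid) for lid in current.layer_ids}
    for lid, z in zip(current.layer_ids, current.z):
        bank.push(lid, z.data)
    return external


def momentum_update(main: nn.Module, aux: nn.Module, m: float) -> None:
    """theta_aux <- m * theta_aux + (1 - m) * theta_main."""
    aux_params = dict(aux.named_parameters())
    for name, p in main.named_parameters():
        aux_params[name].data *= m
        aux_params[name].data += (1.0 - m) * p.data
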