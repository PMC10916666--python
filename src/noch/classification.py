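"""Grid-wise cancer-stage classification of histology-style images.

An image is partitioned into square cells of a fixed physical size (334 µm
by default); each cell is classified independently by a pluggable model into
{normal, IA, IC, IIC, IIIC}, producing a per-cell probability map. The
accuracy map scores each cell with a delta function — 1 when the argmax
class equals the ground truth, 0 otherwise — and the total accuracy is the
mean over cells.

Any callable ``tile (H x W x 3, [0, L]) -> probability vector`` can serve as
the classifier; a small reference CNN trained on phantom renderings is
provided for desk-scale use, along with a uniform dummy for plumbing tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .imagedata import StainedImage

CLASSES = ("normal", "IA", "IC", "IIC", "IIIC")
DEFAULT_CELL_UM = 334.0


@dataclass
class GridCell:
    row: int
    col: int
    bounds_um: tuple[float, float, float, float]   # (top, left, bottom, right)
    probabilities: np.ndarray
    coverage: float = 1.0

    @property
    def argmax_class(self) -> str:
        return CLASSES[int(np.argmax(self.probabilities))]

    @property
    def prob_max(self) -> float:
        return float(np.max(self.probabilities))


@dataclass
class ClassProbabilityMap:
    cells: list[GridCell]
    grid_shape: tuple[int, int]
    cell_um: float
    skipped: list[tuple[int, int]] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "cell_um": self.cell_um,
            "grid_shape": list(self.grid_shape),
            "classes": list(CLASSES),
            "cells": [{"row": c.row, "col": c.col,
                       "bounds_um": list(c.bounds_um),
                       "probabilities": c.probabilities.tolist(),
                       "argmax_class": c.argmax_class}
                      for c in self.cells],
            "skipped": [list(s) for s in self.skipped],
        }


@dataclass
class AccuracyMap:
    values: dict                     # (row, col) -> 0/1
    total_accuracy: float
    n_ties: int = 0

    def to_json(self) -> dict:
        return {"cells": [[r, c, v] for (r, c), v in self.values.items()],
                "total_accuracy": self.total_accuracy, "n_ties": self.n_ties}


class UniformClassifier:
    """Stub assigning equal probability to every class."""

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        return np.full(len(CLASSES), 1.0 / len(CLASSES))


def classify_grid(img: StainedImage, model, cell_um: float = DEFAULT_CELL_UM,
                  min_coverage: float = 0.5) -> ClassProbabilityMap:
    """Partition an image into cell_um x cell_um cells and classify each.

    Edge cells keep their nominal physical bounds but contain only the pixels
    inside the image; cells with less than ``min_coverage`` of the nominal
    area present are skipped and flagged. Probabilities are renormalised to
    sum to 1.
    """
    px = img.pixel_size_um
    if not px or px <= 0:
        raise ValueError("pixel_size_um must be set")
    H, W = img.pixels.shape[:2]
    cell_px = cell_um / px
    if cell_px > H or cell_px > W:
        raise ValueError(
            f"cell size {cell_um} µm exceeds image extent "
            f"({H * px:.0f} x {W * px:.0f} µm)")
    n_rows = int(np.ceil(H / cell_px))
    n_cols = int(np.ceil(W / cell_px))
    cells, skipped = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            r0, r1 = int(round(r * cell_px)), min(int(round((r + 1) * cell_px)), H)
            c0, c1 = int(round(c * cell_px)), min(int(round((c + 1) * cell_px)), W)
            coverage = ((r1 - r0) * (c1 - c0)) / (cell_px * cell_px)
            if coverage < min_coverage:
                skipped.append((r, c))
                continue
            tile = img.pixels[r0:r1, c0:c1]
            probs = np.asarray(model(tile), dtype=np.float64)
            probs = np.clip(probs, 0.0, None)
            s = probs.sum()
            probs = probs / s if s > 0 else np.full(len(CLASSES), 1 / len(CLASSES))
            cells.append(GridCell(r, c, (r0 * px, c0 * px, r1 * px, c1 * px),
                                  probs, coverage=min(coverage, 1.0)))
    return ClassProbabilityMap(cells, (n_rows, n_cols), cell_um, skipped)


def accuracy_map(probs: ClassProbabilityMap, truth) -> AccuracyMap:
    """Delta-function accuracy per cell: 1 iff the argmax class matches the
    ground truth. ``truth`` is a single class label for the whole image or a
    {(row, col): label} mapping covering every cell. Argmax ties resolve to
    the lowest class index, with a warning counter."""
    if isinstance(truth, str):
        truth_of = lambda cell: truth
    else:
        missing = [(c.row, c.col) for c in probs.cells
                   if (c.row, c.col) not in truth]
        if missing:
            raise ValueError(f"truth does not cover cells: {missing}")
        truth_of = lambda cell: truth[(cell.row, cell.col)]
    values, n_ties = {}, 0
    for cell in probs.cells:
        pmax = cell.probabilities.max()
        if (cell.probabilities == pmax).sum() > 1:
            n_ties += 1
        values[(cell.row, cell.col)] = int(cell.argmax_class == truth_of(cell))
    if n_ties:
        warnings.warn(f"{n_ties} cells had tied maximum probabilities; "
                      "lowest class index used", stacklevel=2)
    total = float(np.mean(list(values.values()))) if values else float("nan")
    return AccuracyMap(values, total, n_ties)


def save_probability_map(path, pmap: ClassProbabilityMap,
                         amap: AccuracyMap | None = None,
                         heatmap_path=None) -> None:
    payload = pmap.to_json()
    if amap is not None:
        payload["accuracy"] = amap.to_json()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    if heatmap_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        grid = np.full(pmap.grid_shape, np.nan)
        for cell in pmap.cells:
            grid[cell.row, cell.col] = cell.prob_max
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(grid, vmin=0, vmax=1, cmap="viridis")
        fig.colorbar(im, ax=ax, label="max class probability")
        ax.set_title(f"cell = {pmap.cell_um:.0f} µm")
        fig.savefig(heatmap_path, dpi=100)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Reference desk-scale CNN
# ---------------------------------------------------------------------------

class _SmallCNN(nn.Module):
    def __init__(self, width: int, n_classes: int, seed: int):
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2d(3, width, 3, rng, stride=2, padding=1)
        self.conv2 = nn.Conv2d(width, 2 * width, 3, rng, stride=2, padding=1)
        self.conv3 = nn.Conv2d(2 * width, 4 * width, 3, rng, stride=2, padding=1)
        self.head = nn.Linear(4 * width, n_classes, rng)
        # He-scaled init: the GAN-style 0.02 std starves a plain feed-forward
        # classifier of signal
        for _, p in self.named_parameters():
            if p.ndim > 1:
                fan_in = int(np.prod(p.shape[1:]) if p.ndim == 4 else p.shape[0])
                p.data *= np.sqrt(2.0 / fan_in) / 0.02

    def forward(self, x):
        h = nn.leaky_relu(self.conv1(x), 0.1)
        h = nn.leaky_relu(self.conv2(h), 0.1)
        h = nn.leaky_relu(self.conv3(h), 0.1)
        pooled = h.mean(axis=(2, 3))     # global average pool -> (N, 4w)
        return self.head(pooled)


class ReferenceCNNClassifier:
    """Small CNN tile classifier for phantom stages.

    Tiles are resized to ``input_px`` and normalised to [-1, 1]. Training
    minimises softmax cross-entropy with Adam. This is a desk-scale stand-in
    honouring the plugin contract (tile in -> probability vector out), not a
    clinical model.
    """

    def __init__(self, input_px: int = 32, width: int = 8, seed: int = 0,
                 learning_rate: float = 1e-3, epochs: int = 30):
        self.input_px = input_px
        self.width = width
        self.seed = seed
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.model_: _SmallCNN | None = None

    def _prep(self, tile: np.ndarray, L: float = 255.0) -> np.ndarray:
        t = resize(tile / L, (self.input_px, self.input_px, 3),
                   anti_aliasing=True, preserve_range=True)
        return np.moveaxis(t * 2.0 - 1.0, -1, 0)[None]

    def fit(self, tiles: list[np.ndarray], labels: list[str],
            L: float = 255.0) -> "ReferenceCNNClassifier":
        rng = np.random.default_rng(self.seed)
        self.model_ = _SmallCNN(self.width, len(CLASSES), self.seed)
        opt = nn.Adam(self.model_.parameters(), lr=self.learning_rate,
                      beta1=0.9, beta2=0.999)
        X = np.concatenate([self._prep(t, L) for t in tiles], axis=0)
        y = np.array([CLASSES.index(l) for l in labels])
        n = len(y)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, 8):
                idx = order[start:start + 8]
                logits = self.model_(nn.Tensor(X[idx]))
                lse = nn.logsumexp(logits, axis=1)
                picked = (logits * nn.Tensor(
                    np.eye(len(CLASSES))[y[idx]])).sum(axis=1)
                loss = (lse - picked).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        logits = self.model_(nn.Tensor(self._prep(tile))).data[0]
        e = np.exp(logits - logits.max())
        return e / e.sum()
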