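"""Reading, writing and preprocessing of label-free multichannel microscopy
images and RGB histology images.

Covers the pipeline's deterministic image plumbing: channel inversion against
the bit-depth dynamic range, SHG/2PA crosstalk subtraction, tiling of large
frames into network-sized tiles, and feather-blended stitching of overlapping
tiles back into a mosaic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

MODALITIES = ("3PA_NADH", "SHG", "2PA_FAD", "SRS_protein", "SRS_lipid", "other")

#: µm per pixel for a dual-galvo multiphoton frame: 634 µm field of view
#: sampled at 1024 x 1024 pixels.
DEFAULT_PIXEL_SIZE_UM = 634.0 / 1024.0


class FormatError(ValueError):
    pass


class CoverageError(ValueError):
    pass


@dataclass
class MultichannelImage:
    """A label-free nonlinear image: H x W x C nonnegative intensities."""

    pixels: np.ndarray
    modalities: list[str]
    dynamic_range_L: float = 255.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise FormatError("pixels must be H x W x C")
        if len(self.modalities) != self.pixels.shape[2]:
            raise FormatError("one modality label required per channel")
        for m in self.modalities:
            if m not in MODALITIES:
                raise FormatError(f"unknown modality {m!r}")
        if self.pixels.min() < 0 or self.pixels.max() > self.dynamic_range_L:
            raise FormatError("pixel values outside [0, dynamic_range_L]")

    @property
    def shape(self):
        return self.pixels.shape

    def channel(self, modality: str) -> np.ndarray:
        return self.pixels[:, :, self.modalities.index(modality)]


@dataclass
class StainedImage:
    """An RGB histology-style image (real H&E, virtual, or phantom truth)."""

    pixels: np.ndarray
    dynamic_range_L: float = 255.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    provenance: Literal["real_HE", "virtual_NOCH", "phantom_truth"] = "real_HE"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError("stained image must be H x W x 3 (RGB)")
        if self.pixels.min() < 0 or self.pixels.max() > self.dynamic_range_L:
            raise FormatError("pixel values outside [0, dynamic_range_L]")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class TileSet:
    tiles: list
    origins: list[tuple[int, int]]
    tile_size: tuple[int, int]
    parent_shape: tuple[int, int]
    overlap_fraction: float = 0.0

    def __post_init__(self):
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("tile origins must be unique")
        h, w = self.tile_size
        H, W = self.parent_shape
        for r, c in self.origins:
            if r < 0 or c < 0 or r + h > H or c + w > W:
                raise ValueError(f"tile at {(r, c)} exceeds parent bounds")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_dynamic_range(arr: np.ndarray) -> float:
    bits = arr.dtype.itemsize * 8 if arr.dtype.kind == "u" else 8
    return float(2 ** bits - 1)


def read_image(path, kind: Literal["multichannel", "stained"],
               modalities: Sequence[str] | None = None,
               pixel_size_um: float | None = None):
    """Read a TIFF/PNG image as a typed domain object.

    Bit depth is inferred from the stored dtype (dynamic_range_L = 2^bits - 1);
    the channel order on disk is preserved. ``pixel_size_um`` falls back to the
    documented dual-galvo default when no value is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize to IOError
        raise IOError(f"unreadable image file {path}: {exc}") from exc
    if arr.ndim < 2:
        raise IOError(f"unreadable or truncated image file {path}")
    L = _infer_dynamic_range(arr)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[0] < min(arr.shape[1:]) and kind == "multichannel":
        arr = np.moveaxis(arr, 0, -1)  # planar C x H x W TIFFs
    px = DEFAULT_PIXEL_SIZE_UM if pixel_size_um is None else pixel_size_um
    if kind == "stained":
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise FormatError(f"{path}: stained images must have 3 channels")
        return StainedImage(arr, dynamic_range_L=L, pixel_size_um=px)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    C = arr.shape[2]
    mods = list(modalities) if modalities is not None else ["other"] * C
    if len(mods) != C:
        raise FormatError(f"{path}: {C} channels but {len(mods)} modality labels")
    return MultichannelImage(arr, mods, dynamic_range_L=L, pixel_size_um=px)


def write_image(path, img) -> None:
    """Write an image, quantizing floats back to the original bit depth."""
    path = Path(path)
    L = img.dynamic_range_L
    dtype = np.uint8 if L <= 255 else np.uint16
    arr = np.clip(np.rint(img.pixels), 0, L).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        if isinstance(img, MultichannelImage):
            tifffile.imwrite(str(path), np.moveaxis(arr, -1, 0),
                             photometric="minisblack")
        else:
            tifffile.imwrite(str(path), arr, photometric="rgb")
    else:
        iio.imwrite(path, np.squeeze(arr))


def read_manifest(path) -> list[dict]:
    """Dataset manifest: JSON list of {path, domain ('X'|'Y'), modalities}."""
    with open(path) as fh:
        entries = json.load(fh)
    for e in entries:
        if e.get("domain") not in ("X", "Y"):
            raise FormatError(f"manifest entry missing domain X/Y: {e}")
    return entries


def write_manifest(path, entries: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def invert_channels(img: MultichannelImage) -> MultichannelImage:
    """Invert intensities against the dynamic range: I -> |L - I|.

    Dark-background nonlinear images are inverted to match the white
    background of bright-field histology; the operation is an involution.
    """
    return replace(img, pixels=np.abs(img.dynamic_range_L - img.pixels))


def correct_shg_crosstalk(shg: np.ndarray, twopa: np.ndarray) -> np.ndarray:
    """Remove three-photon FAD crosstalk from the SHG channel.

    The collected SHG band also picks up 3PA FAD, which shares the 2PA FAD
    morphology, so the 2PA image is subtracted; negative values are clamped
    to zero since negative intensity is not physical.
    """
    shg = np.asarray(shg, dtype=np.float64)
    twopa = np.asarray(twopa, dtype=np.float64)
    if shg.shape != twopa.shape:
        raise ValueError(f"shape mismatch: {shg.shape} vs {twopa.shape}")
    return np.maximum(shg - twopa, 0.0)


def as_rgb(img: MultichannelImage) -> MultichannelImage:
    """Render a multichannel image into 3 colour channels.

    SRS: protein -> green, lipid -> blue (red zero). Multiphoton: 2PA FAD ->
    red, SHG -> green, 3PA NADH -> blue. Other layouts keep the first three
    channels, zero-padding when fewer. Enables a single 3-channel encoder to
    ingest both image domains.
    """
    H, W, C = img.pixels.shape
    out = np.zeros((H, W, 3))
    color_of = {"2PA_FAD": 0, "SRS_protein": 1, "SHG": 1, "3PA_NADH": 2,
                "SRS_lipid": 2}
    used = set()
    for c, m in enumerate(img.modalities):
        k = color_of.get(m)
        if k is None or k in used:
            k = next(i for i in range(3) if i not in used)
        used.add(k)
        out[:, :, k] = img.pixels[:, :, c]
        if len(used) == 3:
            break
    return MultichannelImage(out, ["2PA_FAD", "SHG", "3PA_NADH"],
                             dynamic_range_L=img.dynamic_range_L,
                             pixel_size_um=img.pixel_size_um)


# ---------------------------------------------------------------------------
# Tiling / stitching
# ---------------------------------------------------------------------------

def _anchor_positions(extent: int, tile: int, stride: int) -> list[int]:
    """Start offsets covering [0, extent); the final tile is re-anchored to
    the border so every tile contains only real pixels."""
    if tile > extent:
        raise ValueError(f"tile size {tile} exceeds image extent {extent}")
    pos = list(range(0, extent - tile + 1, stride))
    if pos[-1] + tile < extent:
        pos.append(extent - tile)
    return pos


def tile_image(img, tile_size: tuple[int, int],
               stride: tuple[int, int] | None = None) -> TileSet:
    """Split an image into (possibly overlapping) tiles covering it fully."""
    th, tw = tile_size
    sh, sw = stride if stride is not None else tile_size
    px = img.pixels
    H, W = px.shape[:2]
    rows = _anchor_positions(H, th, sh)
    cols = _anchor_positions(W, tw, sw)
    tiles, origins = [], []
    for r in rows:
        for c in cols:
            tiles.append(replace(img, pixels=px[r:r + th, c:c + tw].copy()))
            origins.append((r, c))
    overlap = max(0.0, 1.0 - min(sh / th, sw / tw))
    return TileSet(tiles, origins, (th, tw), (H, W), overlap)


def _feather_weight(h: int, w: int) -> np.ndarray:
    """Separable linear ramp peaking at the tile centre, > 0 everywhere."""
    ri = np.arange(h, dtype=np.float64)
    ci = np.arange(w, dtype=np.float64)
    wr = np.minimum(ri + 1.0, h - ri)
    wc = np.minimum(ci + 1.0, w - ci)
    return np.outer(wr, wc)


def stitch_tiles(ts: TileSet):
    """Blend tiles into a mosaic with linear feathering.

    Every output pixel is a convex combination of contributing tiles; where a
    single tile contributes it is copied verbatim. Raises CoverageError when
    tiles do not cover the parent frame.
    """
    H, W = ts.parent_shape
    th, tw = ts.tile_size
    nchan = ts.tiles[0].pixels.shape[2]
    acc = np.zeros((H, W, nchan))
    wacc = np.zeros((H, W))
    wtile = _feather_weight(th, tw)
    for tile, (r, c) in zip(ts.tiles, ts.origins):
        acc[r:r + th, c:c + tw] += tile.pixels * wtile[:, :, None]
        wacc[r:r + th, c:c + tw] += wtile
    if (wacc == 0).any():
        ys, xs = np.where(wacc == 0)
        box = (int(ys.min()), int(xs.min()), int(ys.max()), int(xs.max()))
        raise CoverageError(f"uncovered pixels within bounding box {box}")
    out = acc / wacc[:, :, None]
    return replace(ts.tiles[0], pixels=out)
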