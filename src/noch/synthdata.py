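"""Synthetic tissue phantoms with paired label-free channels and pseudo-H&E.

A phantom is a stated world: elliptical nuclei placed by a hard-core point
process with stage-dependent density and log-normal areas, fibrous collagen
(the SHG-like channel), smooth cytoplasmic texture (the 2PA-like channel)
and a diffuse low-SNR channel (the 3PA-like channel). The pseudo-H&E image
is rendered from the same geometry through the optical-density stain forward
model (hematoxylin concentration follows nuclei, eosin follows cytoplasm and
fibers), so stain deconvolution, morphometry and training are all testable
against exact ground truth. Optional rigid + elastic misregistration of the
H&E copy mimics adjacent, unregistered tissue sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .histomorphometry import DEFAULT_STAIN_MATRIX, rgb_from_od
from .imagedata import (MultichannelImage, StainedImage, write_image,
                        write_manifest)

STAGES = ("normal", "IA", "IC", "IIC", "IIIC")

#: Stage presets: nuclear density (per mm^2), median nuclear area (µm^2) and
#: log-normal shape. Density and size dispersion increase monotonically from
#: normal tissue to stage IIIC, tracking the loss of architectural order and
#: nuclear pleomorphism of advancing disease.
STAGE_PRESETS = {
    "normal": {"density_per_mm2": 450.0, "median_area_um2": 30.0, "shape": 0.25},
    "IA":     {"density_per_mm2": 600.0, "median_area_um2": 33.0, "shape": 0.30},
    "IC":     {"density_per_mm2": 750.0, "median_area_um2": 36.0, "shape": 0.35},
    "IIC":    {"density_per_mm2": 875.0, "median_area_um2": 38.0, "shape": 0.40},
    "IIIC":   {"density_per_mm2": 1000.0, "median_area_um2": 40.0, "shape": 0.45},
}


class PlacementError(RuntimeError):
    pass


@dataclass
class PhantomParams:
    image_size: int = 512
    pixel_size_um: float = 0.65
    dynamic_range_L: float = 255.0
    stage: str = "normal"
    #: None -> taken from the stage preset
    density_per_mm2: float | None = None
    median_area_um2: float | None = None
    area_shape: float | None = None
    fiber_density_per_mm2: float = 60.0
    fiber_orientation_kappa: float = 2.0   # von Mises dispersion
    cytoplasm_texture_um: float = 8.0
    threepa_noise_sigma: float = 0.35      # Gaussian part, fraction of signal
    threepa_gain: float = 20.0             # Poisson scaling (photons at full scale)
    hematoxylin_od: float = 0.9            # OD of nuclei along the H vector
    eosin_od: float = 0.35                 # OD of cytoplasm along the E vector
    misreg_offset_um: float = 0.0
    misreg_elastic_um: float = 0.0
    max_overlap_fraction: float = 0.0
    seed: int = 0

    def resolved(self) -> "PhantomParams":
        if self.stage not in STAGE_PRESETS:
            raise ValueError(f"unknown stage {self.stage!r}")
        preset = STAGE_PRESETS[self.stage]
        return replace(
            self,
            density_per_mm2=self.density_per_mm2 or preset["density_per_mm2"],
            median_area_um2=self.median_area_um2 or preset["median_area_um2"],
            area_shape=self.area_shape or preset["shape"])


@dataclass
class PhantomTruth:
    nuclei: list[dict]                 # {x_um, y_um, area_um2}
    prop_hematoxylin: float
    stage: str
    fiber_mask: np.ndarray
    nuclei_mask: np.ndarray
    mean_conc_hematoxylin: float = 0.0
    mean_conc_eosin: float = 0.0

    def to_json(self) -> dict:
        return {"nuclei": self.nuclei, "prop_hematoxylin": self.prop_hematoxylin,
                "stage": self.stage, "n_nuclei": len(self.nuclei)}


def _place_nuclei(p: PhantomParams, rng: np.random.Generator):
    """Hard-core placement: centres at least the sum of radii apart (scaled
    by the permitted overlap fraction)."""
    size_um = p.image_size * p.pixel_size_um
    area_mm2 = (size_um / 1000.0) ** 2
    n = int(round(p.density_per_mm2 * area_mm2))
    mu = np.log(p.median_area_um2)
    centers, radii, areas = [], [], []
    margin = 1.0  # µm from the border
    max_tries = 400 * max(n, 1)
    tries = 0
    while len(centers) < n:
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} nuclei at density "
                f"{p.density_per_mm2}/mm^2 after {max_tries} tries")
        tries += 1
        area = float(np.exp(rng.normal(mu, p.area_shape)))
        r = np.sqrt(area / np.pi)
        c = rng.uniform(margin + r, size_um - margin - r, size=2)
        ok = True
        for (cx, cy), rr in zip(centers, radii):
            if np.hypot(c[0] - cx, c[1] - cy) < (r + rr) * (1 - p.max_overlap_fraction):
                ok = False
                break
        if ok:
            centers.append((c[0], c[1]))
            radii.append(r)
            areas.append(area)
    return centers, radii, areas


def _raster_nuclei(p: PhantomParams, centers, areas, rng):
    """Rasterise elliptical nuclei; returns the mask and per-nucleus truth
    with areas measured on the raster (what morphometry can recover)."""
    N = p.image_size
    px = p.pixel_size_um
    mask = np.zeros((N, N), dtype=bool)
    truth = []
    yy, xx = np.mgrid[0:N, 0:N]
    for (cx_um, cy_um), area in zip(centers, areas):
        q = rng.uniform(0.65, 1.0)               # axis ratio
        a = np.sqrt(area / (np.pi * q)) / px      # semi-axes in px
        b = a * q
        theta = rng.uniform(0, np.pi)
        cx, cy = cx_um / px, cy_um / px
        ct, st = np.cos(theta), np.sin(theta)
        lo = max(0, int(cy - a - 2)), max(0, int(cx - a - 2))
        hi = min(N, int(cy + a + 3)), min(N, int(cx + a + 3))
        ys, xs = yy[lo[0]:hi[0], lo[1]:hi[1]], xx[lo[0]:hi[0], lo[1]:hi[1]]
        u = (xs - cx) * ct + (ys - cy) * st
        v = -(xs - cx) * st + (ys - cy) * ct
        ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        mask[lo[0]:hi[0], lo[1]:hi[1]] |= ell
        npx = int(ell.sum())
        if npx:
            truth.append({"x_um": float(cx_um), "y_um": float(cy_um),
                          "area_um2": float(npx * px ** 2)})
    return mask, truth


def _fiber_map(p: PhantomParams, rng) -> np.ndarray:
    """Collagen-like fibers: smoothed random line segments with a dominant
    orientation."""
    N = p.image_size
    px = p.pixel_size_um
    area_mm2 = (N * px / 1000.0) ** 2
    n_fibers = max(1, int(round(p.fiber_density_per_mm2 * area_mm2)))
    canvas = np.zeros((N, N))
    main_theta = rng.uniform(0, np.pi)
    for _ in range(n_fibers):
        theta = rng.vonmises(2 * main_theta, p.fiber_orientation_kappa) / 2.0
        length = rng.uniform(20, 80) / px
        x0, y0 = rng.uniform(0, N, size=2)
        t = np.linspace(0, 1, max(2, int(length)))
        xs = np.clip(x0 + t * length * np.cos(theta), 0, N - 1).astype(int)
        ys = np.clip(y0 + t * length * np.sin(theta), 0, N - 1).astype(int)
        canvas[ys, xs] += 1.0
    fib = ndimage.gaussian_filter(canvas, sigma=1.2 / px)
    if fib.max() > 0:
        fib = fib / fib.max()
    return fib


def _smooth_noise(shape, scale_px, rng) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.normal(size=shape), sigma=scale_px)
    field_ -= field_.min()
    if field_.max() > 0:
        field_ /= field_.max()
    return field_


def _misregister(rgb: np.ndarray, p: PhantomParams, rng) -> np.ndarray:
    if p.misreg_offset_um == 0 and p.misreg_elastic_um == 0:
        return rgb
    N = rgb.shape[0]
    px = p.pixel_size_um
    angle = rng.uniform(0, 2 * np.pi)
    off = p.misreg_offset_um / px
    dy, dx = off * np.sin(angle), off * np.cos(angle)
    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    ey = ex = 0.0
    if p.misreg_elastic_um > 0:
        amp = p.misreg_elastic_um / px
        ey = (_smooth_noise((N, N), 20.0 / px, rng) - 0.5) * 2 * amp
        ex = (_smooth_noise((N, N), 20.0 / px, rng) - 0.5) * 2 * amp
    coords = [yy + dy + ey, xx + dx + ex]
    out = np.stack([ndimage.map_coordinates(rgb[:, :, c], coords, order=1,
                                            mode="reflect")
                    for c in range(3)], axis=-1)
    return out


def generate_phantom(params: PhantomParams):
    """Render one phantom triplet: (label-free channels, pseudo-H&E, truth).

    Deterministic for a given seed (bitwise-identical output).
    """
    p = params.resolved()
    rng = np.random.default_rng(p.seed)
    N, px, L = p.image_size, p.pixel_size_um, p.dynamic_range_L

    centers, _, areas = _place_nuclei(p, rng)
    nuc_mask, truth_nuclei = _raster_nuclei(p, centers, areas, rng)
    fib = _fiber_map(p, rng)
    cyto = 0.45 + 0.55 * _smooth_noise((N, N), p.cytoplasm_texture_um / px, rng)

    # --- label-free channels (dark background, bright signal) -------------
    # anti-alias the nuclear mask by half a pixel only, so rendered nuclear
    # areas stay faithful to the rasterised truth
    soft_nuc = ndimage.gaussian_filter(nuc_mask.astype(float), sigma=0.5)
    twopa = cyto * (1.0 - 0.85 * soft_nuc)
    twopa = twopa + rng.normal(0, 0.02, twopa.shape)           # high SNR
    shg = fib + rng.normal(0, 0.02, fib.shape)
    diffuse = ndimage.gaussian_filter(cyto, sigma=4.0 / px) * 0.6
    counts = rng.poisson(np.clip(diffuse, 0, None) * p.threepa_gain) / p.threepa_gain
    threepa = counts + rng.normal(0, p.threepa_noise_sigma * diffuse.mean(),
                                  diffuse.shape)               # low SNR
    chans = [np.clip(c, 0, 1) * L for c in (threepa, shg, twopa)]
    multichannel = MultichannelImage(
        np.stack(chans, axis=-1), ["3PA_NADH", "SHG", "2PA_FAD"],
        dynamic_range_L=L, pixel_size_um=px)

    # --- pseudo-H&E through the stain forward model ------------------------
    conc_h = p.hematoxylin_od * soft_nuc
    conc_e = p.eosin_od * (0.55 + 0.45 * cyto + 0.6 * fib) * (1.0 - 0.5 * soft_nuc)
    M = DEFAULT_STAIN_MATRIX
    od = conc_h[:, :, None] * M[0] + conc_e[:, :, None] * M[1]
    rgb = rgb_from_od(od, L)

    # ground-truth component intensities under the same intensity rule
    ih = float(np.mean(np.abs(L - rgb_from_od(conc_h[:, :, None] * M[0], L))))
    ie = float(np.mean(np.abs(L - rgb_from_od(conc_e[:, :, None] * M[1], L))))
    prop = ih / (ih + ie) if (ih + ie) > 0 else float("nan")

    rgb = _misregister(rgb, p, rng)
    stained = StainedImage(np.clip(rgb, 0, L), dynamic_range_L=L,
                           pixel_size_um=px, provenance="phantom_truth")
    truth = PhantomTruth(truth_nuclei, prop, p.stage, fib > 0.25, nuc_mask,
                         mean_conc_hematoxylin=float(conc_h.mean()),
                         mean_conc_eosin=float(conc_e.mean()))
    return multichannel, stained, truth


def channel_snr(channel: np.ndarray, smooth_px: float = 1.5) -> float:
    """Crude SNR estimate: smoothed-signal mean over residual noise sigma."""
    smooth = ndimage.gaussian_filter(channel, smooth_px)
    noise = channel - smooth
    return float(smooth.mean() / max(noise.std(), 1e-12))


def generate_dataset(n_images: int, out_dir, template: PhantomParams | None = None,
                     stage_mix: list[str] | None = None, seed: int = 0,
                     misregister: bool = True):
    """Write a phantom dataset: multichannel TIFFs, H&E PNGs, truth JSONs and
    a manifest compatible with training's dataset split.

    Stage labels are allocated in balanced round-robin order from
    ``stage_mix`` (default: all five stages). Per-image seeds derive from the
    master seed, so regeneration is bit-identical.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = template or PhantomParams()
    if misregister and template.misreg_offset_um == 0 and template.misreg_elastic_um == 0:
        template = replace(template, misreg_offset_um=3.0, misreg_elastic_um=1.5)
    stages = stage_mix or list(STAGES)
    seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2 ** 31)
    entries = []
    for i in range(n_images):
        p = replace(template, stage=stages[i % len(stages)], seed=int(seeds[i]))
        mchan, he, truth = generate_phantom(p)
        xpath = out / f"phantom_{i:03d}_nloi.tif"
        ypath = out / f"phantom_{i:03d}_he.png"
        tpath = out / f"phantom_{i:03d}_truth.json"
        write_image(xpath, mchan)
        write_image(ypath, he)
        with open(tpath, "w") as fh:
            json.dump(truth.to_json(), fh)
        entries.append({"path": xpath.name, "domain": "X",
                        "modalities": mchan.modalities, "stage": p.stage,
                        "pixel_size_um": p.pixel_size_um,
                        "pair": ypath.name, "truth": tpath.name})
        entries.append({"path": ypath.name, "domain": "Y", "stage": p.stage,
                        "pixel_size_um": p.pixel_size_um})
    manifest = out / "manifest.json"
    write_manifest(manifest, entries)
    return manifest, entries
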