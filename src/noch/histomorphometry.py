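"""Quantitative evaluation of stained images.

Stain separation works in optical-density space: OD = -log10((I + eps)/L)
per RGB channel, unmixed against a matrix of unit-norm stain OD vectors
(Ruifrok & Johnston H&E values by default). The hematoxylin/eosin component
"intensity" is the mean of the colour-inverted rendered component image,
I_stain = mean(|L - I_deconv,stain|), and the hematoxylin proportion is
Prop = I_hemat / (I_hemat + I_eosin).

Nuclear morphometry: a classical fallback segmenter (hematoxylin channel ->
smoothing -> Otsu -> watershed split -> size filter) or any plugin detector
returning the same records; nearest-neighbour distances between nuclear
centroids in micrometres; normal-approximation 95% confidence intervals and
two-sample Kolmogorov-Smirnov comparisons with the usual significance bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage import feature, filters, measure, morphology, segmentation

from .imagedata import StainedImage

OD_EPSILON = 1.0  # intensity units added before the log to avoid log(0)

#: Published H&E optical-density vectors (hematoxylin, eosin) with the
#: residual completed as their normalised cross product.
_H = np.array([0.650, 0.704, 0.286])
_E = np.array([0.072, 0.990, 0.105])
_R = np.cross(_H, _E)
DEFAULT_STAIN_MATRIX = np.stack([
    _H / np.linalg.norm(_H), _E / np.linalg.norm(_E), _R / np.linalg.norm(_R)])

STAIN_NAMES = ("hematoxylin", "eosin", "residual")


def validate_stain_matrix(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=np.float64)
    if M.shape != (3, 3):
        raise ValueError("stain matrix must be 3 x 3")
    if np.linalg.cond(M) > 1e6:
        raise ValueError("stain matrix is singular or ill-conditioned")
    return M / np.linalg.norm(M, axis=1, keepdims=True)


@dataclass
class DeconvolutionResult:
    concentrations: np.ndarray            # H x W x 3, >= 0
    components: dict                       # stain -> H x W x 3 rendered image
    intensities: dict                      # stain -> scalar I_stain
    prop_hematoxylin: float
    valid: bool = True

    @property
    def I_hemat(self) -> float:
        return self.intensities["hematoxylin"]

    @property
    def I_eosin(self) -> float:
        return self.intensities["eosin"]


def od_from_rgb(pixels: np.ndarray, L: float) -> np.ndarray:
    # epsilon enters as a floor, not an additive offset: intensities above
    # epsilon transform exactly, so deconvolution inverts the forward model
    return -np.log10(np.maximum(pixels, OD_EPSILON) / L)


def rgb_from_od(od: np.ndarray, L: float) -> np.ndarray:
    return np.clip(L * 10.0 ** (-od), 0.0, L)


def stain_deconvolve(img: StainedImage,
                     M: np.ndarray = DEFAULT_STAIN_MATRIX) -> DeconvolutionResult:
    """Unmix an RGB histology image into per-stain concentration maps and
    rendered single-stain component images, with component intensities and
    the hematoxylin proportion."""
    M = validate_stain_matrix(M)
    L = img.dynamic_range_L
    od = od_from_rgb(img.pixels, L)
    conc = np.clip(od.reshape(-1, 3) @ np.linalg.inv(M), 0.0, None)
    conc = conc.reshape(img.pixels.shape)
    components, intensities = {}, {}
    for i, name in enumerate(STAIN_NAMES):
        od_i = conc[:, :, i:i + 1] * M[i].reshape(1, 1, 3)
        comp = rgb_from_od(od_i, L)
        components[name] = comp
        intensities[name] = float(np.mean(np.abs(L - comp)))
    denom = intensities["hematoxylin"] + intensities["eosin"]
    if denom < 1e-3 * L:
        # essentially blank/white image: proportion undefined
        return DeconvolutionResult(conc, components, intensities,
                                   prop_hematoxylin=float("nan"), valid=False)
    prop = intensities["hematoxylin"] / denom
    return DeconvolutionResult(conc, components, intensities, prop)


# ---------------------------------------------------------------------------
# Nuclear segmentation
# ---------------------------------------------------------------------------

@dataclass
class NucleusRecord:
    label: int
    x_um: float
    y_um: float
    area_um2: float
    boundary: np.ndarray | None = None    # (n, 2) polygon in µm, optional


@dataclass
class SegmentationParams:
    smooth_sigma_um: float = 0.5
    min_area_um2: float = 8.0
    max_area_um2: float = 400.0
    min_peak_distance_um: float = 3.0
    threshold: str = "otsu"


def segment_nuclei(img: StainedImage, method="classical_fallback",
                   params: SegmentationParams | None = None,
                   with_boundaries: bool = False) -> list[NucleusRecord]:
    """Detect nuclei in an H&E-style image.

    ``method`` may be any callable ``img -> list[NucleusRecord]`` (e.g. a
    star-convex detector plugin); the default classical fallback thresholds
    the hematoxylin concentration and splits touching nuclei by
    distance-transform watershed. Requires a pixel size in µm.
    """
    if callable(method):
        return method(img)
    if method != "classical_fallback":
        raise ValueError(f"unknown segmentation method {method!r}")
    if not img.pixel_size_um or img.pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be set for morphometry in µm")
    p = params or SegmentationParams()
    px = img.pixel_size_um

    hema = stain_deconvolve(img).concentrations[:, :, 0]
    smoothed = ndimage.gaussian_filter(hema, sigma=p.smooth_sigma_um / px)
    if smoothed.max() - smoothed.min() < 1e-6:
        return []
    thr = filters.threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = ndimage.binary_fill_holes(mask)
    # drop specks below the minimum nuclear area
    min_px_count = max(1, int(p.min_area_um2 / px ** 2))
    lbl, _ = ndimage.label(mask)
    sizes = np.bincount(lbl.ravel())
    keep = np.flatnonzero(sizes >= min_px_count)
    mask = np.isin(lbl, keep[keep != 0])
    if not mask.any():
        return []

    distance = ndimage.distance_transform_edt(mask)
    min_dist_px = max(1, int(round(p.min_peak_distance_um / px)))
    peaks = feature.peak_local_max(distance, min_distance=min_dist_px,
                                   labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndimage.label(markers > 0)
    labels = segmentation.watershed(-distance, markers, mask=mask)

    records = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * px ** 2
        if not (p.min_area_um2 <= area_um2 <= p.max_area_um2):
            continue
        cy, cx = region.centroid
        boundary = None
        if with_boundaries:
            crop = np.pad((labels[region.slice] == region.label), 1)
            contours = measure.find_contours(crop.astype(float), 0.5)
            if contours:
                c = max(contours, key=len)
                r0, c0 = region.bbox[0], region.bbox[1]
                boundary = np.column_stack([
                    (c[:, 1] - 1 + c0) * px, (c[:, 0] - 1 + r0) * px])
        records.append(NucleusRecord(region.label, cx * px, cy * px,
                                     area_um2, boundary))
    return records


# ---------------------------------------------------------------------------
# Distributions, CIs, comparisons
# ---------------------------------------------------------------------------

def mean_ci95(sample: np.ndarray) -> tuple[float, float, float]:
    """Mean with a normal-approximation 95% CI (mean +/- 1.96 SE)."""
    sample = np.asarray(sample, dtype=np.float64)
    if len(sample) == 0:
        return float("nan"), float("nan"), float("nan")
    m = float(sample.mean())
    se = float(sample.std(ddof=1) / np.sqrt(len(sample))) if len(sample) > 1 else 0.0
    return m, m - 1.96 * se, m + 1.96 * se


def _histogram(sample: np.ndarray, bin_edges=None):
    if bin_edges is None:
        counts, edges = np.histogram(sample, bins="fd")
    else:
        counts, edges = np.histogram(sample, bins=bin_edges)
    return edges, counts


@dataclass
class MorphometrySummary:
    n_nuclei: int
    areas_um2: np.ndarray
    nn_distances_um: np.ndarray
    area_hist: tuple
    nn_hist: tuple
    area_mean_ci: tuple
    nn_mean_ci: tuple
    pixel_size_um: float


def nn_distances(nuclei: Sequence[NucleusRecord]) -> np.ndarray:
    """Euclidean distance from each nuclear centroid to its nearest
    neighbour, in µm."""
    if len(nuclei) < 2:
        raise ValueError("need at least 2 nuclei for nearest-neighbor distances")
    pts = np.array([[n.x_um, n.y_um] for n in nuclei])
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


def nn_distance_distribution(nuclei: Sequence[NucleusRecord], bin_edges=None):
    dists = nn_distances(nuclei)
    return {"distances_um": dists, "hist": _histogram(dists, bin_edges),
            "mean_ci": mean_ci95(dists)}


def summarize_morphometry(nuclei: Sequence[NucleusRecord],
                          pixel_size_um: float,
                          area_bins=None, nn_bins=None) -> MorphometrySummary:
    areas = np.array([n.area_um2 for n in nuclei])
    dists = nn_distances(nuclei) if len(nuclei) >= 2 else np.array([])
    return MorphometrySummary(
        n_nuclei=len(nuclei),
        areas_um2=areas,
        nn_distances_um=dists,
        area_hist=_histogram(areas, area_bins) if len(areas) else ((), ()),
        nn_hist=_histogram(dists, nn_bins) if len(dists) else ((), ()),
        area_mean_ci=mean_ci95(areas) if len(areas) else (np.nan,) * 3,
        nn_mean_ci=mean_ci95(dists) if len(dists) else (np.nan,) * 3,
        pixel_size_um=pixel_size_um)


def significance_band(p: float) -> str:
    if p > 0.05:
        return "ns"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    return "*"


def compare_distributions(a: MorphometrySummary,
                          b: MorphometrySummary) -> dict:
    """Two-sample KS comparison of the area and nearest-neighbour
    distributions of two images, with significance bands, mean differences
    and CI-overlap flags."""
    report = {}
    for metric, sa, sb, cia, cib in (
            ("area_um2", a.areas_um2, b.areas_um2, a.area_mean_ci, b.area_mean_ci),
            ("nn_distance_um", a.nn_distances_um, b.nn_distances_um,
             a.nn_mean_ci, b.nn_mean_ci)):
        if len(sa) == 0 or len(sb) == 0:
            raise ValueError(f"empty sample for metric {metric}")
        if len(sa) == len(sb) and np.array_equal(np.sort(sa), np.sort(sb)):
            stat, p = 0.0, 1.0
        else:
            res = stats.ks_2samp(sa, sb)
            stat, p = float(res.statistic), float(res.pvalue)
        report[metric] = {
            "ks_statistic": stat,
            "p_value": p,
            "band": significance_band(p),
            "mean_difference": float(sa.mean() - sb.mean()),
            "ci_overlap": bool(cia[1] <= cib[2] and cib[1] <= cia[2]),
            "n": (len(sa), len(sb)),
        }
    return report
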