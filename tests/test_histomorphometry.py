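"""Stain deconvolution, nuclear segmentation, distance distributions and
statistical comparisons."""

import numpy as np
import pytest

from noch.histomorphometry import (DEFAULT_STAIN_MATRIX, NucleusRecord,
                                   compare_distributions, mean_ci95,
                                   nn_distance_distribution, nn_distances,
                                   od_from_rgb, rgb_from_od, segment_nuclei,
                                   significance_band, stain_deconvolve,
                                   summarize_morphometry,
                                   validate_stain_matrix)
from noch.imagedata import StainedImage
from noch.synthdata import PhantomParams, generate_phantom


def render_from_concentrations(conc_h, conc_e, L=255.0):
    M = DEFAULT_STAIN_MATRIX
    od = conc_h[:, :, None] * M[0] + conc_e[:, :, None] * M[1]
    return StainedImage(rgb_from_od(od, L), pixel_size_um=0.65)


# -- deconvolution -------------------------------------------------------------

def test_stain_matrix_validation():
    validate_stain_matrix(DEFAULT_STAIN_MATRIX)
    singular = np.ones((3, 3))
    with pytest.raises(ValueError):
        validate_stain_matrix(singular)
    with pytest.raises(ValueError):
        validate_stain_matrix(np.eye(2))


def test_pure_hematoxylin_image_separates_cleanly(rng):
    conc_h = rng.uniform(0.3, 0.9, (32, 32))
    img = render_from_concentrations(conc_h, np.zeros((32, 32)))
    res = stain_deconvolve(img)
    assert res.I_eosin / (res.I_hemat + res.I_eosin) < 0.02


def test_proportion_arithmetic():
    res = stain_deconvolve(render_from_concentrations(
        np.full((8, 8), 0.5), np.full((8, 8), 0.5)))
    assert res.prop_hematoxylin == pytest.approx(
        res.I_hemat / (res.I_hemat + res.I_eosin), abs=1e-12)
    # hematoxylin and eosin proportions are complementary
    prop_e = res.I_eosin / (res.I_hemat + res.I_eosin)
    assert res.prop_hematoxylin + prop_e == pytest.approx(1.0, abs=1e-12)


def test_forward_model_round_trip_recovers_concentrations(rng):
    conc_h = rng.uniform(0.1, 0.8, (48, 48))
    conc_e = rng.uniform(0.1, 0.6, (48, 48))
    img = render_from_concentrations(conc_h, conc_e)
    res = stain_deconvolve(img)
    assert np.abs(res.concentrations[:, :, 0].mean() / conc_h.mean() - 1) < 0.01
    assert np.abs(res.concentrations[:, :, 1].mean() / conc_e.mean() - 1) < 0.01


def test_all_white_image_is_flagged_null():
    res = stain_deconvolve(StainedImage(np.full((16, 16, 3), 255.0)))
    assert not res.valid
    assert np.isnan(res.prop_hematoxylin)
    assert res.I_hemat < 1e-6 and res.I_eosin < 1e-6


# -- segmentation ----------------------------------------------------------------

def test_segmentation_recovers_phantom_count(small_phantom):
    _, he, truth = small_phantom
    nuclei = segment_nuclei(he)
    n_true = len(truth.nuclei)
    assert abs(len(nuclei) - n_true) <= 0.1 * n_true


def test_segmentation_blank_image_gives_zero_nuclei():
    blank = StainedImage(np.full((64, 64, 3), 255.0), pixel_size_um=0.65)
    assert segment_nuclei(blank) == []


def test_segmentation_requires_pixel_size(small_phantom):
    _, he, _ = small_phantom
    bad = StainedImage(he.pixels, pixel_size_um=0.0)
    with pytest.raises(ValueError, match="pixel_size"):
        segment_nuclei(bad)


def test_watershed_splits_two_touching_nuclei():
    """Two discs whose boundaries touch must come out as two records."""
    N, px = 64, 0.65
    yy, xx = np.mgrid[0:N, 0:N]
    r = 6.0
    c1, c2 = (32, 26), (32, 38)   # centres 12 px apart, radii 6 px: touching
    mask = ((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= r ** 2) | \
           ((yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= r ** 2)
    conc_h = 0.8 * mask.astype(float)
    img = render_from_concentrations(conc_h, np.full((N, N), 0.2))
    img.pixel_size_um = px
    nuclei = segment_nuclei(img)
    assert len(nuclei) == 2
    xs = sorted(n.x_um / px for n in nuclei)
    assert xs[0] == pytest.approx(c1[1], abs=2.0)
    assert xs[1] == pytest.approx(c2[1], abs=2.0)


def test_segmentation_plugin_path():
    sentinel = [NucleusRecord(1, 5.0, 5.0, 30.0)]
    img = StainedImage(np.full((8, 8, 3), 255.0), pixel_size_um=0.65)
    assert segment_nuclei(img, method=lambda im: sentinel) is sentinel


def test_segmented_boundaries_in_micrometres(small_phantom):
    _, he, _ = small_phantom
    nuclei = segment_nuclei(he, with_boundaries=True)
    rec = nuclei[0]
    assert rec.boundary is not None and rec.boundary.shape[1] == 2
    assert np.hypot(*(rec.boundary - [rec.x_um, rec.y_um]).T).max() < 20.0


# -- nearest-neighbour distances ---------------------------------------------

def _recs(points):
    return [NucleusRecord(i, float(x), float(y), 30.0)
            for i, (x, y) in enumerate(points)]


def test_nn_distance_3_4_5_triangle():
    d = nn_distances(_recs([(0, 0), (3, 4)]))
    assert np.allclose(d, [5.0, 5.0])


def test_nn_distance_collinear_enumeration():
    d = nn_distances(_recs([(0, 0), (1, 0), (10, 0)]))
    assert np.allclose(sorted(d), [1.0, 1.0, 9.0])


def test_nn_distance_needs_two_nuclei():
    with pytest.raises(ValueError):
        nn_distances(_recs([(0, 0)]))


def test_nn_distances_match_all_pairs_oracle(rng):
    pts = rng.uniform(0, 300, size=(100, 2))
    fast = nn_distances(_recs(pts))
    diff = pts[:, None, :] - pts[None, :, :]
    dm = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(dm, np.inf)
    assert np.array_equal(fast, dm.min(axis=1))


def test_nn_distance_distribution_fragment():
    frag = nn_distance_distribution(_recs([(0, 0), (3, 4), (100, 100)]))
    assert len(frag["distances_um"]) == 3
    mean, lo, hi = frag["mean_ci"]
    assert lo <= mean <= hi


# -- statistics -----------------------------------------------------------------

def test_mean_ci95_matches_closed_form(rng):
    x = rng.normal(10, 2, size=400)
    m, lo, hi = mean_ci95(x)
    se = x.std(ddof=1) / np.sqrt(len(x))
    assert m == pytest.approx(x.mean())
    assert hi - m == pytest.approx(1.96 * se, rel=1e-12)


def test_significance_bands():
    assert significance_band(0.2) == "ns"
    assert significance_band(0.03) == "*"
    assert significance_band(0.005) == "**"
    assert significance_band(5e-4) == "***"
    assert significance_band(1e-5) == "****"


def _summary_from(areas, dists):
    s = summarize_morphometry([], 0.65)
    s.areas_um2 = np.asarray(areas, dtype=float)
    s.nn_distances_um = np.asarray(dists, dtype=float)
    s.area_mean_ci = mean_ci95(s.areas_um2)
    s.nn_mean_ci = mean_ci95(s.nn_distances_um)
    s.n_nuclei = len(areas)
    return s


def test_identical_samples_are_not_significant(rng):
    x = rng.normal(40, 5, 200)
    d = rng.normal(15, 2, 200)
    rep = compare_distributions(_summary_from(x, d), _summary_from(x, d))
    for metric in rep.values():
        assert metric["ks_statistic"] == 0.0
        assert metric["p_value"] == 1.0
        assert metric["band"] == "ns"
        assert metric["ci_overlap"]


def test_far_separated_samples_get_four_stars(rng):
    a = _summary_from(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
    b = _summary_from(rng.normal(5, 1, 200), rng.normal(5, 1, 200))
    rep = compare_distributions(a, b)
    assert rep["area_um2"]["band"] == "****"
    assert rep["area_um2"]["p_value"] < 1e-4
    assert not rep["area_um2"]["ci_overlap"]


def test_comparison_records_group_sizes(rng):
    a = _summary_from(rng.normal(40, 5, 160), rng.normal(15, 2, 160))
    b = _summary_from(rng.normal(40, 5, 160), rng.normal(15, 2, 160))
    rep = compare_distributions(a, b)
    assert rep["area_um2"]["n"] == (160, 160)


def test_comparison_rejects_empty_samples(rng):
    a = _summary_from(rng.normal(40, 5, 10), rng.normal(15, 2, 10))
    b = _summary_from([], [])
    with pytest.raises(ValueError):
        compare_distributions(a, b)


def test_morphometry_summary_histograms_account_for_all_nuclei(small_phantom):
    _, he, _ = small_phantom
    nuclei = segment_nuclei(he)
    s = summarize_morphometry(nuclei, he.pixel_size_um)
    assert s.n_nuclei == len(nuclei)
    assert s.area_hist[1].sum() == s.n_nuclei
    assert s.nn_hist[1].sum() == len(s.nn_distances_um)
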