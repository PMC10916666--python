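"""Image I/O, inversion, crosstalk correction, tiling and stitching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noch.imagedata import (CoverageError, FormatError, MultichannelImage,
                            StainedImage, TileSet, as_rgb,
                            correct_shg_crosstalk, invert_channels,
                            read_image, read_manifest, stitch_tiles,
                            tile_image, write_image, write_manifest)


# -- I/O ---------------------------------------------------------------------

def test_png_8bit_rgb_reads_as_stained(tmp_path):
    arr = np.random.default_rng(0).integers(0, 256, (32, 32, 3), dtype=np.uint8)
    img = StainedImage(arr.astype(float))
    path = tmp_path / "he.png"
    write_image(path, img)
    back = read_image(path, "stained")
    assert back.dynamic_range_L == 255
    assert back.pixels.shape == (32, 32, 3)
    assert np.array_equal(back.pixels, arr)


def test_16bit_2channel_tiff_reads_as_multichannel(tmp_path):
    arr = np.random.default_rng(1).integers(0, 65536, (24, 24, 2),
                                            dtype=np.uint16)
    img = MultichannelImage(arr.astype(float),
                            ["SRS_protein", "SRS_lipid"],
                            dynamic_range_L=65535.0)
    path = tmp_path / "srs.tif"
    write_image(path, img)
    back = read_image(path, "multichannel",
                      modalities=["SRS_protein", "SRS_lipid"])
    assert back.dynamic_range_L == 65535
    assert back.pixels.shape == (24, 24, 2)
    assert np.array_equal(back.pixels, arr)


def test_truncated_file_raises_io_error(tmp_path):
    path = tmp_path / "broken.tif"
    path.write_bytes(b"II*\x00garbage")
    with pytest.raises(IOError):
        read_image(path, "multichannel")


def test_missing_file_raises_io_error(tmp_path):
    with pytest.raises(IOError):
        read_image(tmp_path / "nope.png", "stained")


def test_stained_kind_rejects_wrong_channel_count(tmp_path):
    arr = np.zeros((8, 8), dtype=np.uint8)
    import imageio.v3 as iio
    iio.imwrite(tmp_path / "gray.png", arr)
    with pytest.raises(FormatError):
        read_image(tmp_path / "gray.png", "stained")


def test_manifest_round_trip(tmp_path):
    entries = [{"path": "a.tif", "domain": "X", "modalities": ["SHG"]},
               {"path": "b.png", "domain": "Y"}]
    write_manifest(tmp_path / "m.json", entries)
    assert read_manifest(tmp_path / "m.json") == entries
    write_manifest(tmp_path / "bad.json", [{"path": "c.png"}])
    with pytest.raises(FormatError):
        read_manifest(tmp_path / "bad.json")


# -- inversion ---------------------------------------------------------------

def test_inversion_boundary_values():
    img = MultichannelImage(np.array([[[0.0], [255.0]]]), ["SHG"])
    inv = invert_channels(img)
    assert inv.pixels[0, 0, 0] == 255.0
    assert inv.pixels[0, 1, 0] == 0.0
    assert inv.modalities == ["SHG"]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_inversion_is_an_involution(seed):
    rng = np.random.default_rng(seed)
    px = rng.uniform(0, 255, size=(6, 5, 2))
    img = MultichannelImage(px, ["SHG", "2PA_FAD"])
    twice = invert_channels(invert_channels(img))
    assert np.allclose(twice.pixels, px)


# -- crosstalk ---------------------------------------------------------------

def test_crosstalk_subtraction_and_clamp():
    assert correct_shg_crosstalk(np.array([100.0]), np.array([30.0]))[0] == 70.0
    assert correct_shg_crosstalk(np.array([30.0]), np.array([100.0]))[0] == 0.0


def test_crosstalk_identity_when_no_2pa():
    shg = np.random.default_rng(2).uniform(0, 255, (16, 16))
    assert np.array_equal(correct_shg_crosstalk(shg, np.zeros_like(shg)), shg)


def test_crosstalk_bounds_and_shape_check():
    rng = np.random.default_rng(3)
    shg = rng.uniform(0, 255, (8, 8))
    twopa = rng.uniform(0, 255, (8, 8))
    out = correct_shg_crosstalk(shg, twopa)
    assert (out >= 0).all() and (out <= shg).all()
    with pytest.raises(ValueError):
        correct_shg_crosstalk(shg, twopa[:4])


# -- tiling ------------------------------------------------------------------

def _const_stained(h, w, value=128.0):
    return StainedImage(np.full((h, w, 3), value))


@pytest.mark.parametrize("size,tile,stride,expected", [
    ((1024, 1024), 512, 512, 4),     # exact cover
    ((1088, 1088), 544, 544, 4),     # the large-frame tile size, exact cover
    ((100, 100), 64, 64, 4),         # remainder tiles re-anchored to border
])
def test_tile_counts(size, tile, stride, expected):
    img = _const_stained(*size)
    ts = tile_image(img, (tile, tile), (stride, stride))
    assert len(ts.tiles) == expected
    assert len(set(ts.origins)) == len(ts.origins)


def test_edge_tiles_anchor_to_border():
    ts = tile_image(_const_stained(100, 100), (64, 64), (64, 64))
    assert sorted(ts.origins) == [(0, 0), (0, 36), (36, 0), (36, 36)]


def test_tile_larger_than_image_raises():
    with pytest.raises(ValueError):
        tile_image(_const_stained(32, 32), (64, 64))


# -- stitching ---------------------------------------------------------------

def test_tile_then_stitch_round_trip_zero_overlap():
    rng = np.random.default_rng(5)
    img = StainedImage(rng.uniform(0, 255, (96, 96, 3)))
    ts = tile_image(img, (32, 32), (32, 32))
    out = stitch_tiles(ts)
    assert np.allclose(out.pixels, img.pixels)


def test_stitch_constant_tiles_is_constant():
    img = _const_stained(64, 96, 77.0)
    ts = tile_image(img, (64, 64), (32, 32))
    out = stitch_tiles(ts)
    assert np.allclose(out.pixels, 77.0)


def test_stitch_blend_is_monotone_and_convex():
    dark = StainedImage(np.zeros((32, 32, 3)))
    bright = StainedImage(np.full((32, 32, 3), 100.0))
    ts = TileSet([dark, bright], [(0, 0), (0, 16)], (32, 32), (32, 48), 0.5)
    out = stitch_tiles(ts)
    row = out.pixels[16, :, 0]
    assert (out.pixels >= 0).all() and (out.pixels <= 100).all()
    strip = row[16:32]
    assert (np.diff(strip) >= 0).all() and strip[0] < strip[-1]
    assert np.allclose(row[:16], 0) and np.allclose(row[32:], 100)


def test_stitch_reports_coverage_gap():
    tiles = [_const_stained(16, 16), _const_stained(16, 16)]
    ts = TileSet(tiles, [(0, 0), (32, 32)], (16, 16), (48, 48))
    with pytest.raises(CoverageError):
        stitch_tiles(ts)


# -- colour rendering of multichannel inputs ---------------------------------

def test_as_rgb_maps_modalities_to_channels():
    rng = np.random.default_rng(6)
    px = rng.uniform(0, 255, (8, 8, 2))
    srs = MultichannelImage(px, ["SRS_protein", "SRS_lipid"])
    rgb = as_rgb(srs)
    assert rgb.pixels.shape == (8, 8, 3)
    assert np.array_equal(rgb.pixels[:, :, 1], px[:, :, 0])   # protein -> green
    assert np.array_equal(rgb.pixels[:, :, 2], px[:, :, 1])   # lipid -> blue
    assert np.all(rgb.pixels[:, :, 0] == 0)


def test_invariants_rejected_on_bad_inputs():
    with pytest.raises(FormatError):
        MultichannelImage(np.full((4, 4, 1), 300.0), ["SHG"])
    with pytest.raises(FormatError):
        MultichannelImage(np.zeros((4, 4, 2)), ["SHG"])
    with pytest.raises(FormatError):
        StainedImage(np.zeros((4, 4, 2)))
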