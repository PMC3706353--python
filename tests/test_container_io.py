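import struct
from fractions import Fraction

import numpy as np
import pytest
import tifffile
from hypothesis import given
from hypothesis import strategies as st

import gigaslide as gs
from gigaslide.container_io import read_rows
from gigaslide.errors import METADATA_ABSENT
from gigaslide.synthetic import pattern_block


def test_open_reads_headers_not_pixels(gradient_plane):
    """Opening a container must parse geometry/metadata without decoding pixels."""
    plane = gradient_plane.planes[0]
    assert (plane.width, plane.height) == (1000, 800)
    assert plane.tile_grid == gs.TileGrid(256, 256)
    assert (plane.tiles_per_row, plane.tiles_per_col) == (4, 4)
    assert plane.magnification == 40 and plane.focus_offset == 0
    fresh = gs.open_container(gradient_plane.source)
    assert fresh.planes[0].decode_count == 0
    fresh.close()


def test_tile_grid_ceiling_arithmetic(tmp_path):
    container = gs.generate_tiled_plane(tmp_path / "p.tif", 1024, 768, pattern="constant")
    plane = container.planes[0]
    assert (plane.tiles_per_row, plane.tiles_per_col) == (4, 3)
    container.close()


def test_read_tile_constant_and_checkerboard(tmp_path, checkerboard_plane):
    container = gs.generate_tiled_plane(tmp_path / "w.tif", 600, 400, pattern="constant")
    tile = gs.read_tile(container.planes[0], 0, 1)
    assert (tile.valid == 255).all()
    container.close()
    # checkerboard tiles match the analytic parity pattern
    plane = checkerboard_plane.planes[0]
    for row, col in [(0, 0), (0, 1), (1, 2)]:
        tile = gs.read_tile(plane, row, col)
        expected = pattern_block("checkerboard", col * 256, row * 256, 256, 256)
        assert np.array_equal(tile.valid, expected[: tile.valid_height, : tile.valid_width])
    # with one checker cell per tile, adjacent tiles are exact complements
    coarse = gs.generate_tiled_plane(
        tmp_path / "coarse.tif", 1024, 512, pattern="checkerboard", cell=256
    )
    t00 = gs.read_tile(coarse.planes[0], 0, 0).valid
    t01 = gs.read_tile(coarse.planes[0], 0, 1).valid
    assert np.array_equal(t00, 255 - t01)
    coarse.close()


def test_edge_tile_valid_extent(gradient_plane):
    plane = gradient_plane.planes[0]
    tile = gs.read_tile(plane, 3, 3)
    assert (tile.valid_width, tile.valid_height) == (232, 32)
    assert tile.pixels.shape[:2] == (256, 256)


def test_tile_bounds_error(gradient_plane):
    with pytest.raises(gs.BoundsError):
        gs.read_tile(gradient_plane.planes[0], 4, 0)
    with pytest.raises(gs.BoundsError):
        gs.read_tile(gradient_plane.planes[0], 0, -1)


def test_valid_extents_partition_plane(gradient_plane):
    plane = gradient_plane.planes[0]
    total = sum(
        gs.read_tile(plane, r, c).valid_width * gs.read_tile(plane, r, c).valid_height
        for r in range(plane.tiles_per_col)
        for c in range(plane.tiles_per_row)
    )
    assert total == plane.width * plane.height


@pytest.mark.parametrize("compression", ["none", "lzw", "deflate"])
def test_lossless_write_read_roundtrip(tmp_path, compression):
    rng = np.random.default_rng(11)
    full = rng.integers(0, 256, (500, 700, 3)).astype(np.uint8)
    spec = gs.ImagePlane(
        index=0, width=700, height=500, tile_grid=gs.TileGrid(256, 256),
        compression=compression,
    )
    container = gs.write_plane_streamed(
        tmp_path / "rt.tif", spec, lambda r, c: full[r * 256 : (r + 1) * 256, c * 256 : (c + 1) * 256]
    )
    plane = container.planes[0]
    assert plane.compression == compression
    recon = gs.extract_region(plane, gs.Region(0, 0, 700, 500))
    assert np.array_equal(recon, full)
    container.close()


def test_dialect_magic_values(tmp_path):
    spec = gs.ImagePlane(index=0, width=64, height=64, tile_grid=gs.TileGrid(16, 16))
    small = np.zeros((16, 16, 3), np.uint8)
    for force, magic in [(True, 43), (False, 42)]:
        path = tmp_path / f"magic{magic}.tif"
        container = gs.write_plane_streamed(path, spec, lambda r, c: small, force_big_offsets=force)
        assert container.big_offsets is force
        container.close()
        with open(path, "rb") as f:
            _, version = struct.unpack("<2sH", f.read(4))
        assert version == magic


def test_classic_refused_beyond_4gib(tmp_path):
    spec = gs.ImagePlane(
        index=0, width=180224, height=70144, tile_grid=gs.TileGrid(256, 256)
    )
    with pytest.raises(gs.FormatError, match="4 GiB"):
        gs.write_plane_streamed(
            tmp_path / "huge.tif", spec, lambda r, c: None, force_classic=True
        )


magnifications = st.one_of(
    st.integers(min_value=1, max_value=1000),
    st.just("macro"),
    st.fractions(min_value=Fraction(1, 100), max_value=100),
    st.floats(min_value=0.01, max_value=100, allow_nan=False).map(lambda x: round(x, 4)),
)


@given(magnification=magnifications, focus=st.integers(min_value=-50, max_value=50))
def test_metadata_encode_decode_bijection(magnification, focus):
    text = gs.encode_plane_metadata(magnification, focus)
    assert text.isascii() and text.isprintable()
    assert gs.decode_plane_metadata(text) == (magnification, focus)


def test_metadata_absent_is_signal_not_exception():
    assert gs.decode_plane_metadata("just a comment") is METADATA_ABSENT
    assert gs.decode_plane_metadata("") is METADATA_ABSENT
    assert not gs.decode_plane_metadata("magnification=40")  # focus key missing


def test_copy_tile_count_and_equality(checkerboard_plane, tmp_path):
    plane = checkerboard_plane.planes[0]
    paths = gs.split_tiles(plane, tmp_path / "tiles", stem="cb")
    assert len(paths) == 12  # 4 x 3 grid of a 1024x768 plane
    arr = tifffile.imread(tmp_path / "tiles" / "cb_i2j3.tif")
    assert np.array_equal(arr, gs.read_tile(plane, 1, 2).valid)


def test_copy_tile_jpeg_preserves_bytes(tmp_path):
    rng = np.random.default_rng(5)
    full = rng.integers(0, 256, (512, 512, 3)).astype(np.uint8)
    spec = gs.ImagePlane(
        index=0, width=512, height=512, tile_grid=gs.TileGrid(256, 256), compression="jpeg"
    )
    container = gs.write_plane_streamed(
        tmp_path / "j.tif", spec, lambda r, c: full[r * 256 : (r + 1) * 256, c * 256 : (c + 1) * 256]
    )
    plane = container.planes[0]
    source_len = plane._page.databytecounts[1]
    out = tmp_path / "tile.tif"
    gs.copy_tile_compressed(plane, 0, 1, out)
    copied = tifffile.TiffFile(out)
    assert copied.pages[0].databytecounts[0] == source_len  # no transcode
    assert np.array_equal(tifffile.imread(out), gs.read_tile(plane, 0, 1).pixels)
    copied.close()
    container.close()


def test_stripped_plane_read_only_row_bands(tmp_path):
    rng = np.random.default_rng(3)
    full = rng.integers(0, 256, (300, 400, 3)).astype(np.uint8)
    tifffile.imwrite(tmp_path / "s.tif", full, rowsperstrip=64, compression="zlib")
    container = gs.open_container(tmp_path / "s.tif")
    plane = container.planes[0]
    assert not plane.is_tiled
    band = read_rows(plane, 100, 180)
    assert np.array_equal(band, full[100:180])
    with pytest.raises(gs.NotTiledError):
        gs.read_tile(plane, 0, 0)
    with pytest.raises(gs.NotTiledError):
        gs.copy_tile_compressed(plane, 0, 0, tmp_path / "x.tif")
    container.close()


def test_open_errors(tmp_path):
    with pytest.raises(gs.FormatError):
        gs.open_container(tmp_path / "missing.tif")
    bad = tmp_path / "bad.tif"
    bad.write_bytes(b"not a tiff at all")
    with pytest.raises(gs.FormatError):
        gs.open_container(bad)
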