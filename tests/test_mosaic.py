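import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gigaslide as gs
from gigaslide.mosaic import MIB, load_plan, plan_from_dict, plan_to_dict, save_plan


def test_uncompressed_bytes_arithmetic():
    assert gs.uncompressed_bytes(103168, 63232, 3) == 19_570_556_928
    assert gs.uncompressed_bytes(103168, 63232, 3) / 2**30 == pytest.approx(18.2, abs=0.05)
    assert gs.uncompressed_bytes(1, 1, 3) == 3
    # the largest slide plane class exceeds the classic-TIFF 4 GiB limit
    assert gs.uncompressed_bytes(180224, 70144, 3) == 37_924_896_768 > 2**32


def test_plan_grid_published_example():
    assert gs.plan_grid(103168, 63232, 3, gs.RamBudget.mib(512)) == (8, 8)


def test_plan_grid_whole_image_fits():
    assert gs.plan_grid(1000, 800, 3, gs.RamBudget(gs.uncompressed_bytes(1000, 800, 3))) == (1, 1)


def test_plan_grid_small_example():
    # (2,1)/(1,2) pieces need 1,200,000 B > 1 MiB; (2,2) needs 600,000 B
    assert gs.plan_grid(1000, 800, 3, 2**20) == (2, 2)


def test_plan_grid_impossible_budget_reports_minimum():
    with pytest.raises(gs.BudgetError):
        gs.plan_grid(100, 100, 3, 2)


def _exhaustive_pow2_minimum(width, height, bpp, budget):
    """Brute-force oracle: minimum piece count over all power-of-two grids."""
    best = None
    gc = 1
    while gc < 2 * width:
        gr = 1
        while gr < 2 * height:
            piece = math.ceil(width / gc) * math.ceil(height / gr) * bpp
            if piece <= budget:
                best = gc * gr if best is None else min(best, gc * gr)
            if gr >= height:
                break
            gr *= 2
        if gc >= width:
            break
        gc *= 2
    return best


@given(
    width=st.integers(min_value=1, max_value=4096),
    height=st.integers(min_value=1, max_value=4096),
    bpp=st.sampled_from([1, 3, 4]),
    budget_kib=st.integers(min_value=4, max_value=4096),
)
def test_planner_matches_exhaustive_search(width, height, bpp, budget_kib):
    budget = budget_kib * 1024
    expected = _exhaustive_pow2_minimum(width, height, bpp, budget)
    if expected is None:
        with pytest.raises(gs.BudgetError):
            gs.plan_grid(width, height, bpp, budget)
        return
    gc, gr = gs.plan_grid(width, height, bpp, budget)
    assert gc * gr == expected
    assert math.ceil(width / gc) * math.ceil(height / gr) * bpp <= budget


@given(
    width=st.integers(min_value=8, max_value=3000),
    height=st.integers(min_value=8, max_value=3000),
    budget_kib=st.integers(min_value=64, max_value=2048),
    overlap=st.sampled_from([0, 1, 3]),
)
def test_plan_partition_and_budget_invariants(width, height, budget_kib, overlap):
    """Cores partition the plane exactly; every padded box fits the budget."""
    plan = gs.plan_mosaic(
        width, height, 3, budget_kib * 1024, gs.OverlapSpec.pixels(overlap)
    )
    # disjoint cover: paint each core once, every pixel painted exactly once
    canvas = np.zeros((height, width), dtype=np.int32)
    for piece in plan.pieces:
        canvas[piece.core.y : piece.core.y_end, piece.core.x : piece.core.x_end] += 1
        assert piece.core.x >= piece.padded.x and piece.core.y >= piece.padded.y
        assert piece.core.x_end <= piece.padded.x_end
        assert piece.core.y_end <= piece.padded.y_end
    assert (canvas == 1).all()
    assert plan.max_piece_bytes <= budget_kib * 1024
    # near-equal split: core extents differ by at most 1 px per axis
    widths = {p.core.width for p in plan.pieces}
    heights = {p.core.height for p in plan.pieces}
    assert max(widths) - min(widths) <= 1 and max(heights) - min(heights) <= 1


@given(
    width=st.integers(min_value=64, max_value=4000),
    height=st.integers(min_value=64, max_value=4000),
    budget_kib=st.integers(min_value=16, max_value=1024),
)
def test_doubling_budget_never_increases_pieces(width, height, budget_kib):
    gc1, gr1 = gs.plan_grid(width, height, 3, budget_kib * 1024)
    gc2, gr2 = gs.plan_grid(width, height, 3, 2 * budget_kib * 1024)
    assert gc2 * gr2 <= gc1 * gr1


def test_interior_padded_width_includes_both_overlaps():
    plan = gs.plan_mosaic(10000, 8000, 3, (2500, 2000), gs.OverlapSpec.pixels(60))
    interior = plan.piece(1, 1)
    assert interior.padded.width == interior.core.width + 120
    assert interior.padded.height == interior.core.height + 120
    corner = plan.piece(0, 0)
    assert corner.padded.width == corner.core.width + 60  # clipped at plane edge


def test_percent_overlap_resolves_against_plane():
    spec = gs.OverlapSpec.percent(1)
    assert spec.resolve(10000, 5000) == (100, 50)


def test_overlap_must_be_smaller_than_core():
    with pytest.raises(gs.ConfigurationError):
        gs.plan_mosaic(1000, 1000, 3, (250, 250), gs.OverlapSpec.pixels(300))


def test_explicit_piece_size_uses_ceil_division():
    plan = gs.plan_mosaic(1000, 800, 3, (300, 300))
    assert (plan.grid_cols, plan.grid_rows) == (4, 3)


@pytest.mark.parametrize(
    "overlap",
    [gs.OverlapSpec.pixels(0), gs.OverlapSpec.pixels(17), gs.OverlapSpec.pixels(60), gs.OverlapSpec.percent(1)],
)
def test_mosaic_reassemble_identity(gradient_plane, gradient_full, tmp_path, overlap):
    plan = gs.plan_mosaic(1000, 800, 3, (300, 300), overlap)
    files = gs.make_mosaic(
        gradient_plane, 0, plan, "tiff", "g", tmp_path / overlap.mode / str(overlap.amount_x)
    )
    assert len(files) == plan.n_pieces
    assert np.array_equal(gs.reassemble(plan, files), gradient_full)


def test_single_piece_plan_is_identity(gradient_plane, gradient_full, tmp_path):
    plan = gs.plan_mosaic(1000, 800, 3, gs.uncompressed_bytes(1000, 800, 3))
    assert plan.n_pieces == 1
    files = gs.make_mosaic(gradient_plane, 0, plan, "tiff", "one", tmp_path)
    assert np.array_equal(gs.reassemble(plan, files), gradient_full)


def test_pieces_equal_padded_region_extracts(gradient_plane, tmp_path):
    import tifffile

    plan = gs.plan_mosaic(1000, 800, 3, (300, 300), gs.OverlapSpec.pixels(30))
    files = gs.make_mosaic(gradient_plane, 0, plan, "tiff", "p", tmp_path)
    plane = gradient_plane.planes[0]
    for piece, path in zip(plan.pieces, files):
        assert np.array_equal(tifffile.imread(path), gs.extract_region(plane, piece.padded))


def test_missing_piece_reports_coordinates(gradient_plane, tmp_path):
    plan = gs.plan_mosaic(1000, 800, 3, (500, 400))
    files = gs.make_mosaic(gradient_plane, 0, plan, "tiff", "m", tmp_path)
    files[2] = str(tmp_path / "vanished.tif")
    with pytest.raises(gs.GigaslideError, match=r"\(1, 0\)"):  # index 2 in a 2x2 grid
        gs.reassemble(plan, files)


def test_plan_json_roundtrip(tmp_path):
    plan = gs.plan_mosaic(5000, 4000, 3, gs.RamBudget.mib(8), gs.OverlapSpec.pixels(60))
    path = save_plan(plan, tmp_path / "plan.json")
    loaded = load_plan(path)
    assert plan_to_dict(loaded) == plan_to_dict(plan)


def test_jpeg_pieces_decode_close(gradient_plane, tmp_path):
    plan = gs.plan_mosaic(1000, 800, 3, (500, 400))
    files = gs.make_mosaic(gradient_plane, 0, plan, "jpeg", "j", tmp_path, jpeg_quality=95)
    from PIL import Image

    first = np.asarray(Image.open(files[0]))
    ref = gs.extract_region(gradient_plane.planes[0], plan.pieces[0].padded)
    assert first.shape == ref.shape
    assert np.abs(first.astype(int) - ref.astype(int)).mean() < 20
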