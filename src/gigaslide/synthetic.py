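"""Streamed generators for synthetic slide fixtures with known ground truth.

Every generator is a pure function of its parameters and seed: rerunning one
produces byte-identical files.  Pixel content is computed tile by tile at
write time, so generating a plane never allocates more than a few tile rows
— the same memory discipline the rest of the toolkit relies on.

What these fixtures emulate: tiled pyramidal slide containers with
magnification/focus metadata, tissue images where dark nuclei of known
position and size sit on a bright noisy background, and multi-sample slides
whose tissue blocks are separated by scanner-white filler.  They do not
emulate real histology texture, staining variation or focus blur.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .container_io import (
    ImagePlane,
    SlideContainer,
    TileGrid,
    append_plane,
    encode_plane_metadata,
    open_container,
    write_plane_streamed,
)
from .errors import ConfigurationError, GigaslideError
from .region import Region

__all__ = [
    "TissueSpec",
    "pattern_block",
    "generate_tiled_plane",
    "generate_pyramid",
    "generate_tissue",
    "generate_blank_separated",
]


# ---------------------------------------------------------------------------
# analytic patterns
# ---------------------------------------------------------------------------

def pattern_block(
    pattern: str,
    x0: int,
    y0: int,
    width: int,
    height: int,
    *,
    seed: int = 0,
    cell: int = 64,
    samples: int = 3,
) -> np.ndarray:
    """Pixels of a pattern over the block [x0, x0+width) x [y0, y0+height).

    ``constant``, ``checkerboard`` and ``gradient`` are pure per-pixel
    functions of global coordinates, so any block can be regenerated
    independently — the oracle used by the extraction tests.  ``noise`` is
    seeded per block origin: deterministic for a fixed tiling.
    """
    x = np.arange(x0, x0 + width)
    y = np.arange(y0, y0 + height)
    xx, yy = np.meshgrid(x, y)
    if pattern == "constant":
        block = np.full((height, width, samples), 255, dtype=np.uint8)
    elif pattern == "checkerboard":
        parity = ((xx // cell + yy // cell) % 2).astype(np.uint8) * 255
        block = np.repeat(parity[:, :, None], samples, axis=2)
    elif pattern == "gradient":
        channels = [xx % 256, yy % 256, (xx + yy) % 256]
        block = np.stack(channels[:samples], axis=2).astype(np.uint8)
    elif pattern == "noise":
        rng = np.random.default_rng([seed, 3, x0, y0])
        block = rng.integers(0, 256, (height, width, samples), dtype=np.uint8)
    else:
        raise ConfigurationError(f"unknown pattern {pattern!r}")
    return block


def generate_tiled_plane(
    sink: str | os.PathLike,
    width: int,
    height: int,
    tile_grid: TileGrid = TileGrid(256, 256),
    compression: str = "deflate",
    pattern: str = "checkerboard",
    *,
    seed: int = 0,
    cell: int = 64,
    samples: int = 3,
    magnification=None,
    focus_offset: int | None = None,
) -> SlideContainer:
    """Write a single tiled plane with analytic content, tile by tile."""
    spec = ImagePlane(
        index=0,
        width=width,
        height=height,
        samples_per_pixel=samples,
        tile_grid=tile_grid,
        compression=compression,
        magnification=magnification,
        focus_offset=focus_offset,
    )

    def tile_at(row: int, col: int) -> np.ndarray:
        x0 = col * tile_grid.tile_width
        y0 = row * tile_grid.tile_height
        w = min(tile_grid.tile_width, width - x0)
        h = min(tile_grid.tile_height, height - y0)
        return pattern_block(pattern, x0, y0, w, h, seed=seed, cell=cell, samples=samples)

    return write_plane_streamed(sink, spec, tile_at)


# ---------------------------------------------------------------------------
# magnification / focus pyramids
# ---------------------------------------------------------------------------

def generate_pyramid(
    sink: str | os.PathLike,
    base_width: int,
    base_height: int,
    magnifications: list,
    focus_offsets: list[int],
    tile_grid: TileGrid = TileGrid(128, 128),
    compression: str = "deflate",
    *,
    force_big_offsets: bool = False,
) -> SlideContainer:
    """Write a multi-image container: one plane per (magnification, focus).

    Magnifications must be numeric and descending from the base level; a
    plane at magnification m has dimensions ``ceil(base * m / m0)``.  Planes
    are ordered magnification-major, focus-minor, and each carries its
    metadata in the image description.
    """
    mags = list(magnifications)
    if any(m2 > m1 for m1, m2 in zip(mags, mags[1:])):
        raise ConfigurationError("magnifications must be in descending order")
    base_mag = float(mags[0])
    with tifffile.TiffWriter(os.fspath(sink), bigtiff=force_big_offsets) as writer:
        for mag in mags:
            ratio = float(mag) / base_mag
            w = max(1, math.ceil(base_width * ratio))
            h = max(1, math.ceil(base_height * ratio))
            for focus in focus_offsets:
                spec = ImagePlane(
                    index=0,
                    width=w,
                    height=h,
                    samples_per_pixel=3,
                    tile_grid=tile_grid,
                    compression=compression,
                    description=encode_plane_metadata(mag, focus),
                )

                def tile_at(row: int, col: int, w=w, h=h) -> np.ndarray:
                    x0 = col * tile_grid.tile_width
                    y0 = row * tile_grid.tile_height
                    return pattern_block(
                        "gradient",
                        x0,
                        y0,
                        min(tile_grid.tile_width, w - x0),
                        min(tile_grid.tile_height, h - y0),
                    )

                append_plane(writer, spec, tile_at)
    return open_container(sink)


# ---------------------------------------------------------------------------
# tissue with ground-truth nuclei
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueSpec:
    """Parameters of a synthetic tissue plane with known nuclei.

    Defaults describe the standard test slide: a 16000 x 12000 px plane
    carrying 2000 dark nuclei (radii 5-14 px) on a bright noisy background,
    with centers at least 84 px apart (three times the largest diameter) so
    detections are unambiguous.
    """

    width: int = 16000
    height: int = 12000
    n_nuclei: int = 2000
    radius_range: tuple[float, float] = (5.0, 14.0)
    min_separation: float = 84.0
    background_luminosity: int = 230
    nucleus_luminosity: int = 60
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.nucleus_luminosity < self.background_luminosity:
            raise ConfigurationError("nuclei must be darker than the background")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ConfigurationError("radius range must be positive and ordered")
        # hard-disk packing feasibility bound (rejection sampling would stall
        # long before densities anywhere near this)
        exclusion = math.pi * self.min_separation**2 * self.n_nuclei
        if self.n_nuclei and exclusion > 0.5 * self.width * self.height:
            raise ConfigurationError(
                "min_separation infeasible for n_nuclei in the given area"
            )


def place_nuclei(spec: TissueSpec) -> pd.DataFrame:
    """Seeded rejection sampling of nucleus centers honoring min_separation.

    Returns the ground-truth table (x, y, radius); disks lie fully inside the
    plane.  Deterministic given the spec's seed.
    """
    rng = np.random.default_rng([spec.seed, 1])
    margin = spec.radius_range[1] + 1
    xs = np.empty(spec.n_nuclei)
    ys = np.empty(spec.n_nuclei)
    placed = 0
    tries = 0
    max_tries = 1000 * max(spec.n_nuclei, 1)
    min_sep_sq = spec.min_separation**2
    while placed < spec.n_nuclei:
        if tries > max_tries:
            raise GigaslideError(
                f"could not place {spec.n_nuclei} nuclei after {max_tries} tries"
            )
        tries += 1
        x = rng.uniform(margin, spec.width - margin)
        y = rng.uniform(margin, spec.height - margin)
        if placed:
            d2 = (xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2
            if d2.min() < min_sep_sq:
                continue
        xs[placed], ys[placed] = x, y
        placed += 1
    radii = rng.uniform(spec.radius_range[0], spec.radius_range[1], spec.n_nuclei)
    return pd.DataFrame({"x": xs, "y": ys, "radius": radii})


def render_tissue_block(
    spec: TissueSpec, truth: pd.DataFrame, region: Region, *, tile_key: tuple[int, int]
) -> np.ndarray:
    """Render one block of the tissue image (background + disks + noise)."""
    h, w = region.height, region.width
    lum = np.full((h, w), float(spec.background_luminosity))
    r_max = spec.radius_range[1]
    near = truth[
        (truth.x >= region.x - r_max - 1)
        & (truth.x < region.x_end + r_max + 1)
        & (truth.y >= region.y - r_max - 1)
        & (truth.y < region.y_end + r_max + 1)
    ]
    yy, xx = np.mgrid[region.y : region.y_end, region.x : region.x_end]
    for row in near.itertuples():
        mask = (xx - row.x) ** 2 + (yy - row.y) ** 2 <= row.radius**2
        lum[mask] = spec.nucleus_luminosity
    rng = np.random.default_rng([spec.seed, 2, tile_key[0], tile_key[1]])
    lum += rng.normal(0.0, spec.noise_sd, (h, w))
    lum = np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    return np.repeat(lum[:, :, None], 3, axis=2)


def generate_tissue(
    spec: TissueSpec,
    sink: str | os.PathLike,
    truth_sink: str | os.PathLike | None = None,
    tile_grid: TileGrid = TileGrid(256, 256),
) -> tuple[SlideContainer, pd.DataFrame]:
    """Write a tissue plane tile by tile; return the container and ground truth.

    Noise is keyed per tile, so the file is a pure function of (spec, tiling).
    The same gray value is used for all three channels: nuclei differ from
    background in luminosity, which is what the detector thresholds.
    """
    truth = place_nuclei(spec)
    plane_spec = ImagePlane(
        index=0,
        width=spec.width,
        height=spec.height,
        samples_per_pixel=3,
        tile_grid=tile_grid,
        compression="deflate",
        magnification=40,
        focus_offset=0,
    )

    def tile_at(row: int, col: int) -> np.ndarray:
        x0 = col * tile_grid.tile_width
        y0 = row * tile_grid.tile_height
        w = min(tile_grid.tile_width, spec.width - x0)
        h = min(tile_grid.tile_height, spec.height - y0)
        return render_tissue_block(
            spec, truth, Region(x0, y0, w, h), tile_key=(row, col)
        )

    container = write_plane_streamed(sink, plane_spec, tile_at)
    if truth_sink is not None:
        truth.to_csv(os.fspath(truth_sink), index=False)
    return container, truth


# ---------------------------------------------------------------------------
# blank-separated multi-block slides
# ---------------------------------------------------------------------------

def generate_blank_separated(
    sink: str | os.PathLike,
    width: int,
    height: int,
    block_boxes: list[Region],
    gap_luminosity: int = 255,
    *,
    seed: int = 0,
    block_mean: int = 170,
    block_sd: float = 25.0,
    tile_grid: TileGrid = TileGrid(256, 256),
) -> tuple[SlideContainer, list[Region]]:
    """Write a slide of textured tissue blocks separated by uniform filler.

    Blocks must be pairwise disjoint; the returned table records the exact
    block boxes (the ground truth for blank-band splitting).
    """
    for i, a in enumerate(block_boxes):
        for b in block_boxes[i + 1 :]:
            if a.intersects(b):
                raise ConfigurationError(f"blocks {a} and {b} overlap")

    plane_spec = ImagePlane(
        index=0,
        width=width,
        height=height,
        samples_per_pixel=3,
        tile_grid=tile_grid,
        compression="deflate",
    )

    def tile_at(row: int, col: int) -> np.ndarray:
        x0 = col * tile_grid.tile_width
        y0 = row * tile_grid.tile_height
        w = min(tile_grid.tile_width, width - x0)
        h = min(tile_grid.tile_height, height - y0)
        lum = np.full((h, w), float(gap_luminosity))
        tile_box = Region(x0, y0, w, h)
        rng = np.random.default_rng([seed, 4, row, col])
        for block in block_boxes:
            if not tile_box.intersects(block):
                continue
            bx0, by0 = max(x0, block.x), max(y0, block.y)
            bx1, by1 = min(x0 + w, block.x_end), min(y0 + h, block.y_end)
            texture = rng.normal(block_mean, block_sd, (by1 - by0, bx1 - bx0))
            lum[by0 - y0 : by1 - y0, bx0 - x0 : bx1 - x0] = texture
        lum = np.clip(np.rint(lum), 0, 255).astype(np.uint8)
        return np.repeat(lum[:, :, None], 3, axis=2)

    container = write_plane_streamed(sink, plane_spec, tile_at)
    return container, list(block_boxes)
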