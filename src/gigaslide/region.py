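"""Fast rectangular extraction from huge tiled planes.

Cropping a region decodes only the tiles that intersect it, so the cost of a
fixed-size crop is independent of the plane's total area — the property that
makes region-of-interest work on multi-gigapixel slides practical.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np

from .container_io import ImagePlane, read_rows, read_tile
from .errors import BoundsError, ConfigurationError

__all__ = ["Region", "tiles_for_region", "extract_region", "save_region", "clip_region"]


@dataclass(frozen=True)
class Region:
    """Half-open pixel rectangle [x, x+width) x [y, y+height), 0-based, origin top-left."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigurationError(
                f"region must have positive extent, got {self.width}x{self.height}"
            )

    @property
    def x_end(self) -> int:
        return self.x + self.width

    @property
    def y_end(self) -> int:
        return self.y + self.height

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains_point(self, px: float, py: float) -> bool:
        return self.x <= px < self.x_end and self.y <= py < self.y_end

    def intersects(self, other: "Region") -> bool:
        return (
            self.x < other.x_end
            and other.x < self.x_end
            and self.y < other.y_end
            and other.y < self.y_end
        )


def clip_region(region: Region, width: int, height: int) -> Region:
    """Clip a region to a width x height plane; error if disjoint."""
    x0, y0 = max(region.x, 0), max(region.y, 0)
    x1, y1 = min(region.x_end, width), min(region.y_end, height)
    if x0 >= x1 or y0 >= y1:
        raise BoundsError(f"region {region} does not intersect {width}x{height} plane")
    return Region(x0, y0, x1 - x0, y1 - y0)


def tiles_for_region(region: Region, plane: ImagePlane) -> set[tuple[int, int]]:
    """Exactly the (row, col) indices of tiles whose extent intersects *region*."""
    inter = clip_region(region, plane.width, plane.height)  # raises if disjoint
    tw, th = plane.tile_grid.tile_width, plane.tile_grid.tile_height
    col0, col1 = inter.x // tw, (inter.x_end - 1) // tw
    row0, row1 = inter.y // th, (inter.y_end - 1) // th
    return {(r, c) for r in range(row0, row1 + 1) for c in range(col0, col1 + 1)}


def extract_region(plane: ImagePlane, region: Region) -> np.ndarray:
    """Return exactly the region's pixels, decoding only intersecting tiles.

    The region must lie fully inside the plane (use :func:`clip_region` first
    if it may not); silent clipping would corrupt downstream coordinates.
    Peak memory is the region buffer plus one tile.
    """
    if not (
        0 <= region.x
        and 0 <= region.y
        and region.x_end <= plane.width
        and region.y_end <= plane.height
    ):
        raise BoundsError(
            f"region {region} outside plane bounds {plane.width}x{plane.height}"
        )
    if not plane.is_tiled:
        warnings.warn(
            f"plane {plane.index} is stripped; falling back to row-band reads",
            stacklevel=2,
        )
        band = read_rows(plane, region.y, region.y_end)
        return band[:, region.x : region.x_end].copy()

    out = np.empty(
        (region.height, region.width, plane.samples_per_pixel), dtype=np.uint8
    )
    tw, th = plane.tile_grid.tile_width, plane.tile_grid.tile_height
    for row, col in sorted(tiles_for_region(region, plane)):
        tile = read_tile(plane, row, col)
        tx0, ty0 = col * tw, row * th
        # overlap of tile's valid extent with the region, in global coords
        gx0 = max(region.x, tx0)
        gy0 = max(region.y, ty0)
        gx1 = min(region.x_end, tx0 + tile.valid_width)
        gy1 = min(region.y_end, ty0 + tile.valid_height)
        out[gy0 - region.y : gy1 - region.y, gx0 - region.x : gx1 - region.x] = (
            tile.pixels[gy0 - ty0 : gy1 - ty0, gx0 - tx0 : gx1 - tx0]
        )
    return out


def save_region(
    plane: ImagePlane,
    region: Region,
    sink: str | os.PathLike,
    format: str = "tiff",
    *,
    jpeg_quality: int = 75,
) -> str:
    """Extract a region and save it as a TIFF, JPEG or PNG file."""
    pixels = extract_region(plane, region)
    sink = os.fspath(sink)
    if format == "tiff":
        import tifffile

        tifffile.imwrite(sink, pixels, photometric="rgb" if pixels.shape[2] == 3 else None)
    elif format in ("jpeg", "png"):
        from PIL import Image

        img = Image.fromarray(pixels if pixels.shape[2] > 1 else pixels[:, :, 0])
        if format == "jpeg":
            img.save(sink, "JPEG", quality=jpeg_quality)
        else:
            img.save(sink, "PNG")
    else:
        raise ConfigurationError(f"unsupported output format {format!r}")
    return sink
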