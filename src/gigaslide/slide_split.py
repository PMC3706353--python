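"""Split multi-plane slide containers into standard per-plane files.

Covers the batch-conversion workflow: select planes by magnification, focus
level or explicit index; write each selected plane to its own single-image
TIFF (or to a mosaic when it exceeds the RAM budget); pick the preview plane
that fits a screen; and carve multi-sample slides apart along blank filler
bands.  Output names encode magnification, focus and mosaic coordinates so
every file is self-describing.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from . import mosaic as mosaic_mod
from .container_io import (
    ImagePlane,
    SlideContainer,
    TileGrid,
    write_plane_streamed,
)
from .errors import ConfigurationError, SelectionError
from .mosaic import NO_OVERLAP, MosaicPlan, OverlapSpec, RamBudget
from .region import Region, extract_region

__all__ = [
    "PlaneFilter",
    "PreviewSelection",
    "split_container",
    "preview_plane",
    "blank_band_split",
    "build_name",
    "parse_name",
]


# ---------------------------------------------------------------------------
# naming convention: stem_x{mag}_z{focus}[_i{row}j{col}]
# row/col are 1-based in names (reading order); all internal indices 0-based.
# ---------------------------------------------------------------------------

def _mag_token(magnification) -> str:
    if magnification is None:
        return "unk"
    if magnification == "macro":
        return "macro"
    if isinstance(magnification, Fraction):
        return f"{magnification.numerator}over{magnification.denominator}"
    if isinstance(magnification, float) and not magnification.is_integer():
        return repr(magnification).replace(".", "p")
    return str(int(magnification))


def _mag_from_token(token: str):
    if token == "unk":
        return None
    if token == "macro":
        return "macro"
    if "over" in token:
        num, _, den = token.partition("over")
        return Fraction(int(num), int(den))
    if "p" in token:
        return float(token.replace("p", "."))
    return int(token)


def build_name(
    stem: str,
    magnification=None,
    focus: int | None = None,
    row: int | None = None,
    col: int | None = None,
) -> str:
    """Canonical output name (without extension) for a plane or mosaic piece."""
    name = f"{stem}_x{_mag_token(magnification)}_z{0 if focus is None else int(focus)}"
    if row is not None and col is not None:
        name += f"_i{row + 1}j{col + 1}"
    return name


_NAME_RE = re.compile(
    r"^(?P<stem>.+)_x(?P<mag>[^_]+)_z(?P<focus>-?\d+)(?:_i(?P<row>\d+)j(?P<col>\d+))?$"
)


def parse_name(name: str):
    """Inverse of :func:`build_name`: (stem, magnification, focus, row, col)."""
    name = re.sub(r"\.(tif|tiff|jpg|jpeg|png)$", "", name)
    m = _NAME_RE.match(name)
    if m is None:
        raise ConfigurationError(f"name {name!r} does not follow the naming scheme")
    row = int(m.group("row")) - 1 if m.group("row") else None
    col = int(m.group("col")) - 1 if m.group("col") else None
    return (m.group("stem"), _mag_from_token(m.group("mag")), int(m.group("focus")), row, col)


# ---------------------------------------------------------------------------
# plane selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneFilter:
    """Select planes by magnification/focus sets or by explicit indices.

    Explicit ``plane_indices`` override the other two filters, mirroring the
    ``file,0,1,2,3,4`` selection syntax of the command line.
    """

    magnifications: object = "all"  # "all" or a set of magnification values
    focus_offsets: object = "all"  # "all" or a set of focus offsets
    plane_indices: tuple[int, ...] | None = None

    def select(self, container: SlideContainer) -> list[int]:
        if self.plane_indices is not None:
            bad = [i for i in self.plane_indices if not 0 <= i < len(container.planes)]
            if bad:
                raise SelectionError(
                    f"plane indices {bad} out of range; container has "
                    f"{len(container.planes)} planes"
                )
            selected = list(self.plane_indices)
        else:
            selected = []
            for plane in container.planes:
                if self.magnifications != "all" and plane.magnification not in self.magnifications:
                    continue
                if self.focus_offsets != "all" and plane.focus_offset not in self.focus_offsets:
                    continue
                selected.append(plane.index)
        if not selected:
            available = [
                (p.index, p.magnification, p.focus_offset) for p in container.planes
            ]
            raise SelectionError(
                f"filter selected no planes; available (index, mag, focus): {available}"
            )
        return selected


FILTER_ALL = PlaneFilter()


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _write_single_plane(
    container: SlideContainer,
    plane: ImagePlane,
    path: str,
    piece_format: str,
    jpeg_quality: int,
) -> None:
    """Copy one plane into a standalone file, streamed tile-band by tile-band."""
    if piece_format == "jpeg":
        from PIL import Image

        pixels = extract_region(plane, Region(0, 0, plane.width, plane.height))
        img = pixels if pixels.shape[2] > 1 else pixels[:, :, 0]
        Image.fromarray(img).save(path, "JPEG", quality=jpeg_quality)
        return
    grid = plane.tile_grid or TileGrid(256, 256)
    spec = ImagePlane(
        index=0,
        width=plane.width,
        height=plane.height,
        samples_per_pixel=plane.samples_per_pixel,
        tile_grid=grid,
        compression="deflate",
        magnification=plane.magnification,
        focus_offset=plane.focus_offset,
        description=plane.description,
    )

    def tile_at(row: int, col: int) -> np.ndarray:
        if plane.is_tiled:
            from .container_io import read_tile

            return read_tile(plane, row, col).valid
        x0 = col * grid.tile_width
        y0 = row * grid.tile_height
        w = min(grid.tile_width, plane.width - x0)
        h = min(grid.tile_height, plane.height - y0)
        return extract_region(plane, Region(x0, y0, w, h))

    write_plane_streamed(path, spec, tile_at).close()


def split_container(
    container: SlideContainer,
    filter: PlaneFilter = FILTER_ALL,
    budget: RamBudget = RamBudget(),
    overlap: OverlapSpec = NO_OVERLAP,
    mosaic_mode: str = "never",
    piece_format: str = "tiff",
    out_dir: str | os.PathLike = ".",
    stem: str | None = None,
    *,
    jpeg_quality: int = 75,
    manifest_path: str | os.PathLike | None = None,
) -> list[str]:
    """Write each selected plane as a standalone file or as a mosaic.

    ``mosaic_mode``: ``never`` (always one file per plane), ``if_needed``
    (mosaic only for planes whose uncompressed size exceeds the budget) or
    ``always``.  Returns the list of emitted files; a JSON manifest with
    per-file provenance is written when ``manifest_path`` is given.
    """
    if mosaic_mode not in ("never", "if_needed", "always"):
        raise ConfigurationError(f"mosaic_mode must be never|if_needed|always, got {mosaic_mode!r}")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if stem is None:
        stem = os.path.splitext(os.path.basename(container.source))[0]
    indices = filter.select(container)
    outputs: list[str] = []
    records: list[dict] = []
    ext = ".tif" if piece_format == "tiff" else ".jpg"
    for index in indices:
        plane = container.planes[index]
        needs_mosaic = mosaic_mode == "always" or (
            mosaic_mode == "if_needed" and plane.uncompressed_bytes > budget.max_bytes
        )
        if needs_mosaic:
            plan = mosaic_mod.plan_mosaic(
                plane.width, plane.height, plane.bytes_per_pixel, budget, overlap
            )
            files = mosaic_mod.make_mosaic(
                container,
                index,
                plan,
                piece_format,
                name_stem=stem,
                out_dir=out_dir,
                jpeg_quality=jpeg_quality,
            )
            plan_path = os.path.join(
                out_dir, build_name(stem, plane.magnification, plane.focus_offset) + ".plan.json"
            )
            mosaic_mod.save_plan(plan, plan_path)
            outputs.extend(files)
            for piece, path in zip(plan.pieces, files):
                records.append(
                    {
                        "path": path,
                        "plane": index,
                        "piece": [piece.row, piece.col],
                        "bytes": os.path.getsize(path),
                    }
                )
        else:
            path = os.path.join(
                out_dir, build_name(stem, plane.magnification, plane.focus_offset) + ext
            )
            _write_single_plane(container, plane, path, piece_format, jpeg_quality)
            outputs.append(path)
            records.append(
                {"path": path, "plane": index, "piece": None, "bytes": os.path.getsize(path)}
            )
    if manifest_path is not None:
        with open(os.fspath(manifest_path), "w") as f:
            json.dump({"source": container.source, "outputs": records}, f, indent=1)
    return outputs


# ---------------------------------------------------------------------------
# preview selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreviewSelection:
    """The plane chosen for on-screen preview plus its focus stack."""

    index: int
    stack: tuple[int, ...]  # all planes at the chosen magnification, by focus


def preview_plane(
    container: SlideContainer, max_width: int, max_height: int
) -> PreviewSelection:
    """Pick the largest plane that still fits a max_width x max_height screen.

    Falls back to the smallest plane when nothing fits.  When the container
    carries several focus levels, the full focus stack at the chosen
    magnification is reported (ascending focus offset) so a viewer can show
    it as an image stack.
    """
    if not container.planes:
        raise SelectionError("container has no planes")
    fitting = [
        p for p in container.planes if p.width <= max_width and p.height <= max_height
    ]
    if fitting:
        chosen = max(fitting, key=lambda p: p.width * p.height)
    else:
        chosen = min(container.planes, key=lambda p: p.width * p.height)
    stack = [
        p.index
        for p in container.planes
        if p.magnification == chosen.magnification
        and (p.width, p.height) == (chosen.width, chosen.height)
    ]
    stack.sort(
        key=lambda i: (
            container.planes[i].focus_offset
            if container.planes[i].focus_offset is not None
            else 0
        )
    )
    return PreviewSelection(index=chosen.index, stack=tuple(stack))


# ---------------------------------------------------------------------------
# blank-band splitting
# ---------------------------------------------------------------------------

def _luminosity(pixels: np.ndarray) -> np.ndarray:
    if pixels.shape[2] == 1:
        return pixels[:, :, 0].astype(np.int16)
    return np.rint(
        0.299 * pixels[:, :, 0] + 0.587 * pixels[:, :, 1] + 0.114 * pixels[:, :, 2]
    ).astype(np.int16)


def _estimate_background(plane: ImagePlane) -> int:
    """Modal luminosity of the plane's corner patches (scanner-white fill)."""
    s = 64
    xs = (0, max(0, plane.width - s))
    ys = (0, max(0, plane.height - s))
    values = []
    for y in ys:
        for x in xs:
            patch = extract_region(
                plane,
                Region(x, y, min(s, plane.width - x), min(s, plane.height - y)),
            )
            values.append(_luminosity(patch).ravel())
    counts = np.bincount(np.concatenate(values).clip(0, 255).astype(np.int64), minlength=256)
    return int(counts.argmax())


def _blank_lines(
    plane: ImagePlane, box: Region, axis: int, background: int, tolerance: int
) -> np.ndarray:
    """Boolean mask over rows (axis=0) or columns (axis=1) of `box` that are
    entirely within `tolerance` of the background level.  Scanned in
    tile-height bands so memory stays bounded."""
    n = box.height if axis == 0 else box.width
    blank = np.ones(n, dtype=bool)
    band_h = plane.tile_grid.tile_height if plane.is_tiled else 256
    for y0 in range(box.y, box.y_end, band_h):
        h = min(band_h, box.y_end - y0)
        band = _luminosity(extract_region(plane, Region(box.x, y0, box.width, h)))
        is_blank = np.abs(band - background) <= tolerance
        if axis == 0:
            blank[y0 - box.y : y0 - box.y + h] &= is_blank.all(axis=1)
        else:
            blank &= is_blank.all(axis=0)
    return blank


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as half-open (start, end)."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_len:
        runs.append((start, len(mask)))
    return runs


def _split_once(
    plane: ImagePlane,
    box: Region,
    axis: int,
    background: int,
    tolerance: int,
    min_band: int,
    depth: int,
) -> list[Region]:
    if depth <= 0:
        return [box]
    blank = _blank_lines(plane, box, axis, background, tolerance)
    # treat leading/trailing blank margins as separators of any width
    separators = _runs(blank, min_band)
    keep = np.ones(len(blank), dtype=bool)
    for s, e in separators:
        keep[s:e] = False
    # also trim fully blank margins shorter than min_band? No: only runs count.
    segments = _runs(keep, 1)
    if not segments:
        return []
    if len(segments) == 1 and segments[0] == (0, len(blank)):
        # no separator along this axis; try the other axis once
        if depth == 1:
            return [box]
        other = _split_once(plane, box, 1 - axis, background, tolerance, min_band, depth - 1)
        return other
    out: list[Region] = []
    for s, e in segments:
        if axis == 0:
            sub = Region(box.x, box.y + s, box.width, e - s)
        else:
            sub = Region(box.x + s, box.y, e - s, box.height)
        out.extend(
            _split_once(plane, sub, 1 - axis, background, tolerance, min_band, depth - 1)
        )
    return out


def blank_band_split(
    plane: ImagePlane,
    background_level: int | None = None,
    tolerance: int = 8,
    min_band: int | None = None,
    *,
    max_depth: int = 4,
) -> list[Region]:
    """Find the non-blank sub-images of a plane holding several tissue blocks.

    Rows (then columns, recursively, alternating axes up to ``max_depth``
    passes) whose every pixel lies within ``tolerance`` of the background
    level, in runs at least ``min_band`` long, act as separators.  Returns
    the maximal non-blank regions in reading order; a fully blank plane
    yields an empty list.  The scan is streamed in tile-row bands.
    """
    if background_level is None:
        background_level = _estimate_background(plane)
    if min_band is None:
        min_band = plane.tile_grid.tile_height if plane.is_tiled else 256
    full = Region(0, 0, plane.width, plane.height)
    regions = _split_once(
        plane, full, 0, background_level, tolerance, min_band, max_depth
    )
    regions.sort(key=lambda r: (r.y, r.x))
    return regions
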