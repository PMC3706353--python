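"""RAM-budgeted mosaic planning, production and reassembly.

A mosaic divides one huge plane into pieces, each guaranteed to fit a
per-piece uncompressed-RAM budget (default 1024 MiB) once decoded, with an
optional overlap margin so objects straddling a cut appear whole in at least
one piece.  Piece cores partition the plane exactly; reassembling the cores
reproduces the original image pixel for pixel.

The canonical planner restricts grid counts to powers of two per dimension
and picks the smallest such grid whose (overlap-padded) pieces fit the
budget; a free-grid planner is available for explicit piece sizes and via
``free_grid=True``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .container_io import SlideContainer
from .errors import BudgetError, ConfigurationError, GigaslideError
from .region import Region, extract_region

__all__ = [
    "MIB",
    "RamBudget",
    "OverlapSpec",
    "PieceBox",
    "MosaicPlan",
    "uncompressed_bytes",
    "plan_grid",
    "plan_mosaic",
    "make_mosaic",
    "reassemble",
    "save_plan",
    "load_plan",
]

MIB = 2**20
DEFAULT_BUDGET_BYTES = 1024 * MIB


def uncompressed_bytes(width: int, height: int, bytes_per_pixel: int) -> int:
    """Exact RAM needed to hold a decoded width x height image (integer math).

    E.g. a 103168 x 63232 RGB slide plane needs 3*103168*63232 =
    19,570,556,928 bytes (~18.2 GiB) — far beyond what standard software can
    load whole.
    """
    if width < 1 or height < 1 or bytes_per_pixel < 1:
        raise ConfigurationError("width, height and bytes_per_pixel must be >= 1")
    return int(width) * int(height) * int(bytes_per_pixel)


@dataclass(frozen=True)
class RamBudget:
    """Maximum uncompressed bytes a single mosaic piece may need to open."""

    max_bytes: int = DEFAULT_BUDGET_BYTES

    def __post_init__(self) -> None:
        if self.max_bytes < 1:
            raise ConfigurationError("budget must be positive")

    @classmethod
    def mib(cls, mib: float) -> "RamBudget":
        return cls(int(mib * MIB))


@dataclass(frozen=True)
class OverlapSpec:
    """Overlap between adjacent pieces, in pixels or percent of plane size."""

    mode: str = "pixels"  # "pixels" | "percent"
    amount_x: float = 0
    amount_y: float = 0

    def __post_init__(self) -> None:
        if self.mode not in ("pixels", "percent"):
            raise ConfigurationError(f"overlap mode must be pixels|percent, got {self.mode!r}")
        if self.amount_x < 0 or self.amount_y < 0:
            raise ConfigurationError("overlap amounts must be >= 0")

    @classmethod
    def pixels(cls, amount: float, amount_y: float | None = None) -> "OverlapSpec":
        return cls("pixels", amount, amount if amount_y is None else amount_y)

    @classmethod
    def percent(cls, amount: float, amount_y: float | None = None) -> "OverlapSpec":
        return cls("percent", amount, amount if amount_y is None else amount_y)

    def resolve(self, plane_width: int, plane_height: int) -> tuple[int, int]:
        """Overlap in whole pixels per axis (percent resolves against the full plane)."""
        if self.mode == "pixels":
            return int(self.amount_x), int(self.amount_y)
        return (
            int(round(plane_width * self.amount_x / 100.0)),
            int(round(plane_height * self.amount_y / 100.0)),
        )


NO_OVERLAP = OverlapSpec()


@dataclass(frozen=True)
class PieceBox:
    """One mosaic piece: its core (partition cell) and overlap-padded box."""

    row: int
    col: int
    core: Region
    padded: Region


@dataclass
class MosaicPlan:
    """Full geometry of a mosaic: grid counts and per-piece boxes."""

    width: int
    height: int
    bytes_per_pixel: int
    grid_cols: int
    grid_rows: int
    pieces: list[PieceBox]
    budget: RamBudget | None
    overlap: OverlapSpec = NO_OVERLAP

    @property
    def n_pieces(self) -> int:
        return self.grid_cols * self.grid_rows

    @property
    def max_piece_bytes(self) -> int:
        return max(
            uncompressed_bytes(p.padded.width, p.padded.height, self.bytes_per_pixel)
            for p in self.pieces
        )

    def piece(self, row: int, col: int) -> PieceBox:
        return self.pieces[row * self.grid_cols + col]


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

def _near_equal_splits(extent: int, parts: int) -> list[tuple[int, int]]:
    """Partition [0, extent) into `parts` half-open runs differing by <= 1 px.

    The first (extent mod parts) runs get the extra pixel, so the partition
    is exact with no drift.
    """
    base, extra = divmod(extent, parts)
    runs, start = [], 0
    for i in range(parts):
        size = base + (1 if i < extra else 0)
        runs.append((start, size))
        start += size
    return runs


def _pow2_candidates(extent: int) -> list[int]:
    out, g = [], 1
    while g < 2 * extent:
        out.append(g)
        if g >= extent:
            break
        g *= 2
    return out


def _build_pieces(
    width: int, height: int, grid_cols: int, grid_rows: int, ov_x: int, ov_y: int
) -> list[PieceBox]:
    col_runs = _near_equal_splits(width, grid_cols)
    row_runs = _near_equal_splits(height, grid_rows)
    pieces = []
    for r, (y0, h) in enumerate(row_runs):
        for c, (x0, w) in enumerate(col_runs):
            core = Region(x0, y0, w, h)
            px0 = max(0, x0 - ov_x)
            py0 = max(0, y0 - ov_y)
            px1 = min(width, x0 + w + ov_x)
            py1 = min(height, y0 + h + ov_y)
            pieces.append(PieceBox(r, c, core, Region(px0, py0, px1 - px0, py1 - py0)))
    return pieces


def _grid_fits(
    width: int, height: int, bpp: int, gc: int, gr: int, ov_x: int, ov_y: int, budget: int
) -> bool:
    # worst-case padded piece: largest core extent plus overlap on both sides
    core_w = -(-width // gc)
    core_h = -(-height // gr)
    pad_w = min(width, core_w + (2 * ov_x if gc > 1 else 0))
    pad_h = min(height, core_h + (2 * ov_y if gr > 1 else 0))
    return pad_w * pad_h * bpp <= budget


def plan_grid(
    width: int,
    height: int,
    bytes_per_pixel: int,
    budget: RamBudget | int,
    overlap: OverlapSpec = NO_OVERLAP,
    *,
    free_grid: bool = False,
) -> tuple[int, int]:
    """Choose the mosaic grid (columns, rows) under a per-piece RAM budget.

    Grid counts are powers of two per dimension; among feasible grids the
    piece count is minimal, ties broken by the most-square piece (smallest
    |log aspect ratio|), then by fewer columns.  ``free_grid=True`` searches
    all integer grids instead.
    """
    max_bytes = budget.max_bytes if isinstance(budget, RamBudget) else int(budget)
    if max_bytes < bytes_per_pixel:
        raise BudgetError(
            f"budget {max_bytes} B below the minimum feasible {bytes_per_pixel} B "
            "(one pixel)"
        )
    ov_x, ov_y = overlap.resolve(width, height)
    cols_cands = _pow2_candidates(width) if not free_grid else range(1, width + 1)
    rows_cands = _pow2_candidates(height) if not free_grid else range(1, height + 1)

    best = None
    for gc in cols_cands:
        for gr in rows_cands:
            if not _grid_fits(width, height, bytes_per_pixel, gc, gr, ov_x, ov_y, max_bytes):
                continue
            aspect = math.log((width / gc) / (height / gr))
            key = (gc * gr, abs(aspect), gc)
            if best is None or key < best[0]:
                best = (key, (gc, gr))
            break  # larger gr only increases the product for this gc
    if best is None:
        min_feasible = (
            -(-width // max(cols_cands)) * -(-height // max(rows_cands)) * bytes_per_pixel
        )
        raise BudgetError(
            f"no grid satisfies budget {max_bytes} B; minimum feasible budget is "
            f"{min_feasible} B"
        )
    return best[1]


def plan_mosaic(
    width: int,
    height: int,
    bytes_per_pixel: int,
    sizing: RamBudget | int | tuple[int, int],
    overlap: OverlapSpec = NO_OVERLAP,
    *,
    free_grid: bool = False,
) -> MosaicPlan:
    """Build the full mosaic geometry under a RAM budget or explicit piece size.

    ``sizing`` is a :class:`RamBudget` (or raw byte count) — the planner picks
    the grid — or an explicit ``(piece_width, piece_height)`` pair, in which
    case grid counts come from ceiling division.  The overlap counts toward
    the budget: it is the padded box, the thing a consumer actually opens,
    that must fit in RAM.
    """
    ov_x, ov_y = overlap.resolve(width, height)
    budget: RamBudget | None
    if isinstance(sizing, tuple):
        pw, ph = sizing
        if pw < 1 or ph < 1:
            raise ConfigurationError("explicit piece size must be >= 1 px per axis")
        grid_cols = -(-width // pw)
        grid_rows = -(-height // ph)
        budget = None
    else:
        budget = sizing if isinstance(sizing, RamBudget) else RamBudget(int(sizing))
        grid_cols, grid_rows = plan_grid(
            width, height, bytes_per_pixel, budget, overlap, free_grid=free_grid
        )
    core_w = width // grid_cols
    core_h = height // grid_rows
    if (grid_cols > 1 and ov_x >= core_w) or (grid_rows > 1 and ov_y >= core_h):
        raise ConfigurationError(
            f"overlap ({ov_x}, {ov_y}) px must be smaller than the core piece "
            f"extent ({core_w}, {core_h}) px"
        )
    pieces = _build_pieces(width, height, grid_cols, grid_rows, ov_x, ov_y)
    return MosaicPlan(
        width=width,
        height=height,
        bytes_per_pixel=bytes_per_pixel,
        grid_cols=grid_cols,
        grid_rows=grid_rows,
        pieces=pieces,
        budget=budget,
        overlap=overlap,
    )


# ---------------------------------------------------------------------------
# production and reassembly
# ---------------------------------------------------------------------------

def _piece_filename(stem: str, plane, piece: PieceBox, fmt: str) -> str:
    from .slide_split import build_name  # local import: slide_split imports mosaic

    ext = ".tif" if fmt == "tiff" else ".jpg"
    return (
        build_name(
            stem,
            magnification=plane.magnification,
            focus=plane.focus_offset,
            row=piece.row,
            col=piece.col,
        )
        + ext
    )


def make_mosaic(
    container: SlideContainer,
    plane_index: int,
    plan: MosaicPlan,
    piece_format: str = "tiff",
    name_stem: str = "mosaic",
    out_dir: str | os.PathLike = ".",
    *,
    jpeg_quality: int = 75,
) -> list[str]:
    """Write one file per mosaic piece, reading only the tiles each piece needs.

    Peak memory is one padded piece plus one tile.  On a write failure the
    partial outputs are removed and the failing piece's grid coordinates are
    reported.
    """
    if piece_format not in ("tiff", "jpeg"):
        raise ConfigurationError(f"piece format must be tiff|jpeg, got {piece_format!r}")
    plane = container.planes[plane_index]
    if (plane.width, plane.height) != (plan.width, plan.height):
        raise ConfigurationError(
            f"plan is for {plan.width}x{plan.height} but plane {plane_index} is "
            f"{plane.width}x{plane.height}"
        )
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    try:
        for piece in plan.pieces:
            pixels = extract_region(plane, piece.padded)
            path = os.path.join(out_dir, _piece_filename(name_stem, plane, piece, piece_format))
            if piece_format == "tiff":
                import tifffile

                tifffile.imwrite(
                    path,
                    pixels,
                    photometric="rgb" if pixels.shape[2] == 3 else None,
                    compression="zlib",
                )
            else:
                from PIL import Image

                img = pixels if pixels.shape[2] > 1 else pixels[:, :, 0]
                Image.fromarray(img).save(path, "JPEG", quality=jpeg_quality)
            written.append(path)
    except OSError as exc:
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        failing = plan.pieces[len(written)]
        raise GigaslideError(
            f"mosaic write failed at piece ({failing.row}, {failing.col}): {exc}"
        ) from exc
    return written


def _load_piece(path: str) -> np.ndarray:
    if path.endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def reassemble(plan: MosaicPlan, pieces: Sequence[str]) -> np.ndarray:
    """Rebuild the full plane from piece files (cores only; overlap discarded).

    For losslessly encoded pieces the result is pixel-identical to the
    original plane.  ``pieces`` must align with ``plan.pieces``.
    """
    if len(pieces) != len(plan.pieces):
        have = {i for i, p in enumerate(pieces) if p}
        for i, box in enumerate(plan.pieces):
            if i not in have and i >= len(pieces):
                raise GigaslideError(f"missing mosaic piece ({box.row}, {box.col})")
        raise GigaslideError("piece list does not match the plan")
    out = None
    for box, path in zip(plan.pieces, pieces):
        if path is None or not os.path.exists(path):
            raise GigaslideError(f"missing mosaic piece ({box.row}, {box.col})")
        arr = _load_piece(os.fspath(path))
        if out is None:
            out = np.empty((plan.height, plan.width, arr.shape[2]), dtype=arr.dtype)
        # the core's offset inside the padded (stored) box
        ox = box.core.x - box.padded.x
        oy = box.core.y - box.padded.y
        out[box.core.y : box.core.y_end, box.core.x : box.core.x_end] = arr[
            oy : oy + box.core.height, ox : ox + box.core.width
        ]
    return out


# ---------------------------------------------------------------------------
# plan (de)serialization — the manifest consumed by the analysis stage
# ---------------------------------------------------------------------------

def plan_to_dict(plan: MosaicPlan) -> dict:
    return {
        "width": plan.width,
        "height": plan.height,
        "bytes_per_pixel": plan.bytes_per_pixel,
        "grid_cols": plan.grid_cols,
        "grid_rows": plan.grid_rows,
        "budget_bytes": plan.budget.max_bytes if plan.budget else None,
        "overlap": {
            "mode": plan.overlap.mode,
            "amount_x": plan.overlap.amount_x,
            "amount_y": plan.overlap.amount_y,
        },
        "pieces": [
            {
                "row": p.row,
                "col": p.col,
                "core": [p.core.x, p.core.y, p.core.width, p.core.height],
                "padded": [p.padded.x, p.padded.y, p.padded.width, p.padded.height],
            }
            for p in plan.pieces
        ],
    }


def plan_from_dict(data: dict) -> MosaicPlan:
    pieces = [
        PieceBox(
            row=p["row"],
            col=p["col"],
            core=Region(*p["core"]),
            padded=Region(*p["padded"]),
        )
        for p in data["pieces"]
    ]
    return MosaicPlan(
        width=data["width"],
        height=data["height"],
        bytes_per_pixel=data["bytes_per_pixel"],
        grid_cols=data["grid_cols"],
        grid_rows=data["grid_rows"],
        pieces=pieces,
        budget=RamBudget(data["budget_bytes"]) if data.get("budget_bytes") else None,
        overlap=OverlapSpec(
            data["overlap"]["mode"],
            data["overlap"]["amount_x"],
            data["overlap"]["amount_y"],
        ),
    )


def save_plan(plan: MosaicPlan, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    with open(path, "w") as f:
        json.dump(plan_to_dict(plan), f, indent=1)
    return path


def load_plan(path: str | os.PathLike) -> MosaicPlan:
    with open(os.fspath(path)) as f:
        return plan_from_dict(json.load(f))
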