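"""Tile-granular reading and streamed writing of TIFF/BigTIFF slide containers.

A whole-slide container is a (possibly multi-image) TIFF file in which every
image ("plane") corresponds to one (magnification, focus) pair.  Opening a
container parses headers and metadata only; pixel data is touched exclusively
through :func:`read_tile` / :func:`read_rows`, one compressed segment at a
time, so peak memory never depends on the plane's pixel count.

Magnification and focus level are carried in each plane's ImageDescription
field using a small ``key=value`` grammar (see :func:`encode_plane_metadata`).
"""

from __future__ import annotations

import io
import os
import struct
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Iterator, Union

import numpy as np
import tifffile

from .errors import (
    METADATA_ABSENT,
    BoundsError,
    FormatError,
    NotTiledError,
    UnsupportedCodecError,
)

__all__ = [
    "TileGrid",
    "ImagePlane",
    "SlideContainer",
    "Tile",
    "open_container",
    "read_tile",
    "read_rows",
    "write_plane_streamed",
    "encode_plane_metadata",
    "decode_plane_metadata",
    "copy_tile_compressed",
    "CLASSIC_TIFF_LIMIT",
]

#: Largest file size a classic (32-bit offset) TIFF can address.
CLASSIC_TIFF_LIMIT = 2**32 - 1

# TIFF compression tag value -> token used throughout the toolkit
_COMPRESSION_TOKENS = {
    1: "none",
    5: "lzw",
    7: "jpeg",
    8: "deflate",
    32946: "deflate",  # legacy Deflate code
}
# token -> argument understood by tifffile.TiffWriter
_WRITER_COMPRESSION = {
    "none": None,
    "jpeg": "jpeg",
    "lzw": "lzw",
    "deflate": "zlib",
}

Magnification = Union[int, float, Fraction, str]


@dataclass(frozen=True)
class TileGrid:
    """Tile geometry of a tiled plane, in pixels."""

    tile_width: int
    tile_height: int

    def __post_init__(self) -> None:
        if self.tile_width <= 0 or self.tile_height <= 0:
            raise ValueError("tile dimensions must be strictly positive")


@dataclass
class Tile:
    """One decoded tile: full-size pixel block plus the valid (unpadded) extent."""

    pixels: np.ndarray  # (tile_height, tile_width, samples)
    valid_width: int
    valid_height: int

    @property
    def valid(self) -> np.ndarray:
        """The pixels actually belonging to the plane (edge padding stripped)."""
        return self.pixels[: self.valid_height, : self.valid_width]


@dataclass
class ImagePlane:
    """One image of a slide container (a single magnification x focus plane)."""

    index: int
    width: int
    height: int
    samples_per_pixel: int = 3
    bits_per_sample: int = 8
    tile_grid: TileGrid | None = None  # None => stripped
    compression: str = "none"
    description: str = ""
    magnification: Magnification | None = None
    focus_offset: int | None = None
    decode_count: int = field(default=0, repr=False)  # segments decoded so far
    _page: "tifffile.TiffPage | None" = field(default=None, repr=False)
    _filehandle: object = field(default=None, repr=False)

    @property
    def is_tiled(self) -> bool:
        return self.tile_grid is not None

    @property
    def tiles_per_row(self) -> int:
        if self.tile_grid is None:
            raise NotTiledError(f"plane {self.index} is stripped, not tiled")
        return -(-self.width // self.tile_grid.tile_width)

    @property
    def tiles_per_col(self) -> int:
        if self.tile_grid is None:
            raise NotTiledError(f"plane {self.index} is stripped, not tiled")
        return -(-self.height // self.tile_grid.tile_height)

    @property
    def bytes_per_pixel(self) -> int:
        return self.samples_per_pixel * self.bits_per_sample // 8

    @property
    def uncompressed_bytes(self) -> int:
        return self.width * self.height * self.bytes_per_pixel


@dataclass
class SlideContainer:
    """An open slide container: ordered planes plus the source file handle.

    Opening reads headers and metadata only — the cumulative pixel bytes
    decoded is observable through each plane's ``decode_count``.
    """

    planes: list[ImagePlane]
    source: str
    big_offsets: bool
    _tiff: "tifffile.TiffFile | None" = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.planes)

    def close(self) -> None:
        if self._tiff is not None:
            self._tiff.close()
            self._tiff = None

    def __enter__(self) -> "SlideContainer":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


# ---------------------------------------------------------------------------
# metadata grammar
# ---------------------------------------------------------------------------

_MAG_KEY = "magnification"
_FOCUS_KEY = "focus"


def encode_plane_metadata(magnification: Magnification, focus_offset: int) -> str:
    """Render (magnification, focus) as a printable ``key=value`` ASCII line.

    ``magnification`` is a positive rational (int, float or Fraction) or the
    token ``"macro"`` for the low-resolution overview image.  The inverse is
    :func:`decode_plane_metadata`; the pair is a bijection on this domain.
    """
    if magnification == "macro":
        mag_text = "macro"
    else:
        if isinstance(magnification, Fraction):
            mag_text = f"{magnification.numerator}/{magnification.denominator}"
        elif isinstance(magnification, float) and not magnification.is_integer():
            mag_text = repr(magnification)
        else:
            mag_text = str(int(magnification))
        if not (float(Fraction(mag_text)) > 0):
            raise ValueError(f"magnification must be positive, got {magnification!r}")
    return f"{_MAG_KEY}={mag_text};{_FOCUS_KEY}={int(focus_offset)}"


def decode_plane_metadata(text: str):
    """Parse a description written by :func:`encode_plane_metadata`.

    Returns ``(magnification, focus_offset)``, or the METADATA_ABSENT
    sentinel when the expected keys are missing — an unlabeled plane is not
    an error.
    """
    fields = {}
    for part in (text or "").split(";"):
        if "=" in part:
            key, _, value = part.partition("=")
            fields[key.strip()] = value.strip()
    if _MAG_KEY not in fields or _FOCUS_KEY not in fields:
        return METADATA_ABSENT
    raw = fields[_MAG_KEY]
    magnification: Magnification
    if raw == "macro":
        magnification = "macro"
    elif "/" in raw:
        magnification = Fraction(raw)
    elif "." in raw or "e" in raw or "E" in raw:
        magnification = float(raw)
    else:
        magnification = int(raw)
    return magnification, int(fields[_FOCUS_KEY])


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _plane_from_page(index: int, page: "tifffile.TiffPage", fh) -> ImagePlane:
    comp_value = int(page.compression)
    if comp_value not in _COMPRESSION_TOKENS:
        raise UnsupportedCodecError(
            f"plane {index}: unsupported compression scheme {comp_value}"
        )
    grid = None
    if page.is_tiled:
        grid = TileGrid(int(page.tilewidth), int(page.tilelength))
    description = page.description or ""
    meta = decode_plane_metadata(description)
    if meta is METADATA_ABSENT:
        magnification, focus = None, None
    else:
        magnification, focus = meta
    return ImagePlane(
        index=index,
        width=int(page.imagewidth),
        height=int(page.imagelength),
        samples_per_pixel=int(page.samplesperpixel),
        bits_per_sample=int(page.bitspersample)
        if not isinstance(page.bitspersample, tuple)
        else int(page.bitspersample[0]),
        tile_grid=grid,
        compression=_COMPRESSION_TOKENS[comp_value],
        description=description,
        magnification=magnification,
        focus_offset=focus,
        _page=page,
        _filehandle=fh,
    )


def open_container(path: str | os.PathLike) -> SlideContainer:
    """Open a classic-TIFF or BigTIFF container, reading headers only.

    Every plane's dimensions, tile geometry and magnification/focus metadata
    are parsed; no pixel data is decoded (``decode_count`` stays 0 until a
    tile is actually requested).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        tif = tifffile.TiffFile(path)
    except tifffile.TiffFileError as exc:
        raise FormatError(f"{path}: not a TIFF/BigTIFF container ({exc})") from exc
    planes = [
        _plane_from_page(i, page, tif.filehandle) for i, page in enumerate(tif.pages)
    ]
    return SlideContainer(
        planes=planes, source=path, big_offsets=tif.is_bigtiff, _tiff=tif
    )


def _read_segment(plane: ImagePlane, index: int) -> np.ndarray:
    """Decode compressed segment *index* of a plane (tile or strip)."""
    page = plane._page
    if page is None:
        raise FormatError(f"plane {plane.index} is not backed by an open file")
    fh = plane._filehandle
    offset = page.dataoffsets[index]
    count = page.databytecounts[index]
    fh.seek(offset)
    data = fh.read(count)
    try:
        segment, _, _ = page.decode(data, index, jpegtables=page.jpegtables)
    except Exception as exc:
        raise FormatError(
            f"plane {plane.index}: segment {index} failed to decode ({exc})"
        ) from exc
    plane.decode_count += 1
    return segment[0]  # drop leading depth axis


def read_tile(plane: ImagePlane, row: int, col: int) -> Tile:
    """Decode exactly one tile of a tiled plane.

    Edge tiles come back at full tile size (TIFF stores them padded); the
    returned :class:`Tile` records the valid extent so callers can strip the
    padding.
    """
    if plane.tile_grid is None:
        raise NotTiledError(
            f"plane {plane.index} is stripped; use read_rows/extract_region"
        )
    n_rows, n_cols = plane.tiles_per_col, plane.tiles_per_row
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise BoundsError(
            f"tile ({row}, {col}) outside grid {n_rows}x{n_cols} of plane {plane.index}"
        )
    tw, th = plane.tile_grid.tile_width, plane.tile_grid.tile_height
    index = row * n_cols + col
    pixels = _read_segment(plane, index)
    if pixels.ndim == 2:
        pixels = pixels[:, :, None]
    valid_w = min(tw, plane.width - col * tw)
    valid_h = min(th, plane.height - row * th)
    return Tile(pixels=pixels, valid_width=valid_w, valid_height=valid_h)


def read_rows(plane: ImagePlane, y0: int, y1: int) -> np.ndarray:
    """Decode the row band ``[y0, y1)`` of a *stripped* plane.

    Only the strips intersecting the band are decoded; this is the graceful
    degradation path for non-tiled planes.
    """
    if plane.is_tiled:
        raise NotTiledError(f"plane {plane.index} is tiled; use read_tile")
    if not (0 <= y0 < y1 <= plane.height):
        raise BoundsError(f"row band [{y0}, {y1}) outside plane of height {plane.height}")
    page = plane._page
    rps = int(page.rowsperstrip)
    first, last = y0 // rps, (y1 - 1) // rps
    out = np.empty((y1 - y0, plane.width, plane.samples_per_pixel), dtype=np.uint8)
    for s in range(first, last + 1):
        band = _read_segment(plane, s)
        if band.ndim == 2:
            band = band[:, :, None]
        s_y0 = s * rps
        s_y1 = min(s_y0 + band.shape[0], plane.height)
        lo, hi = max(y0, s_y0), min(y1, s_y1)
        out[lo - y0 : hi - y0] = band[lo - s_y0 : hi - s_y0, : plane.width]
    return out


# ---------------------------------------------------------------------------
# streamed writing
# ---------------------------------------------------------------------------

TileSource = Union[Iterable[np.ndarray], Callable[[int, int], np.ndarray]]


def _iter_tiles(spec: ImagePlane, tile_source: TileSource) -> Iterator[np.ndarray]:
    """Normalize a tile source to a row-major iterator of full-size tiles."""
    grid = spec.tile_grid
    tw, th = grid.tile_width, grid.tile_height
    if callable(tile_source):
        n_rows = -(-spec.height // th)
        n_cols = -(-spec.width // tw)
        source: Iterable[np.ndarray] = (
            tile_source(r, c) for r in range(n_rows) for c in range(n_cols)
        )
    else:
        source = tile_source
    for tile in source:
        if tile.ndim == 2:
            tile = tile[:, :, None]
        if tile.shape[0] != th or tile.shape[1] != tw:
            padded = np.zeros((th, tw, tile.shape[2]), dtype=tile.dtype)
            padded[: tile.shape[0], : tile.shape[1]] = tile
            tile = padded
        yield tile


def write_plane_streamed(
    sink: str | os.PathLike,
    spec: ImagePlane,
    tile_source: TileSource,
    force_big_offsets: bool = False,
    *,
    force_classic: bool = False,
    jpeg_quality: int = 75,
) -> SlideContainer:
    """Write a single tiled plane, consuming tiles in row-major order.

    The output dialect is BigTIFF when ``force_big_offsets`` is set or when
    the projected uncompressed size exceeds the classic 4 GiB offset limit;
    ``force_classic`` instead refuses (with a size report) rather than
    silently emitting a file that classic offsets cannot address.  Peak
    memory is bounded by a constant number of tile rows regardless of the
    plane's pixel count.
    """
    if spec.tile_grid is None:
        raise NotTiledError("write_plane_streamed requires a tiled plane spec")
    projected = spec.uncompressed_bytes
    if force_classic:
        if projected > CLASSIC_TIFF_LIMIT:
            raise FormatError(
                f"classic TIFF requested but projected size {projected} B "
                f"({projected / 2**30:.2f} GiB) exceeds the 4 GiB offset limit"
            )
        bigtiff = False
    else:
        bigtiff = force_big_offsets or projected > CLASSIC_TIFF_LIMIT
    compression = _WRITER_COMPRESSION[spec.compression]
    compressionargs = {"level": jpeg_quality} if spec.compression == "jpeg" else None
    description = spec.description
    if not description and spec.magnification is not None:
        description = encode_plane_metadata(spec.magnification, spec.focus_offset or 0)
    with tifffile.TiffWriter(os.fspath(sink), bigtiff=bigtiff) as writer:
        writer.write(
            _iter_tiles(spec, tile_source),
            shape=(spec.height, spec.width, spec.samples_per_pixel)
            if spec.samples_per_pixel > 1
            else (spec.height, spec.width),
            dtype=np.uint8,
            tile=(spec.tile_grid.tile_height, spec.tile_grid.tile_width),
            compression=compression,
            compressionargs=compressionargs,
            photometric="rgb" if spec.samples_per_pixel == 3 else "minisblack",
            description=description,
        )
    return open_container(sink)


def append_plane(
    writer: "tifffile.TiffWriter",
    spec: ImagePlane,
    tile_source: TileSource,
    *,
    jpeg_quality: int = 75,
) -> None:
    """Append one plane to an already-open multi-image writer (streamed)."""
    compression = _WRITER_COMPRESSION[spec.compression]
    compressionargs = {"level": jpeg_quality} if spec.compression == "jpeg" else None
    description = spec.description
    if not description and spec.magnification is not None:
        description = encode_plane_metadata(spec.magnification, spec.focus_offset or 0)
    writer.write(
        _iter_tiles(spec, tile_source),
        shape=(spec.height, spec.width, spec.samples_per_pixel)
        if spec.samples_per_pixel > 1
        else (spec.height, spec.width),
        dtype=np.uint8,
        tile=(spec.tile_grid.tile_height, spec.tile_grid.tile_width),
        compression=compression,
        compressionargs=compressionargs,
        photometric="rgb" if spec.samples_per_pixel == 3 else "minisblack",
        description=description,
    )


# ---------------------------------------------------------------------------
# raw tile transfer (tiffsplittiles-style)
# ---------------------------------------------------------------------------

# Tags copied verbatim from the source IFD into each single-tile file, so the
# compressed payload stays byte-identical (no transcode) yet decodes alone.
_COPY_TAGS = (258, 259, 262, 277, 284, 317, 338, 347, 530, 532)

_TYPE_SHORT, _TYPE_LONG, _TYPE_RATIONAL, _TYPE_UNDEFINED = 3, 4, 5, 7


def _pack_value(dtype: int, values) -> bytes:
    if dtype == _TYPE_SHORT:
        return struct.pack(f"<{len(values)}H", *values)
    if dtype == _TYPE_LONG:
        return struct.pack(f"<{len(values)}I", *values)
    if dtype == _TYPE_RATIONAL:
        flat = []
        for v in values:
            frac = Fraction(v).limit_denominator(2**31)
            flat += [frac.numerator, frac.denominator]
        return struct.pack(f"<{len(flat)}I", *flat)
    if dtype == _TYPE_UNDEFINED:
        return bytes(values)
    raise ValueError(f"unsupported tag type {dtype}")


def copy_tile_compressed(
    plane: ImagePlane, row: int, col: int, sink: str | os.PathLike
) -> str:
    """Transfer one compressed tile into a standalone single-tile TIFF.

    The compressed payload is copied byte-for-byte — no decode/re-encode —
    so even JPEG tiles survive losslessly.  The output declares the tile's
    valid extent as its image size, hence decodes to exactly the tile's
    pixels with edge padding clipped.
    """
    if plane.tile_grid is None:
        raise NotTiledError(
            f"plane {plane.index} is stripped; use extract_region to crop instead"
        )
    n_rows, n_cols = plane.tiles_per_col, plane.tiles_per_row
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise BoundsError(f"tile ({row}, {col}) outside grid {n_rows}x{n_cols}")
    page = plane._page
    index = row * n_cols + col
    fh = plane._filehandle
    fh.seek(page.dataoffsets[index])
    payload = fh.read(page.databytecounts[index])

    tw, th = plane.tile_grid.tile_width, plane.tile_grid.tile_height
    valid_w = min(tw, plane.width - col * tw)
    valid_h = min(th, plane.height - row * th)

    # entries: (tag, type, count, raw_value_bytes)
    entries: list[tuple[int, int, int, bytes]] = [
        (256, _TYPE_LONG, 1, _pack_value(_TYPE_LONG, [valid_w])),
        (257, _TYPE_LONG, 1, _pack_value(_TYPE_LONG, [valid_h])),
        (322, _TYPE_LONG, 1, _pack_value(_TYPE_LONG, [tw])),
        (323, _TYPE_LONG, 1, _pack_value(_TYPE_LONG, [th])),
        (324, _TYPE_LONG, 1, b""),  # offset patched below
        (325, _TYPE_LONG, 1, _pack_value(_TYPE_LONG, [len(payload)])),
    ]
    for code in _COPY_TAGS:
        tag = page.tags.get(code)
        if tag is None:
            continue
        value = tag.value
        if tag.dtype.name in ("SHORT", "LONG"):
            dtype = _TYPE_SHORT if tag.dtype.name == "SHORT" else _TYPE_LONG
            values = list(value) if isinstance(value, (tuple, list)) else [int(value)]
            values = [int(v) for v in values]
            entries.append((code, dtype, len(values), _pack_value(dtype, values)))
        elif tag.dtype.name == "RATIONAL":
            values = list(value) if isinstance(value, (tuple, list)) else [value]
            entries.append(
                (code, _TYPE_RATIONAL, len(values), _pack_value(_TYPE_RATIONAL, values))
            )
        elif tag.dtype.name in ("UNDEFINED", "BYTE"):
            raw = bytes(value)
            entries.append((code, _TYPE_UNDEFINED, len(raw), raw))

    payload_offset = 8
    cursor = payload_offset + len(payload)
    if cursor % 2:
        cursor += 1
    # out-of-line value placement
    out_of_line: dict[int, int] = {}
    for tag, dtype, count, raw in entries:
        if tag == 324:
            continue
        if len(raw) > 4:
            out_of_line[tag] = cursor
            cursor += len(raw) + (len(raw) % 2)
    ifd_offset = cursor

    buf = io.BytesIO()
    buf.write(struct.pack("<2sHI", b"II", 42, ifd_offset))
    buf.write(payload)
    if buf.tell() % 2:
        buf.write(b"\x00")
    for tag, dtype, count, raw in sorted(entries):
        if tag == 324 or len(raw) <= 4:
            continue
        buf.write(raw)
        if len(raw) % 2:
            buf.write(b"\x00")
    assert buf.tell() == ifd_offset
    buf.write(struct.pack("<H", len(entries)))
    for tag, dtype, count, raw in sorted(entries):
        if tag == 324:
            inline = struct.pack("<I", payload_offset)
        elif len(raw) > 4:
            inline = struct.pack("<I", out_of_line[tag])
        else:
            inline = raw.ljust(4, b"\x00")
        buf.write(struct.pack("<HHI", tag, dtype, count) + inline)
    buf.write(struct.pack("<I", 0))  # no next IFD

    sink = os.fspath(sink)
    with open(sink, "wb") as f:
        f.write(buf.getvalue())
    return sink


def split_tiles(
    plane: ImagePlane, out_dir: str | os.PathLike, stem: str = "tile"
) -> list[str]:
    """Split a tiled plane into one single-tile TIFF per tile (raw transfer)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for row in range(plane.tiles_per_col):
        for col in range(plane.tiles_per_row):
            path = os.path.join(out_dir, f"{stem}_i{row + 1}j{col + 1}.tif")
            copy_tile_compressed(plane, row, col, path)
            paths.append(path)
    return paths
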