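"""Nucleus detection and spatial statistics over mosaic pieces.

Dark cell nuclei (high chromatin content) are segmented per mosaic piece by
thresholding pixel luminosity, then detections duplicated in the overlap
zones between adjacent pieces are merged: two detections from different
pieces closer than their (mean) equivalent radius are the same nucleus seen
twice.  The merged set feeds nearest-neighbor distance statistics — the
probability density of each nucleus' distance to its closest neighbor, a
standard summary of tissue architecture.

Coordinates are global plane pixels throughout; per-piece detections are
shifted by the piece origin at detection time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError, GigaslideError
from .mosaic import MosaicPlan

__all__ = [
    "Nucleus",
    "NucleusSet",
    "DistanceHistogram",
    "luminosity",
    "detect_nuclei",
    "dedup",
    "nn_distances",
    "distance_pdf",
    "write_nucleus_table",
    "read_nucleus_table",
]

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def luminosity(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel luminosity 0-255 (ITU-R 601 weights, rounded) of an RGB block."""
    if pixels.ndim == 2 or pixels.shape[2] == 1:
        return np.asarray(pixels).reshape(pixels.shape[0], pixels.shape[1]).astype(np.uint8)
    return np.rint(pixels[:, :, :3].astype(np.float32) @ _LUMA.astype(np.float32)).astype(
        np.uint8
    )


@dataclass(frozen=True)
class Nucleus:
    """One detected nucleus in global plane coordinates."""

    centroid_x: float
    centroid_y: float
    area: int  # px^2
    equivalent_radius: float  # sqrt(area / pi)
    piece: tuple[int, int]  # (row, col) of the originating mosaic piece
    mean_luminosity: float
    touches_border: bool = False  # clipped by the padded piece edge


@dataclass
class NucleusSet:
    """Detections plus the mosaic plan they were made on (None for whole-image)."""

    nuclei: list[Nucleus]
    plan: MosaicPlan | None = None

    def __len__(self) -> int:
        return len(self.nuclei)

    def coordinates(self) -> np.ndarray:
        return np.array(
            [(n.centroid_x, n.centroid_y) for n in self.nuclei], dtype=float
        ).reshape(-1, 2)

    def radii(self) -> np.ndarray:
        return np.array([n.equivalent_radius for n in self.nuclei], dtype=float)


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def detect_nuclei(
    pixels: np.ndarray,
    piece_origin: tuple[int, int] = (0, 0),
    threshold: int = 100,
    min_area: int = 10,
    max_area: int = 10**6,
    piece: tuple[int, int] = (0, 0),
    plan: MosaicPlan | None = None,
) -> NucleusSet:
    """Threshold-and-label nucleus detection on one decoded piece.

    Connected components (8-connectivity) of pixels with luminosity strictly
    below ``threshold``, filtered to ``[min_area, max_area]``.  Centroids are
    reported in global coordinates (piece origin added).  Components touching
    the piece's outer border are flagged: their shapes are truncated by the
    cut, so area statistics should exclude them.

    When a mosaic ``plan`` is given, components clipped by an *interior
    overlap border* — a padded-box edge that lies inside the plane and beyond
    the piece's own core — are discarded outright: the overlap margin of the
    neighboring piece contains the same nucleus whole (guaranteed when the
    overlap is at least one nucleus diameter), and the clipped copy's
    centroid is displaced, so keeping it would corrupt both count and
    positions.  On a mosaic without overlap padded = core, no edge qualifies,
    and cut nuclei appear as fragments in both pieces — the artifact the
    overlap feature exists to prevent.
    """
    if not 0 <= threshold <= 255:
        raise ConfigurationError(f"threshold must be in [0, 255], got {threshold}")
    lum = luminosity(pixels)
    mask = lum < threshold
    labels, n_labels = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    nuclei: list[Nucleus] = []
    if n_labels:
        index = np.arange(1, n_labels + 1)
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index)
        centroids = ndimage.center_of_mass(mask, labels, index)
        mean_lum = ndimage.mean(lum, labels, index)
        edges = {
            "top": labels[0, :],
            "bottom": labels[-1, :],
            "left": labels[:, 0],
            "right": labels[:, -1],
        }
        border = np.zeros(n_labels + 1, dtype=bool)
        for edge in edges.values():
            border[np.unique(edge)] = True
        clipped = np.zeros(n_labels + 1, dtype=bool)
        if plan is not None:
            box = plan.piece(*piece)
            interior_overlap_edges = {
                "top": box.padded.y > 0 and box.padded.y < box.core.y,
                "bottom": box.padded.y_end < plan.height
                and box.padded.y_end > box.core.y_end,
                "left": box.padded.x > 0 and box.padded.x < box.core.x,
                "right": box.padded.x_end < plan.width
                and box.padded.x_end > box.core.x_end,
            }
            for name, edge in edges.items():
                if interior_overlap_edges[name]:
                    clipped[np.unique(edge)] = True
        ox, oy = piece_origin
        for lab, area, (cy, cx), ml in zip(index, areas, centroids, mean_lum):
            area = int(area)
            if not min_area <= area <= max_area:
                continue
            if clipped[lab]:
                continue
            nuclei.append(
                Nucleus(
                    centroid_x=cx + ox,
                    centroid_y=cy + oy,
                    area=area,
                    equivalent_radius=float(np.sqrt(area / np.pi)),
                    piece=piece,
                    mean_luminosity=float(ml),
                    touches_border=bool(border[lab]),
                )
            )
    return NucleusSet(nuclei=nuclei, plan=plan)


# ---------------------------------------------------------------------------
# overlap deduplication
# ---------------------------------------------------------------------------

def _in_overlap_zone(nucleus: Nucleus, plan: MosaicPlan) -> bool:
    """A nucleus sits in an overlap zone iff >= 2 padded boxes cover it."""
    covering = 0
    for box in plan.pieces:
        if box.padded.contains_point(nucleus.centroid_x, nucleus.centroid_y):
            covering += 1
            if covering >= 2:
                return True
    return False


def _depth_in_core(nucleus: Nucleus, plan: MosaicPlan) -> float:
    """Distance from the centroid to its own piece's core boundary (signed:
    negative when the centroid falls outside the core)."""
    core = plan.piece(*nucleus.piece).core
    dx = min(nucleus.centroid_x - core.x, core.x_end - nucleus.centroid_x)
    dy = min(nucleus.centroid_y - core.y, core.y_end - nucleus.centroid_y)
    return min(dx, dy)


def merge_sets(sets: list[NucleusSet]) -> NucleusSet:
    plans = {id(s.plan) for s in sets if s.plan is not None}
    if len(plans) > 1:
        raise GigaslideError("nucleus sets reference different mosaic plans")
    plan = next((s.plan for s in sets if s.plan is not None), None)
    return NucleusSet(nuclei=[n for s in sets for n in s.nuclei], plan=plan)


def dedup(
    sets: "list[NucleusSet] | NucleusSet",
    plan: MosaicPlan | None = None,
    rule: str = "mean",
) -> NucleusSet:
    """Merge duplicate detections from the overlap zones of a mosaic.

    A pair of nuclei from *different* pieces, both inside an overlap zone
    (an area covered by more than one padded box), is the same nucleus seen
    twice when their centroid distance is smaller than their radius — taken
    as the mean of the two equivalent radii (``rule="mean"``, default) or
    the larger of the two (``rule="max"``).  Because detections clipped by an
    interior overlap border are discarded at detection time, surviving
    duplicates are whole-vs-whole sightings at near-identical positions and
    either rule merges them.  Of a duplicate group the
    detection whose centroid lies deepest inside its own piece's core is
    kept: detections near a piece edge are the ones liable to be clipped.

    Candidate pairs come from a KD-tree over overlap-zone nuclei only, never
    an all-pairs scan of the full set.  With zero overlap the operation is
    the identity.
    """
    if rule not in ("mean", "max"):
        raise ConfigurationError(f"dedup rule must be mean|max, got {rule!r}")
    merged = merge_sets(sets) if isinstance(sets, list) else sets
    if plan is None:
        plan = merged.plan
    if plan is None:
        raise GigaslideError("dedup requires a mosaic plan")
    if merged.plan is not None and merged.plan is not plan:
        raise GigaslideError("nucleus set references a different mosaic plan")
    nuclei = merged.nuclei
    if len(nuclei) < 2:
        return NucleusSet(nuclei=list(nuclei), plan=plan)

    overlap_idx = [i for i, n in enumerate(nuclei) if _in_overlap_zone(n, plan)]
    if len(overlap_idx) < 2:
        return NucleusSet(nuclei=list(nuclei), plan=plan)
    coords = np.array(
        [(nuclei[i].centroid_x, nuclei[i].centroid_y) for i in overlap_idx]
    )
    radii = np.array([nuclei[i].equivalent_radius for i in overlap_idx])
    tree = cKDTree(coords)
    # the merge limit never exceeds the largest equivalent radius, for either rule
    pairs = tree.query_pairs(r=float(radii.max()))

    parent = list(range(len(overlap_idx)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        na, nb = nuclei[overlap_idx[a]], nuclei[overlap_idx[b]]
        if na.piece == nb.piece:
            continue
        dist = float(np.hypot(na.centroid_x - nb.centroid_x, na.centroid_y - nb.centroid_y))
        limit = (
            (na.equivalent_radius + nb.equivalent_radius) / 2.0
            if rule == "mean"
            else max(na.equivalent_radius, nb.equivalent_radius)
        )
        if dist < limit:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    groups: dict[int, list[int]] = {}
    for local, global_i in enumerate(overlap_idx):
        groups.setdefault(find(local), []).append(global_i)

    drop: set[int] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        keep = max(members, key=lambda i: _depth_in_core(nuclei[i], plan))
        drop.update(i for i in members if i != keep)

    kept = [n for i, n in enumerate(nuclei) if i not in drop]
    return NucleusSet(nuclei=kept, plan=plan)


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def nn_distances(nucleus_set: "NucleusSet | np.ndarray") -> np.ndarray:
    """Euclidean distance from each nucleus to its nearest other nucleus.

    Computed with a KD-tree; identical to the brute-force all-pairs result.
    """
    coords = (
        nucleus_set.coordinates()
        if isinstance(nucleus_set, NucleusSet)
        else np.asarray(nucleus_set, dtype=float)
    )
    if len(coords) < 2:
        raise GigaslideError("nearest-neighbor distances need at least 2 nuclei")
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=2)
    return dists[:, 1]


@dataclass
class DistanceHistogram:
    """Normalized nearest-neighbor distance density (uniform bins)."""

    bin_edges: np.ndarray  # length n_bins + 1, pixels
    density: np.ndarray  # per-pixel probability density, length n_bins

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def integral(self) -> float:
        return float(np.sum(self.density) * self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"distance_px": centers, "density": self.density})


def distance_pdf(distances: np.ndarray, bin_width: float) -> DistanceHistogram:
    """Empirical probability density of the distances, integrating to one.

    Bins are uniform over [0, max distance rounded up to a bin edge].
    """
    if bin_width <= 0:
        raise ConfigurationError(f"bin width must be positive, got {bin_width}")
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ConfigurationError("distance list is empty")
    top = float(np.ceil(distances.max() / bin_width)) * bin_width
    top = max(top, bin_width)
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    density, edges = np.histogram(distances, bins=edges, density=True)
    return DistanceHistogram(bin_edges=edges, density=density)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["x", "y", "area", "radius", "piece_row", "piece_col"]


def write_nucleus_table(nucleus_set: NucleusSet, sink: str | os.PathLike) -> str:
    """One CSV row per nucleus: coordinates, size and originating piece."""
    frame = pd.DataFrame(
        [
            {
                "x": n.centroid_x,
                "y": n.centroid_y,
                "area": n.area,
                "radius": n.equivalent_radius,
                "piece_row": n.piece[0],
                "piece_col": n.piece[1],
            }
            for n in nucleus_set.nuclei
        ],
        columns=_TABLE_COLUMNS,
    )
    sink = os.fspath(sink)
    frame.to_csv(sink, index=False)
    return sink


def read_nucleus_table(path: str | os.PathLike) -> NucleusSet:
    frame = pd.read_csv(os.fspath(path))
    nuclei = [
        Nucleus(
            centroid_x=float(row.x),
            centroid_y=float(row.y),
            area=int(row.area),
            equivalent_radius=float(row.radius),
            piece=(int(row.piece_row), int(row.piece_col)),
            mean_luminosity=float("nan"),
        )
        for row in frame.itertuples()
    ]
    return NucleusSet(nuclei=nuclei, plan=None)
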