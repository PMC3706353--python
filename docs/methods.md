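# Methods

## Scope and model

`gigaslide` treats a whole-slide image as a TIFF/BigTIFF container of image
*planes*, one per (magnification, focus) pair, each stored as a grid of
independently compressed tiles. All algorithms are written against two
invariants: opening a container touches headers and metadata only, and every
pixel access decodes a bounded set of tiles. Proprietary scanner dialects
are out of scope; a standard multi-image TIFF with magnification/focus
metadata in each plane's ImageDescription plays the role of the vendor
container.

Coordinates are 0-based with origin at the top-left; rectangles are
half-open `[x, x+w) × [y, y+h)`; tiles are row-major. TIFF stores edge tiles
padded to full tile size, so every tile read reports its valid extent and
the valid extents of a plane's tiles partition it exactly.

### Plane metadata

Magnification and focus are carried as a printable ASCII line
`magnification=<m>;focus=<z>` where `<m>` is an integer, decimal, fraction
(`5/2`) or the token `macro`, and `<z>` is a signed integer. The
encode/decode pair is a bijection on that domain; text lacking the keys maps
to a sentinel, not an exception — unlabeled planes are legal and survive all
operations. This grammar is this package's own convention; it is not
byte-compatible with any vendor tool's description fields.

## Mosaic planning

The planner receives plane dimensions, bytes per pixel `b` (derived from
samples × bits/8), a per-piece RAM budget `B` (default 1024 MiB) and an
overlap request. It restricts grid counts to powers of two per dimension and
returns the feasible grid minimizing the piece count; ties are broken by the
most-square piece (smallest |log aspect|), then fewer columns. The
power-of-two restriction is deliberate: for an 18.2 GiB plane and a 512 MiB
budget a free grid would admit 37 pieces (⌈18.2 GiB / 512 MiB⌉), but slide
tooling in practice produces 64 = 8 × 8, and the restriction makes piece
geometry uniform and cache-friendly. A free-grid search is available behind
`free_grid=True`, and an explicit piece size bypasses the planner via
ceiling division.

Feasibility is judged on the *padded* piece — core plus overlap — because
the budget's purpose is the RAM needed to open a piece, and the piece a
consumer opens includes its overlap. Core extents use a near-equal split
(the first `extent mod n` pieces get one extra pixel) so cores partition the
plane exactly with no drift. Overlap is symmetric per interior edge, clipped
at plane borders; percent mode resolves against the full plane dimension per
axis; a resolved overlap must be smaller than the core extent or planning
fails. Reassembly copies only cores, so mosaic → reassemble is the identity
for lossless piece formats regardless of overlap.

JPEG pieces use Pillow with quality 75 by default (configurable); piece
dimensions are not forced to JPEG MCU multiples — the encoder handles
partial blocks. TIFF pieces are deflate-compressed.

## Region extraction

`tiles_for_region` computes the exact tile index ranges
(`floor(x/tw) … floor((x+w−1)/tw)` and likewise for rows);
`extract_region` decodes precisely those tiles, asserted by a per-plane
decode counter. Out-of-bounds regions raise rather than clip — silent
clipping corrupts downstream coordinates — with a separate `clip_region`
helper for callers that want clipping. Stripped (non-tiled) planes degrade
to row-band reads with a warning. The container's tile index is parsed once
at open; repeated extracts reuse it.

## Container splitting

Plane selection composes magnification/focus set filters, with explicit
plane indices overriding both. Output names follow
`stem_x{mag}_z{focus}[_i{row}j{col}]`, 1-based row/col in names (reading
order) while all programmatic indices stay 0-based; names parse back to
their components, and every emitted file carries its metadata in its own
description, so outputs are self-describing. Mosaic mode `if_needed`
compares each plane's exact uncompressed size against the budget; `always`
forces mosaics.

Preview selection returns the largest plane fitting the given screen bounds
(smallest plane if none fits) together with the full focus stack at that
magnification, ordered by ascending focus offset.

Blank-band splitting finds maximal non-blank regions of a multi-sample
slide: a run (≥ `min_band`, default one tile height) of rows or columns
whose every pixel is within `tolerance` (default 8 levels) of the background
luminosity acts as a separator; the recursion alternates axes and is capped
at 4 passes to guarantee termination. Background defaults to the modal
luminosity of the plane's corner patches — robust for scanner-white fill.
The scan runs in tile-row bands, never holding the plane. This
separator-run procedure is this package's own reconstruction of blank-region
removal; no published reference algorithm exists for it.

## Nucleus detection and overlap deduplication

Detection is deliberately plain thresholding: luminosity
`round(0.299 R + 0.587 G + 0.114 B)` (ITU-R 601), 8-connected components of
pixels strictly below the threshold, area-filtered to `[min_area,
max_area]`, centroids shifted into global plane coordinates by the piece
origin. No hole-filling or watershed splitting of touching nuclei is
applied; that is an extension point, not a default.

Two rules govern mosaic pieces:

1. **Interior-clip discard.** A component touching a padded-box edge that
   lies *inside* the plane and *beyond the piece's own core* is discarded at
   detection time. Such a component is a nucleus cut by the overlap margin:
   its centroid is displaced toward the cut, and — decisively — its intact
   twin in the neighboring piece can lie outside every overlap zone, where
   no pair rule can reach it. When the overlap is at least one nucleus
   diameter the discarded object is guaranteed whole in the neighbor, so
   nothing is lost. On a mosaic without overlap, padded = core, no edge
   qualifies, and cut nuclei surface as fragments in both pieces — the
   artifact overlap exists to prevent. Components touching the global plane
   border are kept but flagged (`touches_border`) so area statistics can
   exclude their truncated shapes.
2. **Pair merging.** Among detections whose centroids are covered by two or
   more padded boxes, a pair from different pieces merges when its centroid
   distance is below the mean of the two equivalent radii (`rule="mean"`,
   default) or the larger of the two (`rule="max"`). After the interior-clip
   discard, surviving duplicates are whole-vs-whole sightings at
   near-identical positions, and the two rules agree in practice. Candidate
   pairs come from a KD-tree over overlap-zone detections only, with radius
   equal to the largest equivalent radius — never an all-pairs scan. Merge
   groups are closed transitively (a corner nucleus can appear in up to four
   pieces); the kept representative is the detection deepest inside its own
   piece's core, the one least likely to be clipped. The operation is
   idempotent and is the identity on zero-overlap plans.

Nearest-neighbor distances use a KD-tree (`k=2` query) and equal the
brute-force all-pairs result exactly. The distance PDF is a uniform
histogram over `[0, max rounded up to a bin edge]`, normalized so that
`Σ density · bin_width = 1` to within 1e−9.

## Synthetic fixtures

All generators are pure functions of their parameters and seed and write
tile by tile, so fixture generation is byte-reproducible and uses memory
independent of output size.

- **Patterns** `constant`, `checkerboard`, `gradient` are per-pixel
  functions of global coordinates — any block can be regenerated
  analytically, which is the oracle for extraction tests. `noise` seeds a
  generator per block origin: deterministic for a fixed tiling.
- **Pyramids** scale plane dimensions by magnification ratio
  (`ceil(base · m/m₀)`) and stamp each plane's metadata; 5 magnifications ×
  11 focus offsets reproduce the 55-plane container layout of real
  multi-focus scans.
- **Tissue** places nucleus centers by seeded rejection sampling under a
  minimum separation, draws each as a filled disk of its radius at the
  nucleus luminosity on a brighter background, and adds clipped Gaussian
  noise (same value on all three channels, so luminosity is the controlled
  quantity). Defaults — 16000 × 12000 px, 2000 nuclei, radii 5–14 px,
  separation 84 px (3× the largest diameter), background 230, nuclei 60,
  noise σ 8 — make detection unambiguous at threshold 145 while keeping
  thresholding nontrivial. A packing bound rejects infeasible
  separation/count combinations before sampling.
- **Blank-separated slides** fill given disjoint boxes with Gaussian texture
  (mean 170, σ 25) on uniform filler, recording the exact boxes as ground
  truth.

What passing tests on these fixtures shows: the geometry, bookkeeping and
statistics of the pipeline are exact (counts, centroids, partitions,
round-trips). What they do not show: detection quality on real stained
tissue, where nuclei touch, vary in chromatin density, and sit on textured
stroma — threshold choice and the no-splitting limitation matter there.

## Numerical and design notes

- All size arithmetic is exact integer math; the classic-TIFF limit
  (2³² − 1 bytes) is checked against the projected uncompressed size before
  writing, and the writer switches to BigTIFF automatically (or refuses,
  when classic output is explicitly forced) rather than emit a corrupt file.
- Raw tile transfer (`copy_tile_compressed`) writes a minimal single-tile
  TIFF around the original compressed payload — byte-identical, no
  transcode — copying codec-relevant tags (predictor, photometric,
  subsampling, JPEG tables) from the source IFD, and declares the tile's
  valid extent as the image size so edge padding clips on decode.
- Test and acceptance problem sizes are scaled to what the checks need:
  planner behavior is exercised at full slide geometry (pure arithmetic),
  pixel pipelines on planes up to 16000 × 12000 (the geometry is
  size-independent, and the scaled runs exercise every code path, including
  multi-tile and multi-piece boundaries).
- The nearest-neighbor law test uses 10⁵ uniform points in the unit square
  against `2πλr·exp(−πλr²)`; at that intensity edge effects bias well under
  the 0.01 Kolmogorov–Smirnov acceptance bound.

## Known limitations

- No vendor binary dialects, JPEG2000, or ICC color management; compressions
  are none/JPEG/LZW/Deflate.
- Stripped planes are read-only fallbacks; tile-level operations require
  tiled storage.
- The interior-clip discard assumes overlap ≥ one object diameter; with
  smaller overlaps, objects larger than the margin can be lost at cuts.
- Nucleus counts on real tissue depend on threshold and area-filter choices
  the user must calibrate; touching nuclei are merged into one component.
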