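# Methods

This note documents the models, conventions and numerical choices behind
`nucalign`, and what the synthetic test scenes do and do not establish
about behavior on real Xenium data.

## Coordinate and intensity conventions

All images are row-major grids: the row index is y (along the image
*length* L), the column index is x (along the *width* W), 0-based, with
pixel centers at integer coordinates. Intensities are handled as 8-bit
everywhere (maximum value L = 255); deeper DAPI planes are min–max
stretched to [0, 255] at load so that the PSNR formula has a single peak
value and patches from both modalities share a scale. H&E rasters are
converted to inverted BT.601 luminance (255 − Y) before any comparison with
DAPI, so both modalities present bright nuclei on a dark background —
raw-luminance MSE would reward matching background, not structure.

## Orientation search

Scanned H&E images may be rotated and/or mirrored relative to the
instrument's morphology image. The search space is the 8-element dihedral
group (4 right-angle rotations × optional horizontal mirror, the mirror
applied before the rotation). Each candidate correction is applied to the
inverted-luminance H&E image, both images are resized to a square thumbnail
(512 px by default; bilinear, no anti-alias filter, for determinism) and
scored by MSE; the smallest score wins, with ties broken toward the
identity by scanning it first under a strict-improvement rule. Because
mirrored orientations are reflections (involutions) and pure rotations
invert by angle negation, reporting the *inverse* of the winning correction
as "the orientation applied to the scan" is exact for all 8 candidates.
Sub-degree rotations are out of scope: Xenium Explorer's own least-squares
alignment absorbs fine transforms once the keypoints are right.

## Nucleus records

Every nucleus center is the midpoint of the axis-aligned bounding box of
its boundary — the mean of the min and max coordinate per axis — for both
modalities, so the two sides of a keypoint are computed by the same rule.
H&E boundaries are the convex hulls of segmentation-label pixel sets;
labels with fewer than 3 pixels (or collinear ones) cannot form a polygon
and are dropped with a logged count. DAPI boundaries come from the
Xenium-exported vertex table (CSV or parquet; column names configurable,
defaulting to `cell_id`, `vertex_x`, `vertex_y`); nuclei with fewer than 3
vertices are skipped with a warning.

Segmentation backends are adapters behind one interface. Cellpose is the
primary external model (min 15 pixels per mask, error threshold 0.8,
channel index exposed as a parameter since "channel 1" is ambiguous between
0- and 1-based conventions — the default is the green channel) and StarDist
the fallback (object probability threshold 0.3), invoked when the segment
ratio — distinct labels over the DAPI nucleus count — is *strictly* below
0.5. Both are optional dependencies; a `ground_truth` backend accepts an
externally supplied label image, which is how every test runs and how a
user with an existing segmentation bypasses the models entirely.

## Search regions and patch matching

An H&E center maps into DAPI coordinates by pure size proportionality
(X·W_DAPI/W_HE, Y·L_DAPI/L_HE, real-valued). The square search region has
half-side `crop_radius_ratio · min(W, L)` of the DAPI image; regions
holding fewer than `extracted_region_min` (50) nucleus centers (inclusive
square membership test) are rejected, not errors.

Patches are half-open windows `[c − r, c + r)` per axis (side 2r), cropped
at the nucleus center and at four displaced centers (±move along one axis;
"up" is decreasing row index). Windows that would cross the image border
are skipped rather than padded — padding would inject synthetic signal into
PSNR, skipping only shrinks the candidate pool. All patches are resized to
`patch_size` × `patch_size` (224 default) with bilinear interpolation.

The H&E side is rendered from the segmentation as a binary mask (nucleus
255, background 0); candidate DAPI patches are cropped around each
candidate's own center with the same radius/move scheme and contrast
stretched to [0, 255] per patch before PSNR, which makes the five rankings
comparable per candidate. One deliberate coordinate choice: the crop radius
and move distance are specified in DAPI pixels, and the H&E windows use
per-axis values scaled by the image-size ratio, so that both patches cover
the same tissue footprint before the common resize. When the two images
have equal resolution this reduces to using the same pixel radius on both
sides; when they differ, comparing equal pixel radii would compare
different tissue regions and the PSNR ranking would be meaningless.

PSNR = 10·log₁₀(L²/MSE); identical patches (MSE 0) score +∞, which ranks
above all finite values. Argmax ties break toward the smallest candidate
id for determinism. A correspondence is accepted only when the same
candidate wins all five directions; with move distance 0 the directions
coincide and any per-direction winner is automatically a consensus.

## Delaunay edge-consistency filter

Both sides of the surviving correspondences are Delaunay-triangulated
(scipy's Quickhull-based implementation) over the shared correspondence
indices, and edges are normalized as unordered index pairs. Each iteration
compares every node's incident-edge set between the two graphs, in index
order; all nodes with inconsistent connectivity are removed from both
sides, the triangulations are rebuilt, and the process repeats until the
two edge sets are identical (or fewer than 3 nodes remain, in which case
filtering degenerates with a warning and the downstream 3-keypoint minimum
governs). Each iteration removes at least one node, so termination is
immediate to bound; the filter is idempotent, and the postcondition —
identical rebuilt edge sets over the survivors — is asserted by the tests
after every run.

Removing *all* inconsistently connected nodes per iteration, rather than a
single designated node, was a deliberate design decision: single-node
variants (several were measured) leave a grossly displaced correspondence
in place in roughly a quarter of randomized trials, because removing an
innocent neighbor first can restore consistency around the outlier. The
per-node rule removes a planted outlier (displaced by 5× the median
nearest-neighbor spacing) in ≥ 95% of trials at the cost of also dropping
some of the outlier's distorted neighbors — acceptable here, since
downstream accumulation only needs enough keypoints, not all of them.
Cocircular point sets make the triangulation non-unique; the underlying
triangulator's deterministic choice stands, and the identical-edge-sets
postcondition is the authoritative contract.

## Polygon overlap filter

Nucleus polygons are convex hulls (Quickhull). For scoring, the H&E polygon
is scaled per-axis by the DAPI/H&E image-size ratio (undoing the pixel-grid
difference; an identity scale is available), then each polygon is
translated so its bounding-box midpoint — the keypoint location — sits at
the origin, making the overlap a pure shape/size comparison. The
intersection of two convex polygons is computed by robust polygon clipping
(shapely), and validated in the tests against a 10⁵-sample Monte-Carlo
rasterization oracle. The overlap index is either the average
½(A∩/S + A∩/T) or the minimum min(A∩/S, A∩/T) proportion; the minimum can
never exceed the average, so every pair kept under the minimum rule at a
given threshold also passes the average rule there. Keeping uses ≥, i.e. a
pair is removed exactly when its index is lower than the threshold
(defaults 0.9 average, 0.92 minimum).

## Epoch loop

Each epoch samples `cell_num_each_epoch` (100) H&E nuclei uniformly without
replacement from the not-yet-tried pool — without replacement so the pool
depletes and termination is guaranteed even when no matches appear. The
epoch's consensus pairs pass the Delaunay filter, then the polygon filter
(both per epoch, matching the per-epoch accumulation structure; an
optional global Delaunay pass over the final set exists behind
`final_global_filter`, default off). Survivors accumulate, deduplicated by
(H&E id, DAPI id) and one-to-one on both ids — a landmark set with
duplicate anchors is geometrically degenerate for least-squares alignment.
The loop stops at `keypoints_min` accumulated pairs, pool exhaustion, or
`max_epochs` (100). Fewer than 3 final pairs is a hard failure with a
diagnostic; between 3 and the minimum is a success with a warning. Empty
epochs count toward the epoch number and are logged. With a fixed
`rng_seed` and inputs, two runs write byte-identical CSVs.

## Keypoint file

The CSV header is `fixedX,fixedY,alignmentX,alignmentY` (configurable
casing, since the Explorer dialect may evolve): fixed = DAPI morphology
pixel coordinates, alignment = H&E pixel coordinates in the oriented frame,
full float precision, UTF-8, LF endings. A JSON sidecar manifest records
both image dimensions, the orientation applied to the H&E, the backend
used, and the full configuration, so the coordinates remain interpretable
— including reconstructing original-frame H&E coordinates if an unrotated
scan is imported.

## Synthetic scenes

The generator plants elliptical nuclei (closed-form centers, boundary
polygons and areas, which is why ellipses and not arbitrary blobs) with a
minimum pairwise center spacing via grid-accelerated dart throwing, renders
them as a noisy bright-on-dark DAPI image and a dark-purple-on-light H&E
RGB raster at an independent pixel scale, applies a known orientation to
the H&E side (image, ground-truth label image and all), and emits the
boundary table, correspondence list, and a closed-form oracle transform
from fixture H&E coordinates to DAPI coordinates. A `decoy_fraction` adds
nuclei present in only one modality. Default scene scale (hundreds of
nuclei in a few-hundred-pixel image) keeps every test at desk scale —
seconds, not hours; the synthetic preset scales the pixel-valued crop
radius (to 0.10·min dim) and move distance (0.075·min dim, preserving the
4:3 crop-to-move ratio of the full-scale defaults) and uses the wide 0.5
search-region ratio, because at synthetic densities narrower regions
cannot hold the required 50 nuclei — the same adaptation applied to
thin-aspect real samples.

Additive clipped Gaussian noise (sd 6 by default) is the only corruption
model; PSNR degrades smoothly under it. The scenes deliberately do not
simulate staining artifacts, tissue folds, out-of-focus regions,
segmentation errors beyond planted decoys, or non-rigid tissue deformation
between the two stains. Passing tests therefore establish the geometric and
algorithmic correctness of the pipeline — orientation recovery, correct
matching under exact correspondence, outlier removal, file contracts — not
robustness to real-world stain variation, for which the external
segmentation models and the PSNR consensus carry the burden on real data.

## Known limitations

- PSNR against a binary segmentation rendering presumes the segmentation
  is reasonable; heavily merged or missed nuclei degrade the ranking (the
  polygon filter catches merged-nucleus matches downstream).
- The orientation search covers only the 8 axis-aligned symmetries; a scan
  rotated by an arbitrary angle must be coarsely oriented first.
- The Delaunay filter removes some inliers adjacent to each outlier; on
  very small correspondence sets this can be a large fraction of an epoch.
- Border nuclei whose directional crops would leave the image are never
  candidates, so keypoints cannot appear within one crop radius plus move
  distance of the image edge.
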