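# Methods

This note documents the models, conventions and numerical choices behind
orbitlite, and what the synthetic test scenes do and do not show about
real slide data.

## Image model and tiling conventions

Images are multi-resolution pyramids with a fixed integer downsampling
factor (default 4, the common WSI convention) built by block averaging;
levels are appended until the top level is smaller than one tile, so the
level dimensions follow `ceil(d / f^l)`. Pixels are held as float32 in
[0, 1]; 8/16-bit inputs are scaled by their type maximum and rescaled on
export. Coordinates are 0-based, x rightward, y downward; annotations are
always in level-0 pixel coordinates. Tiles are 512 px by default,
addressed as `(tx, ty)` and iterated row-major.

Tile halos — and any read outside the image — are mirror-padded
(reflection about the border without repeating the edge row, matching
`np.pad(mode="reflect")` / SciPy `mode="mirror"`). Mirror padding avoids
the spurious edge responses that constant padding would inject into
texture features at image borders. Because the same convention is used by
the whole-image filters and by haloed tile reads, per-tile feature
computation is bit-identical to the untiled computation; this is the
backbone of the tiling-invariance guarantees.

Image identity is the md5 digest of the level-0 pixels in the source
integer dtype, row-major with channels interleaved. This is a repository
convention: it makes identity a pure function of image content, but the
digests are not interchangeable with those of other systems, which may
hash different byte layouts.

## Map-reduce engine

A tile job is a map function over haloed tile rasters plus a reduce
function over the list of partial results. The local executor runs map
calls in a thread pool; partial results are handed to the reducer in
row-major tile order regardless of completion order, so the outcome is
identical for any worker count. Failures abort the job and name the
failing tile. Tile enumeration intersects tile footprints with the ROI's
supporting geometry (union of roi and inclusion polygons); exclusions do
not drop tiles — excluded pixels simply contribute nothing — which keeps
enumeration conservative and cheap.

## Pixel classification

Features per channel and per level: window minimum, maximum, mean,
standard deviation (population), edge factor, and the centre intensity.
The window is a square of side `2s+1` including the centre pixel, and the
edge-factor denominator is `|W| - 1`; the centre's own term contributes
zero. The feature levels are *relative* pyramid offsets from the working
level (default `(0, 1)`), so a model can be reapplied at a coarser working
level — that is exactly how exclusion models run at the pyramid level
whose pixel count is closest to 2^20 (ties to the finer level).

The classifier is a linear SVM (C = 1, one-vs-rest beyond two classes) on
features z-scored with training statistics stored in the model. Training
samples at most 40,000 pixels uniformly from the union of all training
shapes (global, not per class; per-class support is logged), reproducibly
from a seed. Training-set accuracy is computed on the training set
without cross-validation; below 0.85 a structured warning is logged and a
boolean flag set on the model — this system is headless, so there is no
popup.

Two configuration notes, both deliberate:

* For *area-ratio* analyses on scenes with sharp region boundaries,
  single-level features (`levels=(0,)`) are preferable: the coarse level's
  effective window (structure size × factor) smears features across the
  boundary and can bias ratios by a few percent. The multi-level default
  is aimed at heterogeneous tissue where context helps.
* The structure-size demonstration (fine vs coarse grating of equal mean
  and amplitude, drowned in pixel noise) also uses `levels=(0,)` so that
  the window size alone controls the available context: a 3×3 window sees
  only noise (held-out accuracy ≈ 0.55), a 21×21 window separates the
  textures essentially perfectly.

## Object segmentation

Foreground bitmaps are cleaned by binary erosion then dilation (3×3
square, 1 iteration each by default; the structuring element and counts
are configurable), labelled 8-connected, optionally split per component by
a distance-transform watershed seeded at local maxima with a minimum peak
separation, and filtered by area bounds. Outside the image the foreground
is background (constant padding), matching the untiled reference.

Tiled segmentation reads each tile with a halo of `erosion + dilation + 1`
pixels (the morphological influence radius), crops to the footprint,
labels locally and flags objects touching interior grid borders as open.
The reduce step unions open objects whose pixels are 8-adjacent across a
border (union-find), then runs the watershed split and area filter on the
merged components. Since watershed input per component is identical in
both paths, tiled output equals untiled output exactly — for any tile
size and any grid offset.

Object features are a fixed, versioned set: area, perimeter, circularity
`4πA/P²`, eccentricity, bbox aspect, normalized centroid, and per-channel
mean/sd/min/max intensity plus mean edge factor (window size 2) as a
texture statistic. Object classification reuses the pixel-classifier SVM
contract, including the accuracy warning. Two-level segmentation
restricts a secondary foreground to the pixel sets of primary objects;
children carry their parent's id.

## Fibre tracing

The response map is the (Gaussian-smoothed) channel intensity, its
inverse (bright-field, where fibres are dark), or the gradient magnitude.
Hysteresis keeps 8-connected components of `response ≥ low` that contain
at least one `response ≥ high` pixel. Per tile, *all* low components are
emitted as fragments with a has-high flag; the reduce step reconnects
fragments across borders and re-evaluates the keep rule on merged
components, so a dim cross-border tail survives when its partner holds a
high pixel. Tile halos cover the smoothing kernel's true support
(`round(4σ) + 1`), making the tiled result pixel-identical to the
single-pass computation.

A junction crossing is an 8-connected run of fibre pixels within 1 px of
the junction polyline whose pixels lie strictly on both sides of it
(side = sign against the nearest segment's normal; terminal segments
extend beyond their endpoints). Touching without a side change does not
count. This strict both-sides rule is this package's operationalization —
clinical counting guidelines leave room for interpretation here, so the
rule is documented rather than claimed canonical. Fibres farther than `d`
pixels from the polyline (default 5, explicit in the CLI) are dropped.
Density is crossings per millimetre when a µm/px scale is supplied, else
per kilopixel.

## Tile-mask refinement and evaluation

The predictor contract is a pure function from a 512×512 tile raster (plus
its position, which only simulated predictors use) to a binary mask. The
shipped `SimulatedPredictor` emits ground-truth pixels only for objects
entirely inside the tile's central window (margin `m`, default 64),
reproducing the characteristic behaviour of tile-wise CNN inference:
clean detections at the tile centre, missing or partial detections near
borders, zero false positives.

Refinement predicts each tile under the identity and four half-tile
translations (up, down, left, right), inverse-shifts the variant masks and
unions them over the tile footprint — the union is taken at mask level,
before segmentation. The refined mask therefore always contains the
identity prediction. Remaining partial detections are re-predicted on a
virtual tile centred on the object; the overlapping re-centred detection
replaces the input (objects larger than the virtual tile are kept with a
warning). Duplicates are removed largest-first: an object is dropped when
a kept object covers ≥ 90% of its pixels (exact containment passes at any
threshold; the 0.9 default is a package choice).

Axis-aligned translations cannot recover an object that sits within the
margin of a vertical *and* a horizontal grid line at once (corner zones),
because every variant still sees it near one border, and an object never
detected cannot be re-centred. The composite-scene generator therefore
keeps objects out of double-margin corner zones (`corner_margin`, default
70 px) — border-straddling objects sit on exactly one grid line. On real
slides this blind spot would be addressed by adding diagonal translations;
the translation list is configurable for exactly that reason.

The Dice object index matches each ground-truth object to the segmented
object of maximal pixel overlap and vice versa (ties broken by centroid
distance, zero overlap contributes 0), weights each object's Dice by its
pixel count within its own set, and averages the two directions. Empty vs
empty scores 1; one empty side scores 0.

## Synthetic scenes

The generator renders, deterministically from a seed: polygonal texture
regions (noisy sinusoidal gratings with set mean, amplitude and period),
blob fields (discs with exact counts and controlled tile-border
straddling), fibre sets (smooth random polylines with a bright core and
optionally a dim tail between the hysteresis thresholds), and composite
textured discs for the refinement pipeline. Ground truth is returned as
label maps and per-element records (centres, radii, polylines, areas).

These scenes exercise the algorithmic contracts — tiling invariance,
threshold logic, merge correctness, refinement recovery — but they are
far cleaner than scanned tissue: no staining variability, no scanner
artefacts, no touching heterogeneous structures, and texture classes that
are separable by construction. Passing tests therefore validates the
machinery, not end-to-end biological accuracy; models for real slides
still need representative training shapes and visual validation.

## Problem sizes

Test scenes range from 384² to 1536² pixels with 512-px (and smaller)
tiles; the refinement property uses 50-object scenes with ~1/3 of objects
straddling tile borders; classifier checks use up to the 40,000-pixel
training cap. The acceptance script reruns all of the above from a single
seed in well under a minute.
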