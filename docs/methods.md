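# Methods

This note documents the models, parameters and design choices behind
`canoplot`, and what the synthetic-trial tests do and do not demonstrate.

## Scene model and coordinate conventions

Rasters are 0-based pixel grids, (x = column, y = row), pixel centers at
integer coordinates; 224 px crop boxes are half-open. World coordinates are
local (no CRS): pixel (0, 0) maps to a configurable origin, x grows with
columns, world y decreases with rows. All pixel↔world conversions go through
one function pair on `RasterGrid`, so converting forth and back is the
identity. Orientations are angles of the field rectangle's long side in
[0, 180): a field has no front/back, so everything is reported modulo 180°.

## Field localization

Candidate masks come from the segmentation backend on the image resized to
1024 px (long side). The field is assumed roughly centered (standard flight
planning), so candidates whose bounding-box centre lies farther than
`center_radius_px` (default 5, in resized coordinates — the scale at which
the candidates were generated) from the image centre are discarded, and the
best mean of predicted-IoU and stability wins. Orientation is taken from the
minimum-area enclosing rectangle of the mask; the first principal component
of the mask pixels is computed as a cross-check and a disagreement beyond 2°
on an elongated mask is logged. Square masks are a degenerate tie broken
toward the smaller angle.

The classical backend scores each candidate by its fill fraction with
respect to its *minimum oriented* bounding rectangle rather than the
axis-aligned box: the axis-aligned variant is not rotation-invariant (a
rotated rectangular field would score ~0.5 and lose to a single canopy
blob), which would break the rotation-sweep protocol. Its field-level
candidate is the filled convex hull of the vegetation mask — a
parameter-free way to present "the whole trial" as one candidate; individual
canopy blobs fill their oriented rectangle at roughly the ellipse ratio
(~0.79) and rank below it.

Axis alignment applies the minimal rotation that cancels the orientation,
then decides which image axis carries the bare-soil alleys: alleys (2 m) are
several times wider than inter-row gaps (~0.1 m), so the vegetation profile
with the larger empty fraction marks the across-range axis, and the scene is
rotated a further 90° when the alleys come out horizontal. This keeps the
convention (ranges vertical, bed lines horizontal) independent of whether
the trial is longest along or across the beds.

## Vegetation index and row/range detection

ExG−ExR on chromatic coordinates (r = R/(R+G+B), …): ExG = 2g − r − b,
ExR = 1.4r − g; black pixels (R+G+B = 0) score 0. The literature uses both
raw-DN and chromatic variants; the chromatic form is adopted here as the
standard one and is what the synthetic renderer is checked against.
Profiles are smoothed with a moving average of width 0.25 × the expected row
spacing in pixels (row spacing 0.91 m by default, converted via the GSD).
Valleys are runs below `valley_frac` (0.1) of the profile maximum, with
boundaries at interior valley midpoints and clamped to the image edges; row
peaks must exceed `peak_frac` (0.3) of their profile maximum and be at least
half a row spacing apart. Provisional plot centroids are vegetation
centroids within each (range, row) band rather than interval midpoints, so
foreground prompts land on canopy even in edge ranges whose interval
includes image margin. Each prompt uses the k = 4 nearest other centroids as
background points (row above/below and adjacent ranges); k is configurable
since nothing pins the exact number.

Masks returned per centroid are clipped to the centroid's range interval; a
pixel claimed by several prompts (duplicated masks over visually similar
neighbours) is assigned to the nearest claiming centroid.

## Terrain model

Two samples per row mask sit `offset_px` outside the mask's bounding box at
its centroid row — across the range direction, so they land on bare bed top
in the alleys, and the interpolated surface represents the *bed* surface
rather than the furrow bottoms. The default offset is a quarter of the alley
width (0.5 m); samples are nudged outward off vegetation and clamped at the
raster edge (flagged). Elevation is read from the single DSM pixel, with an
optional 3×3 median. The DTM is the piecewise-linear interpolant of the
Delaunay triangulation (exact for any affine terrain, regardless of sample
placement); outside the convex hull the nearest sample's elevation is used,
an explicit choice since triangulation gives no answer there. Because
terrain is sampled locally per plot, a terrain anomaly can only perturb its
immediate neighbourhood, not the whole field.

## Bed lines and plot delineation

Pixels with nDSM < −`depth_threshold` (default 0.01 m — the field's furrows
are ~5 cm deep, so the threshold only needs to clear DSM noise) vote in a
Hough accumulator restricted to within ±2° of horizontal, θ step 0.25°,
ρ resolution 1 px. Peaks need `min_support` votes (default 10 % of the
raster width); suppression spans half a bed pitch in ρ across the whole
angle window, and surviving peaks are clustered strongest-first with
centroid linkage — weak peaks from slightly tilted lines attach to the
nearest real boundary instead of chaining adjacent boundaries together.
Voting should be restricted to the trial area (`roi`): outside the terrain
samples' hull the DTM is an extrapolation and spuriously negative regions
are common. The pipeline passes the detected range extent padded by half a
bed width.

Cells between consecutive bed lines crossed with range intervals are scanned
bed-major, then range left-to-right (a stable, documented order for joining
trait tables); a cell with no mask pixels is a missing plot. The plot centre
is the centre of mass of all mask pixels in the cell; the 224×224 crop box
is shifted inward at raster edges so crops contain real data (zero-padding
is available as an option).

## Canopy height

The nDSM crop is split horizontally at the plot centre and the statistic
(max by default; 95/97/99th percentiles available) is taken per half over
finite pixels; the plot's CH is the mean of the two, in cm. Single-row plots
use the occupied half. When the caller provides the plot's bed-line bounds
(the pipeline always does), the crop is clipped to them first: at 1 cm/px
the 2.24 m box is taller than the 1.82 m bed pitch, and without clipping the
half-maximum can capture the neighbouring bed's canopy and bias CH upward.

## Trait classifiers

No deep-learning stack is required: the package ships a compact classifier
family — a frozen, parameter-free pooling encoder (per-channel block means
on a g×g grid, standardized) feeding one trainable hidden fully-connected
layer. Registry keys `alexnet` / `resnet18` / `efficientnet_b0` select
capacity presets (pool 16/8/4, hidden 192/96/48) and keep configuration
compatible with the common CNN naming; only the head trains, mirroring a
frozen-backbone fine-tuning protocol. Training uses cross-entropy, Adam with
decoupled weight decay (0.01 default; the coefficient is a free choice),
dropout 0.5 on the hidden layer, and a one-cycle cosine schedule (10 %
linear warmup, cosine decay to 0.001 × the peak rate). Model selection runs
the full 2×3×3 grid (batch 16/32 × epochs 10/15/20 × lr 1e−5/1e−4/1e−3)
with stratified 5-fold CV scored by macro F1 (the plain "average F1" is
underspecified; macro is symmetric in the classes), then retrains and tests
the winner `runs` times with distinct seeds. One master seed fans out to
split, folds, initialization and runs.

Modalities: `rgb` (raw crop), `ndsm` (cm-scaled height clipped to [0, 255]
and replicated into three channels so any 3-channel model applies
unchanged — whether height-only inputs should be raw meters is open; the
scaled form keeps the dynamic range comparable to images), and `combined`
(G′ = clip(G + 100 × nDSM, 0, 255), R and B untouched). Augmentation is
horizontal flip, vertical flip, and "mirroring" interpreted as the diagonal
transpose (distinct from the two flips), giving 4× training data.

## Synthetic trials

The generator renders the geometry of a raised-bed nursery: beds 1.82 m wide
carrying two rows 0.91 m apart, ~0.5 m planted plots with 2 m alleys
(2.5 m range pitch), 1–2 cm/px GSD, wheel-track furrows (default 0.30 m
wide, 5 cm deep) on every bed boundary including the outer two — without
outer tracks the outermost beds would have no detectable boundary. Terrain
is an affine surface plus the furrow cuts, with optional i.i.d. Gaussian DSM
noise. Canopies are elliptical height bumps whose peak equals the plot's
true CH: bunch plots are compact and domed, spreading plots wide and
flat-topped; apparent mainstems carry a narrow along-row ridge (off-ridge
height reduced 14 %) with the peak unchanged. Colors are a jittered green on
jittered soil chosen so that canopy pixels always satisfy ExG−ExR > 0 and
soil never does. Class priors (50.8 % spreading, 65.7 % apparent) follow the
reference population. CH is drawn from a truncated normal on [16, 40] cm
whose *parent* mean/SD are solved numerically so the truncated distribution
has mean 24.8 cm and SD 6.37 cm — naively truncating a N(24.8, 6.37²) would
shift the realized mean to ≈25.7 cm and contradict the target moments.
Missing-plot and single-row rates default to 0 (a fully established trial)
and are exercised explicitly in tests.

What the synthetic scenes do *not* contain: weeds, senescent or lodged
vegetation, shadows, texture, photogrammetric artifacts, or georeferencing
error. Segmentation metrics therefore saturate near 1.0 — the synthetic
checks validate the pipeline's logic and geometry, not its robustness to
real-scene clutter; the thresholds they are held to are the ones a real
field achieves.

## Problem sizes and numerical choices

The test-suite and acceptance runs use 3×4 to 9×12-plot trials at 1–2 cm/px
(canvases up to ~2700×2700 px), a 0–180° sweep in 5° steps, and 60-patch
classifier datasets — sizes chosen so the full suite completes in a few
minutes on one CPU while every stage still runs at realistic resolution.
Raster rotation uses bilinear resampling (nearest-neighbour for label
rasters) with NaN fill for elevation; rotating out and back loses only a
thin boundary band (vegetation IoU ≥ 0.98 at 1 cm/px). Undefined metrics
(empty denominators, constant observations) are NaN, never 0. Hough ties and
square-mask orientation ties break toward the smaller coordinate/angle.

## Known limitations

Single field per scene, roughly centred; straight beds after rotation
(curved rows are out of scope); the classical backend requires a vegetation
signal (closed canopies merging across rows would defeat the
connected-component prompt model); the foundation-model adapter is untested
offline (it needs external weights); CH regression by learning is
deliberately absent — heights come from the nDSM directly.
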