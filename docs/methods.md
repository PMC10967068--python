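# Methods

This note records the models and procedures histotile implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the choices made where the design was genuinely open.

## Coordinate and magnification conventions

All geometry lives in the level-0 pixel frame: origin top-left, x
rightward, y downward, half-open regions. Physical (µm) coordinates
convert through the level-0 microns-per-pixel (MPP). Magnification labels
use the common brightfield anchor 10x ≡ 1 µm/px, stored as a pluggable
`MagnificationConvention` (so 40x ≡ 0.25 µm/px and a 453 µm / 299 px tile,
1.515 µm/px, labels as 6.6x). Scanner conventions for rounding labels are
not uniform, so the label precision is a parameter (default one decimal).

## Micron-based tile extraction

Given `tile_um` and `tile_px`, the required resolution is
`tile_um / tile_px`. The source level is the one with the largest MPP not
exceeding it (the nearest higher magnification); a square of
`round(tile_um / level_mpp)` px is read there and resized to `tile_px`.
Resampling is bilinear by default with Lanczos as an option; when the
source crop already has `tile_px` pixels the crop is returned untouched,
making native-resolution reads bit-exact. Slides whose finest level is
still too coarse raise an "insufficient magnification" signal that callers
may treat as skip-this-slide. Reads that would cross the slide boundary
are rejected; rounding at interior positions is clamped by at most one
source pixel.

Pyramid levels are fetched whole and cached. That is the right trade for
the synthetic and test-scale slides this package targets; a production
reader for multi-gigapixel slides would want windowed reads, which the
`reader` callable on `SlidePyramid` leaves open.

## Slide-level QC

QC runs on a thumbnail at a fixed resolution (default 16 µm/px) so that
its parameters are independent of scanner resolution; the resulting mask
is queried by physical footprint (nearest-neighbor in effect) during grid
construction.

*Otsu*: 256-bin histogram on 0–255 grayscale over non-excluded pixels;
threshold maximizes between-class variance (delegated to scikit-image's
histogram-based Otsu; an exhaustive scan serves as the test oracle).
Pixels strictly brighter than the threshold are background — H&E
background is near-white. The polarity is a parameter for inverted stains.

*Gaussian-blur filtering*: the target artifacts (uniform pen ink,
defocus, blank glass) share one property — no local texture. We compute
`gaussian(|laplace(gray)|, sigma)` and mask pixels whose energy falls
below a cutoff (defaults: sigma 3 px at thumbnail scale, cutoff 0.02 on
[0,1] grayscale, calibrated on the synthetic generator; vendor defaults
are not published). The mask is monotone in the cutoff by construction.

*Composition*: steps run in order; each later step receives the union of
earlier masks as its exclusion set, and the result is the union. This is
why blur-then-Otsu handles pen marks: ink pixels are flagged by blur
filtering first and therefore never enter Otsu's histogram, which would
otherwise read dark ink as foreground tissue. Any callable
`(thumbnail, exclude) -> QCMask` can be registered as a step.

One caveat the synthetic tests make visible: the blur detector cannot mask
the outermost border band of a smooth region (about 2–3 sigma at thumbnail
scale), because gradient energy from the boundary bleeds inward. The
pen-mark acceptance check therefore uses a centimeter-scale pen mark —
the realistic case — where the band is a small fraction of the area.

## Tile grid, ROI constraints and background filters

The grid is a regular lattice with stride ≤ tile width (overlap allowed);
optional jitter displaces each position by a seeded uniform offset up to
±stride/4. A tile is kept iff it passes the include-ROI test (vacuously
true when no include-ROIs exist), fails the same test against every
exclude-ROI, and its QC-masked footprint fraction is ≤ `mask_fraction_max`
(default 0.6). The ROI test is `center` by default — the tile center lies
in the polygon union, boundary counting as inside — with a `fraction` mode
(≥ x% area overlap) as an alternative. Polygons must be simple; shapely
does the geometry.

Grayspace marks a tile background when the fraction of pixels with HSV
saturation < 0.05 exceeds 0.6; whitespace when the fraction with mean-RGB
brightness > 230 exceeds 0.95. The published toolkits do not print their
defaults; these are conventional choices and fully configurable. Filtering
reads the tile footprint from the coarsest pyramid level that still gives
at least 8 px per tile, since background decisions do not need full
resolution.

Every extraction writes a lineage log: a canonical JSON of all parameters
(geometry, QC and filter settings, normalizer, codec, seed, software
version) with a SHA-256 digest, plus a machine-readable report of kept and
discarded counts; a visual report (thumbnail with kept/discarded overlay
and sample tiles) renders to PDF/PNG via matplotlib.

## Stain normalization

*Reinhard.* Channel-wise affine transfer in CIELAB:
`out = (in − mean_img) · std_ref/std_img + mean_ref`. The standard variant
first standardizes brightness (scale so the 95th-percentile mean-RGB
brightness maps to 240); the fast variant skips that step. The masked
variant computes statistics over, and transforms only, non-white pixels
(brightness < 230, the same convention as the whitespace filter, so the
two notions of background agree). Reference fits are computed on the
brightness-standardized reference, and bundled references are stored
standardized — consequently normalizing a reference under its own fit is
a fixed point up to rounding. Degenerate inputs (zero channel variance)
pass through with a warning rather than dividing by zero.

*Macenko.* Optical density `OD = −log10((I+1)/256)` (base 10, +1 offset
to avoid log 0). Pixels with any channel OD ≤ beta (default 0.15) are
transparent background and excluded from fitting; fits require ≥ 100
tissue pixels. The OD cloud is projected on its top-2 principal plane and
the stain vectors taken at the alpha / 100−alpha angle percentiles
(default alpha = 1), made nonnegative and unit-norm; hematoxylin is the
row with the larger blue-channel component. Concentrations solve the 2×3
least-squares system, clipped at zero (a fast stand-in for full
nonnegative least squares that is exact whenever the unconstrained
solution is already nonnegative, i.e. for genuine H&E mixtures);
per-stain maxima are 99th percentiles over tissue pixels. Normalization
estimates the input's own vectors and concentrations, rescales by
`ref_max / source_max`, and reconstructs through the reference vectors.
With a context image, `source_max` comes from the context instead
(contextual normalization) — stabilizing faint tiles — and a context with
no usable tissue warns and falls back to self-context, as does a
degenerate source fit (pass-through with warning).

*Augmentation.* The normalization target itself is perturbed: each fit
entry gets independent Gaussian noise (stain-vector entries and LAB
means/stds with `sigma_matrix`, Macenko concentration maxima with
`sigma_cmax`), stain rows re-normalized, then the ordinary normalization
runs toward the perturbed target. Zero sigma reduces exactly to plain
normalization. Defaults (0.05) keep augmented tiles in-gamut and are
implementation-defined — the magnitude used in prior art is unpublished.

*Synthetic stain model.* `make_stain_field` renders fields from a known
2-row stain matrix with blocky nonnegative concentration maps, a quarter
of whose patches are zeroed per stain. The sparsity matters: without
near-pure pixels (eosin-only stroma, hematoxylin-dense nuclei) the stain
vectors are not identifiable from angular extremes. The simulation basis
deliberately differs from the classic eosin vector (red component 0.07):
at realistic concentrations such pixels fall under the beta cut, making
exact recovery of that basis impossible for *any* Macenko implementation —
a property of the background cut, not of this one. The simulation instead
uses an eosin vector (≈[0.20, 0.95, 0.26]) whose components all clear beta
at unit concentration. The model emulates staining chemistry only — no
tissue morphology, no scanner noise — so a green recovery test establishes
correct deconvolution, not realism of tissue appearance. Vahadane
normalization (sparse-NMF) is out of scope.

## Tile store, labels and balancing

Records (`slide_id`, level-0 x/y, codec, encoded payload) are framed as
`uint32 length | JSON meta | payload` in an append-only stream with a JSON
header and an offset-index sidecar — TFRecord-like but framework-free.
Duplicate (slide, x, y) keys are rejected at write. JPEG writes default to
quality 100; PNG round-trips are bit-exact. Decode-time augmentation draws
uniformly from the 8 dihedral symmetries and applies random JPEG
re-encoding (quality 50–100, p = 0.1) and random Gaussian blur
(sigma ∈ {0.5, 1, 1.5, 2}, p = 0.1); probabilities are conventional
defaults, configurable. Standardization is per-image z-score or /255.

Labels join from a CSV (patient, slide, outcome); slides missing from the
table are reported, not dropped silently; numeric outcomes are continuous
unless flagged categorical. Balanced sampling draws with replacement:
`category` splits each batch equally across classes (within one when the
batch size is not divisible), `slide` across slides, `both` equalizes
classes then slides within class; minority strata are thereby oversampled
and an epoch may repeat tiles. One epoch is `floor(n_tiles / batch_size)`
batches in every mode.

## Aggregation, uncertainty and heatmaps

Slide predictions are the mean of tile probability vectors; patient
predictions pool all tiles across the patient's slides (not a mean of
slide means — slides contribute proportionally to their tile counts). Any
function from the n×C tile matrix to a C-vector may replace the mean.

Monte-Carlo-dropout statistics reduce K stochastic passes to a mean vector
and a scalar uncertainty: the population standard deviation of the
predicted-class probability (class 1 for binary problems; the
max-probability class for C > 2 — a documented scalarization with
alternatives pluggable). Two-stage confidence thresholding scans candidate
cutoffs (the unique uncertainty values) on validation tiles, maximizing
accuracy among retained predictions subject to a retention floor
(ties prefer the larger cutoff, hence higher retention); surviving tiles
are aggregated to slides and the scan repeats for the slide cutoff. The
scan runs per cross-validation fold over slides (default 3-fold) and the
final cutoffs average across folds, so a cutoff never sees the slides it
is evaluated on. The scan objective is a documented stand-in: the original
algorithm's exact objective is not restated in the source this package
follows. Degenerate inputs (all correct or all wrong) retain everything
with a warning. Applying thresholds drops tiles above the tile cutoff,
flags slides above the slide cutoff — or slides that lost every tile — as
low-confidence; slide uncertainty is the mean surviving-tile uncertainty
(simplest consistent pooling, implementation-defined).

Heatmaps place each tile's prediction (or uncertainty) at its grid cell,
NaN where no prediction exists; rendering draws NaN as transparent over an
optional thumbnail.

## Mosaic maps

The embedding bounding box (from the data, not figure axes) is split into
grid_n × grid_n uniform cells, half-open with the upper boundary closed.
Selection per nonempty cell is seeded-uniform (default) or
nearest-to-cell-centroid. UMAP runs with a fixed random state and library
defaults (recorded in lineage); PCA is the deterministic fallback for
tests. Rendering paints decoded tiles onto an RGBA canvas, empty cells
transparent.

## Synthetic slides

The generator renders: near-white background (µ ≈ 241, sd 1.5), tissue
discs at a muted H&E pink with coarse-grained texture (default grain
32 µm) plus fine noise, uniform saturated pen-mark polygons, and
Gaussian-defocused rectangles; coarser levels are anti-aliased
downsamples of level 0. Ground-truth tissue/pen/blur masks are registered
to level 0. The coarse texture grain is essential: real chromatin texture
survives downsampling to QC-thumbnail resolution, and iid pixel noise
would not, which would make synthetic tissue indistinguishable from
defocus at 16 µm/px. Output TIFFs carry resolution tags
(pixels/cm = 10⁴/MPP) and are byte-identical for identical spec and seed.
What the generator does not emulate: nuclei/cellular morphology, scanner
optics and compression artifacts, stain variability within a slide. Green
tests on synthetic slides therefore establish the geometry, masking and
bookkeeping contracts — not performance on real tissue.

## Numerical choices and degenerate inputs

- Otsu on a constant image (or with everything excluded) raises a
  degenerate-histogram error rather than returning an arbitrary cut.
- Mask-fraction queries use ceil/floor pixel bounds on the thumbnail grid;
  a footprint outside the grid counts as unmasked.
- Tie-breaks: ROI boundary counts as inside; threshold-scan ties prefer
  retention; mosaic cells iterate in sorted order so seeded random
  selection is order-independent.
- Seeds are threaded explicitly (numpy `default_rng`); nothing touches
  global RNG state. Store digests, lineage digests and synthetic TIFFs are
  reproducible byte-for-byte under a fixed seed.

## Known limitations

Only TIFF pyramids (and SVS-as-TIFF) are read; vendor formats, windowed
region reading for very large slides, learned QC models, GPU/tensor
implementations, and any network training or feature extraction are out of
scope — feature matrices and tile predictions enter as plain tables.
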