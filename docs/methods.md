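# Methods

This note documents the models, parameters and numerical choices
behind `nmjmorph`, and what the synthetic-data tests do and do not
demonstrate about real microscope data.

## Pipeline model and assumptions

The package assumes two registered z-stacks per specimen: channel 2 is
a terminal scaffold marker (Dlg1, Hrp, Syt or Csp) that delineates the
NMJ footprint, channel 1 an active-zone marker (Brp) forming bright
puncta inside that footprint. All 2D analysis (outline, skeleton,
boutons) is performed on the maximum-intensity projection; only
active-zone counting works in 3D. The skeleton is treated as planar
deliberately: larval NMJs spread along the muscle surface, their
branching structure is essentially two-dimensional, and a planar
skeleton is what human annotators trace. A polygon ROI per specimen
restricts all stages to one terminal (type 1b); drawing it is a human
task, the package only consumes it.

Default calibration is a 63x wide-field acquisition: 6.932 px/µm in
x/y, 42 planes at 0.3 µm. The confocal alternative (4.83 px/µm,
0.91 µm steps) is supported through the calibration options and the
`confocal` spot preset.

## Automatic thresholds

Four 256-bin histogram criteria are implemented from their original
formulations and verified against exhaustive 255-candidate scans:

* **Rényi entropy** — maximum-entropy thresholds at orders ρ→1
  (Shannon/Kapur), ρ=½ and ρ=2, blended by the published three-value
  weighting rule (thresholds within 5 bins of each other count as
  agreeing). Used for the terminal outline, and for the skeleton with
  Hrp staining.
* **Li minimum cross entropy** — found by direct scan rather than the
  fixed-point iteration; on shallow criterion curves the iteration can
  settle away from the discrete minimum, and the scan is the
  definition. Selects systematically wider segmentations than the
  entropy criterion on unimodal-plus-shoulder histograms, which is why
  it drives the skeleton stage for Dlg1/Syt/Csp.
* **Huang fuzzy** — minimizes the Shannon entropy of the fuzzy
  membership function; provides the automatic intensity floor for
  wide-field spot detection.
* **Moments (Tsai)** — moment-preserving split; drives the
  vesicle-marker bouton variant.

Conventions, stated because the classical papers leave them open:
foreground is strictly above the returned bin; candidate thresholds
need mass on both sides; ties and float-flat plateaus resolve to the
smallest qualifying bin (a relative tolerance of 1e-9 on the criterion
guards the tie-break against last-digit rounding). Images of any bit
depth are mapped linearly onto 256 bins over their own [min, max]
range, and histograms are always built from within-ROI pixels only, so
content outside the ROI cannot bias the threshold.

## Background subtraction

The rolling-ball background (radius 20 px by default) is computed as
the grey-level opening of the image by a ball-shaped (hemispherical,
non-flat) structuring function — the ball is rolled under the
intensity landscape and its upper envelope is the background. The
opening is evaluated exactly with scipy's non-flat grey morphology;
note this differs from implementations that report only the
erosion-based ball apex without the dilation pass. One consequence
worth knowing: structures wider than the ball diameter in both axes
are treated as background, so the radius must exceed the half-width of
the terminal (20 px against typical 10–30 px tubes is adequate).

## Watershed bouton counting

Boutons are watershed basins of the Euclidean distance transform of
the binary footprint. Seeds are regional maxima of the distance map
with plateaus merged; additionally, maxima whose dome rises less than
1.0 EDT unit above the connecting saddle are merged into one seed
(h-maxima). This tolerance absorbs digitization plateaus and the ~1 px
ridge ripple produced by segmentation-boundary noise, while any real
interbouton constriction produces a dome several pixels high. Regions
of at least 100 px (10 px in the vesicle variant, always preceded by
the small-particle filter and a 2 px dilation) count as boutons; the
area floors are applied as ≥, and sub-floor watershed fragments stay
part of the outline for area/perimeter, which are measured before
splitting.

The scaffold-marker bouton count is knowingly biased: when
constrictions are shallow (neck nearly as wide as the bouton, typical
of Dlg1), the distance ridge is flat, seeds merge, and the count drops
below truth. The test suite pins this down as a directional behavior
(shallow-constriction fixtures are undercounted) rather than an
accuracy claim; accurate counting is the job of the vesicle-marker
variant, whose dark interbouton gaps make the segmentation trivial.

## Skeleton graph

The wider segmentation is thinned by homotopy-preserving 2D
skeletonization. Skeleton pixels are classified by 8-neighbor count
(1 endpoint, 2 path, ≥3 junction); mutually adjacent junction pixels
form one junction node, honoring the definition that one branching
point connects three or more branches. Three cleanup rules, all
raster-artifact driven:

* terminal edges shorter than `spur_prune_um` (default 0.5 µm ≈ 3.5 px
  at 63x) are removed and the mask re-thinned and re-classified once;
* junction pairs linked by an internal edge shorter than the same
  floor collapse into a single junction (thinning occasionally splits
  one wide branching region into two junction pixels a step apart);
* pure cycles (possible when boutons fuse into loops) become a
  self-loop edge whose length is the cycle length.

Edge geometric length is measured along the traced pixel path through
every 4th pixel plus the endpoint (chord subsampling). Raw chain-code
summation (1 per axial, √2 per diagonal step) inflates oblique digital
lines by up to ~8%, which would be the dominant error of the length
features; the subsampled chord is exact on axial and diagonal lines
(so a 70 px horizontal line still measures 69 px) and within ~1% on
oblique ones. Total length is the sum over edges; the longest branch
is the maximal cycle-free endpoint-to-endpoint path, found by
exhaustive simple-path search (skeleton graphs here have a few dozen
nodes at most; beyond a 50-node cap the weighted diameter is used and
a quality flag raised); islands are connected components, branches are
edges, branching points are junction nodes.

## Active-zone detection

The spot stack is first closed in grey-scale with a ball of radius
1 voxel (fills sub-element dark dips inside a punctum so it yields a
single maximum). A voxel is maximal if ≥ all 26 neighbors; touching
maximal voxels merge into one spot (centroid reported). The noise
tolerance is a prominence test — a maximum survives only if it rises
more than the tolerance above its surrounding saddle — implemented via
the h-maxima transform, which makes the count provably non-increasing
in the tolerance. Spots must strictly exceed the intensity floor and
fall inside outline ∧ ROI in x/y. Presets: wide-field uses the Huang
auto-floor on the within-footprint histogram of the closed stack (the
values actually searched) and a tolerance of 10% of the
within-footprint dynamic range; confocal uses tolerance 100 and floor
250 in intensity units. Voxel anisotropy (0.3 µm z vs ~0.14 µm x/y) is
ignored in the neighborhood definitions; at these spot densities the
isotropic 26-neighborhood is adequate and matches the simple
"horizontally/vertically or diagonally" adjacency rule.

## Agreement statistics

Lin's ccc uses population (1/n) moments, per the original derivation;
the 95% CI is the Fisher-z interval with Lin's asymptotic standard
error, degenerate at |ccc| = 1. Percent deviation is
(manual − macro)/manual × 100, so a method reading high yields a
negative deviation. The per-object sensitivity/specificity pair
follows the protocol convention this package mirrors — sensitivity =
TP/(TP+FP), specificity = TP/(TP+FN) — which is nonstandard
(conventionally precision and recall); the result object carries both
namings to prevent downstream confusion. Object matching itself
(which detection corresponds to which manual object) is out of scope:
the function consumes pre-matched counts.

## Synthetic generator

`synthgen` renders what the pipeline must cope with: a random polyline
tree per island (leaf tips split into 2–3 arms, directions ≥ 30°
apart, arms kept clear of one another so the rasterized topology is
exactly the planted one), tubes of configurable width, bouton discs
centered on the arms (Dlg1 style: continuous tube with constrictions
set by `neck_ratio`; Syt style: disjoint discs with dark gaps), a
Gaussian axial intensity profile across planes, constant/ramp/blob
backgrounds, per-plane Gaussian PSF blur, and white sensor noise.
Spots are planted by rejection sampling inside the eroded footprint
under a 3D minimum-separation constraint (default 8 px). Everything
derives from one seeded generator, so outputs are bit-identical per
seed. Defaults reflect a realistic wide-field acquisition: 42 planes,
0.3 µm steps, 6.932 px/µm, 2 islands, 6 branches, ~250 spots. Spot
fixtures quote SNR as rendered peak over noise sd: amplitude 1000 with
σ=1.5 px blur gives a ~500-count peak, so noise sd 50 is peak SNR 10.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: anisotropic and depth-varying PSFs,
shot-noise statistics, staining heterogeneity along the terminal,
subsynaptic texture inside boutons, muscle autofluorescence, 1s/1b
terminal mixtures, and registration error between channels. Synthetic
recovery rates are an upper bound on real-data performance; the
agreement statistics on real data are the published validation route.

## Test and acceptance problem sizes

The suite runs entirely on generated data at desk scale: 320–384 px
frames, 6–42 planes, 25 random trees for topology recovery, 30
Syt-style fixtures for bouton recovery, 10 full-depth stacks with
50–300 spots for active-zone recovery. The acceptance script uses 3
noiseless specimens end to end, 12 noisy specimens for the agreement
statistics, 15 Syt fixtures and 3 deep stacks. These sizes were chosen
so each property is exercised well inside a single-CPU desk budget
while leaving the measured margins (e.g. length errors ≤ ~4% against a
5% bound) visible rather than averaged away.

## Known limitations

* The bouton count from scaffold markers is structurally unreliable
  (see above); use the vesicle variant for bouton-centric questions.
* Perimeter uses a boundary-pixel-center contour with 1/√2 step
  weights; like all chain-code estimators it runs a few percent above
  the continuum perimeter of smooth shapes (a radius-50 disc measures
  ~5% high). Comparisons between conditions measured with the same
  estimator are unaffected.
* ROIs are consumed, never drawn; there is no automated 1b/1s
  discrimination.
* Channel registration, deconvolution and proprietary microscope
  formats are out of scope; convert to per-plane TIFF first.
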