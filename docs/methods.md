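# Methods

## Scope and data model

The package analyzes one isolated adherent cell per field of view, imaged in
two fluorescence channels (ECFP donor, FRET/acceptor) as multi-page TIFFs
with one frame per minute. Acquisition metadata — flow direction as a unit
vector `(d_row, d_col)` in image coordinates, stimulus onset frame, frame
interval, pixel size — travels in a flat key/value sidecar file, since TIFF
tags for these fields are nonstandard. Ingestion is strictly
value-preserving: pixels are promoted to float64 and never rescaled,
whatever the on-disk bit depth. Images are indexed `[frame, row, column]`,
0-based, origin top-left. Flow direction is metadata, never assumed: a flow
running bottom-to-top of the image is `(-1, 0)`.

## Pipeline stages and their conventions

**Background.** The camera offset plus stray light is taken as the mean of
the four corner windows of each frame, per channel and per frame (so slow
illumination drift over a 30–60 min run is tracked). Window size defaults to
8 × 8 px: large enough to average noise, small enough that a centered cell
with the generator's 16 px margin never touches it. Subtraction clamps at
zero; negative intensities have no physical meaning and would poison the
ratio.

**Despeckle.** A median filter over a `(2r+1)²` window, `r = 1` by default,
with replicated borders. `despeckle_radius_px: 0` disables the filter; that
is the appropriate setting for noise-free synthetic data, where the filter's
only effect is a slight bias at the cell boundary (the median mixes in
background zeros). Recovery tests on noise-free data therefore run with the
filter off; noisy-data tests run the full default chain.

**Segmentation.** "Edge recognition" is implemented as a deterministic,
parameter-free chain: global Otsu threshold over the nonzero intensities of
the donor channel (channel selectable), largest 4-connected component, hole
fill. If all nonzero pixels share one value (a clean two-level image) the
threshold is placed at half that value, which recovers the support exactly.
A segmented cell must cover at least `min_cell_area_px` (200 by default);
otherwise the frame errors, or — with `mask_propagation` — inherits the
previous frame's mask, for transiently dim frames.

**Ratiometry.** The per-pixel ratio is FRET/donor on the mask. Pixels whose
background-subtracted donor falls below `donor_floor` are excluded and
counted rather than allowed to blow up the ratio; the default floor is twice
the donor frame's corner-pixel SD (a noise-scale proxy), configurable as an
absolute value. The whole-cell value per frame is the unweighted mean of
per-pixel ratios ("average ratio of the whole cell"), not the ratio of
summed intensities; the alternative weighting is available via the profile
options for sensitivity checks. The series is normalized by the mean over
all pre-stimulus frames, which exists by contract (`stimulus_onset_frame >=
1`). An in-vitro helper computes the 475 nm / 515 nm emission ratio of a
spectrum by linear interpolation between bracketing samples.

**Flow-axis profile.** Valid pixels are projected onto the flow vector; the
projection range over the mask is cut into 50 equal-width slabs, bin 1 at
the largest projections (downstream: where the flow exits the cell), bin 50
upstream. Each bin's percentage is its ratio-weighted share of the cell
total, so the raw profile sums to 100 by construction. Figure conventions in
this field label these "ratio percentages", hence ratio values are the
default weights; raw-intensity weighting is a config switch. Bin edges are
recomputed from each frame's own mask extent because cells deform under
flow; `edges_mode: fixed` freezes frame-one edges instead, clipping outside
pixels into the end bins. Per-bin normalization divides each bin's trace by
its own pre-stimulus mean; a bin with zero pre-stimulus signal is flagged
invalid and carried as missing, never as zero (zero is a meaningful
percentage).

Two numerical choices make the profile's symmetry guarantees exact rather
than approximate:

* Per-bin sums are accumulated with `math.fsum`, which returns the
  correctly rounded sum of a multiset and is therefore independent of pixel
  scan order — jointly rotating the image and the flow vector by multiples
  of 90° changes the iteration order but not the result.
* A pixel whose projection lands exactly on an interior bin edge
  contributes half its weight to each adjacent bin. No all-or-nothing
  assignment rule can make profile reversal under flow-vector flip exact (a
  pixel on the central edge would need to map to "bin 25.5 of 50"); the
  half-split rule makes both the flip-reversal and the 90°-rotation
  identities hold exactly whenever projections are computed exactly, as
  with axis-aligned flow on integer pixel coordinates.

**Spatio-temporal map.** Normalized profiles stack into a 50 × T matrix
(pure reshaping; missing frames are NaN columns when tolerated). Rendering
is a heatmap with the bin axis labeled downstream → upstream and a stimulus
marker; it is purely presentational.

**Polarity test.** Per cell, the mean of normalized bins 1–5 is the
downstream value, bins 46–50 the upstream value, read at the frame closest
to the chosen time after onset (30 min by convention). Averaging five
regions damps single-slab discreteness. The test compares these per-cell
values across replicate cells with a two-tailed two-sample t-test — cells
are the independent units; pixels within a cell are not. Welch
(unequal-variance) is the default for robustness; the pooled-variance
Student variant is selectable to mirror spreadsheet t-tests. Two identical
zero-variance groups return p = 1 rather than NaN. Polarity is called at
p < alpha (0.05).

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes: a single
elliptical cell (default semi-axes 40 × 28 px in a 128 × 128 field, ≥ 16 px
background margin so corner windows stay clean), donor baseline 500 counts,
ratio baseline 1.2, background offset 100 counts per channel, frame interval
60 s, stimulus at frame 10. The ratio field is

```
R(x, t) = ratio_baseline · (1 − d·s(t)) · (1 + g·u(x)·s(t)),
s(t) = 1 − exp(−(t − t0)/τ) for t ≥ t0, else 0,
```

with `u(x) ∈ [−0.5, +0.5]` the normalized flow-axis coordinate (+0.5
downstream). Defaults: decay amplitude `d = 0.25` (whole-cell drops of
roughly 20–40% are what the live-cell literature reports for this kind of
stimulus; ~25% is the canonical mid value), time constant τ = 300 s, so the
response effectively plateaus within a 30-min observation; gradient `g = 0`
unless a polarized condition is simulated. The gradient term is gated by
the same kinetics `s(t)` as the decay, because polarity is a *response* to
flow — a gradient present from frame 0 would cancel identically under
per-bin pre-stimulus normalization and could never produce a polarity
signal. A `gradient_onset: "static"` option bakes the gradient in from the
start for exactly that kind of null check. The exponential-approach form of
`s(t)` is a modeling choice (responses decrease and then stabilize); no
claim is made that real kinetics are single-exponential.

Noise is Poisson (photon) plus additive Gaussian read noise (SD 5 counts, a
typical cooled-CCD scale), applied after the offset; intensities clamp at
zero. Bleaching is per-channel exponential in frame index, off by default.
All randomness flows from one integer seed, so stacks are bit-reproducible.
Cohorts draw per-cell decay, gradient, and baseline from normal
distributions around the condition values (default SDs 0.05, 0.05, 0.10 —
the few-percent cell-to-cell scatter seen across replicate cells), jitter
the geometry, and derive per-cell seeds from a master seed via
`SeedSequence`, so cohorts are reproducible piecewise.

The generator also computes its own closed-form expectations: the
normalized whole-cell trace `(1 − d·s(t))(1 + g·ū·s(t))` and per-bin
normalized traces by an independent per-pixel loop over the true ellipse.
These are the oracles for the recovery tests.

What the generator does **not** emulate: optical blur (no PSF), cell
motility and deformation, channel crosstalk and bleed-through, uneven
illumination, multi-cell fields, focus drift. Passing recovery tests
therefore demonstrates that the analysis chain is correct and unbiased for
data matching its geometric and photometric assumptions — not that it is
robust to every artifact of real microscopy.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks use 100 random 32 × 32 instances per operation at
1e-9 tolerance. Noise-free recovery runs the full pipeline at 128 × 128 ×
20 frames for d ∈ {0.1, 0.25, 0.4} × g ∈ {−0.4, 0, 0.4} with τ = 120 s (two
frame intervals), so the final frame sits within 10⁻³ of the asymptotic
plateau `1 − d`; recovery there is exact to machine precision. These runs
use a cell whose flow-axis span (79 px) is coprime with the 50 bins, so no
pixel sits exactly on an interior bin edge and the independent truth loop
needs no tie-break of its own. Noisy recovery uses 5 seeds at the default
noise model and 40 frames. The polarity calibration measures the noise
floor of the up/down summaries from one full-pipeline null cohort (8 cells,
41 frames, read at 30 min) and then evaluates type-I error and power of the
t-test over 1000 replicate cohorts drawn at that noise scale — the
replicate dimension is simulated at the summary level, where the test
actually operates, keeping the calibration at n = 1000 tractable while the
image pipeline itself is exercised end to end by the cohort runs.

## Known limitations

* Segmentation assumes one dominant bright object; debris larger than the
  cell would be picked instead.
* Otsu on heavy-tailed intensity histograms can bite into dim cell
  peripheries; the donor floor then excludes those pixels from ratios,
  which is visible in the per-frame exclusion counts of the diagnostics.
* The 50-bin profile is a 1-D marginal along the flow axis; orthogonal
  spatial structure is integrated out by design.
* The t-test treats cells as exchangeable replicates; no mixed-effects
  structure, and p-values are per-comparison (no multiplicity correction),
  matching the field's reporting convention.
* Exactness of the rotation/flip symmetries holds at the assignment level;
  for non-axis-aligned flow vectors, floating-point projections make them
  exact only up to representation of the projections themselves.
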