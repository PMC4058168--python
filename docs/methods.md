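# Methods

## Scope and data model

The pipeline consumes an ordered stack of grayscale frames (values in
[0, 1]) of a longitudinal carotid view and produces, per case: a wall
segmentation, a sub-pixel inner-boundary track, per-ROI radial distension
signals, a spatiotemporal map (time × ROI), a spatiospectral map
(normalized frequency × ROI), five scalar features, and a three-way class
call. Rows index image depth (row 0 at the top), columns are the
longitudinal axis; all ranges are 0-based and half-open.

## Synthetic phantom

No suitable public dataset exists for this kind of wall-motion analysis, so
the generator is a first-class component, not a test fixture. It renders a
single horizontal wall band (the analysis tracks the most prominent of the
two walls, so one suffices) between an anechoic lumen above and speckled
tissue below.

**Geometry and intensities.** Defaults are 128×256 px, 120 frames at
30 frames/s spanning 3 cardiac cycles. With a plausible in-plane resolution
of ≈0.045 mm/px this corresponds to a ≈11.5 mm segment; the 16 px band
matches a ≈0.7 mm intima–media complex, and the default 2 px motion
amplitude a ≈0.1 mm single-wall distension. Mean gray levels: lumen 0.05,
wall 0.85, tissue 0.35. The band carries a layered radial profile (bright
intima, echolucent media dip at 45% depth, bright adventitia) and a
multiplicative texture field that is defined in wall coordinates and moves
rigidly with the band; tissue carries its own static texture. A static
smoothed multiplicative speckle field of relative strength `speckle_scale`
(default 0.05) covers the scene, plus per-frame additive noise of standard
deviation `0.01·speckle_scale` — deliberately below both the 8-bit
quantization step and the no-wall detector's 1e-3 temporal-std floor, so a
zero-amplitude phantom is still recognized as static.

**Motion.** The inner boundary at column x and frame t sits at
`wall_row − d(x, t)` with

```
d(x,t) = A·[ P(x) · s_c(φ(t − x/c)) + band(x, φ) ]
```

where `A` is the amplitude in pixels, `c` the longitudinal phase velocity
(default 40 px/frame, i.e. the pulse wave crosses the field of view in ~6
frames), `φ` the cardiac phase, and `s_c` the per-category waveform: damped
sinusoids with 3 local maxima per cycle (young, unit peak), 2 maxima at 0.4
peak (elderly: slow, faded), and 2 maxima at 0.65 peak (CAD — slower and
weaker than young, per the visual phenomenology the classes are defined by).
CAD cycles are additionally jittered per cycle in amplitude (±0.3·irr),
phase (0.8·irr) and frequency (±0.35·irr), drawn deterministically from the
seed and cycle index.

`P(x) = 1 + (0.04 + 0.05·het)·sin(3πx/W)` modulates amplitude along the
wall. The fixed 4% baseline reflects that even a healthy wall never
distends perfectly evenly; it vanishes at column 0 so the boundary trace
there equals the pure waveform exactly. `band(x, φ)` is the spectral
heterogeneity mechanism: a sum of equal-amplitude sinusoids on the DFT bin
grid between 4 cycles/cycle and a per-position upper edge

```
f_edge(x) = 4 + (f_Nyq − 4) · het^0.7 · g(x),    g(x) ∈ [0, 1] smooth,
```

with a smooth spatial gain, common random phases, and overall scale
`1.2·het/√n_comp`. Heterogeneity therefore widens the local motion
bandwidth along the wall — at `het = 1` some positions cover nearly the
whole spectrum — rather than merely rescaling a fixed waveform. An
amplitude-only heterogeneity cannot work here: the downstream envelope
feature max-normalizes the across-ROI spectral standard deviation, so any
purely multiplicative disagreement cancels out of the feature.

**Ground truth** returned with each phantom: the wall mask at its
time-averaged position, the exact sub-pixel boundary `b(t, x)`, and the
mean-removed radial signal (positive toward the lumen). Identical
configuration and seed give bit-identical output.

**What the phantom does not emulate:** beam point-spread functions and RF
speckle statistics, longitudinal tissue motion, out-of-plane decorrelation,
probe pressure drift, plaques and focal stenoses, and frame-rate jitter.
Passing tests demonstrate that the pipeline recovers known motion from a
speckled, layered, moving scene — not clinical performance.

## Segmentation

The reference frame is the pixelwise temporal median of the sequence.
Spatial features use a 9×9 window (reflection-padded): mean, population
standard deviation, and Shannon entropy in bits over a fixed 16-bin
intensity histogram — 9×9 spans the texture grain without blurring away the
band at the default scale; entropy with 16 bins is stable in an 81-pixel
window. The fourth channel is the per-pixel population standard deviation
across frames. All four channels are z-scored (constant channels dropped)
and clustered with k-means, k = 3, k-means++ with 10 restarts, best inertia,
fixed seed. The wall cluster must have mean neighborhood intensity above the
global median (visibility guard) and, among those, the largest mean temporal
standard deviation; below 1e-3 the scene is declared static ("no wall
found"). The mask is that cluster's largest 4-connected component after
morphological closing (disk radius 2).

## Boundary tracking and ROIs

The lumen side is the side of the mask with lower mean reference-frame
intensity. Per frame and column, the intensity profile from the lumen into
the wall is searched within ± half the mask thickness of the reference mask
edge; after 1-2-1 smoothing along the profile (suppresses impulsive bracket
switches on textured walls while preserving a symmetric edge's crossing
exactly), the boundary is the linear sub-pixel crossing of the
half-maximum level, shifted +0.5 from pixel centers to the geometric edge.
Columns without a crossing (or columns absent from the mask) are filled by
linear interpolation along the wall; the usable range is the longest
contiguous column window with ≥90% direct detections in aggregate.

ROIs of even width w start every w/2 columns: `R = ⌊(L − w)/(w/2)⌋ + 1`,
trailing columns dropped. The default width targets ~16 ROIs
(`w ≈ 2L/17`, rounded down to even), matching the ROI counts visible in
the original maps. Each ROI's radial signal is the mean boundary row over
its columns, oriented positive toward the lumen, with the temporal mean
removed (mean-referencing is phase-shift friendly, and the spectral stage
discards DC anyway).

## Maps and features

Per ROI column the mean is removed and the one-sided DFT magnitude kept for
bins 1..⌊n/2⌋, divided by n so a unit sinusoid reads 0.5 regardless of
sequence length; the frequency axis is bin/(n/2) with 1 at Nyquist. No
taper is applied by default (a Hann option exists) — the phantom's cycles
fit the window exactly and the features compare relative shapes.

* FT² area: one-sided DFT magnitude of the mean-removed ROI-averaged
  spectrum, normalized by the bin count F; the scalar is
  `100·(2/F)·Σ(curve)`. The reporting constant 100 just places typical
  values in a readable range.
* Ramp feature: the across-ROI population standard deviation per frequency
  bin is divided by its maximum; its upper envelope interpolates linearly
  through the strict local maxima (endpoints always included as knots, an
  elementwise maximum enforces dominance); the scalar is
  `ln(mean(f·env) + 1e-6)` — the natural log spreads the small-area regime,
  and ε guards the all-zero (perfectly homogeneous) case, which reports the
  floor ln(1e-6) ≈ −13.8 and should be treated as degenerate.
* Legacy band areas: the mean of the ROI-averaged spectrum over 0 < f ≤ 1
  and over 0 < f ≤ 0.15, as simpler single-curve summaries. They are
  computed on the mean spectrum; selecting a single best ROI (as the older
  analysis they derive from did) is out of scope.

## Classification

FT² votes pathological when the area falls *below* its threshold, the ramp
feature when it rises *above* its threshold; ties resolve to healthy.
Combination rules: `either_positive` (default — a case is pathological if
either feature says so), `either_agrees` (both must), or either feature
alone. A non-pathological case is young-like when its FT² area reaches the
young floor and the ramp vote is negative. The shipped defaults
(27.3 / −0.1 / 33.8) are the published clinical values for a different
feature normalization and exist as documented anchors only; on any other
normalization, fit thresholds with `calibrate_thresholds` (an exhaustive
midpoint scan maximizing accuracy, ties to the lowest threshold). An
optional `suspected_margin` labels cases whose features sit within a band
around both thresholds as `suspected`, off by default. Cohort metrics use
pathological as the positive class and report NaN with a warning when a
rate's denominator is zero.

## Numerical choices and degenerate inputs

Population (ddof = 0) standard deviations throughout. Envelope of an
all-zero curve is all-zero (no division by a zero maximum). Sequences need
≥8 frames; spectra need ≥8 frames and ≥1 ROI (≥2 for the std curve); the
threshold scan needs both classes, and a single distinct value falls back
to the majority-class accuracy. k-means requires at least k distinct
feature vectors. All stochastic steps (phantom fields, per-cycle jitter,
k-means restarts) are seeded; two runs with the same configuration produce
byte-identical feature files.

## Problem sizes

Defaults were chosen so that one full case — generation, segmentation,
tracking, maps, features — takes about half a second: 120 frames of
128×256 px, ~16 ROIs, 60 spectral bins. The shipped cohort study uses 15
cases per class; the paired heterogeneity comparison uses 10 seeds at three
levels. These sizes give stable cohort statistics (separation margins are
several times the within-class spread) while keeping a complete run on a
single CPU in the low minutes.

## Known limitations

Thresholds and absolute feature scales are normalization-specific by
construction. The tracker assumes one roughly horizontal wall with the
lumen consistently on one side; vessels crossing the frame diagonally or
both walls in view require cropping. The ECG is schematic (used for map
alignment and rendering, not gating). Sensitivity/specificity against
clinical truth cannot be validated synthetically; the cohort-level numbers
this package computes describe phantom populations only.
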