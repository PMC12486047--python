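# Methods

This note documents the models, the parameter defaults and why they were
chosen, what the synthetic cohort does and does not emulate, and the
numerical conventions used throughout `vascbci`.

## Coordinate and labelling conventions

All geometry is in RAS millimetres.  The rostro-caudal ("coronal") axis
is `y`, anterior positive; the midline plane is `x = 0`.  Cortical
regions are modelled as four exhaustive rostro-caudal bands — SMA, M1,
S1, and everything caudal of S1 — assigned per vertex by half-open
interval `[lo, hi)`, with `OTHER` outside the bands.  Slice grids bin
the rostro-caudal axis into half-open mm intervals indexed from a
configurable origin; the midpoint of an even-width interval maps to the
nearest slice index with exact `.5` ties resolved to the nearest even
index (IEEE round-half-even), so the tie rule is deterministic and
unbiased over scenes.

## Motor signal strength

The statistic chain per test block:

1. **High-gamma isolation.**  4th-order Butterworth band-pass
   (100–200 Hz) applied forward and backward (`sosfiltfilt`): zero
   phase, effective magnitude response the square of the single-pass
   response.  Requires `fs > 2 × 200 Hz`; the synthetic default is
   1 kHz.
2. **Burst detection.**  Envelope = 20 ms moving RMS.  Threshold =
   baseline median + `k`·(1.4826 × MAD) with `k = 3`; the baseline is
   the channel's own envelope restricted to the REST epochs of the same
   block, which makes the operator self-contained per block and robust
   to slow drift.  Excursions shorter than 20 ms are discarded and
   excursions separated by less than 10 ms are merged.  All four
   constants are exposed in `BurstConfig`; published descriptions of
   comparable systems do not pin them down, so they are configuration,
   not science.
3. **Epoch densities.**  A burst belongs to the epoch whose half-open
   interval `[start, end)` contains its *onset* (no double counting).
   Default aggregation pools counts over active channels before
   dividing by epoch duration, making densities additive over channels;
   `mean` (invariant to channel duplication) and `best_channel` are
   alternatives.
4. **Sensitivity index.**  `d' = (μ_move − μ_rest) / √((σ²_move +
   σ²_rest)/2)` with unbiased sample variances.  If both variances are
   zero: 0 for equal means, ±∞ (flagged degenerate) otherwise;
   degenerate blocks are excluded from downstream correlations.

A participant's signal strength is the maximum block d′ over all blocks
of all sessions, ties to the earliest session.  Session values are
tested against zero with a two-sided Wilcoxon signed-rank test, exact
null for n ≤ 25 after dropping zeros; fewer than 5 sessions is refused
because the exact test cannot reach significance there.

With Poisson burst counts pooled over `c` channels in epochs of `T`
seconds, the expected index for per-channel rates `(r_m, r_r)` is
`√(2Tc)·(r_m − r_r)/√(r_m + r_r)`; the generator inverts this in closed
form to plant a target d′.  At 10 + 10 epochs the single-block d′
estimator has a coefficient of variation near 25%, which is why the
pipeline measures each participant over several sessions and takes the
best block.

## Implant geometry

The device is modelled as a 25 mm polyline through the middle of the
sinus: the rostral tip is the centerline point nearest (by rostro-caudal
station) the most rostral point of the device segmentation, and the line
follows the centerline caudally until its arc length reaches 25 mm,
resampled at 0.5 mm spacing (51 points) so quadrature error is
sub-millimetre.  Distances are therefore mean device-to-cortex
separations, not the smallest clearance of the nearest electrode — the
model deliberately carries no per-electrode information.

- **Distances.**  Per line sample, nearest pial *vertex* per hemisphere
  (k-d tree); the summary mean averages the two per-hemisphere nearest
  distances at each sample (accounting for cortical folding under the
  vessel), and the minimum is global over samples × hemispheres.
  Vertex (rather than point-to-triangle) distance is adequate at the
  synthetic mesh resolution (≤ 1.5 mm spacing ⇒ ≤ 0.75 mm bias); the
  summary is exact against a brute-force all-pairs scan by
  construction.
- **ROI overlap.**  Defined purely on the rostro-caudal axis: the
  percent of the stent's rostro-caudal interval intersecting each
  band's interval.  Band intervals are estimated from vertices within
  15 mm of the midline (the dorsal strip; configurable), with band
  edges at midpoints between adjacent labelled stations so exhaustive
  bands tile the axis exactly and overlaps sum to 100.  Edge estimates
  are accurate to half the vertex spacing.
- **Sinus width.**  2 × lumen radius linearly interpolated at each line
  sample, averaged — a 51-point quadrature of the width profile.
- **Cortical thickness.**  Mean per-vertex pial-to-white Euclidean
  separation over a region's vertices, pooled across hemispheres.

## Slice-based targeting

Per-vertex activity within the dorsal strip is binned by slice; each
slice's value is the mean over its strip vertices.  The center of
gravity is the mass-weighted mean station after clamping negative
values to zero (a mass interpretation requires non-negativity; a
threshold-first variant is available).  The stent's slice span is the
set of slices whose bins intersect its rostro-caudal interval with
positive length; slice-based M1 coverage is `100 × |stent ∩ M1| /
|stent|` slices.  The signed CoG-to-stent distance is positive when the
activity centroid lies rostral of the stent midpoint.  Surface- and
slice-based coverage agree within one slice-width of percent on shared
scenes, and refining the grid changes the estimate by less than one
coarse-slice equivalent.

## Predictor screen

Sixteen user-specific factors are screened against signal strength with
Spearman correlations: years since diagnosis, residual muscle strength,
active channels, mean activation and suprathreshold spread (z > 2.3,
strict) in SMA/M1/S1, mean and minimum stent-to-cortex distance, sinus
width, overlap with SMA/M1/S1, and M1 thickness.  No published list
pins the exact factor set; this reconstruction spans the five factor
families (clinical, functional, neuroanatomy, neurovasculature, device)
and is configurable.  P-values are uncorrected by design (the screen is
exploratory); Benjamini–Hochberg is available behind a flag.  For
n ≤ 9 the Spearman p enumerates the full permutation null (vectorised
over an `(n!, n)` table); above that a t approximation with n − 2 df is
used.  Constant factors are flagged degenerate and ranked last rather
than failing the screen.

Lasso selection standardizes features and centers the response, fits a
60-point log-spaced penalty path by coordinate descent, and picks the
penalty by leave-one-out CV with the one-standard-error rule (the
largest penalty within one SE of the minimum CV error) — the sparser,
more stable choice at n ≈ 10.  Standardization is refit inside every
fold: with more factors than participants, scaling by full-data moments
leaks the held-out response into the design and collapses the CV error
(measured: LOO MSE 0.003 leaky vs 7.7 honest on one cohort), so
fold-internal scaling is load-bearing, not stylistic.  Rank tests
(signed-rank, rank-sum) use exact null distributions for small
tie-free samples and the tie-corrected normal approximation otherwise.

## The synthetic cohort

`vascbci.synth` generates scenes with known ground truth:

- **Surfaces.**  Two mirrored hemisphere sheets; the pial sheet is a
  lateral dome with sinusoidal rostro-caudal folds (amplitude 2 mm,
  wavelength 12 mm), the white sheet the pial offset inward along
  vertex normals by the cortical thickness.  Default bands: SMA
  [45, 70), M1 [20, 45), S1 [5, 20), caudal [−40, 5) mm.
- **Sinus and stent.**  The centerline runs along the midline above a
  15-mm-smoothed dorsal profile (a dural venous sinus bridges sulci
  rather than dipping into them); stent points lie exactly on the lumen
  wall across the requested span.  Per-participant lumen radius ~
  N(3.55, 0.45) mm clipped to [2.5, 4.8] so sinus width varies across
  the cohort around 7.1 mm.
- **Recordings.**  Pink (1/f amplitude with a white floor) background
  noise at 10 µV RMS on all 16 channels; on active channels, bursts are
  an independent Poisson process per epoch label.  A burst is an 80 ms
  Gaussian-windowed 150 Hz tone at 5× the in-band noise SD.  Planted
  onset times are stored as ground truth.  At the default move rate the
  detector undercounts slightly (bursts colliding within the merge
  window) while dead-time effects reduce count variance; the two biases
  nearly cancel, and the measured block d′ median matches a pure
  Poisson-count oracle to within a few percent.
- **Cohort.**  Ten participants by default.  Years since diagnosis ~
  U[1, 12]; muscle strength an integer 0–50 declining with duration;
  active channels ~ U{9..16}; M1 thickness declines 0.09 mm/year from
  3.2 mm (planting the atrophy–duration and atrophy–strength
  correlations).  The stent's M1 overlap fraction is drawn across
  10–95% and realised caudally (excess in S1/caudal) or, with
  probability 0.3, rostrally (overshooting into SMA) plus 1.5 mm
  placement jitter — the rostral branch exists because purely caudal
  placements make S1 overlap an exact mirror of M1 overlap, an
  artificial collinearity no real cohort has.  The planted relation is
  `d' = 0.2 + 0.05 × (realised M1 overlap %) + N(0, 0.3)`, chosen so
  best-session values span roughly 0.7–5 and cohort-level correlations
  land near 0.8–0.9, the scale of effect the analysis is designed to
  detect; per-channel move rates are then obtained by the closed-form
  Poisson inversion given each participant's active-channel count
  (rest rate 0.5 bursts/s/channel).
- **Sessions.**  Three test sessions per participant by default, the
  response being the best block across them, reflecting repeated
  longitudinal testing; a single session leaves the response dominated
  by single-block estimator noise.

What the generator does *not* emulate: real cortical folding geometry
and sulcal ROI boundaries (bands are rostro-caudal strips),
vascular branching or non-midline vessel courses, spatially correlated
or non-stationary noise, artifacts, electrode-level gain differences,
disease progression within a participant, and any coupling between
functional activation maps and signal strength (activation maps are
noise with respect to the planted relation).  Passing tests therefore
show that the analysis recovers relations of the planted kind at the
study's scale and noise level — not that it is robust to every artifact
of clinical recordings.

## Problem sizes

The test suite and acceptance script run cohorts of 10 participants
with 3 sessions each; the end-to-end recovery property uses 50 seeded
cohorts (plus 20 null cohorts), and the d′ oracle comparison uses 15
measured blocks against 10,000 Poisson draws.  These sizes give
stable pass/fail behaviour for rates asserted at the 80–90% level.

## Known limitations

- Band-interval extraction assumes each region occupies one contiguous
  rostro-caudal interval in the dorsal strip; a union-of-runs mode
  would be needed for fragmented labels.
- Vertex-based distances inherit mesh resolution; the point-to-triangle
  refinement is not implemented.
- The exact Spearman permutation is capped at n = 9 (9! ≈ 3.6 × 10⁵
  permutations); larger cohorts fall back to the t approximation.
- The d′ inversion assumes ideal Poisson counting; detector
  imperfections compress the planted scale by a few percent at high
  rates.
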