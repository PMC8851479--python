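# Methods

## Scope and data model

The package analyzes open-field calcium-imaging sessions of medial
entorhinal cortex (MEC) populations: a tracking table (time, position, head
direction), per-cell deconvolved event amplitudes aligned to frames, and
per-cell soma positions (µm) with region labels (MEC / PAS / excluded).
Real recordings are interchangeable with the synthetic sessions produced by
`synthio`; everything downstream consumes the same structures.

## Synthetic sessions

**Trajectory.** Foraging is modeled as an Ornstein–Uhlenbeck speed process
(mean 15 cm/s, relaxation 0.8 s⁻¹, noise sd 0.5·mean — so a zero-speed mean
yields a frozen path) with a diffusing heading (1.4 rad/√s).  Near walls
(within 8 cm) the heading steers smoothly toward the arena center
(gain 1.5 s⁻¹); residual contacts reflect.  Pure reflection produces long
wall-running bouts that give head-direction cells genuine border-like
spatial structure; gentle wall avoidance, which OU-foraging simulators
commonly include, keeps the position–heading coupling weak while 20-min
sessions still visit ≈ 99 % of 2.5-cm bins.  Head direction is the movement
heading plus 8° Gaussian noise.  Sampling is 7.52 fps; sessions default to
80×80 cm.

**Rate models.** Grid: rectified sum of three cosines on a hexagonal
lattice, λ ∝ max(0, Σⱼcos(k uⱼ·(x−x₀))/3) with k = 4π/(√3·spacing); spacing
~ U(35, 55) cm, orientation U(0°, 60°), uniform phase.  HD: von Mises,
λ ∝ exp(κ(cos(θ−θ₀)−1)), κ ~ U(4, 8).  Border: exponential decay from one
wall, depth U(4, 8) cm.  OV: Gaussian bump at object + (r, θ) offset,
r ~ U(10, 30) cm, width U(6, 10) cm (several objects combine by maximum).
Untuned: constant rate.  Event amplitudes are Poisson counts per frame times
lognormal(0, 0.5) single-event amplitudes — heavy-tailed like deconvolved
transients.  Optional dF/F convolves events with a τ = 1.5 s exponential
(GCaMP6-class indicators) plus Gaussian noise; it feeds only the SNR filter,
never the analyses.

**Layouts.** Somata are placed in a 367×558 µm FOV: uniformly
(intermingled), around per-class Gaussian centers (clustered), or split by
class across a boundary at fixed x (territory), with a deterministic
fraction (`mixing`) of each class placed uniformly to soften the boundary.
Territory cells are labeled MEC/PAS by side.  Two frozen reference
scenarios set the study conditions for parameter recovery, calibrated once
against the session-mean effect sizes the topography analysis is expected
to report: territory FOVs of 300 cells (100 grid, 100 HD, 50 border, 50 OV;
boundary 180 µm; mixing 0.58) give normalized grid-vs-HD NN distances of
1.13 ± 0.08 across sessions, and clustered FOVs (100 grid cells, σ = 180 µm,
over 200 intermingled others) give grid starter 5-NN values of 0.94 ± 0.04.

**What the generator does not emulate:** raw movies, motion artifacts, ROI
segmentation errors, spike-to-calcium nonlinearity, theta dynamics,
behavioral idiosyncrasies (thigmotaxis bouts, rearing), cross-session cell
registration noise, or grid modules/spacing gradients.  Passing tests
therefore validate the statistical machinery under a clean generative
model, not robustness to every artifact of real imaging data.

## Tuning scores

Spatial maps use 2.5-cm bins, a 2.5 cm/s speed filter, and Gaussian
smoothing (σ = 1.5 bins) applied to binned amplitude and dwell time
separately before division; unvisited bins are missing (never zero) and all
correlations are pairwise-complete.  Direction tuning uses 60 bins (6°)
with wrapped smoothing (σ = 1 bin).

**Autocorrelogram and grid score.** The autocorrelogram is the Pearson
correlation of the map with itself at every integer offset over bins
defined in both copies (≥ 20 overlapping bins, FFT-accelerated).  For
gridness the rate map is first masked to its inscribed disk: per-offset
Pearson normalization on a square window is itself four-fold anisotropic
(corr at 90° ≈ 1 even for an isotropic map), which would bias a
rotation-based score; the disk restores rotational symmetry so a single
place field scores ≈ 0.  The annulus spans the central peak's extent
(contiguous r ≥ 0.3 region) to 1.25× the median distance of the six
nearest surrounding peaks (fallback: the largest radius still ≥ 95 %
defined all-around); GS compares annulus correlations at 60°/120° against
30°/90°/150°.

**Border score.** Fields are connected components ≥ 30 % of the map peak
with ≥ 20 bins; c_M is the largest single-wall coverage by a single field;
d_m is the rate-weighted mean distance of field bins to the nearest wall
(edge bins count zero) normalized by half the arena side.

**Object-vector maps.** Frames are binned by distance (2.5 cm) × allocentric
angle (6°) of the animal relative to the object; numerator and denominator
are smoothed (σ = 1.5 bins, wrapped in angle) before division — unsmoothed
polar bins at 7.52 fps are too sparse for a stable cross-session Pearson.
The OV score is the correlation of the two object sessions' polar maps over
bins defined in both (≥ 100).

**SNR.** Peak event-triggered dF/F over 1.4826×MAD of the trace at least
2τ from any event; cells with no events are dropped, noiseless transients
cap at 10⁶.

## Classification

Null distributions circularly shift the event series against tracking by
uniform offsets in [30 s, T − 30 s] (preserving the series'
autocorrelation) and recompute the score; 100–300 shuffles per cell.
Percentile cutoffs use the *higher* order statistic, which makes the
nominal exceedance of the 95th cutoff (n+1-rank argument) ≈ 5 % exactly;
linear interpolation would inflate it to ≈ 6 %.  Grid/HD/border flags are
single-score criteria; OV flags require all of: (i) OV score above the
cutoff of shuffle nulls built from either object session, (ii) the
best-matching field's centroid at least one equivalent field radius from
every wall (a field overlapping a wall is indistinguishable from a border
response), and (iii) arena-frame map correlation across the two object
sessions below the object-frame correlation (the field moves with the
object).  Purity: exactly one flag ⇒ pure; two or more ⇒ conjunctive; a
parallel tally includes conjunctive cells.

## Composition statistics

The discrimination index (n_grid − n_OV)/(n_grid + n_OV) is undefined when
both counts are zero.  Cross-class Spearman correlations filter sessions
below 15 cells.  The grid/OV label-shuffle experiment labels
⌊932·0.5⌋ = 466 cells grid and 466 OV among 4,399, draws samples of 129
without replacement, classifies each by majority, and excludes ties;
sampling uses the exact nested-hypergeometric equivalence of index
sampling (a per-sample binomial relabeling variant sits behind a flag and
shifts the summaries by < 0.01).  Conditional summaries (means/SDs of
fractions and discrimination index) are reported per classification.

## Topography statistics

All NN statistics size-match by randomly downsampling the larger group to
the smaller (100 subsample rounds by default), exclude pairs closer than
10 µm (overlapping-ROI guard, applied per pair), and are normalized by
label permutations over the full recorded population of the session (1,000
by default; positions are never jittered, only labels move).  Within-class
clustering compares the starter group's mean distance to its k = 5 nearest
groupmates against size-matched subsets of the non-starters (Ref) and of
all cells (All), normalized to All; a median-pairwise-distance variant is
provided.  Minimum group sizes: 5 (interclass), 15 (clustering).

## Spring-loaded graph

Edge weights are 1/normalized NN distance on the complete grid-HD-border-OV
graph.  Layout is Fruchterman–Reingold (networkx) in 2-D with optimal
distance k = 1/√4 and linear cooling, 1,000 iterations from seeded random
initial positions.  The separation ratio divides the grid node's distance
to the centroid of the other three by their mean pairwise distance; it is
invariant to rigid motion and scaling.  The null permutes the six observed
weights over the six edges (not redrawing them) and relayouts from fresh
random positions; with the session-mean weights the null median is ≈ 0.83,
close to the equal-weight limit where the layout converges to a square
(ratio 2√2/3/((2+√2)/3) ≈ 0.8284).

## Topographic maps

FOVs are aligned with least-squares similarity transforms on ≥ 3
non-collinear landmark pairs (residual RMS reported; SSIM between the
reference and warped mean image as quality).  Scores are binned at 20 µm
(30 µm in the bundled analyses of composite animals) with the per-bin mean
over all cells of all aligned sessions; empty bins are missing.  Moran's I
uses queen contiguity over defined bins; its null scrambles the
score-to-cell assignment over the pooled cells and rebuilds the map
(salt-and-pepper control).  Map correlations smooth both maps (Gaussian,
σ = 2 bins, missing-aware normalized convolution) and correlate jointly
defined bins; delta = r − median(null) with the same scramble null, and the
across-animal discrimination ratio counts animals above the 95th minus
below the 5th null percentile over the number of animals.

## Numerical conventions and degenerate inputs

Missing scores are NaN, never silently zero.  Constant maps have undefined
autocorrelations (except the center), zero-variance maps have undefined
Moran's I, coincident non-focal graph nodes give an undefined separation
ratio.  A stationary trajectory under the speed filter raises an
empty-occupancy error.  All randomness flows from integer seeds through
`numpy.random.SeedSequence`; per-cell streams key on a CRC of the cell id,
so any session is bitwise reproducible.

## Problem sizes in the bundled runs

The test suite and scripts run at desk scale, chosen as the package's own
defaults: classification checks use 100 shuffles per score and 300–1,200 s
sessions; parameter recovery uses 100 sessions per scenario with 25–50
subsample rounds and 100–200 label permutations; the acceptance script uses
6,000 label-shuffle samples and 1,000×1,000 spring-model permutations.

## Known limitations

Grid-score annulus detection on very noisy shuffled maps occasionally fails
(NaN samples are dropped from the null).  The OV wall criterion evaluates
the first object session only.  The label-shuffle fraction summaries depend
on the chosen denominator (sample size); the discrimination index does not,
which is why it is the headline quantity.  Normalized NN statistics on
territory layouts compress non-focal classes into a shared sub-region, so
their within-pair values can dip slightly below 1 — a property of the
scenario, not of the estimator (exchangeable layouts calibrate to 1).
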