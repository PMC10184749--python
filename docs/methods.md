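# Methods

`somatolayers` implements, end to end on synthetic cortical surface data, the
analysis logic used to test whether the 3-D structural architecture of the
human primary somatosensory (BA 3b) hand area is topographic: are individual
finger representations separated by low-myelin borders (septa), ordered along
a structural gradient, or distinguishable in their laminar microstructure
profiles?  Real 7T quantitative MRI data for this question are not publicly
deposited, so the package pairs every analysis with a generative model whose
ground truth is explicit, making each stage falsifiable.

## The synthetic world

**Cortical patch.** A regular triangulated grid (default 40 × 60 vertices at
0.26 mm spacing, the vertex-to-vertex distance of a high-resolution inflated
surface) stands in for the BA 3b hand region.  Rows run inferior→superior
(y), columns anterior→posterior (x).  Grid-cell diagonals alternate
orientation per row so the edge graph has no global diagonal bias.  An
optional cylindrical bend makes geodesic and chord distances differ, so the
shortest-path machinery is exercised non-trivially.

**Depth profiles.** Quantitative values are sampled at 21 intracortical
depths, depth 1 at the CSF surface and depth 21 at white matter.  The
canonical qT1 profile (ms) decreases from ~2160 to ~1496 with a localized
dip-and-recovery around depths 9–12 — the signature of the heavily
myelinated outer Band of Baillarger — and a flat plateau over the two deepest
depths.  Its construction is derivative-first: the profile was designed so
that the second derivative of the 21-sample central-difference estimate
crosses zero steeply and exactly at depths 4 and 11.  Consequently the
anatomical layering below recovers an outer/middle/inner split of 4/7/8
depths, with compartment means ≈ 2115/1863/1670 ms (within 1.1% of the
reference values 2105/1884/1658), and the split survives i.i.d. noise of 1%
of the profile range in ≥ 97% of repeats.  A strictly monotone profile
cannot achieve that robustness: with the range fixed by the compartment
means, monotonicity caps the curvature available at the crossings; the dip
is therefore a structural feature of the stated world, not a cosmetic one.
Companion profiles: nQSM (ppm) is u-shaped and everywhere ≤ 0 with its
maximum (closest to zero) at mid-depth; pQSM is a top-hat with an upper peak
at depth 8 (middle compartment) and a lower peak at depth 15 (inner);
aQSM decreases monotonically from outer to inner.

**Ground truth and injections.** Five finger bands (D1 inferior … D5
superior) tile the patch; each vertex in a band gets a ground-truth pRF
center on the ±12.5-unit sensory axis (5 units per finger), varying linearly
with y within the band, and width σ = 2.  Optional injections, all additive:

* *Septa*: a Gaussian cross-section in surface distance (default sd 0.5 mm)
  at a named band border, elevating qT1 (low myelin) at all depths with a
  depth weight peaking in the middle compartment (0.4 + 0.6 · Gaussian at
  depth 8, sd 3.5).  The default +80 ms elevation is a sensitivity knob —
  no published value exists for a hypothetical finger septum.
* *Gradient*: linear in y, normalized over the D1-to-D5 band-center span so
  the slope is in units of the normalized geodesic distance used downstream.
* *Body part*: a "face" band placed 10 mm inferior to the D1 band with
  per-compartment offsets (default: face qT1 lower by 30/0/37 ms in
  outer/middle/inner — an interaction-generating pattern; small negative
  pQSM/aQSM offsets).

Measurement noise is i.i.d. Gaussian per vertex × depth (defaults: 60 ms
qT1, 0.002 ppm QSM — chosen so that per-vertex SNR and the resulting
group-level SEMs of ~5–30 ms are in the range of laminar qMRI data).
Cohorts jitter band centers (default sd 0.26 mm, one vertex spacing) and
profile amplitude (~3% relative sd) between participants; the laminar shape
itself is shared, treating it as a population feature.  All generation is
bit-reproducible from the ground-truth parameters and seed.

**Functional runs.** The phase-encoded design is 20 cycles of 25.6 s (each
finger 5.12 s per cycle; forward or reverse order), TR 2 s, 256 volumes,
with 3 randomly placed 180 ms attention gaps per finger (15 per run).  The
blocked design stimulates each finger 10 times in pseudorandom order (never
more than twice in a row) with counterbalanced 2 s (70%) / 6 s (30%)
pauses (416 s ≈ 208 volumes).  BOLD is the ground-truth Gaussian pRF drive
evaluated at the stimulated finger's axis position, convolved with a
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6 — configurable; no
HRF is stated for the original protocol), sampled at TR, plus Gaussian
noise (default sd 0.8 against a unit-amplitude drive).

What the generator does **not** emulate: volumetric/k-space physics,
registration and segmentation error, spatially correlated noise, vascular
structure, within-finger pRF scatter, or pin-level stimulus detail.  A green
test therefore establishes that the *analysis logic* behaves as claimed on
data satisfying its assumptions — not that the original acquisitions would.

## Layer compartmentalization

Derivatives of the 21-depth group qT1 profile are central differences
between neighboring samples (one-sided at the ends); extrema of the first
derivative are located at the zero crossings of the second derivative,
linearly interpolated and snapped to the nearest sampling depth.  Two
estimator details are ours (the source method does not state them): the two
boundary intervals are excluded from the crossing search (their second
derivative rests on one-sided differences and is ~1.9× noisier), and
adjacent extremum pairs whose first-derivative prominence is below 15% of
the derivative range are pruned as noise.  The anatomical scheme drops the
two deepest (plateau) depths, takes the first-minimum depth as the last
outer depth and the first-maximum depth as the last middle depth.  The
equally spaced scheme drops 3 superficial + 2 deep depths and splits the
remaining 16 into four compartments of four.  Functional (BOLD-derived)
maps are never layered anatomically; they use the 20–100% depth mean
(dropping the 4 most superficial of 21 samples) to suppress surface veins.

Equivolume depth placement solves the quadratic cumulative-volume equation
for a linear area interpolation between the pial and white surfaces;
positions are fractions of thickness from the outer surface.  Note the
direction: with a larger outer area, equal-volume shells are thinner near
the outer surface, so the half-volume surface lies *nearer the outer
boundary* (verified against brute-force shell-volume integration to 1e-6).

## Topography estimation

Blocked runs are fit per vertex by OLS with five HRF-convolved finger
regressors plus intercept; each finger's t-map uses the contrast +4 on that
finger and −1 on the others.  Vertices with zero residual variance relative
to signal power are flagged and their t set to 0 — in particular, exactly
noise-free simulations have no defined t, so "noiseless" localization tests
run at SNR ≈ 100.

Phase-encoded runs are fit with a 1-D Gaussian pRF (center x, width σ) on
the sensory axis: an omnibus F prefilter (p < 0.05 uncorrected), a grid
search (x in 0.25-unit steps, σ in 20 log-spaced steps over [0.5, 25] —
1/10 of a finger to the whole hand), then bounded Nelder–Mead refinement of
the residual sum of squares with ties broken to smaller σ.  Model
confidence is the posterior probability of the pRF model against an
intercept-only model via a BIC approximation to the Bayes factor,
thresholded at 0.95 — a declared surrogate for the variational posterior
model probability of the original toolbox; it preserves the selection
semantics, not the numerical values.  Centers at the extreme axis ends
(|x| ≳ 10) are only weakly identifiable (one active finger plus a free
amplitude leaves a flat x–σ ridge); errors there (~1 unit) remain inside
the correct finger bin.  Winner-takes-all labelling assigns each vertex the
finger whose 5-unit bin contains its center; overlapping candidate labels
resolve to the highest explained variance.  Finger activation peaks are the
maximum-t vertices inside each pRF-restricted ROI.

## Geodesic analyses

Paths are graph geodesics (Dijkstra over mesh edges with Euclidean weights,
ties to the lowest predecessor index), matching the surface-based
shortest-path approach; exact polyhedral geodesics are out of scope.
Functional borders are the first crossing of two fingers' t-vectors sampled
along the peak-to-peak path, snapped to the bracketing vertex with the
smaller |t difference| (earlier vertex on ties); structural values exist
only at vertices, so no sub-vertex interpolation is attempted.  Pairs whose
t-vectors are not in peak-to-peak orientation or never cross are excluded
for that participant, reducing that pair's n only.  Gradient samples take
each compartment map along the D1→D5 peak path (D2→D5 when D1/D2 appear in
reversed order) with distances normalized to [0, 1].  Corridor sampling
draws five equally spaced parallel paths (outermost ±2 vertex spacings from
the D1 seed) from a face anchor 10 mm inferior of D1 through the seed row
to the D2 axis, keeping vertices within one vertex spacing of each line,
and reads middle-compartment qT1 along them; the axis can be switched to x.

## Inference

**Septa.** For each neighboring pair × compartment, qT1 at the two peaks
(averaged) is compared with qT1 at the border by a one-sided JZS paired
Bayes factor (H1: peak < border, i.e. a low-myelin border; Cauchy prior
scale 0.707, with a robustness sweep over [0.1, 2]).  BF10 is computed by
marginalizing the noncentral-t likelihood of the observed paired t over the
(truncated) Cauchy prior with adaptive quadrature under a tan substitution;
the reported numerical error is the quadrature's relative error estimate
(not the error measure of any particular GUI package).

**Gradients.** Layer-specific values are regressed on normalized geodesic
distance with random intercepts and slopes per participant: maximum
likelihood via statsmodels MixedLM (Wald z intervals; singular
random-effects covariance falls back to random-intercept-only, flagged),
and a conjugate Gibbs sampler (4 chains × 2000 iterations, first 1000
warmup, 4000 retained draws; split-chain R̂ with a 1.01 convergence flag).
Priors: layer-specific normal intercept priors for qT1 (outer 2058 ± 483,
middle 1770 ± 294, inner 1703 ± 183), slope priors centered at 0 with the
same sd; QSM priors from the physical value ranges (±0.125 signed,
[0, 0.125] absolute; mean = half the range center, sd = a quarter of the
range).  Random-effect variances are independent per component
(inverse-gamma hyperpriors) — a diagonal simplification of the full
covariance an HMC fit would use; the slope BF10 is the Savage–Dickey density
ratio at 0 with a Gaussian KDE posterior density.  Bonferroni thresholds:
0.05/3 for three anatomical layers, 0.05/4 for the equally spaced scheme.

**Structure ANOVAs.** Two-way within-subject ANOVAs (layer × finger; layer ×
body part) are computed from explicit sums of squares with per-effect
Greenhouse–Geisser ε; the correction applied follows the violation size (GG
if ε < 0.75, Huynh–Feldt if 0.75 ≤ ε < 1, none at ε = 1, e.g. any 2-level
factor).  η² is effect SS over total SS.  Post hoc: two-tailed paired t
(effect size r = √(t²/(t² + df))) and Wilcoxon signed-rank, at
Bonferroni-adjusted α.  Extreme outliers (outside Q1 − 3·IQR, Q3 + 3·IQR;
linear-interpolation quartiles) trigger a with/without rerun.  The robust
one-way repeated-measures ANOVA uses 20%-trimmed level means over a
winsorized error term with h = n − 2·floor(0.2 n) and Huynh–Feldt-style
ε-adjusted degrees of freedom (Wilcox-style); its null rejection rate
calibrates to 0.03–0.07 at α = 0.05.  With trim 0 the same routine is the
classical ε-adjusted one-way RM ANOVA, used when all level distributions
pass Shapiro–Wilk.

**Similarity.** Finger profiles are embedded as 2-D polylines (depth scaled
to [0, 1]; values min–max scaled with the participant's pooled five-finger
range per contrast, so shape rather than amplitude drives distances — the
pooling choice is ours; a z-score mode exists).  The discrete Fréchet
distance is computed by dynamic programming over the coupling lattice.
Profile meta-parameters are bias-corrected sample skewness and excess
kurtosis of the 21 depth values (a raw-kurtosis flag exists).

## Numerical and design notes

* Everything stochastic is driven by `numpy` Generators seeded from the run
  config; cohorts use `SeedSequence.spawn`, so runs are bit-reproducible.
* Cohort-level pipeline runs default to ground-truth pRF topography (t-maps
  are always estimated by GLM); full pRF estimation per participant is
  available via `AnalysisConfig(topography="fit")` and is validated by its
  own recovery, false-positive and SNR-monotonicity tests.
* Participant exclusion is per-analysis: a missing peak or crossing reduces
  n for that pair/path only, and each output table reports its n.
* Known limitations: graph geodesics overestimate true surface distance by
  the usual metrication bias; the BIC confidence surrogate is not the
  variational posterior probability; the Gibbs sampler's diagonal
  random-effect prior understates intercept–slope correlation; corridor
  "equal spacing" is exact only on the regular grid.
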