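# Methods

## The analysis problem

A hidden-platform Morris water maze experiment produces, per animal and
trial, a 10 Hz swim path in a 170 cm circular pool.  Learning is
multidimensional: escape latency, path efficiency, goal proximity and
wall-hugging each capture a different, noisy facet of it, and no single
variable is a sufficient summary (latency, for instance, confounds
learning with swimming speed).  This package implements a multivariate
analysis built around a supervised PCA of group summary vectors,
variance decomposition with permutation inference, and censored mixed
models for the single-variate view — exercised end to end on a synthetic
cohort generator, since the motivating class of experiments rarely
deposits raw tracking data.

## Pool geometry and metric definitions

Coordinates are pool-centered, in cm.  Defaults: pool radius 85 cm,
platform radius 6 cm with its edge 22 cm from the wall on the NE
diagonal (center ≈ (40.3, 40.3)), trial cutoff 60 s at 10 Hz (600
samples).

* **Latency**: time of first sample within the platform radius;
  censored at the cutoff when the platform is never contacted.  Probe
  trials (platform removed) run a fixed 60 s and are censored by
  convention.
* **Distance**: summed Euclidean inter-sample steps.  **Speed** =
  distance / latency per trial — a path-average, chosen because an
  instantaneous-speed average is not identifiable from the same data
  once the path is resampled.
* **Gallagher proximity index**: per-sample distances to the goal,
  averaged within consecutive 1 s blocks (10 samples); block means are
  then averaged, a trailing partial block being averaged over its own
  length (not dropped).
* **Whishaw corridor index**: % of path length inside the capsule of
  half-width `corridor_half_width` around the straight release→goal
  segment; a sub-step counts only when both endpoints are inside.  The
  corridor width is not standardized anywhere; the default half-width is
  platform radius + 6 cm = 12 cm and is an explicit, reported parameter.
* **Thigmotaxis**: % of samples with radius ≥ pool radius − band width.
  "Periphery" has no published convention either; the default band is
  the outer 20 % of the radius (17 cm), also explicit and configurable.
  Note that a release at the wall forces even a perfectly direct swim to
  spend its first ~18 cm inside this band, so per-trial thigmotaxis has
  a geometric floor of roughly 10–15 % for direct paths.
* **Quadrant occupancy**: sample shares per quadrant of the
  pool-centered axes; points exactly on an axis are assigned to the
  counterclockwise-adjacent quadrant ([0°, 90°) → NE and so on), a
  deterministic tie-break.

Cued (visible-platform) trials are a motivation/vision control: subjects
with cued latency ≥ 30 s ("less than 30 s" read strictly) are excluded
from all analyses.

## Synthetic cohort generator

The generator is the package's stand-in for real tracking data and
defines the study conditions for every test.  The default cohort is
2 genotypes × 4 treatments with group sizes 10, 11, 14, 11, 11, 9, 12, 8
(86 subjects); the protocol is 1 pretraining trial (visible platform at
the pool center), 5 acquisition sessions × 4 trials (release points a
per-session permutation of N/S/E/W), a probe trial, a cued trial and 3
reversal sessions × 4 trials with the platform point-reflected through
the pool center (the concrete reading of "opposite quadrant").

Movement is a discrete-time heading-persistence random walk: the new
heading is the normalized mixture

    g · (bearing to goal) + t(1−g) · (wall direction) + (1−t)(1−g) · (previous heading)

rotated by Gaussian noise (SD 1.2 rad per step), with step length =
speed × 0.1 s and speed drawn once per trial from N(base, 2) cm/s.  The
wall direction mixes the tangent (0.85) with the outward radial (0.15)
so a wall-follower stays pressed against the rim; steps leaving the pool
are clamped radially back onto the disc, which preserves the in-pool
invariant without rejection sampling.  The goal weight g grows linearly
across sessions, g = clip(g₀ + rate·(session−1), 0, 1) — this is the
learning model.  Group parameters (weight of wall-following t, g₀, rate,
base speed) encode the qualitative structure of the motivating design:
wild-type groups learn fastest; enrichment and combined-treatment
trisomic groups learn at intermediate rates; untreated and EGCG-only
trisomic groups stay nearly flat; trisomic groups have elevated
wall-following; EGCG lowers base speed.  Per-subject Gaussian effects on
learning rate (SD 0.025) and base speed (SD 1.5 cm/s) create the good
learner / poor learner stratification seen in real cohorts.  In the two
analytic limits the model degenerates correctly: g = 1 with zero noise
gives a straight path to the platform; t = 1, g = 0 gives pure
wall-following and certain censoring.

Randomness uses one master seed with counter-based substreams keyed by
(subject, phase, session, trial), so outputs are bit-reproducible and
adding subjects or phases never perturbs other subjects' draws.

What the generator does **not** emulate: momentum/inertia of real
swimming, wall-release behavioral artifacts, inter-trial carry-over,
circadian or handling effects, and any raw-video noise.  Tests passing
on this generator therefore validate the *analysis chain* — metric
computation, ordination, inference — not claims about real mouse
behavior.

A fast path (`generate_metric_table`) draws per-subject-session metric
vectors directly from a truncated multivariate normal with
group×session means and a one-factor covariance; it is used where only
the joint distribution of the seven metrics matters (calibration
studies), because downstream stages are pure functions of the metric
table.

## Supervised PCA and supplementary points

Session means (the four trials averaged) are summarized by group
medians — medians for robustness to outliers — giving a G·S × 7 table.
Columns are Z-scored with the **population** (1/N) variance; the sample
(N−1) alternative is rejected because it would make the between-group
variance (N−1)/N instead of exactly 1.  The SVD of the scaled table
gives orthonormal variable loadings, eigenvalues λ_p = s_p²/N (summing
to 7 at full rank), and row scores U·s in distance-preserving principal
coordinates: pairwise row distances equal those of the Z-scored table to
machine precision.  Where "standard coordinates" might instead mean
axis-standardized scores, both conventions give V_B = 1 at full rank but
differ for V_BS; the distance-preserving choice is implemented and
documented rather than guessed silently.  Percent variance is computed
at full rank, and variable contributions are 100 · (squared loading) /
(column sum of squared loadings).

Axis signs are fixed deterministically: PC1 is oriented so the Gallagher
loading is negative (high PC1 = close to target = good learning), PC2 so
the speed loading is positive; remaining axes make their largest-|loading|
entry positive.

Individuals enter only as supplementary points: each subject-session
vector is centered and scaled by the *model's* constants and mapped
through the loadings.  Projection is affine and reproduces a median
row's own score exactly.  The reversal sessions reuse the identical
machinery on their own G×R median table.

## Variance decomposition and permutation inference

All variances share one form, V = (1/(n_vars · N)) Σ d_i², with d_i the
full-rank distance from the origin.  V_B (median rows, N = G·S) equals 1
by construction under population Z-scaling — this identity is the
pipeline's structural invariant and a free regression test of scaling,
SVD and bookkeeping; `scripts/acceptance.py` recomputes it from scratch.  V_T uses the supplementary individuals;
V_BS uses the squared norms of per-session G-group-average coordinates
(N = S); V_WS = V_B − V_BS.  Because distances from the origin are
rotation-invariant, the whole decomposition can be recomputed from the
Z-scored tables without any PCA; the test suite keeps this brute-force
oracle and requires agreement to 1e-9.

Permutation tests draw uniform random partitions of subjects into groups
of the original sizes; a subject's sessions always travel together.  The
full pipeline (medians → Z-scaling → PCA → supplementary projection →
decomposition) is re-derived at every draw.  The separation statistic is
V_WS as % of V_T, upper tail: real group structure both raises V_WS's
share and shrinks individuals' scaled scatter.  Learning contrasts use a
Welch two-sample t (group sizes are unequal, 8–14) on supplementary PC1
at one session, two-sided; all pairs are evaluated on the same
permutation stream, and a max-|t| familywise-adjusted p is reported
alongside the raw per-pair p since the adjustment convention for
permutation p-values is otherwise unspecified.  p-values use the
add-one convention (1 + #{null ≥ observed})/(1 + B) and can never be 0;
with B = 10⁴ the attainable floor is just under 10⁻⁴.

## Censored mixed models

Latency is analyzed on the log scale with the censoring bound at
log 60.  The model is a Gaussian random-intercept regression of the
latent response on session (numeric 1..S, a linear learning trend),
group, and their interaction, with the subject intercept capturing
repeated-measures correlation.  Censored rows contribute
P(y* ≥ c | u) = Φ((μ + u − c)/σ_e).  The random intercept is integrated
by **adaptive** Gauss–Hermite quadrature: the integrand's per-subject
mode is found by Newton iterations (it is log-concave) and the nodes are
recentered and rescaled there.  Order 16 then agrees with order 64 to
~1e-9 on realistic fits; plain non-adaptive quadrature at order 16 was
measured at ~2e-4 and rejected.  Optimization is BFGS on
(β, log σ_u, log σ_e) with 3-point finite-difference gradients from an
OLS-based start plus jittered restarts; Wald z-tests use the
pseudo-inverse of a numerical Hessian (the pseudo-inverse matters when
σ_u estimates at its boundary, where the Hessian has a near-null
direction).  Setting the bound to +∞ recovers the ordinary mixed model
(verified against statsmodels MixedLM), and additionally dropping the
random intercept recovers OLS to 1e-6.

Two reference codings are reported, against untreated wild-type and
untreated trisomic groups; Benjamini–Hochberg adjustment is applied to
the session×group slope contrasts.  Classical repeated-measures ANOVA
(pingouin's mixed ANOVA) with Tukey HSD on subject means covers the
single-variate analyses.

Known limitation: ML variance components are biased low by O(1/m) in the
number of subjects, and right-censoring amplifies this (≈ −0.02 on
σ_u = 0.4 at 50 subjects × 5 sessions with 30 % censoring, shrinking to
≈ −0.009 at 200 subjects).  Fixed-effect slopes — the quantities the
analysis reports — are unbiased at these sizes.  No REML-type correction
exists for the censored case, so the bias is documented rather than
patched.

## Problem sizes and numerical choices

Default analysis sizes follow the motivating design (86 subjects, 40
median rows, 430 supplementary points).  Simulation-based tests use 200
replicates where a rate or a sampling mean is asserted (permutation
type-I error at B = 500; censored-model recovery at 50 subjects × 5
sessions), 100 random cohorts for the structural variance identities,
and B = 10⁴ only where the permutation floor itself matters.  Tolerances:
machine-precision identities are asserted at 1e-9–1e-12; stochastic
assertions carry 2–3 SE slack computed from the replicates themselves.
Degenerate inputs fail loudly: empty median-table cells name the cell,
zero-variance columns name the column and suggest removal or jitter,
all-censored responses are refused as non-identifiable, and pipeline
stage failures name the stage.
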