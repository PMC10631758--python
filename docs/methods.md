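# Methods

## The model

Responses in an analog (continuous-report) working-memory task are treated
as draws from a three-source mixture on the circle. For a trial probing an
item with value θ among m non-probed items θ\*₁…θ\*ₘ, the response θ̂ has
density

    p(θ̂) = p_T φ(θ̂; θ, κ) + (p_N / m) Σᵢ φ(θ̂; θ*ᵢ, κ) + p_U / 2π ,

with φ the von Mises density and p_T + p_N + p_U = 1. The three weights
are the probability of reporting the probed item (target response), of
reporting a non-probed item (swap / misbinding error), and of guessing
uniformly. A single concentration κ is shared by all von Mises components:
the memory noise is assumed to be a property of the report, not of which
item was retrieved. Swap mass is divided equally across the m non-targets.
With m = 0 (single-item condition) the model degenerates to target +
uniform, so p_U = 1 − p_T identically.

Concentration is reported as the circular SD, sd = √(−2 ln A₁(κ)) with
A₁ = I₁/I₀, the scale on which group means are usually published.

**Orientation doubling.** Bar orientations live on a period-π circle. All
orientations are doubled onto the full circle ("model space") before any
circular computation, and fitted SDs are reported in this doubled space —
the scale on which the published group values (e.g. 0.51 rad for healthy
three-bar sessions) are expressed. The simulators generate data directly
in model space, so parameter-recovery results are independent of the
convention; the CSV layer stores native degrees on [0, 180) and converts
at the I/O boundary only.

## Fitting

Maximum likelihood by EM. The E-step computes per-trial responsibilities
over {target, each non-target, uniform}; the M-step sets the weights to
mean responsibilities (floored at 10⁻⁶ to avoid log 0 and renormalised)
and updates κ by solving A₁(κ) = responsibility-weighted mean cosine of
the component-centred deviations. A₁⁻¹ uses the Fisher rational
approximation as an initialiser refined by Brent bisection; the
approximation alone is not accurate enough for round-trip tests.
Convergence at |Δ log L| < 10⁻⁶ or 10⁴ iterations; the monotonicity of
the observed-data log-likelihood is asserted on every iteration.

Mixture likelihoods are multimodal, so each fit uses 20 restarts: an
18-point lattice over p_T ∈ {0.5, 0.7, 0.9} × p_U ∈ {0.05, 0.2} × κ ∈
{2, 8, 32} (projected onto the simplex with a 0.05 swap-weight floor,
since two lattice corners would otherwise leave negative swap mass), a
moment-based start and a flat start. The best restart by log-likelihood
wins; exact ties break toward smaller κ. Fits are refused below 20 trials.

Numerical guards: κ is capped at 700 (beyond which the distribution is
numerically a point mass; values above clamp with a warning); Bessel
ratios use exponentially scaled I₀/I₁ so nothing overflows; resultant
lengths below 10⁻¹² flag the circular mean as undefined. Angles are
canonicalised to (−π, π], half-open at −π.

**Known identifiability limit.** When the data carry no item signal at all
(pure guessing), a κ → 0 von Mises component is indistinguishable from the
uniform source and the MLE weights sit on a ridge: the fitted distribution
is uniform but p_U itself need not approach 1. Tests therefore check the
implied density, not the raw weights, in that regime. Real (or simulated)
sessions with κ well above 0 do not suffer from this.

## Synthetic cohorts

The generators emulate the two paradigm designs:

* **Sequential report** — 6 blocks × 30 trials (three-bar) or 1 × 30
  (one-bar); orientations uniform on the orientation circle with
  consecutively presented bars at least 10 orientation-degrees apart
  (consecutive pairs only, exactly as the design specifies); colours
  permuted per trial; the probed serial position balanced within block.
  Responses are drawn from the swap mixture; each response's generative
  component label is stored with the trial (hidden from fitters) so
  ground-truth composition checks are possible.
* **MGL** — 6 blocks × 30 trials; eccentricities {3.22, 6.44, 9.66}° and
  delays {0.5, 1, 2, 4, 8} s balanced within block by shuffled assignment;
  the target at a uniform angle on the eccentricity circle; the response
  adds isotropic bivariate Gaussian noise with σ = mean_error·√(2/π), so
  the expected Euclidean error equals the group mean (Rayleigh identity).
  Per-eccentricity / per-delay noise multipliers default to 1 (flat); the
  monotone distance/delay effects can be dialled in but no per-cell means
  are published to calibrate them against.

Group profiles default to the published group means and between-subject
SDs of the mixture parameters (three-bar and one-bar) and of MGL recall
error, with the study's sample sizes (sequential 46/39/32, MGL 23/16/25
for healthy/RRMS/SPMS). Between-subject heterogeneity draws p_T and p_N
from truncated normals and gives p_U the remainder, resampling when the
simplex constraint fails (bounded retries); heterogeneity can be switched
off for recovery studies. Response times are lognormal (medians 0.8–1.5 s,
log-dispersion 0.35–0.4, patients slower) and demographic covariates are
truncated-normal samplers loosely matched to the published cohort tables —
both exist to exercise the data paths, not to model the population; no RT
or demographic quantity feeds any headline analysis.

What the simulators deliberately do not reproduce: sequential dependencies
and learning/fatigue trends, eye movements, feedback effects, non-mixture
response processes (e.g. variable precision across trials), and any
relation between RT and accuracy. Passing recovery tests therefore shows
the estimator is unbiased and well-calibrated *under the assumed
generative model at the published parameter values and sample sizes* — it
cannot certify the model itself against real patient data.

## Descriptive measures and exclusions

Recall error: |wrapped angular difference| (sequential, model-space
radians) or Euclidean distance (MGL, visual degrees). Precision: 1/circular
SD of the signed errors (sequential) or 1/sample SD of the Euclidean errors
(MGL) — the plain reciprocal, with no chance-level correction (some prior
literature subtracts the chance expectation; the convention here follows
the source analyses and is stated to avoid ambiguity). Subjects whose mean
recall error falls outside [Q1 − 3·IQR, Q3 + 3·IQR] (quartiles by linear
interpolation of order statistics, pooled across groups, applied to the MGL
and three-bar paradigms) are excluded from all analyses of that paradigm.
The two-sided rule fires on ~1% of well-behaved size-30 samples; that is
inherent to sample quartiles, not a bug. MoCA scores classify as ≥26
normal, 18–25 mild, 10–17 moderate, ≤9 severe; the published band edges
overlap at 10, resolved here to the moderate band.

## Group inference

Mixed-design ANOVA with one between factor (group) and one within factor,
classical weighted-means sums of squares with a subject-within-group error
stratum; unequal group sizes are supported, every subject must have the
complete within profile (incomplete subjects are dropped with a warning).
No sphericity correction is applied — a documented limitation, matching
how such results are usually reported in this literature. With one within
cell the decomposition reduces exactly to one-way ANOVA. Post hoc
comparisons use Tukey HSD (Tukey–Kramer for unequal n) with p-values from
the studentized-range distribution. The implementation is cross-checked in
the tests against pingouin (ANOVA) and statsmodels (Tukey).

ROC analysis treats the patient group as positive and higher recall error
as more positive; AUC is the tie-adjusted rank probability. AUC < 0.5 is
reported as-is rather than flipped, keeping the orientation auditable.

## Problem sizes and determinism

Recovery studies run at the study's own scale: 46 subjects × 180 trials
(three-bar), 46 × 30 (one-bar), 25 × 180 (MGL); property simulations use
10³–10⁵ draws per check and the ANOVA null calibration uses 10³
replicates. All randomness flows through numpy `SeedSequence` spawning —
one stream per subject — so cohorts are bit-identical under a fixed seed
regardless of how many are simulated.
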