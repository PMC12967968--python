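# Methods

## Model

A surgical attempt is reduced to the behavioural vector X = (d, s): the
Euclidean deviation of the instrument tip from the stereotactic target
(mm), and a scalar motor-instability measure. Performance is represented as
a single-valued neutrosophic set — three *independent* memberships in
[0, 1], Truth T (competent), Indeterminacy I (borderline) and Falsity F
(unsafe), with 0 ≤ T + I + F ≤ 3. Unlike a fuzzy or probabilistic score,
the three channels are not forced to trade off against each other: a steady
hand near the tolerance edge and a tremoring hand on target produce
different (T, I, F) signatures even at similar distances.

The functional forms are deliberately piecewise-linear for transparency:

- T(d, s) = max(0, 1 − d/d_max) · max(0, 1 − s/s_max): competence requires
  *both* accuracy and stability; either factor rectifies to zero at its
  normaliser.
- I(d, s) = max(0, 1 − |d − d_mid|/d_range) · min(1, s/s_max): a triangular
  kernel centred on the mid-risk distance, active only when instability is
  non-zero — "on-target but shaky" is ambiguity, not competence.
- F(d, s) = max(min(1, d/d_crit), min(1, s/s_max)): a safety-critical
  worst-case criterion; either channel alone can condemn an attempt.

The composite score S = (2 + T − I − F)/3 is a standard SVNS score
function: bounded in [0, 1], strictly increasing in T and strictly
decreasing in I and F, penalising hesitation and error equally.

Two structural consequences matter for everything downstream:

- **Saturation.** For d ≥ d_crit (with defaults, d ≥ 4 mm) the bundle is
  pinned at (T, I, F) = (0, 0, 1) and S = 1/3 *exactly*, for any s. Large
  parts of the novice prior land there, producing exact ties.
- **Non-monotonicity in d.** S is non-increasing in d only up to d_mid; the
  triangular kernel releases its penalty again past the ambiguous zone, so
  S can tick up slightly between d_mid and the saturation region. S is
  globally non-increasing in s at fixed d.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| d_max | 3.0 | mm | Truth distance normaliser; upper bound of generally accepted targeting error |
| s_max | 0.30 | model units | instability normaliser / acceptable ceiling |
| d_crit | 4.0 | mm | unacceptable-deviation threshold; Falsity saturates |
| d_mid | 1.5 | mm | centre of the ambiguous mid-risk zone |
| d_range | 1.5 | mm | half-width of the triangular indeterminacy kernel |

Defaults reflect deep-brain-stimulation accuracy practice (sub-2-mm
targeting tolerance, physiological tremor headroom). They are illustrative,
not clinical thresholds, and are injected everywhere via
`ModelParameters` / YAML config, never hard-coded at call sites.

**Units of s.** Instability is formally a positional variance (mm²), but
the model only ever consumes the ratio s/s_max, so s is treated as a
dimensionless "model units" scalar; only consistency between s and s_max
matters. `trajectory_instability` computes it as the trace of the
positional covariance of a tip trajectory (population normalisation 1/n by
default, sample 1/(n−1) available) — translation- and rotation-invariant,
quadratic under uniform scaling. Windowing is the caller's responsibility.

Band classification (default cuts 0.3 / 0.5 / 0.7 into unsafe, at-risk,
indeterminate, expert) uses left-closed intervals: a score exactly on a cut
is assigned upward. This is a documented tie-break convention; the bands
are plumbing for decision-region maps, not part of the score itself.

## Synthetic cohort

The simulator emulates a three-class psychomotor study: per class, d and s
are drawn independently from Gaussian priors (expert N(0.5, 0.20) /
N(0.05, 0.01); indeterminate N(2.0, 0.30) / N(0.15, 0.05); novice
N(4.0, 0.50) / N(0.25, 0.07); 20 attempts per class), then rectified
non-negative. These priors and sizes are the study conditions; they are not
tuned. Rectification defaults to truncation max(0, x); an absolute-value
mode |x| is provided as an alternative convention. Draws come from a single
seeded `numpy` Generator consumed class-by-class, so a cohort is
byte-reproducible from (specs, parameters, seed, mode).

What the generator does *not* emulate: correlation between d and s within a
performer, trajectory-level time series (s is sampled directly as a scalar
surrogate), learning effects across attempts, or non-Gaussian skill
distributions. Passing tests therefore demonstrate the internal consistency
and statistical behaviour of the scoring pipeline under idealised
conditions, not validity on real surgical kinematics.

## Statistics

The validation pipeline mirrors standard practice for small multi-group
skill studies: per-group descriptives of S; Shapiro–Wilk normality per
group (delegated to scipy — assessment plumbing, not a contribution of this
package); a Kruskal–Wallis omnibus; Dunn's pairwise post-hoc z tests with
Bonferroni adjustment (m = k(k−1)/2). Because novice scores tie *exactly*
at the 1/3 saturation floor, tie handling is material: ranks are mid-ranks,
H is divided by 1 − Σ(t³−t)/(N³−N), and the Dunn variance subtracts
Σ(t³−t)/(12(N−1)). Both statistics are implemented directly (Kruskal–Wallis
cross-checked against scipy; both checked against a brute-force rank oracle
in the test suite); p-values are two-sided; α = 0.05. If all pooled values
are identical, H is defined as 0 and Dunn z as 0. The normality gate is
reported but never silently switches the output: both the gate outcome and
the nonparametric results always appear.

Expected behaviour under the default conditions, across replicate seeds:
the omnibus and both expert contrasts reject essentially always
(H typically in the mid-40s); the novice group fails normality in the
overwhelming majority of seeds. The indeterminate-vs-novice contrast is a
genuine knife-edge: its Bonferroni-adjusted p has its median almost exactly
at α, so rejection from seed to seed is close to a coin flip — the model's
intended "zone of partial overlap" between borderline and unsafe
performance, and the reason single-run conclusions about that contrast
should not be over-read.

## Landscape artifacts

All figure-level outputs are numeric matrices (CSV), with plotting as a
thin optional layer, so nothing downstream depends on rendering. The
default grid spans d ∈ [0, 5] mm (step 0.01) and s ∈ [0, 0.35]
(step 0.005), covering all class priors to ±4σ plus the saturation region;
extents and steps are configurable. Grid evaluation is the same vectorised
code path as scalar evaluation and is tested for exact equality against it.
Contour levels at S = 0.3/0.5/0.7 are exported as super-level-set masks
(nested by construction); decision regions apply the band classifier
cellwise. The discordance table flags attempts that pass the classical
d ≤ 2 mm rule while scoring below the top band — under the default cohort,
several indeterminate attempts per run are flagged.

## Numerical choices

Pure closed-form arithmetic throughout; no iterative numerics. Consistency
checks use 1e-9 absolute tolerance; grid-vs-scalar equality holds to 1e-12
(identical code path). CSV serialisation uses %.17g, guaranteeing exact
float round-trip; human-readable summaries round to 4 decimals. Degenerate
inputs: constant samples are rejected by Shapiro–Wilk (reported as
gate-violated with an undefined statistic inside the pipeline); groups must
be non-empty; negative or non-finite d, s are rejected at every entry point
(the CLI `evaluate` command can rectify instead under an explicit flag).

## Problem sizes

The replicate study used by the acceptance script averages 50 cohorts of
60 attempts each (3000 simulated attempts per quantity) — enough to pin the
replicate means of the group-level scores to ±0.003 and H to well under one
unit. The test suite's replicate checks use a fixed window of 100 seeds.

## Known limitations

- The membership kernels are fixed (rectified-linear / triangular); no
  trapezoidal or Gaussian alternatives, no interval-valued extensions, and
  no fitting of parameters to data.
- s as a single variance scalar discards tremor spectral structure and
  temporal dynamics.
- The per-seed Shapiro–Wilk W of the saturated novice group is highly
  variable (SD ≈ 0.11 across seeds); any single run's W should be read as
  one draw from a wide distribution.
- Group draws are i.i.d. within class; no subject-level random effects.
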