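# Methods

## Data model

A trial table is a tidy DataFrame, one row per trial, joining trial fields
(task, block, trial index, target emotion and intensity, identity, signed
response, response time, timeout flag) with participant fields (age group,
gender, trait anxiety, optional mood scores). Everything downstream works
on the signed intensity scale: fearful −1…−100, neutral 0, happy +1…+100;
`signed_target` is always recomputed from (emotion, intensity) and
cross-checked against any stored column. Admissible target intensities are
0–45% and 55–100% in 5% steps; 50% is excluded from the morph ladder, so
the nonzero ladder has 19 levels per emotion with grid mean 1000/19 ≈
52.63. Validation is strict by default; a lenient mode drops invalid rows
with logged warnings.

A response of exactly 0 on an emotional target reports no emotion type: it
is *not* treated as a wrong-emotion trial by the exclusion filter, and it
is dropped from both numerator and denominator of the valence
proportion-correct analysis. Wrong-emotion means strictly opposing signs.

## Scoring

Trial error |t − r| and trial bias r − t are exact integer arithmetic; the
per-participant mean error is the plain trial mean. The overall bias is
the mean of the psychometric curve, implemented by default as the
unweighted mean of per-intensity-condition mean responses over the 39
distinct signed conditions. A `weighting="trial"` flag averages raw trials
instead. The two coincide only when every condition holds the same number
of trials; on the actual design they differ slightly even before
exclusions, because the neutral condition is sampled from both ladders (8
trials vs 4 per emotional condition), and they diverge further after
exclusions. Condition-mean averaging is the default because it weights the
curve, not the sampling. Empty condition cells after exclusions are
dropped from the average, not imputed.

Per-emotion bias flips fearful responses to positive, excludes neutral
targets, averages the 19 nonzero condition means and subtracts 50. Because
the grid mean is 1000/19, an unbiased responder scores +2.6316 under this
convention; the `normalizer="exact"` option subtracts 1000/19 so the
unbiased score is exactly 0. The default keeps the conventional constant
so values are comparable with analyses that use it; the residual is a
constant offset and cancels in all group contrasts.

Block feedback is 100 − mean block error and may go negative for extreme
error; it is reported as-is. The binned psychometric curve uses eleven
bins: five 20-unit fear bins with the last covering −20…−1, a 0 bin, and
five mirrored happy bins.

## Task schedules

The WM schedule is 8 blocks × 20 trials: each of the 20 intensity
conditions per emotion ladder appears exactly 4 times (80 per ladder; the
two 0% conditions are presented as neutral faces). Identities 1–10 are
allocated by permuting a pool with exactly 16 appearances each, rejecting
the rare permutation in which some identity misses an emotion ladder.
Trials are then shuffled globally and chunked into blocks, rejecting
shuffles that leave any block single-emotion; only intermixing is
constrained, not finer balance. The published description also notes that
some identities spanned restricted intensity ranges; the governing
constraint is unstated, so it is not enforced.

The matching schedule is 2 blocks × 20 trials with each per-ladder
condition presented once. The description of its counts is internally
inconsistent (each condition "twice" with "20 trials per emotion type"
cannot both hold with 20 conditions per emotion); once-each satisfies the
block structure and the per-emotion total and is what we implement. For
every condition the matching identity is drawn from the identities *not*
assigned to that condition in the WM schedule, enforcing the
different-pairing constraint.

Both builders are deterministic functions of an integer seed.

## Response simulator

The simulator exists to exercise the pipeline and support parameter
recovery; it is not fitted to data and makes no empirical claims. For a
signed emotional target t:

- with probability `flip_base_rate · exp(−|t| / flip_decay)` the report is
  of the opposite emotion type with magnitude |N(15, 10)| clipped to
  1…100 — flips concentrate at low, ambiguous intensities, the pattern the
  valence analysis is designed to detect;
- otherwise the report is round(t + bias_shift + N(0, noise_sd)) clipped
  to ±100, with `bias_shift` signed toward happy and settable per emotion
  (units: intensity percent). Rounding mirrors the 1% morph steps.

Neutral targets produce round(N(0, noise_sd)). Defaults — noise sd 12,
flip base rate 0.3, flip decay 30, timeout rate 0.01, trait anxiety
N(38, 9), 65% female — are plausible magnitudes for this kind of task
(mean WM errors in the teens, wrong-emotion proportions of a few to ~15%,
no group anxiety difference) chosen once as the reference conditions.
Response times are gamma-distributed around ~3 s and capped below the 11 s
window; timeouts are an independent Bernoulli event. Each participant
draws from an independent RNG substream, so enlarging a cohort leaves
existing participants' data untouched.

What the simulator does not emulate: identity-specific difficulty, serial
(block-order, fatigue) effects, anxiety-linked response changes, and any
coupling between flips and memory noise. Passing pipeline tests therefore
show correctness of the measures and inference machinery under a known
generative process, not behavioural realism.

## Statistics

`mixed_ancova` implements the classical univariate split-plot analysis
through the multivariate layout. Responses are arranged subject ×
within-cell; within effects use orthonormal Helmert contrasts (Kronecker
products for crossed within factors); the between design uses effects
(sum-to-zero) coding with continuous covariates centered, so testing a
term's coefficients gives Type III sums of squares — the convention of the
R packages this style of analysis standardly uses. For each effect the
univariate F is tr(H)/tr(E) with degrees of freedom scaled by the contrast
dimension. Between-subject effects are tests on the within-cell mean.

Sphericity: the Greenhouse–Geisser epsilon is computed from the pooled
error covariance in contrast space (the SPSS/afex convention — computing
it from the total covariance as some packages do differs slightly when
between-group means differ) and applied to within effects with ≥ 3
within-cell contrasts when Mauchly's test rejects at α = .05 (the
`gg="always"/"never"` options override). Epsilon lies in (1/(k−1), 1] and
GG-corrected p-values are never smaller than uncorrected ones.

Partial η² = SS_eff/(SS_eff + SS_err), with CIs from inverting the
noncentral F cdf for the noncentrality λ at the two tail probabilities and
mapping via η² = λ/(λ + df₁ + df₂ + 1). Cohen's d uses the pooled SD
between groups and d_z (mean difference / SD of differences) for paired
and one-sample contrasts, with pooled d also reported for paired tests;
d CIs invert the noncentral t cdf (with a monotone normal approximation
where scipy's cdf underflows at extreme noncentralities). Unbalanced or
missing within cells and rank-deficient between designs raise errors;
nothing is imputed. A constant covariate is dropped with a warning, which
reduces the ANCOVA to the corresponding ANOVA exactly.

Welch's t uses Satterthwaite degrees of freedom. The valence slope is the
OLS slope of proportion correct on bin index 1…5 (units: proportion per
bin step — consistent with the magnitudes such analyses report), with
missing bins omitted; with five equally spaced populated bins this equals
the linear-contrast estimate up to scale.

## Numerical and testing choices

Scoring is exact rational/float arithmetic; oracle tests require agreement
with naive loop recomputations to 1e−12 (scoring) and 1e−10 (statistics).
Test problem sizes are chosen to keep the full suite under a minute while
leaving Monte-Carlo margins wide: flip-rate recovery uses 10⁵ draws at one
intensity (4 binomial SEs) and 2 × 10³ per ladder level; parameter
recovery uses 50 participants per group (3 MC SEs around the analytic
expectation 4·19/39 for a +4 fear shift); ANCOVA type-I calibration uses
1,000 null cohorts of 20 + 20 subjects (3 binomial SEs around .05), and
η²-CI coverage 1,000 noncentral-F draws.

## Known limitations

No mixture-model (precision / guess-rate) decomposition of errors is
fitted. The ANCOVA requires complete balanced within-cells. The simulator's
flip-magnitude distribution is a convention; recovery tests condition on
it. Gender coding is effects coding; with strongly unbalanced gender the
Type III tests remain valid but lose power. Stimulus handling (face
morphing, presentation) and questionnaire scoring are out of scope:
numeric scores are accepted as inputs.
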