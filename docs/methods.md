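# Methods

## Model

`predictbc` implements a competing-risks prognostic model for early invasive
breast cancer of the PREDICT v2 family.  Two cause-specific Cox
proportional-hazards models — breast-cancer mortality, fitted separately by
ER status, and an age-only other-cause mortality model — are combined into
absolute 10-year risks.

**Prognostic terms.**  Continuous factors enter as fractional-polynomial
(FP) basis functions of conventionally rescaled variables (age/10, size/100,
(nodes+1)/10; the +1 shift admits node-negative disease).  A term is
`f(x) = x^p` (`p = 0` meaning ln x; a repeated power contributing
`x^p·ln x`) minus a centering constant, so the reference patient scores 0;
grade enters linearly coded 1–3 without centering, and screen detection is a
0/1 indicator in the ER-positive model only.  The shipped coefficient file
(`src/predictbc/data/predict_v2.json`) encodes the published terms digit for
digit: ER-negative {age linear, √(size/100), ((nodes+1)/10)^−½, grade};
ER-positive {an FP2 age pair (age/10)^−2 and (age/10)^−2·ln(age/10),
ln(size/100), ln((nodes+1)/10), grade, screen-detected}; other-cause
{(age/10)²}.

**Baselines.**  The baseline cumulative hazard is parametric:
`Λ0(t) = exp(B(t))` with `B` an FP2-in-time polynomial (the three shipped
baselines use power pairs (−2, −1), (−½, −½) and (0, ½)).  The printed
functions are interpreted as the *logarithm* of the cumulative baseline
hazard — they are negative everywhere on the supported horizon, so the
exponential reading is the only one that yields risks in [0, 1].

**Absolute risk.**  With prognostic index PI and mortality index MI,

    H_B = 1 − exp(−exp(PI) Λ_B0(t)),  H_O = 1 − exp(−exp(MI) Λ_O0(t)),
    Rb = H_B (1 − H_O),               Ro = H_O (1 − H_B).

Predictions are supported on t ∈ [1, 10] years: the ER-negative baseline
polynomial is non-monotone below t ≈ 0.27 and the model class was built for
5/10-year horizons; out-of-range times raise rather than extrapolate.
Nothing is rounded internally.

**Treatments.**  Adjuvant endocrine-therapy and chemotherapy effects are
*configuration*: log hazard ratios shipped in the model file (defaults
−0.386 ≈ ln 0.68 and −0.248 ≈ ln 0.78, trial-meta-analysis-scale values,
marked non-authoritative in their `source` fields) added to PI.  Hormone
therapy applies only to ER-positive disease; requesting it for an
ER-negative endpoint is an error.  Cumulative benefit is displayed hormone
first, then chemotherapy — the order affects only the decomposition, never
the combined Rb.  All benefits are differences of Rb, i.e. on the
competing-risks scale using the patient's own MI.

## Fitting machinery

**Cox estimation.**  The partial likelihood with Breslow tie handling is
maximised by Newton–Raphson with step-halving (a step is halved until the
likelihood does not decrease), covariates centered internally for
conditioning (the partial likelihood is shift-invariant).  Convergence:
relative log-likelihood change < 1e-9, cap 100 iterations; standard errors
come from the inverse observed information.  For breast endpoints,
other-cause deaths are censored (and vice versa) and follow-up is truncated
at 10 years, matching the 10-year event-counting convention.  Separable
instances (monotone likelihood) run toward the boundary without crashing and
are reported with their likelihood path.

**Variable and function selection.**  Backward elimination drops the least
significant variable by likelihood-ratio test (df = its number of basis
columns) until all survive at α (default 0.05).  MFP selection runs the
standard closed test per continuous variable on the grid
{−2, −1, −½, 0, ½, 1, 2, 3}: best FP2 vs null (4 df), vs linear (3 df), vs
best FP1 (2 df), each at α; one pass over the variables by default, with
optional cycling to stability.  Centering constants are taken from the
transform specification, not recomputed, so PI scales are preserved across
refits.

**Baseline derivation.**  The Breslow estimator increments
`d_j / Σ_{at risk} exp(PI_i)` at each distinct event time, with covariates
entered exactly as fitted, so "baseline" means all centered FP columns zero
(including grade = 0, an extrapolation shared with the shipped model's
conventions).  Smoothing regresses ln(cumulative hazard) on FP2 bases of
time chosen by residual sum of squares, discarding candidates whose implied
hazard is not non-decreasing on a dense [1, 10] grid.  The regression is run
*per patient* — the step function is evaluated at every patient's follow-up
time and the least squares weighted by patient counts — because that is how
the published baselines were derived and because weighting each distinct
event time equally over-weights the sparse early tail (empirically ±10%
swings in the recovered 10-year baseline, vs mean error ≈ 0–1.5%, SD ≈ 3.4%
at n = 50,000 with patient weighting).  The unweighted variant remains
available by omitting `at_times`.

## Synthetic cohorts

The simulator generates registry-like cohorts whose event times come from
the model itself, so fitting and validation are testable without real data.

**Covariates** are sampled from configurable marginal laws emulating an
early-2000s UK registry case mix: age ~ truncated normal (mean 58, SD 12,
bounds 25–79); tumour size ~ log-normal (median 20 mm, log-SD 0.55, clipped
to [1, 90] mm); positive nodes ~ zero-inflated negative binomial (55%
structural node-negative mass, node-positive counts 1 + NB with mean 3.5 and
size 1.2); grade probabilities (0.20, 0.45, 0.35); screening detection 0.35
inside the 50–70 invitation ages and 0.05 outside; ER-positive fraction
4718/5738 (the development cohort's margin); independent treatment
assignment (chemotherapy 0.35; endocrine therapy 0.70 among ER-positive).
These are defaults chosen once to be registry-plausible — configuration, not
claims about any real joint distribution.  Not emulated: missingness, stage
migration, screening rollout over calendar time, or covariate-dependent
treatment allocation; passing tests therefore demonstrate correctness of the
machinery under the model, not transportability to real registries.

**Event times** are inverse-transform draws: independent latent breast and
other-cause times solve `exp(index)·Λ0(t) = −ln u` by bisection to 1e-8
years on the baseline extended beyond [1, 10] linearly in ln t (boundary
slope; simulation only — scoring never extrapolates), with +∞ marking
survival past the extrapolated range.  One master seed is split into
documented independent substreams (covariates; latent times/censoring), so
cohorts are byte-identical given (config, seed).  Censoring is
administrative at 10 years plus optional exponential dropout.

**Two competing-risks accounting modes.**  The published adjustment
`Rb = H_B(1−H_O)`, `Ro = H_O(1−H_B)` is *not* the cumulative incidence of
any single event-time process: the three states sum to `1 − H_B·H_O`,
i.e. the mass of patients whose latent times for both causes fall inside
the horizon is assigned to neither cause.  Consequently no simulator can
simultaneously (a) realise the model's cause-specific hazards and (b) make
observed death counts match summed Rb/Ro.  `simulate_outcomes` therefore
offers an explicit `cause_rule`:

* `"first"` (default): observed time = min(latent times, censoring), cause =
  argmin.  This realises the cause-specific hazards exactly — Cox refits on
  such data are unbiased — and is the realistic registry process.  Observed
  10-year breast deaths exceed ΣRb by roughly the double-death mass (~6–7%
  of breast deaths under the default case mix).
* `"exclusive"`: a breast death is recorded only when T_b ≤ c < T_o (and
  symmetrically), the double-death mass censored at c.  Death counts at the
  administrative horizon then equal ΣRb/ΣRo in expectation — the mode to use
  when exercising calibration machinery against the scorer — at the price of
  attenuated hazard-scale refits.

Choose the rule to match the question; the two agree on every record except
the double-death mass.

## Validation suite

Expected deaths are sums of per-patient Rb/Ro.  Calibration tables use the
conventionally printed strata (age decades 20–79; size 0–9/10–19/20–29/
30–49/50+ mm; nodes 0/1/2–4/5–9/10+; grade; quintiles of predicted risk with
stable tie-breaking); observed events are deaths of the endpoint cause by
the horizon with censored-early patients kept in the denominator (a
sensitivity mode restricts to complete potential follow-up).  Per-stratum
p-values treat observed deaths as Poisson with mean equal to predicted
(exact doubled tail for expected ≤ 50, normal approximation above) — the
convention is documented and isolated in one function.  Goodness of fit is
the χ² of observed vs expected deaths over quintiles referred to 5 df, as
conventional for this model family.  The AUC is tie-aware pair concordance
between predicted risk and the 10-year death indicator (censored-before-10
patients count as non-deaths by default); its SE and the comparison of two
correlated AUCs use DeLong placement values with a two-sided normal test.

## Numerical choices and degenerate inputs

Tumour size < 1 mm, non-integer or negative nodes, grade outside {1,2,3},
non-positive age, and uniform deviates outside (0,1) raise errors naming the
field.  Model JSON round-trips losslessly (sorted-keys canonical form; a
SHA-256 prefix of that form is logged in CLI reports).  Quintile boundaries
use stable rank order; χ² groups with zero expected count are an error, as
are single-class AUC inputs, smoothing with < 5 distinct event times, and
fits with < 2 events.  Exact ties between latent death and censoring times
resolve death-first, breast-first (probability zero for continuous times).

## Scale of the shipped checks

The test suite and acceptance script use cohorts of 50,000 patients for
coefficient recovery and simulator consistency (replicated three times per
ER stratum for the pooled recovery check), 10,000 × 50 replicates for the
goodness-of-fit calibration study, and small enumerable fixtures for the
oracle-equivalence checks (brute-force AUC, double-loop DeLong variance,
likelihood grid search).  These sizes give Monte-Carlo error comfortably
inside the tolerances tested while keeping the default run to a few minutes
on one core.

## Known limitations

* Treatment effects are external constants; no treatment-by-covariate
  interaction, generation-specific chemotherapy, or trastuzumab/HER2/Ki67
  extensions.
* The 15-year horizon, bisphosphonates, and left truncation are out of
  scope; no time-varying coefficients, stratified baselines or frailties.
* The competing-risks adjustment is the published approximation, with the
  accounting caveat described above; it is not a Fine–Gray or
  cause-specific-CIF model.
* Registry cohort-construction rules (surgery/node-sampling exclusions)
  concern fields the synthetic cohorts do not model and are not implemented.
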