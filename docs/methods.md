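# Methods

This note documents the models, conventions, numerical choices and known
limitations of `rivalrykit`.

## Event parsing and the dominance metrics

Raw data are key press/release events, one of three keys per percept
(happy / neutral / mixed), recorded in seconds from trial onset.  Seconds
are the canonical unit everywhere inside the package; milliseconds appear
only at the I/O boundary when a log dialect declares them.

**Report convention.**  Two conventions are implemented and selected by a
dialect switch.  The default is *hold-to-report*: a percept is dominant
while its key is held.  Overlapping holds are resolved by *last-key-wins* —
at any instant the dominant label is that of the most recent still-held
press, so a new press truncates the open interval and an earlier,
still-held key resumes after the later key is released.  Gaps between holds
are unreported time; unreported is deliberately not imputed to any percept
(absence of a report is not absence of a percept).  The alternative
*toggle* convention switches the report on each press until the next press
and ignores releases.  A missing release is imputed at trial end: under
hold-to-report semantics a key still held when the stimulus disappears
means the percept persisted.

The parser is an exact event-boundary sweep.  Its independent test oracle
is a 1-ms rasterization (`simulate.grid_oracle_metrics`): at every grid
cell center the dominant label is recomputed from scratch from the most
recent still-held press.  The two routes agree to one grid step per event
on adversarial inputs (overlaps, unreleased holds, events past trial end).

**Components.**  IP is the label of the first non-mixed interval (mixed
reports reflect unresolved competition and cannot be an initial winner);
ORT is that interval's onset; CT sums interval durations per label.  The
conservation identity CT(happy) + CT(neutral) + CT(mixed) + unreported =
duration holds to 1e-9 by construction and is asserted in tests.

**Aggregation and exclusions.**  Trial metrics are averaged per subject ×
condition × label before inference (the ANOVA operates on subject means,
not trial-wise values).  Uncoded trials (no events) are retained in the
session but excluded listwise from all denominators.  For the ORT analysis
a subject must contribute at least one happy and one neutral IP in *both*
conditions; subjects with any empty cell are excluded from the ORT ANOVA
only — CT analyses keep everyone.  ORT is analyzed as the natural log of
the per-cell mean in seconds (the base and unit shift the transformed
values only by constants that within-subject contrasts cancel); a mean ORT
of exactly 0 (press at trial onset) is floored at 1 ms before the log,
which is unreachable from valid data with positive onsets and therefore
never alters an analysis in practice.

## The synthetic rivalry process

Each trial is a finite renewal process on [0, 15] s:

1. an initial unresolved period τ ~ LogNormal(μ_onset, σ_onset) with no
   report (median 1.1 s, σ = 0.45 by default);
2. a first resolved percept, happy with probability p₁ = 0.72;
3. alternating dominance epochs with Gamma(k, θ_label) durations
   (k = 3.5 for both labels; θ_happy = 0.78 s, θ_neutral = 0.28 s);
4. at each switch, an optional mixed interlude with probability 0.60 and
   LogNormal(ln 0.9, 0.5) duration;
5. truncation at trial end, then serialization to press/release events
   with N(0, 0.05 s) report-latency jitter, clamped so press/release pairs
   stay ordered and inside the trial.

Gamma-distributed dominance durations with shape 3–4 are the standard
empirical description of rivalry epochs; the happy-face advantage is
realized both through the first-percept bias and the longer happy scale.
The default scales were fixed once by Monte-Carlo so that free-condition
per-trial CT means sit near the empirical benchmarks for this paradigm
(happy ≈ 7.7 s, neutral ≈ 2.7 s, the remainder split between mixed reports
and unreported time).

**Between-subject heterogeneity.**  Each subject carries a standard-normal
happy-dominance factor z; the happy scale is multiplied and the neutral
scale divided by exp(0.25 · z).  Questionnaire totals are drawn at the
normal-range means (TAS-20 43.6 ± 11.5, IRI 98.75 ± 8); TAS-20 is coupled
to z at correlation ρ = −0.4 by default so questionnaire-metric
correlation stages have a recoverable signal, IRI is independent.

**The injected condition effect.**  The experimental effect of interest —
blocking facial mimicry lengthening neutral dominance — is specified as a
target increment Δ (default 0.70 s) of the *marginal mean per-trial
neutral CT* in the blocked condition, and realized as a multiplier on the
neutral gamma scale (stabilization of neutral percepts, not a change in
switch rate).  The multiplier is found by bisection on a Monte-Carlo
estimate of measured neutral CT — trials are serialized and parsed exactly
as the analysis pipeline does, so the calibration targets the quantity the
CT analysis estimates rather than the latent timeline (report jitter and
boundary clipping shift measured CT by a few hundredths of a second).
Common random numbers across multiplier values make the objective smooth;
16,000 trials per evaluation put the residual calibration error near
0.005 s.  The calibration stream is fixed and independent of the study
seed, so the Δ → multiplier mapping is a deterministic function of the
parameters (and is cached).

**Randomness.**  All draws use numpy's PCG64 (`default_rng`) with streams
keyed by (study seed, params seed, subject, block, trial), so any single
trial is reproducible in isolation and studies are deterministic given
their seeds.

**What the generator does not emulate.**  No serial dependence between
trials (fatigue, adaptation, carry-over), no stimulus-identity effects, no
toggle-style reporting, no response errors (wrong key), and dominance
epochs are independent draws rather than the weakly autocorrelated
sequences sometimes reported.  Passing calibration/recovery tests
therefore demonstrates correctness of the pipeline under this model, not
robustness of the paradigm to those real-data features.

## Statistical battery

**Repeated-measures ANOVA.**  One or two fully-within factors on a
complete balanced subject × cell table.  Every effect is computed through
orthonormal within-subject contrast scores: with C the (df × cells)
orthonormal contrast matrix of an effect (Kronecker products of a
normalized Helmert basis and normalized unit vectors), the subject scores
Z = YCᵀ give SS_effect = n‖Z̄‖², SS_error = ‖Z − Z̄‖², and
F = (SS_eff/df)/(SS_err/(df(n−1))).  This reproduces the textbook
marginal-mean decomposition exactly (asserted to 1e-8 against a
design-matrix least-squares oracle in tests) and yields the F = t²
identity on two-level factors.  For any effect involving a factor with
three or more levels the Greenhouse–Geisser ε = tr(Σ)²/(df·tr(Σ²)) is
computed from the covariance of Z (equivalently, the double-centered cell
covariance), clamped to [1/df, 1], and reported alongside the uncorrected
test with corrected dfs ε·df_num, ε·df_den.  Two-level effects need no
correction and report none.  Missing or duplicated cells raise with the
offending subjects and cells named — no silent dropping.

**Paired contrasts.**  Classical paired t with d_z = mean(diff)/sd(diff);
one- or two-sided.  Bonferroni adjustment is min(1, p·m) with an explicit
family size m — family membership is always stated by the caller (the CT
post-hoc family is the three content labels), never inferred.

**JZS Bayes factor.**  For a paired/one-sample t statistic, the default
Bayes factor with a Cauchy(0, r) prior on the standardized effect,
r = √2/2 ("medium") by default and recorded in the output.  The marginal
likelihood is evaluated as the one-dimensional integral over the
g ~ InverseGamma(1/2, r²/2) mixing variable, in log space over u = ln g
with adaptive quadrature after locating the integrand mode on a grid; the
quadrature's relative error bound is reported and must be ≤ 1e-6 or the
call raises.  Tests verify agreement to 1e-6 relative with an independent
dense Simpson integration over the effect-size space itself
(∫ nct(t; ν, δ√n) Cauchy(δ; 0, r) dδ / t(t; ν)).

**Random-intercept logistic regression.**  IP (happy vs neutral) on
mimicry condition with a Gaussian subject intercept:
logit P(happy) = β₀ + β₁·blocked + u_i, u_i ~ N(0, σ²); the free condition
is the reference, so exp(β₁) is the blocked-vs-free odds ratio.  The
marginal likelihood is maximized with adaptive Gauss–Hermite quadrature:
per subject, the integrand mode is found by Newton iterations on the
(concave) log integrand, nodes are centered and scaled by the mode and
curvature, and 25 Hermite nodes evaluate the integral (n_quad = 1 is the
Laplace approximation).  Standard errors come from the inverse numerical
Hessian of the negative log likelihood.  The implementation matches
`lme4::glmer(..., nAGQ = 25)` to five decimals on β, SE, σ² and the log
likelihood.  Degenerate inputs refuse loudly: fewer than two subjects, or
a pooled condition × outcome cell with zero trials (separation).  With the
variance constrained to zero the model collapses to ordinary logistic
regression (statsmodels), whose slope on pooled counts equals the
closed-form 2×2 log odds ratio.

**Power.**  Exact paired-t power via the noncentral t: df = n − 1,
noncentrality d√n; two-sided power includes both rejection tails.
`required_n` reports the smallest integer n meeting the target, the
fractional root of the power equation (continuous df), and the
normal-approximation n = ((z_α + z_power)/d)², because published sample
sizes are computed under different conventions; at d = 0.478 and 80%
one-sided power the normal approximation gives 28 while the exact
computation requires 29, and the audit emits both rather than reconciling
them.

## Pipeline

`run_analysis` executes, in order: ratings ANOVAs (valence, arousal;
mimicry × expression averaged over the two stimulus identities, with a
happy-vs-neutral follow-up t), the IP stage (frequency table + mixed
logistic), the ORT stage (exclusions → log transform → 2×2 ANOVA), the CT
stage (2×3 ANOVA with GG correction, blocked-vs-free post-hocs per content
with Bonferroni m = 3 and a JZS BF each), and exploratory TAS-20/IRI
correlations per condition × metric × label — emitted uncorrected but
tagged "exploratory, uncorrected" rather than silently unadjusted.
Missing questionnaire scores skip only the correlation stage, with a
warning.  Every run writes the tidy tables, `report.json`, `report.md`,
and a manifest (config, seed, versions, config hash); rerunning an
identical manifest reproduces every number bit-identically on one
platform.  A stage failure is re-raised naming the stage, preserving all
outputs written before it.

## Test problem sizes

Monte-Carlo test sizes were chosen as the smallest designs that make the
assertions statistically meaningful: type-I-error calibration uses 500
replicate studies of 10 subjects × 8 trials per condition (binomial band
0.05 ± 2.6·SE); effect recovery uses 60 replicates of 16 subjects;
logistic recovery uses 200 replicates of 28 subjects × 16 trials per
condition; oracle equivalence uses 1,000 randomized event logs.  All
stochastic tests run under fixed seeds and are therefore deterministic.

## Known limitations

* The hold-vs-toggle convention of a given dataset must be known; the two
  conventions give different metrics and the package cannot infer which
  applies.
* The ANOVA layer handles fully-within, complete, balanced designs only —
  by design: incomplete data should be handled explicitly (exclusion
  rules) rather than by silent unbalanced-design fallbacks.
* Post-hoc contrasts are classical paired t-tests on subject means; no
  mixed-model marginal contrasts (with their pooled fractional dfs) are
  provided.
* The mixed logistic fits a single binary predictor with a random
  intercept; no random slopes or crossed stimulus effects.
* An adapter for external repository deposits of real sessions is an
  explicit hook (`events.Dialect`), but no concrete third-party format
  adapter ships with the package.
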