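# Methods

## The scientific problem

An observer receiving an auditory and a visual cue must decide, implicitly
or explicitly, whether the two signals arose from one physical source or
two.  If one source is assumed, the optimal percept fuses the cues weighted
by their reliabilities (ventriloquism); if two, each cue should be localized
on its own.  `causalcue` implements the hierarchical Bayesian observer that
performs this *causal inference*, the descriptive analyses that expose its
behavioral signatures, and a synthetic-data layer that reproduces the trial
designs of a five-experiment audio-visual study (unisensory localization and
cue combination; auditory localization under large audio-visual disparities;
explicit common-cause reports over spatial and over temporal disparity; and
a heading-discrimination design that is generated but not modeled).

## Generative model

On each trial with true locations eps_a, eps_v (degrees, rightward
positive; disparity Delta = eps_a − eps_v), the observer measures

    Xa ~ N(eps_a, sigma_a^2),   Xv ~ N(eps_v, sigma_v^2),

with sigma_v depending on the visual reliability level (high / medium /
low).  The observer's prior over source locations combines Gaussian
*natural priors* N(mu_a, sigma_ap^2), N(mu_v, sigma_vp^2) with a causal
structure variable C: with probability `p_common` both cues share one
source (Sa = Sv), otherwise the sources are independent.  The structure
likelihoods are analytic:

    p(Xa, Xv | C=1) = N(Xa; Xv, sigma_a^2 + sigma_v^2) ·
                      N(m; mu_p, s^2 + sigma_p^2)
    p(Xa, Xv | C=2) = N(Xa; mu_a, sigma_a^2 + sigma_ap^2) ·
                      N(Xv; mu_v, sigma_v^2 + sigma_vp^2)

where (mu_p, sigma_p^2) is the precision-weighted fusion of the two natural
priors and (m, s^2) of the two measurements.

**Implicit (localization) rule.**  The trial category D = ±1 is the side of
the auditory source.  Within each causal structure the source posterior is
Gaussian; the task prior truncates it to a half-line, and the Bernoulli
choice prior `p_choice_implicit` weighs the two categories, with the
truncated-prior normalizers P(S>0), P(S<0) entering the category posterior.
The observer mixes the two structures with the cause posterior
p(C=1 | Xa, Xv) and answers with the larger category posterior (ties go
rightward; they have measure zero under continuous noise).

**Explicit (common-cause) rule.**  The observer reports "common" iff
p(Xa,Xv|C=1) · p_combined > p(Xa,Xv|C=2) · (1 − p_combined).  The single
criterion parameter `p_combined` absorbs p_common, the explicit choice
prior and a task-learning parameter alpha; these trade off exactly and only
their mixture is estimable, so the component form is exposed for forward
exploration only (`p_combined_from_components`, derived by collecting the
structure-likelihood coefficients of the category-posterior inequality; at
full task learning with an unbiased choice prior it equals 1/2 because the
category prior then follows the choice prior, not the environment).  The
rule is equivalent to thresholding the cause posterior at a criterion t
with p_combined = (1−t)p_common / ((1−t)p_common + t(1−p_common)).

**Lapses.**  With probability `lapse_rate` (≤ 0.5) the response is replaced
by a coin flip that lands on the task's positive code (rightward / common /
synchronous) with probability `lapse_bias`.

**Temporal task.**  The synchrony experiment is analyzed descriptively in
this package (the temporal observer model is out of scope): synthetic
synchrony judgments follow a Gaussian bump in asynchrony
amplitude · exp(−(Delta−mean)²/2·width²) mixed with the lapse process, and
are analyzed with the same Gaussian-curve fits as the spatial explicit task.

## Numerical marginalization

Response probabilities marginalize the deterministic decision over
measurement noise.  A naive two-dimensional Gauss–Hermite product rule
applied to the decision indicator converges hopelessly slowly (≈8% error at
order 61 in one dimension, because the integrand is discontinuous), so the
package integrates the auditory dimension *exactly*:

* implicit rule - the rightward belief is monotone non-decreasing in Xa
  (verified by randomized grid scans), so the decision region is a
  half-line whose boundary c(Xv) is found by vectorized bisection; because
  c(Xv) is smooth it is solved on a 65-point grid spanning the quadrature
  nodes and evaluated by monotone (PCHIP) interpolation.  The auditory mass
  is then a Gaussian tail probability.
* explicit rule - the log-likelihood ratio is an exact quadratic in Xa, so
  the "common" region is an interval (or its complement) with closed-form
  Gaussian mass from the quadratic's roots.

Only the visual dimension is left to quadrature (Gauss–Hermite, default
order 61; order 41 in the fitting configuration), where the integrand is
smooth.  The scheme is validated against Monte-Carlo simulation (3 SE at
1e5 draws) and dense-grid integration in the test suite.  All densities are
computed in log space with `log_ndtr`-based stable forms; bisection uses 60
refinements over ±1e4 degrees (48 in fitting).

## Fitting

`CausalInferenceObserver` fits one subject (or a pooled aggregate subject)
by staged maximum likelihood:

1. cumulative-Gaussian psychometric fits to the unisensory trials give
   starting values for sigma_a and the three sigma_v (with centered priors
   these psychometric MLEs coincide with the model's sensory MLEs);
2. bounded L-BFGS-B multi-start optimization (default 20 starts; tolerance
   1e-8 on the NLL; ties broken by lower NLL then smaller parameter norm)
   of the Bernoulli trial likelihood over the variant's free parameters,
   jointly refining the sigmas (they remain identified by the unisensory
   cells, which stay in the likelihood).

The natural priors default to centered Gaussians with 25 deg SD and are
held fixed during fitting: the unisensory choice data carry no information
about prior width when the prior is centered and the choice prior unbiased,
and at desk-scale trial counts the multisensory data constrain it only
weakly.  The width matters mostly through a mild shrinkage of effective
biases; it is exposed on `ObserverParams` for users who wish to fit it.

Model variants: `full_CI` (all inference/choice parameters free),
`alt_A_forced_fusion` (p_common = 1), `alt_B_no_fusion` (p_common = 0),
`alt_C_no_lapse_bias` (lapse bias = 1/2), and `alt_D_choice_only`
(sensory and inference parameters frozen to a reference fit; only lapse
rate/bias and, in implicit tasks, the choice prior are free).  Comparison
uses AIC = 2k + 2·NLL.  Confidence intervals are seeded nonparametric
percentile bootstraps (trials within subject; subjects within a cohort for
aggregate fits), replacing posterior quantiles; this keeps the pipeline
fully reproducible from one integer seed.

**Goodness of fit.**  R² on per-condition proportions (1 − RSS/TSS) is used
for descriptive fits, with the conventional 0.50 screening threshold for
flat observers.  Absolute model fit uses explainable variance explained,

    EVE = 1 − (MSE_model − v̄) / (Var_data − v̄),

with v̄ the mean plug-in binomial variance p̂(1−p̂)/n across conditions,
clipped at 1.  A model as good as the generating process scores ≈1, the
grand mean ≈0; the statistic is undefined (raised as an error) when the
data's variance does not exceed its sampling noise.

## Synthetic observers

The generators reproduce the published designs exactly: 1680 trials (exp 1:
7 auditory locations ×15; 14 nonzero visual locations ×3 reliabilities ×15;
7 mean locations ×3 reliabilities ×{0,±6°} conflicts ×15, cues placed at
mean ± Delta/2), 1512 (exp 2: {0,±3,±6,±12,±24°} ×7 speakers ×3
reliabilities ×8), 1323 (exp 3: same ×7), 575 (exp 4: 23 asynchronies
×25), and 910 (exp 5: 2 directions ×5 speeds ×13 headings ×7, schedule
only).  Interleaving is a seeded uniform shuffle of the full factorial.

Cohort defaults encode the study's group conditions: sensory noise at the
reported group-average unisensory thresholds (sigma_a = 4.8°, sigma_v =
1.10/4.76/13.96°), identical across groups; control observers with
p_common ≈ 0.25 versus ASD-like observers at three times that (≈0.75) in
the implicit task; explicit criteria p_combined ≈ 0.35 (control) versus
0.25 (ASD-like), chosen so the model-predicted aggregate common-report
curves peak near the reported group amplitudes (≈0.79 vs ≈0.64 against the
published 0.75 vs 0.62); and synchrony-curve parameters at the published
group values (amplitude 0.98 vs 0.83; width 171.68 vs 363 ms).  One medium
sigma_v per subject is used (patch-size variation across subjects is not
modeled; only sigma_v enters the model).  Between-subject spread is
truncated-normal with modest SDs.

What the generator does *not* emulate: sequential effects and learning,
attention and eye-movement artifacts, subject-specific natural-prior
geometry, and the heading task's observer.  Passing tests therefore show
that the analysis chain recovers what this generative family produces at
these trial counts - not that real data satisfy the model.

One deliberate divergence from the published descriptive statistics: at the
reported sensory noise levels the causal-inference model cannot produce
spatial common-cause curves as wide as the reported ≈30° (model widths are
9-14° for any criterion), so synthetic curve widths follow from the model
rather than being imposed.

## Problem sizes and numerical choices

Tests and the acceptance script run simulation studies at reduced replicate
counts (e.g. 20 recovery replicates, 10-12 model-comparison seeds, cohorts
of 3+3 subjects) with single-start warm-started fits at quadrature order
41 - sizes chosen so the full suite completes on a single CPU in minutes
while keeping every check's statistical power explicit in its assertion
(rates asserted at or below the level the information supports, computed in
the test docstrings).  Degenerate inputs are flagged, not silently fitted:
all-identical responses set `degenerate_`, descriptive fits with R² < 0.5
set `flat_`, EVE raises on uninformative data, and exp5 schedules are
rejected by the simulator and the likelihood.

## Known limitations

* The natural-prior width is fixed, not fitted, by default (see above).
* `alt_D_choice_only` freezes the reference parameters rather than
  performing a simultaneous two-group joint fit; the contrast it encodes
  (only choice parameters differ between groups) is the same.
* Bootstrap CIs with full refits are expensive; `FitConfig.n_boot = 0`
  disables them by default and CLI runs enable them explicitly.
* The implicit-rule monotonicity in Xa that licenses the half-line
  integration is established by randomized scans, not proof; the scans and
  the Monte-Carlo cross-checks run in the test suite.
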