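# causalcue

Bayesian causal inference and optimal cue combination for audio-visual
psychophysics: synthetic observers, ideal-observer models for implicit
(localization) and explicit (common-cause report) tasks, descriptive
psychometric analyses, and maximum-likelihood model fitting with AIC / EVE
model comparison.

## Who this is for

Researchers modeling multisensory behavior - in particular the question of
whether an observer *integrates* two sensory cues (one inferred source) or
*segregates* them (two sources), and how the prior probability of a common
cause (`p_common`) and choice biases shape localization and common-cause
reports.  The package ships the full analysis chain of a five-experiment
audio-visual study design (cue combination, implicit causal inference over
spatial disparity, explicit common-cause reports over spatial and temporal
disparity, and a heading-discrimination schedule), exercised end to end on
simulated observers so every stage is testable without behavioral data.
Real trial tables in the same CSV schema (one row per trial: experiment,
condition, cue locations, reliability, disparity, response, subject, group)
drop into the same functions.

## The model

On each trial the observer measures the true cue locations with Gaussian
sensory noise, `Xa ~ N(eps_a, sigma_a^2)`, `Xv ~ N(eps_v, sigma_v^2)`, and
infers the causal structure C (one source with prior `p_common`, else two)
using the analytic structure likelihoods `p(Xa, Xv | C)`.  Localization
responses report the side of the auditory source, mixing the two structures
by the cause posterior; explicit reports compare the structure likelihoods
at a criterion set by `p_combined`, the single estimable mixture of
`p_common`, explicit choice bias and task learning.  Forced fusion
(`p_common = 1`) reduces to classic reliability-weighted integration:

    sigma_com = sqrt(sigma_a^2 sigma_v^2 / (sigma_a^2 + sigma_v^2)),
    w_v = (1/sigma_v^2) / (1/sigma_v^2 + 1/sigma_a^2).

See `docs/methods.md` for the full model, the numerical marginalization
scheme, fitting design and known limitations.

## Worked example

```python
import pandas as pd
from causalcue import (ObserverParams, FitConfig, fit_subject,
                       make_schedule_exp1, make_schedule_exp2, simulate_observer)

truth = ObserverParams(p_common=0.5)          # causal prior to recover
sched = pd.concat([make_schedule_exp1(0),      # 1680 unisensory+conflict trials
                   make_schedule_exp2(1)],     # 1512 implicit CI trials
                  ignore_index=True)
data = simulate_observer(sched, truth, seed=1234)

fit = fit_subject(data, "full_CI", FitConfig(n_starts=2))
print(f"p_common = {fit.params.p_common:.3f}   sigma_a = {fit.params.sigma_a:.2f} deg")
print(f"nll = {fit.nll:.1f}   aic = {fit.aic:.1f}   eve = {fit.eve:.3f}")
```

Output from this exact snippet:

```
p_common = 0.547   sigma_a = 4.67 deg
nll = 1258.2   aic = 2540.3   eve = 0.993
```

The fitted causal prior lands near the generating value 0.5 (recovery at
these trial counts is good to roughly ±0.1); `sigma_a` is the auditory
noise recovered jointly from the unisensory and conflict trials (truth
4.8°); EVE ≈ 1 says the model captures essentially all of the explainable
(above-sampling-noise) variance in the per-condition response proportions.

A command-line pipeline wraps the same machinery:

```
causalcue run --seed 7 --outdir my_run     # simulate + fit + report
```

writing the cohort CSV, per-group model fits (JSON), model-comparison
tables and headless figures (measured-vs-predicted weights, bias-vs-
disparity curves, common-cause report curves) under `my_run/`.

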