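# nnskit

Analysis pipeline for **neonatal non-nutritive sucking (NNS)** experiments:
from raw pacifier-pressure recordings to the statistical results of an
auditory-attention study, plus a synthetic-cohort generator that makes every
stage testable against known ground truth.

## Who this is for

Developmental and psychophysiology researchers who measure newborn attention
with a pressure-instrumented pacifier. A newborn sucks in *bursts* — runs of
pressure peaks (*cycles*) at roughly 2 Hz — separated by respiratory pauses.
Auditory stimulation modulates this microstructure: salient stimuli typically
inhibit sucking. The pipeline quantifies that modulation across four trial
conditions (silent **baseline**, and a nursery rhyme **narrated** by an
actress, **hummed** by the same actress, or **synthesized** with flat
affect), relates it to prenatal auditory exposure, and audits the stimuli's
acoustics.

## What it computes

**Signal → features.** Each recording is conditioned the standard way:
resting-pressure subtraction, anti-aliased decimation to 100 Hz, zero-phase
0.5–20 Hz Butterworth band-pass, 50 ms zero-phase smoothing. A *cycle* is a
conditioned peak above 1.5 mbar; a *burst* is a run of ≥ 2 cycles whose
consecutive gaps are < 1.2 s. Per 43 s trial, eight variables are derived:
cycles/trial, bursts/trial, cycles/burst, burst duration, burst interval,
cycle interval, within-burst cycle interval, and amplitude (mean peak
pressure, cmH₂O; 1 mbar = 1.01972 cmH₂O).

**Features → inference.** For each variable `y` of subject *i* in trial *t*:

```
y_it = β₀ + β_cond(it) + u_i + ε_it,   u_i ~ N(0, σ_b²),  ε_it ~ N(0, σ_e²)
```

fit by REML with baseline as the reference condition. Omnibus F and pairwise
contrasts use Satterthwaite denominator degrees of freedom; the six condition
pairs are Tukey-adjusted and accompanied by Cohen's d on subject-level means.
Non-parametric confirmations: Friedman χ² with Durbin–Conover post hocs and a
single-factor Aligned Rank Transform (ART) LMM. Prenatal-questionnaire
covariates are correlated with the condition-sensitive features
(Pearson/point-biserial, Benjamini–Hochberg FDR within each condition).
Baseline features are reduced by PCA on a common log scale (eigenvalues,
loadings, square cosines). A Monte-Carlo sensitivity analysis reports the
smallest synthesized-vs-baseline effect detectable with 80 % power.

**Stimulus audit.** The Modulation Power Spectrum — the squared magnitude of
the 2-D Fourier transform of a mean-removed log-magnitude spectrogram — is
computed per stimulus; temporal and spectral modulation profiles are compared
across conditions with paired t-tests over log-power bins.

**Synthetic cohorts.** `nnskit.simulate` generates sessions that follow the
study design (baseline first, then 1–4 counterbalanced repetitions per
condition, 4–13 trials) with bursts of 6–12 cycles at 2 Hz, respiratory
pauses, drift and jitter, subject random intercepts, planted condition
effects on the generative parameters, and questionnaire covariates linked to
sucking propensity — all with exact per-trial ground truth.

## Worked example

```python
import pandas as pd
from nnskit.simulate import SimParams, simulate_cohort
from nnskit.extract import extract_session
from nnskit.types import FeatureTable
from nnskit.stats import fit_condition_lmm, summarize_by_condition

cohort = simulate_cohort(SimParams(n_subjects=30), seed=1)
tables = [extract_session(cohort.recordings[s.subject_id], s).df
          for s in cohort.sessions]
features = FeatureTable(pd.concat(tables, ignore_index=True))

summary = summarize_by_condition(features)
print(summary[summary.feature == "cycles_trial"]
      [["condition", "n", "mean", "sd"]].round(1).to_string(index=False))

res = fit_condition_lmm(features, "cycles_trial")
print(f"condition effect: F({res.df_num:.0f}, {res.df_den:.1f}) "
      f"= {res.f:.2f}, p = {res.p:.2g}")
```

prints

```
  condition  n  mean  sd
   baseline 30  39.5 6.5
   narrated 30  34.4 7.0
     hummed 30  31.7 6.7
synthesized 30  29.7 7.3
condition effect: F(3, 225.3) = 34.94, p = 1.4e-18
```

Newborns in this simulated cohort suck ~10 cycles/trial less under the
synthesized voice than in silence — the planted inhibition pattern — and the
mixed model recovers it with a strongly significant condition effect
(pairwise baseline–synthesized contrast: t = 9.57, Tukey-adjusted p < 0.0001,
d = 1.42). The extracted cycle and burst counts equal the generator's ground
truth on every trial.

The same stages are available from the shell:

```bash
nnskit run --seed 1 --n-subjects 30 --out report/
nnskit mps --audio narrated.wav hummed.wav synthesized.wav --out mps/
```

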