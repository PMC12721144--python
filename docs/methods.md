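# Methods

This note documents the models, algorithms, and numerical choices behind
nnskit, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal conditioning and segmentation

The conditioning chain operates on the whole recording, in this order:

1. **Resting-pressure subtraction.** The resting (no-suck) level is the
   median of the lowest decile of samples. This estimator is robust when
   most of the trace is occupied by sucking bursts, where a plain mean or
   median would sit above the true baseline. A constant trace maps to
   zeros. The decile is configurable (`resting_decile`).
2. **Decimation to 100 Hz** via polyphase resampling (FIR anti-alias
   filter). Upsampling is out of contract: the pipeline assumes
   acquisition at ≥ 100 Hz.
3. **Band-pass 0.5–20 Hz**, 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`). Zero-phase filtering is essential:
   every downstream variable is a function of peak *times*, and a causal
   filter would bias them by its group delay. The band removes
   posturing/thermal offsets below 0.5 Hz and jitter above 20 Hz; the
   effective magnitude response is the square of a single pass.
4. **Smoothing**: 50 ms zero-phase moving average (odd kernel, reflected
   edges). A one-sample window is the identity.

**Cycle detection.** A suck cycle is a local maximum of the conditioned
signal at or above 1.5 mbar. Peaks closer than 0.2 s are deduplicated
greedily, keeping the larger — 0.2 s is a physiological ceiling (~5 Hz)
well above the ~2 Hz within-burst rate. The implementation
(`scipy.signal.find_peaks` with height and distance constraints) is
verified in the tests against an exhaustive brute-force scan with the
same greedy rule; the two agree exactly on hundreds of simulated trials.

**Burst segmentation.** Maximal runs of cycles whose consecutive gaps
are strictly below 1.2 s; runs of ≥ 2 cycles are bursts, shorter runs
are isolated cycles. The boundary is strict: a gap of exactly 1.2 s
splits. Isolated cycles still count toward cycles/trial by default
(`include_isolated_cycles`), and the minimum burst size is configurable
(`min_cycles_per_burst`).

**Features.** Eight variables per trial. Statistics with empty support
are missing (NaN), never zero: burst interval needs ≥ 2 bursts,
within-burst interval needs a burst with ≥ 2 cycles, and a cycle-free
trial has cycles/trial = 0 with everything else missing. `cycle_interval`
averages *all* consecutive-cycle gaps in the trial, including
between-burst gaps — otherwise it would duplicate the within-burst
interval; a config switch (`cycle_interval_all_gaps`) restricts it to
within-burst gaps. Amplitude is measured on the conditioned signal
(matching the pipeline order) and converted at 1 mbar = 1.01972 cmH₂O.

Sessions are processed by conditioning the full recording once and
assigning detected cycles to trials by their half-open windows
[t_start, t_end), so per-trial values are independent of annotation
order. Burst segmentation is per trial: activity spanning a trial
boundary is split, as the trial is the unit of analysis.

## Statistical stages

**Condition contrasts.** Trial-level rows enter a linear mixed model
with condition as a fixed factor (baseline reference) and a random
intercept per subject, estimated by REML. The covariance structure
V = σ_e²(I + λZZ'), λ = σ_b²/σ_e², is block diagonal by subject, so the
REML criterion is profiled to a one-dimensional search in λ
(Sherman–Morrison per block). Satterthwaite denominator df for a
contrast ℓ use 2φ²/(g'Wg) with φ = ℓ'C(θ)ℓ, g its numeric gradient in
θ = (σ_b², σ_e²), and W the inverse observed REML information (numeric
Hessian); the multi-df omnibus F combines per-eigenvector Satterthwaite
df through the usual sum of ν/(ν−2) terms. The engine is cross-checked
in the tests against statsmodels MixedLM (identical REML estimates) and
reduces to OLS when the random-intercept variance is forced to zero. A
boundary estimate (λ ≈ 0) is reported as a singular fit with a warning;
fixed effects are still returned, and the residual df is used where the
Satterthwaite machinery is undefined.

Pairwise contrasts among the four conditions are adjusted with Tukey's
method over the six pairs (studentized range on the Satterthwaite df).
Cohen's d uses subject-level means and the pooled SD of the two groups,
so it is invariant to shifting all observations.

Group summaries, Friedman tests, and covariate correlations first
aggregate trials to subject × condition means, so each newborn
contributes one observation; the LMM and ART use trial-level rows. This
split matches the df patterns the two kinds of analysis produce
(trial-level denominators of several hundred for the LMM, subject-level
n for correlations).

**Non-parametric confirmations.** Friedman χ² is computed from
within-subject average ranks by the rank-sum formula
χ² = 12/(nk(k+1))·ΣR_j² − 3n(k+1), df = k−1 (no tie-variance correction
in the denominator; ties enter through average ranks). Durbin–Conover
pairwise t statistics compare rank sums with (n−1)(k−1) df. The ART
aligns responses for the single within-subject factor by removing
estimated subject effects (subject mean − grand mean), ranks the aligned
responses with average ranks, and refits the same random-intercept LMM
on the ranks. Note that alignment precedes ranking, so the ART statistic
is invariant to positive affine transforms of the response but not to
arbitrary monotone ones.

**Correlations and FDR.** Pearson correlations between subject-level
features and questionnaire codes; binary covariates (sing, instrument)
use the point-biserial form, which is the same computation on 0/1 codes.
Observations are pairwise complete; cells with < 4 pairs are flagged and
left missing. Benjamini–Hochberg adjustment runs over all feature ×
covariate pairs *within one condition* — the family a reader scans in a
per-condition correlation panel. The questionnaire's verbatim options
are coded monotonically (talk/day 1–4, womb-talk/week 0–3, womb-talk/day
1–3, yes/no 1/0), which is the property correlation analysis needs.

**PCA.** Baseline rows of seven variables (bursts/trial is excluded as
redundant with cycles/trial and burst duration at baseline) are
transformed to log(x + ε), ε defaulting to 10⁻³ of each variable's
median — a common log scale that makes the heterogeneous units
comparable while preserving each variable's relative variation — and
decomposed on the covariance of the transformed variables. Reported:
all eigenvalues and variance proportions, orthonormal loading columns,
square cosines (squared variable–component correlations), and retained
scores; the number of retained components is an explicit argument
(default 2), with the scree available from the eigenvalue vector.

**Power sensitivity.** Monte-Carlo: cohorts are simulated from the
random-intercept LMM (defaults: 30 subjects, 1 baseline + 4 trials per
stimulation condition, intercept 40, σ_b = 8, σ_e = 9 cycles/trial —
round values of the magnitudes the simulated cohorts produce), the model
is refit, and rejections of the synthesized-vs-baseline Satterthwaite t
are counted over an effect grid; the smallest grid effect reaching 80 %
power is reported. 200 simulations per grid point keep the Monte-Carlo
SE near 3 percentage points; fewer than 100 triggers a warning.

**Normality screen.** Shapiro–Wilk per feature × condition on
subject-level means; cells with p < .05 are flagged to route that
variable to the non-parametric confirmations. Cells with < 3
observations or zero range are reported missing.

## Modulation power spectrum

Gaussian-windowed short-time transform (default 50 ms window, 10 ms hop;
window std = M/6 so the window support covers ±3σ), log magnitude floored
at −80 dB relative to the maximum. Frames whose window is not fully
supported by the signal are discarded: zero-padded boundary frames
otherwise inject spurious slow temporal modulation. The MPS is the
squared magnitude of the 2-D FFT of the mean-removed log spectrogram;
axes are temporal rate (Hz, from the hop) and spectral scale (cycles/Hz,
from the bin spacing), and only the non-negative spectral half-plane is
reported (conjugate symmetry). Parseval's identity (total transform
power = total squared deviation of the log spectrogram) is asserted
numerically in the tests.

Two resolution caveats shape usage. First, the zero-rate column carries
the static spectral structure, which dwarfs genuine temporal modulation;
peak queries on temporal profiles therefore exclude it. Second, the
window bounds the observable modulation: once the window resolves the
sidebands of an amplitude-modulated tone (window longer than roughly
half the modulation period), the spectrogram becomes static and the
modulation migrates to harmonics introduced by the log nonlinearity. The
planted-rate tests use 15/25/40 ms windows for an 8 Hz modulation
accordingly.

Condition comparisons are paired t-tests across modulation bins on
**log₁₀ power**: raw bin power spans ~10 orders of magnitude and a few
giant bins dominate a raw-scale test to the point of missing even a
modulated-vs-unmodulated contrast. Identical profiles give t = 0, p = 1;
profiles differing by a constant factor (zero variance of the log
differences) are flagged degenerate rather than given a p-value.

## Synthetic cohorts

The generator emulates the study conditions: 43 s trials; sessions of
4–13 trials (baseline first, then 1–4 pseudo-randomly interleaved
repetitions per stimulation condition); bursts of 6–12 cycles at a 2 Hz
within-burst rate (Gaussian timing jitter, sd 20 ms); respiratory pauses
~N(4.5 s, 1.5 s) floored at 2 s, safely above the 1.2 s burst criterion
so the planted structure is identifiable by construction (a floor at or
below 1.2 s is rejected as unidentifiable); and a waveform that is a sum
of Gaussian pressure pulses (width 0.2 s; any unimodal pulse preserves
peak times) riding on a 2 mbar resting offset, 1 mbar/0.05 Hz drift, and
0.15 mbar white jitter, rendered at 1 kHz.

Each trial opens with a **stationary lead-in**, uniform over one
burst-plus-pause period (the stationary start of a renewal process).
This matters statistically: with a short fixed lead-in the number of
bursts fitting the trial is nearly deterministic for some pause regimes,
which collapses within-subject variance for some newborns and inflates
the type-I error of the mixed model. With the stationary start the null
rejection rate of both the LMM omnibus and the ART sits at the nominal
5 % (verified over 500 null cohorts in the acceptance suite).

**Peak amplitudes** are N(6, 1) mbar floored at 4 mbar. The floor is
deliberately above the 1.5 mbar detection threshold by more than the
conditioning losses: the band-pass removes the burst envelope (roughly
the within-burst mean level, 1.5–2 mbar at these settings), so a peak
near the floor still clears the threshold by ~0.7 mbar after
conditioning. The generator thereby defines a cycle as a supra-threshold
event, keeping its ground truth consistent with the detector's contract;
genuinely sub-threshold sucks are not modelled. Consequently the
*measured* amplitude feature is attenuated relative to the generative
amplitudes (by the envelope removal); recovery guarantees apply to the
count and timing features, not to amplitude in mbar.

**Condition effects** act on generative parameters — pause length +1.0 /
+1.5 / +2.0 s, cycles-per-burst −1.5 / −1.8 / −1.7, within-burst
interval −0.04 / −0.04 / −0.03 s for narrated / hummed / synthesized —
so planted effects propagate through extraction rather than being pasted
onto features. The implied expected cycles/trial are ≈ 40 (baseline),
33.4, 30.6, 28.8 — stimulation inhibits sucking, most strongly for the
synthesized voice, with fewer and shorter bursts. **Subject
heterogeneity** is a random intercept on expected cycles/trial (sd 6),
composed of a questionnaire-linked component (default +3 cycles/trial
per womb-talk/week code) plus noise (sd 5), folded into the subject's
expected pause length in closed form. Questionnaire codes are drawn
uniformly (binary items at 50 % / 35 %).

A single global seed spawns independent per-subject substreams
(`SeedSequence.spawn`), so cohorts are bit-reproducible and subjects are
independent.

**What the synthetic tests do not show.** The generator's pulses are
clean unimodal bumps with stationary noise; real recordings contain
movement artifacts, sub-threshold mouthing, drifting amplitude, and
trial-boundary effects that the recovery guarantees (exact burst counts,
cycle counts within 2 %, timing within 20 ms) do not cover. Passing
tests establish that the pipeline's algebra and thresholds behave as
specified, not that real neonatal data are this clean.

## Numerical choices and degenerate inputs

- REML λ search over log λ ∈ [−14, 14] (bounded scalar minimization,
  xatol 10⁻⁸), with the λ = 0 boundary checked explicitly; λ < 10⁻⁷
  is reported singular.
- Numeric derivatives for Satterthwaite use relative steps of 10⁻⁴
  (floor 10⁻⁸) and fall back to the residual df when the information
  matrix is not positive definite or the df comes out non-finite.
- Satterthwaite df are capped at the residual df of the design.
- CSV time axes must be uniform to a relative tolerance of 10⁻⁶; the
  first offending index is named in the error.
- Peak-separation ties cannot occur on continuous simulated data;
  deduplication keeps the larger peak, with scipy's height-descending
  order as the tie-break.
- The worked-example conversions are exact: 5 cycles in bursts
  {[1.0, 1.5, 2.0], [4.0, 4.4]} at 3 mbar give mean within-burst gap
  7/15 s ≈ 0.4667 and amplitude 3.05916 cmH₂O.

## Problem sizes used by the bundled studies

The test suite and acceptance script size their simulations as: 100
default 43 s trials for ground-truth recovery; 200 short (8 s) trials
for the brute-force segmentation oracle; 500 twelve-subject cohorts
(ground-truth features, no waveform rendering) for null calibration;
1000 random p-vectors for the FDR oracle; one rendered 30-subject cohort
(~260 trials) for the end-to-end study; 200 Monte-Carlo simulations per
power grid point. These sizes keep Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- The LMM supports exactly one random intercept (subject); random slopes
  and crossed effects are out of scope.
- Amplitude recovery is attenuation-biased by design (see above); a
  calibration factor would be needed to compare absolute amplitudes
  across pipelines.
- The MPS spectral-scale axis is reported in cycles/Hz (linear frequency
  axis); a cycles/octave variant would require a log-frequency
  spectrogram front-end.
- Trial windows are taken as given; delimiting trials in a raw stream
  (hardware triggers, manual marks) is upstream of this package.
- Correlations treat ordinal questionnaire codes as interval-scaled, the
  standard practice the monotone coding is designed for; rank-based
  alternatives are not implemented.
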