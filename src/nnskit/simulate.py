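"""Synthetic NNS cohorts with known ground truth.

The generator emulates the study design: sessions open with a 43 s
silent baseline trial followed by 1-4 counterbalanced repetitions of
each stimulation condition (4-13 trials total).  Within a trial, sucking
is organized into bursts of 6-12 cycles at ~2 Hz separated by
respiratory pauses; the waveform is a sum of unimodal (Gaussian) pressure
pulses riding on a resting offset, low-frequency drift, and
high-frequency jitter.  Condition effects act on the generative
parameters (pause length, cycles per burst, within-burst interval) so
planted effects propagate through extraction, mirroring the observed
pattern that auditory stimulation yields fewer and shorter bursts.
Subject-level variation enters as a random intercept on expected
cycles/trial, partly explained by questionnaire covariates.

Each subject draws an independent child stream of a single global seed,
so cohorts are reproducible and subjects are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .extract import Burst, CycleEvent, compute_trial_features
from .types import (
    Condition,
    FeatureTable,
    PressureRecording,
    QuestionnaireRecord,
    SessionDesign,
    TrialAnnotation,
    TrialFeatures,
    CONDITIONS,
    STIMULATION_CONDITIONS,
    MAX_REPEATS,
)

#: Burst-gap criterion the generated structure must stay identifiable under.
BURST_GAP_S = 1.2


@dataclass
class ConditionEffect:
    """Additive shifts of the generative parameters for one condition."""

    pause_shift_s: float = 0.0
    cycles_per_burst_shift: float = 0.0
    interval_shift_s: float = 0.0


#: Default planted effects: stimulation lengthens pauses, trims bursts, and
#: slightly tightens the within-burst rhythm, strongest for the synthesized
#: voice — the attentional-inhibition pattern the pipeline must detect.
DEFAULT_CONDITION_EFFECTS: Dict[str, ConditionEffect] = {
    Condition.BASELINE.value: ConditionEffect(0.0, 0.0, 0.0),
    Condition.NARRATED.value: ConditionEffect(1.0, -1.5, -0.04),
    Condition.HUMMED.value: ConditionEffect(1.5, -1.8, -0.04),
    Condition.SYNTHESIZED.value: ConditionEffect(2.0, -1.7, -0.03),
}

#: Expected values of the questionnaire codes under their sampling scheme,
#: used to centre the covariate model.
COVARIATE_MEANS = {
    "talk_day": 2.5,
    "womb_talk_week": 1.5,
    "womb_talk_day": 2.0,
    "sing": 0.5,
    "instrument": 0.35,
}


@dataclass
class SimParams:
    """Generative parameters of the synthetic cohort.

    Amplitudes are in mbar, times in seconds.  The defaults reproduce the
    study conditions: 43 s trials, bursts of 6-12 cycles at a 2 Hz
    within-burst rate, respiratory pauses of a few seconds, and peak
    pressures several mbar above the 1.5 mbar detection threshold.
    """

    n_subjects: int = 30
    trial_duration_s: float = 43.0
    sample_rate: float = 1000.0
    cycles_per_burst_low: int = 6
    cycles_per_burst_high: int = 12
    within_burst_interval_s: float = 0.5  # 2 Hz within-burst rate
    interval_jitter_sd_s: float = 0.02
    pause_mean_s: float = 4.5
    pause_sd_s: float = 1.5
    pause_min_s: float = 2.0
    amp_mean_mbar: float = 6.0
    amp_sd_mbar: float = 1.0
    amp_floor_mbar: float = 4.0
    pulse_width_s: float = 0.2  # Gaussian bump, sd = pulse_width / 4
    drift_amp_mbar: float = 1.0
    drift_freq_hz: float = 0.05
    jitter_sd_mbar: float = 0.15
    resting_pressure_mbar: float = 2.0
    subject_sd_cycles: float = 6.0  # random-intercept SD on cycles/trial
    condition_effects: Dict[str, ConditionEffect] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS)
    )
    covariate_coefs: Dict[str, float] = field(
        default_factory=lambda: {"womb_talk_week": 3.0}
    )
    covariate_noise_sd: float = 5.0
    questionnaire_missing_rate: float = 0.0
    edge_margin_s: float = 0.5  # keep cycles away from trial edges

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pause_min_s <= BURST_GAP_S:
            raise ValueError(
                "unidentifiable burst structure: minimum pause "
                f"({self.pause_min_s} s) must exceed the burst gap criterion ({BURST_GAP_S} s)"
            )
        for name in ("interval_jitter_sd_s", "pause_sd_s", "amp_sd_mbar",
                     "jitter_sd_mbar", "subject_sd_cycles", "covariate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 2 <= self.cycles_per_burst_low <= self.cycles_per_burst_high:
            raise ValueError("need 2 <= cycles_per_burst_low <= cycles_per_burst_high")
        if self.pulse_width_s >= self.within_burst_interval_s / 0.9:
            raise ValueError("pulse width too large for the within-burst rate")
        for cond, eff in self.condition_effects.items():
            ivl = self.within_burst_interval_s + eff.interval_shift_s
            if not 0.25 <= ivl < BURST_GAP_S:
                raise ValueError(
                    f"condition {cond}: shifted within-burst interval {ivl} s is outside "
                    f"the identifiable range [0.25, {BURST_GAP_S})"
                )

    def effect(self, condition) -> ConditionEffect:
        return self.condition_effects.get(Condition.parse(condition).value, ConditionEffect())

    def expected_cycles_per_trial(self, condition) -> float:
        """Approximate expected cycles/trial implied by the generative parameters.

        Bursts recur with period = burst span + pause and the trial opens
        with a stationary phase (lead-in uniform over one period), so on
        average (usable / period - 1/2) full periods fit.
        """
        eff = self.effect(condition)
        m_c = float(np.clip(
            (self.cycles_per_burst_low + self.cycles_per_burst_high) / 2.0
            + eff.cycles_per_burst_shift, 2.0, None,
        ))
        ivl = self.within_burst_interval_s + eff.interval_shift_s
        dur = (m_c - 1.0) * ivl
        pause = max(self.pause_mean_s + eff.pause_shift_s, self.pause_min_s)
        usable = self.trial_duration_s - 2 * self.edge_margin_s
        return m_c * (usable / (dur + pause) - 0.5)


@dataclass
class TrialGroundTruth:
    """Planted structure of one simulated trial."""

    condition: str
    cycle_times: np.ndarray
    amplitudes: np.ndarray
    burst_membership: List[List[int]]  # cycle indices per burst
    features: TrialFeatures

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_times.size)

    @property
    def n_bursts(self) -> int:
        return len(self.burst_membership)


@dataclass
class SubjectGroundTruth:
    subject_id: str
    intercept: float  # shift of expected cycles/trial
    covariates: Dict[str, Optional[int]]


@dataclass
class CohortData:
    """A full simulated cohort with its ground truth."""

    params: SimParams
    sessions: List[SessionDesign]
    recordings: Dict[str, Optional[PressureRecording]]
    trial_truths: Dict[Tuple[str, int], TrialGroundTruth]
    subject_truths: Dict[str, SubjectGroundTruth]
    questionnaires: List[QuestionnaireRecord]
    true_features: FeatureTable


def _shifted_count(rng: np.random.Generator, low: int, high: int, shift: float) -> int:
    """Integer cycles-per-burst draw under a (possibly fractional) shift."""
    u = int(rng.integers(low, high + 1))
    base = math.floor(shift)
    frac = shift - base
    if frac > 0 and rng.random() < frac:
        base += 1
    return max(2, u + base)


def _truth_features(times: np.ndarray, amps: np.ndarray,
                    membership: List[List[int]], duration: float) -> TrialFeatures:
    cycles = [CycleEvent(time=float(t), amplitude=float(a)) for t, a in zip(times, amps)]
    bursts = [
        Burst(cycle_indices=list(m), start=float(times[m[0]]), end=float(times[m[-1]]))
        for m in membership
    ]
    return compute_trial_features(cycles, bursts, trial_duration=duration)


def simulate_trial(
    params: SimParams,
    condition,
    rng: np.random.Generator,
    subject_delta: float = 0.0,
    render: bool = True,
    lead_in_s: Optional[float] = None,
    subject_id: Optional[str] = None,
) -> Tuple[Optional[PressureRecording], TrialGroundTruth]:
    """Simulate one trial; returns the waveform (or None) and its ground truth.

    `subject_delta` shifts the subject's expected cycles/trial; it is
    absorbed into the pause length so the burst anatomy stays intact.
    The trial opens with a stationary lead-in (uniform over one
    burst-plus-pause period) so the number of bursts that fit is not
    locked to the pause regime.  Within-burst gaps are below 1.2 s and
    inter-burst gaps at or above the minimum pause by construction.
    """
    params.validate()
    cond = Condition.parse(condition).value
    eff = params.effect(cond)
    T = params.trial_duration_s
    ivl = params.within_burst_interval_s + eff.interval_shift_s
    m_c = max(2.0, (params.cycles_per_burst_low + params.cycles_per_burst_high) / 2.0
              + eff.cycles_per_burst_shift)
    dur_mean = (m_c - 1.0) * ivl
    pause_mean = max(params.pause_mean_s + eff.pause_shift_s, params.pause_min_s)

    # fold the subject effect into the expected pause length:
    # E[cycles] = m_c (usable/period - 1/2)  =>  period = usable m_c / (target + m_c/2)
    if subject_delta != 0.0:
        base = params.expected_cycles_per_trial(cond)
        target = max(base + subject_delta, 6.0)
        usable = T - 2 * params.edge_margin_s
        period = usable * m_c / (target + 0.5 * m_c)
        pause_mean = max(period - dur_mean, params.pause_min_s)

    if lead_in_s is None:
        lead_in_s = float(rng.uniform(0.0, dur_mean + pause_mean))
    t = params.edge_margin_s + lead_in_s
    times: List[float] = []
    amps: List[float] = []
    membership: List[List[int]] = []
    while True:
        n_c = _shifted_count(rng, params.cycles_per_burst_low, params.cycles_per_burst_high,
                             eff.cycles_per_burst_shift)
        gaps = np.clip(
            rng.normal(ivl, params.interval_jitter_sd_s, n_c - 1), 0.3, 1.05
        )
        span = float(np.sum(gaps))
        if t + span > T - params.edge_margin_s:
            break
        burst_times = t + np.concatenate([[0.0], np.cumsum(gaps)])
        idx0 = len(times)
        times.extend(burst_times.tolist())
        amps.extend(
            np.maximum(rng.normal(params.amp_mean_mbar, params.amp_sd_mbar, n_c),
                       params.amp_floor_mbar).tolist()
        )
        membership.append(list(range(idx0, idx0 + n_c)))
        t = float(burst_times[-1]) + max(
            float(rng.normal(pause_mean, params.pause_sd_s)), params.pause_min_s
        )

    times_arr = np.asarray(times)
    amps_arr = np.asarray(amps)
    truth = TrialGroundTruth(
        condition=cond,
        cycle_times=times_arr,
        amplitudes=amps_arr,
        burst_membership=membership,
        features=_truth_features(times_arr, amps_arr, membership, T),
    )

    rec = None
    if render:
        fs = params.sample_rate
        n = int(round(T * fs))
        tt = np.arange(n) / fs
        x = np.full(n, params.resting_pressure_mbar)
        if params.drift_amp_mbar > 0:
            phase = rng.uniform(0.0, 2 * np.pi)
            x += params.drift_amp_mbar * np.sin(2 * np.pi * params.drift_freq_hz * tt + phase)
        if params.jitter_sd_mbar > 0:
            x += rng.normal(0.0, params.jitter_sd_mbar, n)
        sd = params.pulse_width_s / 4.0
        half = int(round(5 * sd * fs))
        for tc, a in zip(times_arr, amps_arr):
            c = int(round(tc * fs))
            lo, hi = max(0, c - half), min(n, c + half + 1)
            x[lo:hi] += a * np.exp(-0.5 * ((tt[lo:hi] - tc) / sd) ** 2)
        rec = PressureRecording(samples=x, sample_rate=fs, subject_id=subject_id)
    return rec, truth


def _counterbalanced_order(rng: np.random.Generator, reps: Dict[str, int]) -> List[str]:
    """Round-wise pseudo-random interleaving of condition repetitions."""
    order: List[str] = []
    for r in range(1, MAX_REPEATS + 1):
        rnd = [c for c, k in reps.items() if k >= r]
        rng.shuffle(rnd)
        order.extend(rnd)
    return order


def _draw_questionnaire(rng: np.random.Generator, subject_id: str,
                        missing_rate: float) -> QuestionnaireRecord:
    codes = {
        "talk_day": int(rng.integers(1, 5)),
        "womb_talk_week": int(rng.integers(0, 4)),
        "womb_talk_day": int(rng.integers(1, 4)),
        "sing": int(rng.random() < 0.5),
        "instrument": int(rng.random() < 0.35),
    }
    if missing_rate > 0:
        for k in list(codes):
            if rng.random() < missing_rate:
                codes[k] = None
    return QuestionnaireRecord(subject_id=subject_id, **codes)


def simulate_cohort(
    params: Optional[SimParams] = None,
    seed: Optional[int] = None,
    render: bool = True,
) -> CohortData:
    """Simulate a full cohort: sessions, waveforms, questionnaires, truth.

    Each session opens with the baseline trial and continues with 1-4
    pseudo-randomly interleaved repetitions of each stimulation
    condition.  Subject intercepts are drawn once per subject as
    covariate-linked propensity plus noise; with `render=False` only the
    cycle-level ground truth is produced (no waveforms), which is what
    the statistical calibration studies consume.
    """
    params = params or SimParams()
    if params.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    streams = np.random.SeedSequence(seed).spawn(params.n_subjects)

    sessions: List[SessionDesign] = []
    recordings: Dict[str, Optional[PressureRecording]] = {}
    trial_truths: Dict[Tuple[str, int], TrialGroundTruth] = {}
    subject_truths: Dict[str, SubjectGroundTruth] = {}
    questionnaires: List[QuestionnaireRecord] = []
    feature_rows = []

    T = params.trial_duration_s
    for i in range(params.n_subjects):
        rng = np.random.default_rng(streams[i])
        sid = f"S{i + 1:03d}"
        q = _draw_questionnaire(rng, sid, params.questionnaire_missing_rate)
        delta = float(rng.normal(0.0, params.covariate_noise_sd))
        for cov, beta in params.covariate_coefs.items():
            code = getattr(q, cov)
            if code is not None:
                delta += beta * (code - COVARIATE_MEANS[cov])
        subject_truths[sid] = SubjectGroundTruth(
            subject_id=sid, intercept=delta,
            covariates={c: getattr(q, c) for c in COVARIATE_MEANS},
        )
        questionnaires.append(q)

        reps = {c.value: int(rng.integers(1, MAX_REPEATS + 1)) for c in STIMULATION_CONDITIONS}
        order = [Condition.BASELINE.value] + _counterbalanced_order(rng, reps)
        trials = []
        chunks = []
        for k, cond in enumerate(order):
            rec, truth = simulate_trial(
                params, cond, rng, subject_delta=delta, render=render, subject_id=sid
            )
            idx = k + 1
            trials.append(
                TrialAnnotation(trial_index=idx, condition=Condition.parse(cond),
                                t_start=k * T, t_end=(k + 1) * T)
            )
            # cycle times are trial-relative in the truth; keep them that way
            trial_truths[(sid, idx)] = truth
            feature_rows.append(
                {"subject_id": sid, "trial_index": idx, "condition": cond,
                 **truth.features.as_dict()}
            )
            if render:
                chunks.append(rec.samples)
        sessions.append(SessionDesign(subject_id=sid, trials=trials))
        recordings[sid] = (
            PressureRecording(samples=np.concatenate(chunks), sample_rate=params.sample_rate,
                              subject_id=sid)
            if render else None
        )

    return CohortData(
        params=params,
        sessions=sessions,
        recordings=recordings,
        trial_truths=trial_truths,
        subject_truths=subject_truths,
        questionnaires=questionnaires,
        true_features=FeatureTable(pd.DataFrame(feature_rows)),
    )


def null_params(params: Optional[SimParams] = None, **overrides) -> SimParams:
    """Copy of `params` with all condition effects set to zero."""
    base = params or SimParams()
    zero = {c.value: ConditionEffect() for c in CONDITIONS}
    return replace(base, condition_effects=zero, **overrides)


def simulate_am_tone(
    carrier_hz: float,
    mod_rate_hz: float,
    duration_s: float,
    sample_rate: float,
    mod_depth: float = 1.0,
) -> np.ndarray:
    """Unit-amplitude sinusoidal carrier with sinusoidal amplitude modulation.

    A zero modulation rate gives a pure tone.  Parameters that would
    alias (carrier at or above Nyquist, modulation at or above the
    carrier) raise.
    """
    nyq = sample_rate / 2.0
    if carrier_hz >= nyq:
        raise ValueError(f"carrier {carrier_hz} Hz at or above Nyquist {nyq} Hz")
    if mod_rate_hz < 0 or (mod_rate_hz > 0 and mod_rate_hz >= carrier_hz):
        raise ValueError("need 0 <= mod_rate < carrier")
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    envelope = 1.0 + mod_depth * np.sin(2 * np.pi * mod_rate_hz * t) if mod_rate_hz > 0 else np.ones_like(t)
    return envelope * np.sin(2 * np.pi * carrier_hz * t)
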