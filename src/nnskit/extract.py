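"""Signal conditioning, suck-cycle detection, burst segmentation, NNS features.

The conditioning chain follows the standard pacifier-pressure pipeline:
resting-pressure subtraction, anti-aliased decimation to 100 Hz, zero-phase
0.5-20 Hz band-pass (removes posturing offsets, thermal drift, and
high-frequency jitter), and a short zero-phase moving average.  A suck
cycle is a conditioned peak above 1.5 mbar; a burst is a run of two or
more cycles whose consecutive gaps are under 1.2 s.

All filters are applied forward-backward so peak times are unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .config import ExtractConfig
from .types import (
    MBAR_TO_CMH2O,
    FeatureTable,
    PressureRecording,
    SessionDesign,
    TrialFeatures,
)

logger = logging.getLogger("nnskit")


@dataclass
class CycleEvent:
    """One detected suck cycle: conditioned peak time and height."""

    time: float
    amplitude: float  # mbar, on the conditioned signal


@dataclass
class Burst:
    """A run of >= 2 cycles with consecutive gaps under the burst threshold."""

    cycle_indices: List[int]
    start: float  # time of first peak
    end: float  # time of last peak

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_indices)

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Conditioning

def subtract_resting_pressure(
    rec: PressureRecording, decile: float = 0.1
) -> PressureRecording:
    """Remove the resting (no-suck) pressure level from the whole trace.

    The resting level is estimated as the median of the lowest `decile`
    of samples, which is robust even when most of the trace is occupied
    by sucking bursts.  A constant trace maps to all zeros.
    """
    if rec.n_samples == 0:
        raise ValueError("cannot estimate resting pressure of an empty recording")
    x = rec.samples
    k = max(1, int(np.ceil(decile * x.size)))
    resting = float(np.median(np.partition(x, k - 1)[:k]))
    logger.info("resting pressure estimate: %.4g mbar", resting)
    return rec.copy_with(x - resting)


def resample_to_100hz(rec: PressureRecording, target_rate: float = 100.0) -> PressureRecording:
    """Anti-aliased decimation to the working rate (default 100 Hz).

    Uses polyphase resampling (FIR anti-alias filter).  Recordings
    already at the target rate are returned unchanged; upsampling is out
    of contract.
    """
    if rec.sample_rate == target_rate:
        return rec
    if rec.sample_rate < target_rate:
        raise ValueError(
            f"sample_rate {rec.sample_rate} Hz below the {target_rate} Hz target; "
            "upsampling is out of contract"
        )
    ratio = Fraction(target_rate / rec.sample_rate).limit_denominator(10**6)
    y = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return rec.copy_with(y, sample_rate=target_rate)


def bandpass_filter(
    rec: PressureRecording, low: float = 0.5, high: float = 20.0, order: int = 4
) -> PressureRecording:
    """Zero-phase Butterworth band-pass (default 0.5-20 Hz).

    Applied forward-backward (sosfiltfilt) so that peak times are not
    shifted; the effective magnitude response is the square of a single
    pass of the given order.
    """
    nyq = rec.sample_rate / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sample_rate, output="sos")
    y = signal.sosfiltfilt(sos, rec.samples)
    return rec.copy_with(y)


def smooth(rec: PressureRecording, window_s: float = 0.05) -> PressureRecording:
    """Zero-phase moving average over `window_s` seconds.

    The kernel length is forced odd so the filter is exactly symmetric;
    a one-sample window is the identity.
    """
    n = max(1, int(round(window_s * rec.sample_rate)))
    if n % 2 == 0:
        n += 1
    if n > rec.n_samples:
        raise ValueError(
            f"smoothing window ({n} samples) longer than the trace ({rec.n_samples})"
        )
    if n == 1:
        return rec.copy_with(rec.samples.copy())
    y = ndimage.uniform_filter1d(rec.samples, size=n, mode="reflect")
    return rec.copy_with(y)


def condition_signal(rec: PressureRecording, config: Optional[ExtractConfig] = None) -> PressureRecording:
    """Full conditioning chain: resting subtraction, 100 Hz, band-pass, smooth."""
    cfg = config or ExtractConfig()
    out = subtract_resting_pressure(rec, decile=cfg.resting_decile)
    out = resample_to_100hz(out, target_rate=cfg.target_rate_hz)
    out = bandpass_filter(out, low=cfg.band_low_hz, high=cfg.band_high_hz)
    out = smooth(out, window_s=cfg.smooth_window_s)
    return out


# ---------------------------------------------------------------------------
# Detection and segmentation

def detect_cycles(
    rec: PressureRecording,
    threshold: float = 1.5,
    min_separation: float = 0.2,
) -> List[CycleEvent]:
    """Detect suck cycles as conditioned peaks above `threshold` mbar.

    Local maxima at or above the threshold are found, then any two peaks
    closer than `min_separation` are deduplicated greedily, keeping the
    larger.  On small inputs this is equivalent to a brute-force scan of
    all local maxima followed by the same greedy pruning.
    """
    distance = max(1, int(round(min_separation * rec.sample_rate)))
    idx, props = signal.find_peaks(rec.samples, height=threshold, distance=distance)
    times = rec.start_time + idx / rec.sample_rate
    heights = props["peak_heights"]
    return [CycleEvent(time=float(t), amplitude=float(h)) for t, h in zip(times, heights)]


def segment_bursts(
    cycles: Sequence[CycleEvent],
    gap_threshold: float = 1.2,
    min_cycles: int = 2,
) -> Tuple[List[Burst], List[int]]:
    """Group cycles into bursts; return (bursts, isolated cycle indices).

    Maximal runs whose consecutive gaps are strictly below `gap_threshold`
    become bursts when they contain at least `min_cycles` cycles; shorter
    runs are isolated cycles.  Every cycle is assigned exactly once.
    """
    times = np.array([c.time for c in cycles], dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("cycle times must be strictly increasing")
    bursts: List[Burst] = []
    isolated: List[int] = []
    run: List[int] = []
    for i in range(len(cycles)):
        if run and times[i] - times[run[-1]] >= gap_threshold:
            _close_run(run, times, min_cycles, bursts, isolated)
            run = []
        run.append(i)
    _close_run(run, times, min_cycles, bursts, isolated)
    return bursts, isolated


def _close_run(run, times, min_cycles, bursts, isolated) -> None:
    if not run:
        return
    if len(run) >= min_cycles:
        bursts.append(Burst(cycle_indices=list(run), start=float(times[run[0]]), end=float(times[run[-1]])))
    else:
        isolated.extend(run)


# ---------------------------------------------------------------------------
# Feature derivation

def compute_trial_features(
    cycles: Sequence[CycleEvent],
    bursts: Sequence[Burst],
    trial_duration: float,
    include_isolated_cycles: bool = True,
    cycle_interval_all_gaps: bool = True,
) -> TrialFeatures:
    """Derive the eight NNS variables for one trial.

    cycles_trial counts every detected cycle (bursted + isolated) unless
    `include_isolated_cycles` is False; any statistic with no defined
    support (e.g. burst_interval with < 2 bursts) is NaN, never zero.
    Amplitude is the mean conditioned peak height converted to cmH2O.
    """
    if trial_duration < 0:
        raise ValueError(f"negative trial duration: {trial_duration}")
    nan = float("nan")
    times = np.array([c.time for c in cycles], dtype=float)
    amps = np.array([c.amplitude for c in cycles], dtype=float)

    n_bursted = sum(b.n_cycles for b in bursts)
    n_all = len(cycles)
    cycles_trial = float(n_all if include_isolated_cycles else n_bursted)
    if n_all == 0:
        return TrialFeatures(0.0, nan, nan, nan, nan, nan, nan, nan)

    bursts_trial = float(len(bursts))
    if bursts:
        cycles_burst = float(np.mean([b.n_cycles for b in bursts]))
        burst_duration = float(np.mean([b.duration for b in bursts]))
        within_gaps = np.concatenate(
            [np.diff(times[b.cycle_indices]) for b in bursts if b.n_cycles >= 2]
        )
        cycles_burst_interval = float(np.mean(within_gaps)) if within_gaps.size else nan
    else:
        cycles_burst = burst_duration = cycles_burst_interval = nan
        within_gaps = np.array([])

    if len(bursts) >= 2:
        gaps = [b2.start - b1.end for b1, b2 in zip(bursts, bursts[1:])]
        burst_interval = float(np.mean(gaps))
    else:
        burst_interval = nan

    if cycle_interval_all_gaps:
        cycle_interval = float(np.mean(np.diff(times))) if n_all >= 2 else nan
    else:
        cycle_interval = float(np.mean(within_gaps)) if within_gaps.size else nan

    amplitude = float(np.mean(amps)) * MBAR_TO_CMH2O
    return TrialFeatures(
        cycles_trial=cycles_trial,
        bursts_trial=bursts_trial,
        cycles_burst=cycles_burst,
        burst_duration=burst_duration,
        burst_interval=burst_interval,
        cycle_interval=cycle_interval,
        cycles_burst_interval=cycles_burst_interval,
        amplitude=amplitude,
    )


# ---------------------------------------------------------------------------
# Session-level composition

def extract_trial(
    conditioned: PressureRecording,
    t_start: float,
    t_end: float,
    config: Optional[ExtractConfig] = None,
) -> TrialFeatures:
    """Detect and segment within one trial window of a conditioned recording."""
    cfg = config or ExtractConfig()
    cycles = detect_cycles(
        conditioned, threshold=cfg.cycle_threshold_mbar, min_separation=cfg.min_peak_separation_s
    )
    in_win = [c for c in cycles if t_start <= c.time < t_end]
    bursts, _ = segment_bursts(in_win, gap_threshold=cfg.burst_gap_s, min_cycles=cfg.min_cycles_per_burst)
    return compute_trial_features(
        in_win,
        bursts,
        trial_duration=t_end - t_start,
        include_isolated_cycles=cfg.include_isolated_cycles,
        cycle_interval_all_gaps=cfg.cycle_interval_all_gaps,
    )


def extract_session(
    rec: PressureRecording,
    session: SessionDesign,
    config: Optional[ExtractConfig] = None,
) -> FeatureTable:
    """Run the full pipeline on one session and return per-trial features.

    The whole recording is conditioned once (resting pressure is
    estimated from the entire signal); cycles are then detected globally
    and assigned to trials by their half-open windows, so the per-trial
    values do not depend on annotation order.
    """
    cfg = config or ExtractConfig()
    t0, t1 = rec.start_time, rec.start_time + rec.duration
    for t in session.trials:
        if t.t_start < t0 - 1e-9 or t.t_end > t1 + 1e-9:
            raise ValueError(
                f"trial {t.trial_index} window [{t.t_start}, {t.t_end}) outside the "
                f"recording span [{t0:.3f}, {t1:.3f})"
            )
    conditioned = condition_signal(rec, cfg)
    cycles = detect_cycles(
        conditioned, threshold=cfg.cycle_threshold_mbar, min_separation=cfg.min_peak_separation_s
    )
    logger.info(
        "session %s: %d cycles detected over %.1f s", session.subject_id, len(cycles), rec.duration
    )
    rows = []
    for t in sorted(session.trials, key=lambda a: a.trial_index):
        in_win = [c for c in cycles if t.t_start <= c.time < t.t_end]
        bursts, isolated = segment_bursts(
            in_win, gap_threshold=cfg.burst_gap_s, min_cycles=cfg.min_cycles_per_burst
        )
        feats = compute_trial_features(
            in_win,
            bursts,
            trial_duration=t.duration,
            include_isolated_cycles=cfg.include_isolated_cycles,
            cycle_interval_all_gaps=cfg.cycle_interval_all_gaps,
        )
        logger.info(
            "  trial %d (%s): %d cycles, %d bursts, %d isolated",
            t.trial_index, t.condition.value, len(in_win), len(bursts), len(isolated),
        )
        rows.append(
            {
                "subject_id": session.subject_id,
                "trial_index": t.trial_index,
                "condition": t.condition.value,
                **feats.as_dict(),
            }
        )
    return FeatureTable(pd.DataFrame(rows))
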