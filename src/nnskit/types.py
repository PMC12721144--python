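"""Core data model for the NNS pipeline.

The objects here mirror the stages of a non-nutritive sucking (NNS)
experiment: a pressure trace recorded from a pacifier transducer, a
session design of annotated trial windows, the maternal questionnaire,
and the per-trial feature table that downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

#: Conversion from millibar to centimetres of water.
MBAR_TO_CMH2O = 1.01972

#: Names of the eight NNS microstructure variables, in canonical order.
NNS_FEATURES = [
    "cycles_trial",
    "bursts_trial",
    "cycles_burst",
    "burst_duration",
    "burst_interval",
    "cycle_interval",
    "cycles_burst_interval",
    "amplitude",
]


class Condition(str, Enum):
    """Trial condition: silence or one of three renditions of a nursery rhyme."""

    BASELINE = "baseline"
    NARRATED = "narrated"
    HUMMED = "hummed"
    SYNTHESIZED = "synthesized"

    @classmethod
    def parse(cls, label) -> "Condition":
        """Case-insensitive parsing of a condition label."""
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown condition label {label!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


CONDITIONS = [Condition.BASELINE, Condition.NARRATED, Condition.HUMMED, Condition.SYNTHESIZED]
STIMULATION_CONDITIONS = [Condition.NARRATED, Condition.HUMMED, Condition.SYNTHESIZED]


@dataclass
class PressureRecording:
    """Uniformly sampled pacifier pressure trace.

    Parameters
    ----------
    samples : ndarray
        Pressure values in mbar.
    sample_rate : float
        Sampling rate in Hz (> 0).
    start_time : float
        Offset of the first sample in seconds.
    subject_id : str, optional
        Identifier of the newborn the trace belongs to.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Duration in seconds (n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, including the start offset."""
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, samples: np.ndarray, sample_rate: Optional[float] = None) -> "PressureRecording":
        return PressureRecording(
            samples=np.asarray(samples, dtype=float),
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
            start_time=self.start_time,
            subject_id=self.subject_id,
        )


@dataclass
class TrialAnnotation:
    """One trial window: index, condition, and half-open span [t_start, t_end)."""

    trial_index: int
    condition: Condition
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        self.condition = Condition.parse(self.condition)
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")
        if not self.t_end > self.t_start:
            raise ValueError(
                f"trial {self.trial_index}: t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# Session design bounds: baseline plus at least one repetition of each of the
# three stimulation conditions (4 trials) up to four repetitions each (13).
MIN_TRIALS = 4
MAX_TRIALS = 13
MAX_REPEATS = 4


@dataclass
class SessionDesign:
    """Ordered trial annotations for one subject's session."""

    subject_id: str
    trials: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.trials)
        if not MIN_TRIALS <= n <= MAX_TRIALS:
            raise ValueError(
                f"session {self.subject_id}: {n} trials outside the design bounds "
                f"[{MIN_TRIALS}, {MAX_TRIALS}]"
            )
        if self.trials[0].condition is not Condition.BASELINE:
            raise ValueError(
                f"session {self.subject_id}: first trial must be baseline, "
                f"got {self.trials[0].condition.value!r}"
            )
        counts = {c: 0 for c in STIMULATION_CONDITIONS}
        for t in self.trials[1:]:
            if t.condition is Condition.BASELINE:
                raise ValueError(
                    f"session {self.subject_id}: baseline may only appear as the first trial"
                )
            counts[t.condition] += 1
        for cond, k in counts.items():
            if not 1 <= k <= MAX_REPEATS:
                raise ValueError(
                    f"session {self.subject_id}: condition {cond.value!r} appears {k} "
                    f"times; design requires 1-{MAX_REPEATS}"
                )
        ordered = sorted(self.trials, key=lambda t: t.t_start)
        for a, b in zip(ordered, ordered[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"session {self.subject_id}: trials {a.trial_index} and "
                    f"{b.trial_index} overlap"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class QuestionnaireRecord:
    """Coded responses of one mother's prenatal-exposure questionnaire.

    Ordinal codes follow a monotone mapping of the verbatim response
    options; None marks a missing (unanswered) item.

    talk_day : 1-4  (<2 h, 2-4 h, 4-6 h, >6 h of daily speaking)
    womb_talk_week : 0-3 (never, sometimes, almost every day, every day)
    womb_talk_day : 1-3 (once, two or three times, more than three times)
    sing, instrument : 0/1
    """

    subject_id: str
    talk_day: Optional[int] = None
    womb_talk_week: Optional[int] = None
    womb_talk_day: Optional[int] = None
    sing: Optional[int] = None
    instrument: Optional[int] = None

    _RANGES = {
        "talk_day": (1, 4),
        "womb_talk_week": (0, 3),
        "womb_talk_day": (1, 3),
        "sing": (0, 1),
        "instrument": (0, 1),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if v is None:
                continue
            v = int(v)
            setattr(self, name, v)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside valid range [{lo}, {hi}]")


COVARIATES = ["talk_day", "womb_talk_week", "womb_talk_day", "sing", "instrument"]
BINARY_COVARIATES = ["sing", "instrument"]


@dataclass
class TrialFeatures:
    """The eight NNS variables for one trial.

    Interval/duration statistics are NaN when their support is empty
    (e.g. burst_interval with fewer than two bursts).  `amplitude` is in
    cmH2O; everything temporal is in seconds.
    """

    cycles_trial: float
    bursts_trial: float
    cycles_burst: float
    burst_duration: float
    burst_interval: float
    cycle_interval: float
    cycles_burst_interval: float
    amplitude: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in NNS_FEATURES}


class FeatureTable:
    """Long-format table of NNS variables: one row per (subject, trial).

    Thin wrapper around a pandas DataFrame with the canonical columns
    ``subject_id, trial_index, condition`` + the eight NNS variables.
    """

    KEY_COLUMNS = ["subject_id", "trial_index", "condition"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.KEY_COLUMNS + NNS_FEATURES if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        df = df.loc[:, self.KEY_COLUMNS + NNS_FEATURES].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["trial_index"] = df["trial_index"].astype(int)
        df["condition"] = [Condition.parse(c).value for c in df["condition"]]
        dup = df.duplicated(subset=["subject_id", "trial_index"])
        if dup.any():
            first = df.loc[dup, ["subject_id", "trial_index"]].iloc[0]
            raise ValueError(
                f"duplicate (subject, trial) key: ({first['subject_id']}, {first['trial_index']})"
            )
        neg = [
            c
            for c in NNS_FEATURES
            if np.nanmin(df[c].to_numpy(dtype=float), initial=0.0) < 0
        ]
        if neg:
            raise ValueError(f"negative values in non-negative variables: {neg}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.df.equals(other.df)

    def subjects(self) -> list:
        return sorted(self.df["subject_id"].unique())

    def subject_level(self, feature: Optional[str] = None) -> pd.DataFrame:
        """Aggregate trials to subject x condition means.

        Returns a DataFrame indexed by (subject_id, condition) with one
        column per feature (or only `feature` when given).
        """
        cols = [feature] if feature else NNS_FEATURES
        return (
            self.df.groupby(["subject_id", "condition"], sort=True)[cols]
            .mean()
            .reset_index()
        )

    @classmethod
    def from_records(cls, records: list) -> "FeatureTable":
        return cls(pd.DataFrame.from_records(records))
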