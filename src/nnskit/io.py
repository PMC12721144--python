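"""Readers and writers: pressure recordings, annotations, questionnaires, features.

Formats are deliberately plain: mono WAV or two-column CSV for signals,
CSV for everything tabular, so every intermediate artifact of the
pipeline can be audited with a text editor.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import (
    NNS_FEATURES,
    Condition,
    FeatureTable,
    PressureRecording,
    QuestionnaireRecord,
    SessionDesign,
    TrialAnnotation,
)

logger = logging.getLogger("nnskit")

_REL_TOL = 1e-6  # relative tolerance on the uniformity of CSV time steps


def read_pressure_recording(
    path,
    format: Optional[str] = None,
    calibration_mbar: float = 1.0,
    subject_id: Optional[str] = None,
) -> PressureRecording:
    """Read a pressure trace from a mono WAV or a time/pressure CSV.

    Parameters
    ----------
    path : path-like
        Input file.  Format is inferred from the suffix unless `format`
        ("wav" or "csv") is given.
    calibration_mbar : float
        For WAV input: mbar per unit full-scale.  Integer WAV samples are
        first rescaled to [-1, 1] by their type's full-scale value.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "wav":
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError(f"{path}: expected mono WAV, got {data.shape[1]} channels")
        if data.size == 0:
            raise ValueError(f"{path}: empty file")
        if np.issubdtype(data.dtype, np.integer):
            full_scale = float(np.iinfo(data.dtype).max)
            samples = data.astype(float) / full_scale
        else:
            samples = data.astype(float)
        samples = samples * calibration_mbar
        rec = PressureRecording(samples=samples, sample_rate=float(rate), subject_id=subject_id)
    elif fmt == "csv":
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"{path}: empty file")
        for col in ("time_s", "pressure_mbar"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: need at least 2 samples to infer the rate")
        steps = np.diff(t)
        step = steps[0]
        if step <= 0:
            raise ValueError(f"{path}: non-uniform sampling at index 1 (non-increasing time)")
        bad = np.nonzero(np.abs(steps - step) > _REL_TOL * max(abs(step), 1.0))[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-uniform sampling at index {int(bad[0]) + 1} "
                f"(step {steps[bad[0]]:.9g} != {step:.9g})"
            )
        rec = PressureRecording(
            samples=df["pressure_mbar"].to_numpy(dtype=float),
            sample_rate=1.0 / step,
            start_time=float(t[0]),
            subject_id=subject_id,
        )
    else:
        raise ValueError(f"unsupported recording format {fmt!r} (expected wav or csv)")
    logger.info(
        "read recording %s: %d samples @ %.6g Hz (%.3f s)",
        path.name, rec.n_samples, rec.sample_rate, rec.duration,
    )
    return rec


def write_pressure_recording(rec: PressureRecording, path) -> None:
    """Write a recording as a time/pressure CSV (lossless round-trip)."""
    path = Path(path)
    pd.DataFrame({"time_s": rec.times(), "pressure_mbar": rec.samples}).to_csv(
        path, index=False
    )


def read_annotations(path) -> list:
    """Read trial annotations; returns a list of validated SessionDesigns.

    The CSV must carry subject_id, trial_index, condition, t_start, t_end.
    Condition labels are matched case-insensitively.
    """
    df = pd.read_csv(path)
    required = ["subject_id", "trial_index", "condition", "t_start", "t_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sessions = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("trial_index")
        trials = [
            TrialAnnotation(
                trial_index=int(r.trial_index),
                condition=Condition.parse(r.condition),
                t_start=float(r.t_start),
                t_end=float(r.t_end),
            )
            for r in grp.itertuples()
        ]
        sessions.append(SessionDesign(subject_id=str(sid), trials=trials))
    logger.info("read annotations %s: %d sessions, %d trials", path, len(sessions), len(df))
    return sessions


def write_annotations(sessions: list, path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "trial_index": t.trial_index,
            "condition": t.condition.value,
            "t_start": t.t_start,
            "t_end": t.t_end,
        }
        for s in sessions
        for t in s.trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Questionnaire

def _norm(s: str) -> str:
    return " ".join(str(s).strip().lower().replace("hours", "h").split())

TALK_DAY_MAP = {
    "less than 2 h": 1, "<2 h": 1, "<2h": 1,
    "2 to 4 h": 2, "2-4 h": 2, "from 3 to 4 h": 2,
    "4 to 6 h": 3, "4-6 h": 3, "from 4 to 6 h": 3,
    "more than 6 h": 4, ">6 h": 4, ">6h": 4,
}
WOMB_TALK_WEEK_MAP = {
    "never": 0,
    "sometimes": 1,
    "almost every day": 2,
    "every day": 3,
}
WOMB_TALK_DAY_MAP = {
    "once": 1, "one time per day": 1,
    "two or three times": 2, "two times a day": 2, "two or three times a day": 2,
    "more than three times": 3, "more than 3 times": 3, "more than 3 times a day": 3,
}
YES_NO_MAP = {"yes": 1, "no": 0, "y": 1, "n": 0}

_FIELD_MAPS = {
    "talk_day": TALK_DAY_MAP,
    "womb_talk_week": WOMB_TALK_WEEK_MAP,
    "womb_talk_day": WOMB_TALK_DAY_MAP,
    "sing": YES_NO_MAP,
    "instrument": YES_NO_MAP,
}


def _map_response(field: str, value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    # already-coded numeric responses pass through (range-checked later)
    try:
        return int(value)
    except (TypeError, ValueError):
        pass
    key = _norm(value)
    mapping = _FIELD_MAPS[field]
    if key not in mapping:
        raise ValueError(
            f"questionnaire field {field!r}: unmappable response {value!r}"
        )
    return mapping[key]


def read_questionnaire(path) -> list:
    """Read the maternal questionnaire; verbatim options become ordinal codes.

    Blank cells are preserved as missing (the row is retained).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing column 'subject_id'")
    missing = [c for c in _FIELD_MAPS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for r in df.itertuples():
        records.append(
            QuestionnaireRecord(
                subject_id=str(r.subject_id),
                **{f: _map_response(f, getattr(r, f)) for f in _FIELD_MAPS},
            )
        )
    logger.info("read questionnaire %s: %d records", path, len(records))
    return records


def questionnaire_frame(records: list) -> pd.DataFrame:
    """Coded questionnaire records as a DataFrame (NaN for missing)."""
    return pd.DataFrame(
        [
            {
                "subject_id": q.subject_id,
                **{f: (np.nan if getattr(q, f) is None else getattr(q, f)) for f in _FIELD_MAPS},
            }
            for q in records
        ]
    )


def write_questionnaire(records: list, path) -> None:
    questionnaire_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature tables

def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV; missing values become empty cells."""
    table.df.to_csv(path, index=False, float_format="%.6g")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path)
    for c in NNS_FEATURES:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return FeatureTable(df)
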