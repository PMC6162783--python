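"""CSV and YAML input/output for the session-log pipeline.

File conventions: comma-separated, UTF-8, mandatory header row, '.' decimal.
An absent measurement is an *empty cell*, never 0 — unambiguous missingness
is what makes pairwise deletion downstream trustworthy.

Sessions CSV columns::

    participant_id, week, session_index, duration_min, hr_mean,
    zone_below50_min, zone_50_60_min, zone_60_70_min, zone_70_80_min,
    zone_80_90_min, zone_90_100_min, rpe

Zone columns are minutes in the %HRmax bands ordered below-50%, 50-60,
60-70, 70-80, 80-90, 90-100. Participants CSV columns::

    participant_id, sex, age, hr_rest, hr_max
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cohort import Participant, SessionRecord
from .exceptions import ConfigurationError, FormatError, IntegrityError, ValidationError

__all__ = [
    "ZONE_COLUMNS",
    "read_participants", "write_participants",
    "read_sessions", "write_sessions",
    "read_config_file",
]

ZONE_COLUMNS = (
    "zone_below50_min", "zone_50_60_min", "zone_60_70_min",
    "zone_70_80_min", "zone_80_90_min", "zone_90_100_min",
)

PARTICIPANT_COLUMNS = ("participant_id", "sex", "age", "hr_rest", "hr_max")
SESSION_COLUMNS = (("participant_id", "week", "session_index", "duration_min",
                    "hr_mean") + ZONE_COLUMNS + ("rpe",))
REQUIRED_SESSION_COLUMNS = ("participant_id", "week", "session_index",
                            "duration_min")


def _fmt(value) -> str:
    """Canonical cell text: empty for absent, shortest round-trip repr else."""
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        if value == int(value) and abs(value) < 1e15:
            return str(int(value)) + ".0"
        return repr(value)
    return str(value)


def write_participants(participants: Sequence[Participant], path) -> None:
    lines = [",".join(PARTICIPANT_COLUMNS)]
    for p in participants:
        lines.append(",".join(_fmt(v) for v in (
            p.participant_id, p.sex, float(p.age), float(p.hr_rest),
            float(p.hr_max))))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_participants(path) -> list:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(PARTICIPANT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}")
    if frame["participant_id"].duplicated().any():
        dupes = frame.loc[frame["participant_id"].duplicated(), "participant_id"]
        raise IntegrityError(
            f"{path}: duplicate participant_id {sorted(set(dupes))}")
    return [Participant(participant_id=str(r.participant_id), sex=str(r.sex),
                        age=float(r.age), hr_rest=float(r.hr_rest),
                        hr_max=float(r.hr_max))
            for r in frame.itertuples(index=False)]


def write_sessions(sessions: Sequence[SessionRecord], path) -> None:
    lines = [",".join(SESSION_COLUMNS)]
    for s in sessions:
        zm = s.zone_minutes if s.zone_minutes is not None else (None,) * 6
        cells = [s.participant_id, s.week, s.session_index,
                 float(s.duration_min),
                 None if s.hr_mean is None else float(s.hr_mean),
                 *[None if m is None else float(m) for m in zm],
                 s.rpe]
        lines.append(",".join(_fmt(c) for c in cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _cell(row, col):
    v = getattr(row, col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def read_sessions(path) -> list:
    """Read and validate a sessions CSV into typed records.

    Malformed rows are collected and reported together, each with its file
    line number (header is line 1). Duplicate (participant, week,
    session_index) keys are an integrity error; an empty file with a valid
    header gives an empty list with a warning.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(REQUIRED_SESSION_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}")
    for col in SESSION_COLUMNS:
        if col not in frame.columns:
            frame[col] = float("nan")
    if frame.empty:
        warnings.warn(f"{path}: no session rows", stacklevel=2)
        return []
    keys = frame[["participant_id", "week", "session_index"]]
    if keys.duplicated().any():
        first = keys[keys.duplicated()].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate session key "
            f"({first.participant_id}, week {first.week}, "
            f"session {first.session_index})")

    records, errors = [], []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            zone_cells = [_cell(row, c) for c in ZONE_COLUMNS]
            if all(z is None for z in zone_cells):
                zones = None
            elif any(z is None for z in zone_cells):
                raise ValidationError("zone minutes must be all present or all absent")
            else:
                zones = tuple(float(z) for z in zone_cells)
            rpe = _cell(row, "rpe")
            records.append(SessionRecord(
                participant_id=str(row.participant_id),
                week=int(row.week),
                session_index=int(row.session_index),
                duration_min=float(row.duration_min),
                hr_mean=None if _cell(row, "hr_mean") is None
                else float(row.hr_mean),
                zone_minutes=zones,
                rpe=None if rpe is None else int(rpe),
            ))
        except (ValueError, ConfigurationError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} malformed row(s):\n  " + "\n  ".join(errors))
    return records


def read_config_file(path) -> dict:
    """Read a YAML (or flat ``key: value``) config file into a dict."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return data
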