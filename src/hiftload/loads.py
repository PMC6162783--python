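"""Internal training-load quantification.

Three session-level internal-load metrics, each reducing one training
session to a single number:

* **sRPE** — session rating of perceived exertion load: duration (min)
  times Borg 6-20 RPE.
* **Edwards' TL** — minutes in each of five %HRmax zones weighted by the
  zone factors 1-5 (50-60% -> 1 ... 90-100% -> 5) and summed; time below
  50% HRmax carries factor 0.
* **Banister TRIMP** — duration x HRr x b x exp(k x HRr), with the
  fractional heart-rate reserve HRr = (HRts - HRb) / (HRmax - HRb) and the
  published coefficients b = 0.64, k = 1.92 by default. The original
  Banister method has sex-specific coefficients; those are available behind
  an explicit ``weighting`` choice.

Missing inputs propagate as missing outputs (``None``), never as zero, so
downstream analyses can apply pairwise deletion per criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import Participant, SessionRecord
from .exceptions import IntegrityError, ValidationError

__all__ = [
    "ZoneFactorTable",
    "LoadRecord",
    "TRIMP_COEFFICIENTS",
    "compute_srpe",
    "compute_edwards",
    "compute_hrr",
    "compute_trimp",
    "quantify_sessions",
    "loads_to_frame",
]

#: TRIMP exponential weighting coefficients (b, k). "default" is the single
#: published pair applied to everyone; "male"/"female" are the classic
#: sex-specific Banister pairs selectable via ``weighting="sex_specific"``.
TRIMP_COEFFICIENTS = {
    "default": (0.64, 1.92),
    "male": (0.64, 1.92),
    "female": (0.86, 1.67),
}


@dataclass(frozen=True)
class ZoneFactorTable:
    """Weighting factors for the five %HRmax zones of the Edwards method.

    ``bands`` are (lower %HRmax, upper %HRmax, factor) triples; bands are
    half-open [lower, upper) except the top band, which is closed at 100.
    Time below the first band's lower bound carries ``sub50_factor``.
    """

    bands: tuple = (
        (50.0, 60.0, 1.0),
        (60.0, 70.0, 2.0),
        (70.0, 80.0, 3.0),
        (80.0, 90.0, 4.0),
        (90.0, 100.0, 5.0),
    )
    sub50_factor: float = 0.0

    def __post_init__(self):
        if len(self.bands) != 5:
            raise ValidationError("ZoneFactorTable requires exactly five bands")
        for (lo1, hi1, _), (lo2, _, _) in zip(self.bands, self.bands[1:]):
            if hi1 != lo2 or lo1 >= hi1:
                raise ValidationError(
                    "zone bands must be contiguous, non-overlapping and increasing")

    @property
    def factors(self) -> tuple:
        """Factors ordered (below-50, band 1..5) to match zone-minute vectors."""
        return (self.sub50_factor,) + tuple(f for _, _, f in self.bands)


DEFAULT_ZONE_FACTORS = ZoneFactorTable()


@dataclass(frozen=True)
class LoadRecord:
    """The internal-load quantifications of one session.

    Any metric whose inputs were absent is ``None``. ``rpe``, ``hr_mean``
    and ``duration_min`` are carried along for downstream agreement and
    reporting stages.
    """

    participant_id: str
    week: int
    session_index: int
    duration_min: float
    rpe: Optional[int]
    hr_mean: Optional[float]
    hr_relative: Optional[float]  # HRr, fraction of heart-rate reserve
    srpe: Optional[float]
    edwards_tl: Optional[float]
    trimp: Optional[float]


def compute_srpe(duration_min: float, rpe: Optional[int]) -> Optional[float]:
    """Session-RPE load: ``duration_min * rpe``; ``None`` RPE stays absent."""
    if duration_min <= 0:
        raise ValidationError(f"duration_min must be > 0, got {duration_min}")
    if rpe is None:
        return None
    if not 6 <= rpe <= 20:
        raise ValidationError(f"rpe must lie in 6..20 (Borg scale), got {rpe}")
    return duration_min * rpe


def compute_edwards(zone_minutes, factors: ZoneFactorTable = DEFAULT_ZONE_FACTORS
                    ) -> Optional[float]:
    """Edwards' TL: sum over zones of minutes x zone factor.

    ``zone_minutes`` is ordered (below-50, 50-60, ..., 90-100 %HRmax);
    absent zone data gives an absent result.
    """
    if zone_minutes is None:
        return None
    zm = tuple(zone_minutes)
    if len(zm) != len(factors.factors):
        raise ValidationError(
            f"expected {len(factors.factors)} zone durations, got {len(zm)}")
    if any(m < 0 for m in zm):
        raise ValidationError(f"zone minutes must be non-negative, got {zm}")
    return float(sum(m * f for m, f in zip(zm, factors.factors)))


def compute_hrr(hr_mean: Optional[float], hr_rest: float, hr_max: float
                ) -> Optional[float]:
    """Fractional heart-rate reserve HRr = (HRts - HRb) / (HRmax - HRb).

    Clamped to [0, 1] with a warning when the session mean falls outside
    the resting-to-maximum range (age-predicted HRmax is an estimate, so
    out-of-range sessions are kept rather than dropped).
    """
    if hr_rest >= hr_max:
        raise ValidationError(
            f"hr_rest ({hr_rest}) must be below hr_max ({hr_max})")
    if hr_mean is None:
        return None
    hrr = (hr_mean - hr_rest) / (hr_max - hr_rest)
    if not 0.0 <= hrr <= 1.0:
        warnings.warn(
            f"session mean HR {hr_mean} outside [{hr_rest}, {hr_max}]; "
            f"HRr clamped to [0, 1]", stacklevel=2)
        hrr = min(1.0, max(0.0, hrr))
    return hrr


def compute_trimp(duration_min: float, hrr: Optional[float],
                  weighting: str = "default") -> Optional[float]:
    """Banister TRIMP: ``D * HRr * b * exp(k * HRr)``.

    ``weighting`` selects the coefficient pair from
    :data:`TRIMP_COEFFICIENTS`; clamping of HRr happens upstream in
    :func:`compute_hrr`, so out-of-range values here are an error.
    """
    if duration_min <= 0:
        raise ValidationError(f"duration_min must be > 0, got {duration_min}")
    if hrr is None:
        return None
    if not 0.0 <= hrr <= 1.0:
        raise ValidationError(f"hrr must lie in [0, 1], got {hrr}")
    try:
        b, k = TRIMP_COEFFICIENTS[weighting]
    except KeyError:
        raise ValidationError(
            f"unknown TRIMP weighting {weighting!r}; "
            f"choose from {sorted(TRIMP_COEFFICIENTS)}") from None
    return duration_min * hrr * b * math.exp(k * hrr)


def quantify_sessions(participants: Sequence[Participant],
                      sessions: Sequence[SessionRecord],
                      factors: ZoneFactorTable = DEFAULT_ZONE_FACTORS,
                      weighting: str = "default") -> list:
    """Compute one :class:`LoadRecord` per session.

    ``weighting="sex_specific"`` applies the male/female Banister
    coefficient pairs by participant sex; any other value is passed through
    to :func:`compute_trimp` for every participant.
    """
    by_id = {p.participant_id: p for p in participants}
    out = []
    for s in sessions:
        try:
            p = by_id[s.participant_id]
        except KeyError:
            raise IntegrityError(
                f"session {s.session_index} references unknown participant "
                f"{s.participant_id!r}") from None
        if weighting == "sex_specific":
            w = "male" if p.sex == "M" else "female"
        else:
            w = weighting
        hrr = compute_hrr(s.hr_mean, p.hr_rest, p.hr_max)
        out.append(LoadRecord(
            participant_id=s.participant_id,
            week=s.week,
            session_index=s.session_index,
            duration_min=s.duration_min,
            rpe=s.rpe,
            hr_mean=s.hr_mean,
            hr_relative=hrr,
            srpe=compute_srpe(s.duration_min, s.rpe),
            edwards_tl=compute_edwards(s.zone_minutes, factors),
            trimp=compute_trimp(s.duration_min, hrr, w),
        ))
    return out


def loads_to_frame(load_records: Sequence[LoadRecord]):
    """Tabulate load records, one row per session; absent metrics are NaN."""
    import pandas as pd
    frame = pd.DataFrame([{
        "participant_id": r.participant_id,
        "week": r.week,
        "session_index": r.session_index,
        "duration_min": r.duration_min,
        "rpe": r.rpe,
        "srpe": r.srpe,
        "hr_mean": r.hr_mean,
        "hrr": r.hr_relative,
        "edwards_tl": r.edwards_tl,
        "trimp": r.trimp,
    } for r in load_records])
    if not frame.empty:
        frame["rpe"] = frame["rpe"].astype("Int64")
    return frame
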