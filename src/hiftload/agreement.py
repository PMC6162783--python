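"""Intra-rater reliability via within-subject quartile agreement.

The procedure treats each session as being "rated" twice — once by the
participant's perception (Borg RPE) and once by their physiology (mean
session heart rate) — and asks whether the two ratings land in the same
*within-subject* quartile. Quartiles are computed per participant, never
pooled, so that a participant who habitually reports high RPE at moderate
%HRmax is compared only against their own distribution.

Two agreement indices are reported:

* **CoA** (coefficient of agreement): the raw proportion of sessions whose
  RPE quartile equals the HR quartile — correct agreements over possible
  agreements, with no chance correction;
* **ICC**: an intraclass correlation on the paired quartile indices,
  absolute-agreement single-measurement by default, with a 95% CI.

Quartile convention: a value is assigned 1 + (number of empirical
25th/50th/75th percentile cutpoints it strictly exceeds), with percentiles
computed by the standard linear-interpolation rule. Values exactly at a
cutpoint therefore fall in the lower quartile, and tied values always share
a quartile (no random tie-breaking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "AgreementResult",
    "assign_within_subject_quartiles",
    "quartile_pairs",
    "coefficient_of_agreement",
    "icc_quartiles",
    "reliability_report",
    "DEFAULT_BLOCKS",
]

#: Default training-block definition: two 3-week blocks of the study
#: calendar (weeks 2-4 and 6-8).
DEFAULT_BLOCKS = {"block1": (2, 3, 4), "block2": (6, 7, 8)}

#: Minimum complete sessions a participant needs for quartile assignment.
MIN_SESSIONS_PER_PARTICIPANT = 4

#: Minimum paired sessions for an ICC confidence interval.
MIN_PAIRS_FOR_CI = 10


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between perceived and physiological effort quartiles."""

    icc: Optional[float]
    icc_ci_low: Optional[float]
    icc_ci_high: Optional[float]
    icc_p_value: Optional[float]
    coa: float
    n_pairs: int
    icc_variant: str
    warnings: tuple = ()

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_ci_low": self.icc_ci_low,
            "icc_ci_high": self.icc_ci_high,
            "icc_p_value": self.icc_p_value,
            "coa": self.coa,
            "n_pairs": self.n_pairs,
            "icc_variant": self.icc_variant,
            "warnings": list(self.warnings),
        }


def assign_within_subject_quartiles(values) -> np.ndarray:
    """Map one participant's values to quartile indices 1-4.

    Cutpoints are the empirical 25th/50th/75th percentiles (linear
    interpolation); a value exactly at a cutpoint goes to the lower
    quartile. All-identical values are all assigned quartile 1 with a
    warning (degenerate spread).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < MIN_SESSIONS_PER_PARTICIPANT:
        raise ValidationError(
            f"need at least {MIN_SESSIONS_PER_PARTICIPANT} values for "
            f"quartile assignment, got {v.size}")
    if np.isnan(v).any():
        raise ValidationError("quartile assignment requires non-missing values")
    if np.all(v == v[0]):
        warnings.warn(
            "all values identical; every session assigned quartile 1 "
            "(degenerate spread)", stacklevel=2)
        return np.ones(v.size, dtype=int)
    cuts = np.percentile(v, [25, 50, 75])
    return (1 + (v[:, None] > cuts[None, :]).sum(axis=1)).astype(int)


def quartile_pairs(sessions: pd.DataFrame,
                   rpe_col: str = "rpe",
                   hr_col: str = "hr_mean") -> pd.DataFrame:
    """Build per-session (RPE quartile, HR quartile) pairs.

    Only sessions with both measures present are used; participants with
    fewer than four such sessions are excluded with a warning. Quartiles
    are computed within participant over exactly the rows passed in, so
    callers control the reference window (whole study or one block).
    """
    required = {"participant_id", rpe_col, hr_col}
    missing = required - set(sessions.columns)
    if missing:
        raise ValidationError(f"sessions frame lacks columns {sorted(missing)}")
    complete = sessions.dropna(subset=[rpe_col, hr_col])
    parts = []
    for pid, grp in complete.groupby("participant_id", sort=True):
        if len(grp) < MIN_SESSIONS_PER_PARTICIPANT:
            warnings.warn(
                f"participant {pid}: only {len(grp)} complete sessions; "
                f"excluded from quartile agreement", stacklevel=2)
            continue
        out = grp.copy()
        out["rpe_quartile"] = assign_within_subject_quartiles(
            grp[rpe_col].to_numpy(dtype=float))
        out["hr_quartile"] = assign_within_subject_quartiles(
            grp[hr_col].to_numpy(dtype=float))
        parts.append(out)
    if not parts:
        return complete.iloc[0:0].assign(rpe_quartile=pd.Series(dtype=int),
                                         hr_quartile=pd.Series(dtype=int))
    return pd.concat(parts, axis=0)


def coefficient_of_agreement(rpe_quartile, hr_quartile) -> float:
    """Proportion of sessions whose two quartiles match exactly."""
    rq = np.asarray(rpe_quartile)
    hq = np.asarray(hr_quartile)
    if rq.size == 0:
        raise ValidationError("coefficient of agreement requires >= 1 pair")
    if rq.shape != hq.shape:
        raise ValidationError("quartile vectors must have equal length")
    return float(np.mean(rq == hq))


def _icc_pingouin(rq: np.ndarray, hq: np.ndarray, variant: str):
    """Absolute-agreement/consistency ICC via pingouin's ANOVA tables."""
    import pingouin as pg
    n = rq.size
    long = pd.DataFrame({
        "session": np.tile(np.arange(n), 2),
        "rater": np.repeat(["rpe", "hr"], n),
        "score": np.concatenate([rq, hq]).astype(float),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pingouin warns on edge-case ANOVAs
        table = pg.intraclass_corr(data=long, targets="session",
                                   raters="rater", ratings="score")
    row = table.set_index("Type").loc[variant]
    lo, hi = row["CI95"] if "CI95" in row.index else row["CI95%"]
    return float(row["ICC"]), float(lo), float(hi), float(row["pval"])


def icc_quartiles(rpe_quartile, hr_quartile,
                  variant: str = "ICC(A,1)") -> AgreementResult:
    """ICC + CoA on paired quartile indices.

    ``variant`` names the ICC type (pingouin labels); the default ICC(A,1) is the
    single-measurement absolute-agreement coefficient, matching the
    "correct matching" framing of the agreement question. The variant used
    is recorded in the result. Fewer than 10 pairs: ICC is computed but the
    CI is absent, with a warning. Zero variance in both vectors: ICC is
    undefined and reported absent, with a warning (identical vectors with
    variance give ICC exactly 1).
    """
    rq = np.asarray(rpe_quartile, dtype=float)
    hq = np.asarray(hr_quartile, dtype=float)
    coa = coefficient_of_agreement(rq, hq)
    n = rq.size
    notes = []

    if np.all(rq == rq[0]) and np.all(hq == hq[0]):
        warnings.warn("zero variance in both quartile vectors; ICC undefined",
                      stacklevel=2)
        return AgreementResult(None, None, None, None, coa, n, variant,
                               ("icc undefined: zero variance",))
    if np.array_equal(rq, hq):
        # Perfect agreement with spread: ICC is exactly 1, CI degenerate.
        return AgreementResult(1.0, 1.0, 1.0, 0.0, coa, n, variant, ())

    icc, lo, hi, pval = _icc_pingouin(rq, hq, variant)
    if n < MIN_PAIRS_FOR_CI:
        warnings.warn(
            f"only {n} pairs (< {MIN_PAIRS_FOR_CI}); ICC CI suppressed",
            stacklevel=2)
        notes.append(f"ci suppressed: n_pairs={n}")
        lo = hi = None
    return AgreementResult(icc, lo, hi, pval, coa, n, variant, tuple(notes))


def _check_blocks(blocks: dict, observed_weeks) -> None:
    observed = set(int(w) for w in observed_weeks)
    claimed: list = []
    for name, wks in blocks.items():
        claimed.extend(int(w) for w in wks)
    if len(claimed) != len(set(claimed)):
        raise ConfigurationError("block definition assigns a week to two blocks")
    if set(claimed) != observed:
        raise ConfigurationError(
            f"block definition {sorted(set(claimed))} does not partition the "
            f"observed weeks {sorted(observed)}")


def reliability_report(sessions: pd.DataFrame,
                       blocks: dict = None,
                       quartile_mode: str = "block-local",
                       icc_variant: str = "ICC(A,1)") -> dict:
    """Overall and per-block quartile agreement.

    ``blocks`` maps block label to the weeks it contains and must partition
    the observed weeks (default: weeks 2-4 vs 6-8). ``quartile_mode``
    chooses the reference window for per-block quartiles:

    * ``"block-local"`` (default): quartiles recomputed within each block's
      own sessions — reliability *within the period analysed*;
    * ``"study-wide"``: quartiles from the full study, then split by block.

    Returns ``{"overall": AgreementResult, "per_block": {label: ...},
    "quartile_mode": ...}``.
    """
    if blocks is None:
        blocks = DEFAULT_BLOCKS
    if quartile_mode not in ("block-local", "study-wide"):
        raise ConfigurationError(
            f"quartile_mode must be 'block-local' or 'study-wide', "
            f"got {quartile_mode!r}")
    if "week" not in sessions.columns:
        raise ValidationError("sessions frame lacks a 'week' column")
    complete = sessions.dropna(subset=["rpe", "hr_mean"])
    _check_blocks(blocks, complete["week"].unique())

    overall_pairs = quartile_pairs(sessions)
    overall = icc_quartiles(overall_pairs["rpe_quartile"],
                            overall_pairs["hr_quartile"], icc_variant)
    per_block = {}
    for label, wks in blocks.items():
        wset = set(int(w) for w in wks)
        if quartile_mode == "block-local":
            sub = sessions[sessions["week"].isin(wset)]
            pairs = quartile_pairs(sub)
        else:
            pairs = overall_pairs[overall_pairs["week"].isin(wset)]
        per_block[label] = icc_quartiles(pairs["rpe_quartile"],
                                         pairs["hr_quartile"], icc_variant)
    return {"overall": overall, "per_block": per_block,
            "quartile_mode": quartile_mode}
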