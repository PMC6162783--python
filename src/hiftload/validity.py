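"""Criterion validity of the sRPE load against HR-based criterion loads.

Pearson correlations between sRPE and each HR-based criterion (Edwards' TL,
Banister TRIMP) at three scopes — per individual, pooled group, and pooled
by sex — plus per-training-block simple linear regression of the criterion
on sRPE with an R-squared confidence interval and residual diagnostics
(Durbin-Watson serial-independence statistic with the conventional 1.5-2.5
acceptance window, and a Breusch-Pagan homoscedasticity screen).

Sessions enter each analysis by pairwise deletion: a session is dropped
only when a variable *that analysis* needs is missing, so the analysable n
generally differs between the two criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import DEFAULT_BLOCKS, _check_blocks
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "CorrelationEntry",
    "RegressionResult",
    "CRITERIA",
    "pearson_by_scope",
    "fraction_significant",
    "block_regression",
    "validity_report",
]

#: Criterion load columns sRPE is validated against.
CRITERIA = ("edwards_tl", "trimp")

#: Minimum complete pairs for a defined correlation/p-value.
MIN_PAIRS_FOR_R = 3

#: Minimum block size for a bootstrap R^2 confidence interval.
MIN_PAIRS_FOR_CI = 10

#: Durbin-Watson acceptance window for residual serial independence.
DW_WINDOW = (1.5, 2.5)


@dataclass(frozen=True)
class CorrelationEntry:
    """One Pearson correlation between sRPE and a criterion load."""

    scope: str                 # "individual", "group" or "sex"
    scope_id: Optional[str]    # participant id, sex label, or None for group
    criterion: str
    n: int
    r: Optional[float]
    p_value: Optional[float]
    significant: Optional[bool]


@dataclass(frozen=True)
class RegressionResult:
    """OLS of a criterion load on sRPE within one training block."""

    block: str
    criterion: str
    n: int
    r: float
    r_squared: float
    r_squared_ci_low: Optional[float]
    r_squared_ci_high: Optional[float]
    ci_method: Optional[str]
    slope: float
    intercept: float
    p_value: float
    durbin_watson: float
    durbin_watson_ok: bool
    homoscedastic: Optional[bool]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "block", "criterion", "n", "r", "r_squared",
            "r_squared_ci_low", "r_squared_ci_high", "ci_method",
            "slope", "intercept", "p_value",
            "durbin_watson", "durbin_watson_ok", "homoscedastic")}


def _pearson(x: np.ndarray, y: np.ndarray):
    if np.std(x) == 0 or np.std(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _entry(scope, scope_id, criterion, sub: pd.DataFrame, alpha: float
           ) -> CorrelationEntry:
    n = len(sub)
    if n < MIN_PAIRS_FOR_R:
        warnings.warn(
            f"{scope} {scope_id or ''}: only {n} complete "
            f"(srpe, {criterion}) pairs; correlation undefined", stacklevel=3)
        return CorrelationEntry(scope, scope_id, criterion, n, None, None, None)
    r, p = _pearson(sub["srpe"].to_numpy(float), sub[criterion].to_numpy(float))
    if r is None:
        warnings.warn(
            f"{scope} {scope_id or ''}: zero variance; correlation undefined",
            stacklevel=3)
        return CorrelationEntry(scope, scope_id, criterion, n, None, None, None)
    return CorrelationEntry(scope, scope_id, criterion, n, r, p, bool(p < alpha))


def pearson_by_scope(loads: pd.DataFrame, participants: pd.DataFrame,
                     alpha: float = 0.05) -> list:
    """Correlation entries at individual, group and sex scope.

    One entry per participant per criterion, plus a pooled group entry and
    one pooled entry per sex, each on the pairwise-complete
    (srpe, criterion) sessions. Participants with fewer than three complete
    pairs get an entry with ``r`` absent and a warning.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha!r}")
    if loads.empty:
        raise ValidationError("no load records to correlate")
    sex_of = participants.set_index("participant_id")["sex"]
    entries = []
    for criterion in CRITERIA:
        complete = loads.dropna(subset=["srpe", criterion])
        for pid, grp in complete.groupby("participant_id", sort=True):
            entries.append(_entry("individual", str(pid), criterion, grp, alpha))
        entries.append(_entry("group", None, criterion, complete, alpha))
        sexes = complete["participant_id"].map(sex_of)
        for sex in ("M", "F"):
            entries.append(_entry("sex", sex, criterion,
                                  complete[sexes == sex], alpha))
    return entries


def fraction_significant(entries: Sequence[CorrelationEntry]) -> dict:
    """Per criterion, the share of individual-scope entries reaching
    significance (entries with undefined r count as not significant)."""
    individual = [e for e in entries if e.scope == "individual"]
    if not individual:
        raise ValidationError("no individual-scope correlation entries")
    out = {}
    for criterion in CRITERIA:
        sub = [e for e in individual if e.criterion == criterion]
        if sub:
            out[criterion] = sum(bool(e.significant) for e in sub) / len(sub)
    return out


def _bootstrap_r2_ci(x: np.ndarray, y: np.ndarray, n_boot: int, seed: int):
    """Seeded percentile bootstrap over sessions for R^2 (vectorised)."""
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    r2 = np.full(n_boot, 1.0)
    ok = den > 0
    r2[ok] = (num[ok] / den[ok]) ** 2
    lo, hi = np.percentile(r2, [2.5, 97.5])
    return float(lo), float(hi)


def _fisher_r2_ci(r: float, n: int):
    """Analytic CI: Fisher z interval for r, squared and ordered."""
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    r_lo, r_hi = np.tanh(z - half), np.tanh(z + half)
    bounds = sorted((float(r_lo ** 2), float(r_hi ** 2)))
    if r_lo < 0 < r_hi:  # interval for r straddles zero
        bounds[0] = 0.0
    return bounds[0], bounds[1]


def block_regression(loads: pd.DataFrame,
                     blocks: dict = None,
                     criterion: str = "edwards_tl",
                     ci_method: str = "bootstrap",
                     n_boot: int = 2000,
                     seed: int = 0) -> list:
    """Per-block OLS of ``criterion`` on sRPE with diagnostics.

    The default R^2 CI is a seeded percentile bootstrap over sessions
    (``n_boot`` resamples); ``ci_method="fisher"`` gives the analytic
    Fisher-z interval instead. Blocks with fewer than 10 complete pairs get
    no CI, with a warning. The Durbin-Watson flag marks residual serial
    independence within the conventional 1.5-2.5 window; the Breusch-Pagan
    homoscedasticity flag is an advisory screen at p >= 0.05.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan
    from statsmodels.stats.stattools import durbin_watson

    if blocks is None:
        blocks = DEFAULT_BLOCKS
    if criterion not in CRITERIA:
        raise ConfigurationError(
            f"criterion must be one of {CRITERIA}, got {criterion!r}")
    if ci_method not in ("bootstrap", "fisher"):
        raise ConfigurationError(
            f"ci_method must be 'bootstrap' or 'fisher', got {ci_method!r}")
    complete = loads.dropna(subset=["srpe", criterion])
    if complete.empty:
        raise ValidationError("no complete (srpe, criterion) pairs")
    _check_blocks(blocks, complete["week"].unique())

    results = []
    for label, wks in blocks.items():
        wset = set(int(w) for w in wks)
        sub = complete[complete["week"].isin(wset)]
        if sub.empty:
            raise ValidationError(f"block {label!r} has no complete pairs")
        x = sub["srpe"].to_numpy(float)
        y = sub[criterion].to_numpy(float)
        n = x.size
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        resid = fit.resid
        r2 = float(fit.rsquared)
        r = float(np.sign(fit.params[1]) * np.sqrt(r2))
        dw = float(durbin_watson(resid))
        if np.allclose(resid, 0):
            homo = None  # perfect fit: no residual spread to screen
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, bp_p, _, _ = het_breuschpagan(resid, fit.model.exog)
            homo = bool(bp_p >= 0.05)
        if n < MIN_PAIRS_FOR_CI:
            warnings.warn(
                f"block {label!r}: only {n} pairs; R^2 CI suppressed",
                stacklevel=2)
            lo = hi = method = None
        elif ci_method == "bootstrap":
            lo, hi = _bootstrap_r2_ci(x, y, n_boot, seed)
            method = f"bootstrap-percentile-{n_boot}"
        else:
            lo, hi = _fisher_r2_ci(r, n)
            method = "fisher-z"
        results.append(RegressionResult(
            block=str(label), criterion=criterion, n=n, r=r, r_squared=r2,
            r_squared_ci_low=lo, r_squared_ci_high=hi, ci_method=method,
            slope=float(fit.params[1]), intercept=float(fit.params[0]),
            p_value=float(fit.f_pvalue) if n > 2 else float("nan"),
            durbin_watson=dw,
            durbin_watson_ok=bool(DW_WINDOW[0] <= dw <= DW_WINDOW[1]),
            homoscedastic=homo))
    return results


def validity_report(entries: Sequence[CorrelationEntry],
                    regressions: Sequence[RegressionResult]) -> tuple:
    """Assemble the correlation table and regression summary.

    Returns ``(table, summary)``: ``table`` is a DataFrame with one row per
    participant plus Overall / Males / Females rows and, per criterion,
    n / r / p / significance columns; ``summary`` is a JSON-ready dict with
    the per-block regressions and the per-criterion share of individually
    significant participants.
    """
    if not entries:
        raise ValidationError("no correlation entries to report")
    label_of = {("group", None): "Overall", ("sex", "M"): "Males",
                ("sex", "F"): "Females"}
    rows: dict = {}
    order: list = []
    for e in sorted(entries, key=lambda e: (e.scope != "individual",
                                            str(e.scope_id))):
        label = label_of.get((e.scope, e.scope_id), e.scope_id)
        if label not in rows:
            rows[label] = {"participant": label}
            order.append(label)
        short = "edwards" if e.criterion == "edwards_tl" else "trimp"
        rows[label][f"{short}_n"] = e.n
        rows[label][f"{short}_r"] = e.r
        rows[label][f"{short}_p"] = e.p_value
        rows[label][f"{short}_significant"] = e.significant
    table = pd.DataFrame([rows[k] for k in order])
    summary = {
        "fraction_individuals_significant": fraction_significant(entries),
        "block_regressions": [r.to_dict() for r in regressions],
    }
    return table, summary
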