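"""Quartile agreement: oracle equivalence, null calibration, block logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hiftload as hl
from hiftload.agreement import (
    DEFAULT_BLOCKS,
    assign_within_subject_quartiles,
    coefficient_of_agreement,
    icc_quartiles,
    quartile_pairs,
    reliability_report,
)
from hiftload.exceptions import ConfigurationError, ValidationError


def quartile_oracle(values):
    """Independent quartile assignment: sort, interpolate the three
    cutpoints by hand, count strict exceedances."""
    v = [float(x) for x in values]
    s = sorted(v)
    n = len(s)
    cuts = []
    for p in (0.25, 0.50, 0.75):
        h = (n - 1) * p
        lo = math.floor(h)
        frac = h - lo
        hi = min(lo + 1, n - 1)
        cuts.append(s[lo] + frac * (s[hi] - s[lo]))
    return [1 + sum(x > c for c in cuts) for x in v]


def icc_a1_oracle(a, b):
    """Hand-rolled two-way ANOVA ICC(A,1) (absolute agreement, single
    measurement), independent of pingouin."""
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    grand = x.mean()
    row = x.mean(axis=1)
    col = x.mean(axis=0)
    msr = k * ((row - grand) ** 2).sum() / (n - 1)
    msc = n * ((col - grand) ** 2).sum() / (k - 1)
    mse = ((x - row[:, None] - col[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


# ---------------------------------------------------------------------------
# quartile assignment


def test_four_distinct_values_span_the_quartiles():
    assert list(assign_within_subject_quartiles([1, 2, 3, 4])) == [1, 2, 3, 4]


def test_assignment_matches_oracle_on_random_small_samples():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = rng.integers(4, 13)
        if rng.random() < 0.5:
            values = rng.integers(6, 21, n).astype(float)  # Borg-like ties
        else:
            values = rng.normal(100, 20, n)
        if np.all(values == values[0]):
            continue
        assert list(assign_within_subject_quartiles(values)) == \
            quartile_oracle(values)


def test_assignment_is_monotone_in_value():
    rng = np.random.default_rng(2)
    values = rng.normal(0, 1, 40)
    q = assign_within_subject_quartiles(values)
    order = np.argsort(values, kind="stable")
    assert (np.diff(q[order]) >= 0).all()


def test_degenerate_spread_assigns_quartile_one_with_warning():
    with pytest.warns(UserWarning, match="identical"):
        q = assign_within_subject_quartiles([15, 15, 15, 15, 15])
    assert list(q) == [1, 1, 1, 1, 1]


def test_ties_share_a_quartile():
    values = [10, 10, 12, 12, 14, 14, 16, 16]
    q = assign_within_subject_quartiles(values)
    for val in set(values):
        idx = [i for i, v in enumerate(values) if v == val]
        assert len({q[i] for i in idx}) == 1


def test_too_few_values_rejected():
    with pytest.raises(ValidationError):
        assign_within_subject_quartiles([1, 2, 3])


# ---------------------------------------------------------------------------
# coefficient of agreement


@pytest.mark.parametrize("rq,hq,expected", [
    ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
    ([1, 2, 3, 4], [1, 3, 3, 2], 0.5),
    ([1, 2, 3, 4], [4, 3, 2, 1], 0.0),
])
def test_coa_counts_exact_matches(rq, hq, expected):
    assert coefficient_of_agreement(rq, hq) == expected


def test_coa_rejects_empty_or_mismatched():
    with pytest.raises(ValidationError):
        coefficient_of_agreement([], [])
    with pytest.raises(ValidationError):
        coefficient_of_agreement([1, 2], [1])


def test_coa_matches_direct_counting_oracle():
    rng = np.random.default_rng(5)
    rq = rng.integers(1, 5, 500)
    hq = rng.integers(1, 5, 500)
    direct = sum(int(a == b) for a, b in zip(rq, hq)) / 500
    assert coefficient_of_agreement(rq, hq) == direct


@given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)),
                min_size=1, max_size=60),
       st.randoms(use_true_random=False))
@settings(max_examples=50, deadline=None)
def test_coa_invariant_under_pair_relabeling(pairs, rnd):
    rq = [p[0] for p in pairs]
    hq = [p[1] for p in pairs]
    base = coefficient_of_agreement(rq, hq)
    order = list(range(len(pairs)))
    rnd.shuffle(order)
    assert coefficient_of_agreement([rq[i] for i in order],
                                    [hq[i] for i in order]) == base


# ---------------------------------------------------------------------------
# ICC


def test_icc_identical_vectors_is_one():
    q = [1, 2, 3, 4, 1, 2, 3, 4, 2, 3, 1, 4]
    res = icc_quartiles(q, q)
    assert res.icc == 1.0
    assert res.coa == 1.0
    assert res.icc_variant == "ICC(A,1)"


def test_icc_matches_hand_anova_oracle():
    rng = np.random.default_rng(21)
    a = rng.integers(1, 5, 80)
    b = np.where(rng.random(80) < 0.6, a, rng.integers(1, 5, 80))
    res = icc_quartiles(a, b)
    assert res.icc == pytest.approx(icc_a1_oracle(a, b), abs=1e-6)
    assert res.icc_ci_low <= res.icc <= res.icc_ci_high


def test_icc_zero_variance_reported_absent():
    with pytest.warns(UserWarning, match="zero variance"):
        res = icc_quartiles([2] * 12, [2] * 12)
    assert res.icc is None
    assert res.coa == 1.0


def test_icc_small_n_suppresses_ci():
    with pytest.warns(UserWarning, match="CI suppressed"):
        res = icc_quartiles([1, 2, 3, 4, 1, 2], [1, 2, 3, 3, 2, 2])
    assert res.icc is not None
    assert res.icc_ci_low is None and res.icc_ci_high is None


def test_icc_near_zero_for_independent_quartiles():
    rng = np.random.default_rng(3)
    iccs = [icc_quartiles(rng.integers(1, 5, 300),
                          rng.integers(1, 5, 300)).icc for _ in range(20)]
    assert abs(float(np.mean(iccs))) < 0.05


# ---------------------------------------------------------------------------
# reliability report


def test_single_block_equals_overall(clean_loads):
    blocks = {"all": (2, 3, 4, 6, 7, 8)}
    rep = reliability_report(clean_loads, blocks=blocks)
    assert rep["per_block"]["all"].coa == rep["overall"].coa
    assert rep["per_block"]["all"].icc == pytest.approx(rep["overall"].icc)
    assert rep["per_block"]["all"].n_pairs == rep["overall"].n_pairs


def test_block_pair_counts_sum_to_overall(default_loads):
    rep = reliability_report(default_loads)
    assert sum(b.n_pairs for b in rep["per_block"].values()) == \
        rep["overall"].n_pairs


def test_block_definition_must_partition_weeks(default_loads):
    with pytest.raises(ConfigurationError, match="partition"):
        reliability_report(default_loads, blocks={"b1": (2, 3), "b2": (6, 7, 8)})
    with pytest.raises(ConfigurationError):
        reliability_report(default_loads,
                           blocks={"b1": (2, 3, 4, 6), "b2": (6, 7, 8)})


def test_quartile_modes_differ_only_in_block_reference(default_loads):
    local = reliability_report(default_loads, quartile_mode="block-local")
    wide = reliability_report(default_loads, quartile_mode="study-wide")
    assert local["overall"].coa == wide["overall"].coa
    assert local["quartile_mode"] == "block-local"
    assert wide["quartile_mode"] == "study-wide"


def test_sparse_participant_excluded_with_warning():
    df = pd.DataFrame({
        "participant_id": ["A"] * 8 + ["B"] * 3,
        "week": [2, 2, 3, 3, 4, 4, 2, 3] + [2, 3, 4],
        "rpe": [10, 12, 14, 16, 11, 13, 15, 17] + [12, 13, 14],
        "hr_mean": [120, 130, 140, 150, 125, 135, 145, 155] + [120, 130, 140],
    })
    with pytest.warns(UserWarning, match="participant B"):
        pairs = quartile_pairs(df)
    assert set(pairs["participant_id"]) == {"A"}


def test_block_drift_improves_second_block_agreement():
    """Less perceptual noise in block 2 should raise block-2 CoA relative
    to block 1 in expectation over seeds."""
    deltas = []
    for seed in range(20):
        cfg = hl.GeneratorConfig(seed=seed, perceptual_noise_sd=0.15,
                                 block_drift=-0.5)
        participants, sessions = hl.generate_cohort(cfg)
        loads = hl.loads_to_frame(hl.quantify_sessions(participants, sessions))
        coa = {}
        for label, wks in DEFAULT_BLOCKS.items():
            pairs = quartile_pairs(loads[loads["week"].isin(wks)])
            coa[label] = coefficient_of_agreement(pairs["rpe_quartile"],
                                                  pairs["hr_quartile"])
        deltas.append(coa["block2"] - coa["block1"])
    assert float(np.mean(deltas)) > 0
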