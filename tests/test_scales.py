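"""Instrument scoring: subscale sums, severity cutoffs, SDS conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomnet.scales import (
    MBI_SUBSCALE_ITEMS,
    cohort_summary,
    percentage,
    score_mbi,
    score_sds,
    score_table,
    sds_standard_score,
)
from symptomnet.simulate import SDS_REVERSE_KEYED


def mbi_row(ee=0, dp=0, rpe=0):
    """A 15-item response vector hitting the requested subscale sums."""

    def fill(total, k, cap=6):
        vals = [0] * k
        for i in range(k):
            take = min(cap, total)
            vals[i] = take
            total -= take
        assert total == 0
        return vals

    return fill(ee, 5) + fill(dp, 4) + fill(rpe, 6)


@pytest.mark.parametrize(
    "ee,expected",
    [(16, "severe"), (15, "moderate"), (11, "moderate"), (10, "mild"), (0, "mild")],
)
def test_emotional_exhaustion_severity_cutoffs(ee, expected):
    score = score_mbi(mbi_row(ee=ee))
    assert score.emotional_exhaustion == ee
    assert score.severity["emotional_exhaustion"] == expected


@pytest.mark.parametrize(
    "dp,expected", [(13, "severe"), (12, "moderate"), (8, "moderate"), (7, "mild")]
)
def test_depersonalization_severity_cutoffs(dp, expected):
    assert score_mbi(mbi_row(dp=dp)).severity["depersonalization"] == expected


@pytest.mark.parametrize(
    "rpe,expected", [(23, "severe"), (22, "moderate"), (18, "moderate"), (17, "mild")]
)
def test_reduced_efficacy_severity_cutoffs(rpe, expected):
    assert score_mbi(mbi_row(rpe=rpe)).severity["reduced_professional_efficacy"] == expected


def test_all_zero_responses_floor_case():
    score = score_mbi([0] * 15)
    assert (
        score.emotional_exhaustion,
        score.depersonalization,
        score.reduced_professional_efficacy,
    ) == (0, 0, 0)
    assert set(score.severity.values()) == {"mild"}


def test_mbi_rejects_out_of_range_with_item_index():
    row = [0] * 15
    row[7] = 9
    with pytest.raises(ValueError, match="item 8"):
        score_mbi(row)


@pytest.mark.parametrize(
    "raw,standard", [(20, 25), (40, 50), (48, 60), (56, 70), (80, 100)]
)
def test_sds_standard_conversion_anchors(raw, standard):
    """floor(raw * 1.25) reproduces every published band edge."""
    assert sds_standard_score(raw) == standard


@pytest.mark.parametrize(
    "raw,severity",
    [
        (20, "normal"),
        (40, "mild_to_moderate"),  # standard 50, the clinical threshold
        (47, "mild_to_moderate"),
        (48, "moderate_to_severe"),
        (55, "moderate_to_severe"),
        (56, "severe"),
        (80, "severe"),
    ],
)
def test_sds_severity_bands(raw, severity):
    # build a response row whose keyed sum equals `raw`
    extra = raw - 20
    row = []
    for i in range(20):
        take = min(3, extra)
        extra -= take
        x = 1 + take
        row.append(5 - x if i in SDS_REVERSE_KEYED else x)
    score = score_sds(row)
    assert score.raw == raw
    assert score.severity == severity


def test_sds_reverse_key_count_enforced():
    with pytest.raises(ValueError, match="reverse-keyed"):
        score_sds([1] * 20, reverse_keyed=range(9))


def test_sds_minimum_after_keying_is_normal():
    row = [4 if i in SDS_REVERSE_KEYED else 1 for i in range(20)]
    score = score_sds(row)
    assert (score.raw, score.standard, score.severity) == (20, 25, "normal")


@given(st.lists(st.integers(0, 6), min_size=15, max_size=15))
@settings(max_examples=50, deadline=None)
def test_mbi_severity_is_step_function_of_sums(row):
    score = score_mbi(row)
    assert score.emotional_exhaustion == sum(row[:5])
    assert 0 <= score.depersonalization <= 24
    for name, idxs in MBI_SUBSCALE_ITEMS.items():
        s = sum(row[i] for i in idxs)
        lo, hi = {"emotional_exhaustion": (11, 15),
                  "depersonalization": (8, 12),
                  "reduced_professional_efficacy": (18, 22)}[name]
        expected = "severe" if s > hi else ("moderate" if s >= lo else "mild")
        assert score.severity[name] == expected


def test_cohort_percentage_rounding():
    assert percentage(375, 1322) == 28.37


def test_cohort_summary_counts_match_brute_force(study_table):
    scores = score_table(study_table)
    summary = cohort_summary(scores).set_index("measure")
    n = len(scores)
    assert summary.loc["emotional_exhaustion_gt10", "count"] == int(
        (scores["emotional_exhaustion"] > 10).sum()
    )
    assert summary.loc["sds_standard_gt52", "count"] == int(
        (scores["sds_standard"] > 52).sum()
    )
    for _, row in summary.iterrows():
        assert row["percent"] == round(100 * row["count"] / n, 2)


def test_cohort_of_one_below_all_thresholds():
    row = {f"MBI-{i}": 0 for i in range(1, 16)}
    row.update({f"D{i}": (4 if i - 1 in SDS_REVERSE_KEYED else 1) for i in range(1, 21)})
    scores = score_table(pd.DataFrame([row]))
    summary = cohort_summary(scores)
    assert (summary["count"] == 0).all()
    assert (summary["percent"] == 0.0).all()


def test_scoring_is_permutation_invariant_over_respondents(study_table):
    df = study_table.responses.head(50)
    shuffled = df.sample(frac=1, random_state=3)
    a = score_table(df).sort_values("sds_raw").reset_index(drop=True)
    b = score_table(shuffled).sort_values("sds_raw").reset_index(drop=True)
    pd.testing.assert_frame_equal(
        a[["sds_raw", "sds_standard"]], b[["sds_raw", "sds_standard"]]
    )
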