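"""Scoring for the MBI-GS burnout inventory and the Zung SDS depression scale.

MBI-GS: 15 items on a 0-6 frequency scale in three subscales — emotional
exhaustion (items 1-5), depersonalization (items 6-9) and reduced
professional efficacy (items 10-15). Severity per subscale uses the
conventional cutoffs: EE >15 severe / 11-15 moderate / <11 mild;
DP >12 / 8-12 / <8; RPE >22 / 18-22 / <18.

SDS: 20 items on a 1-4 scale, 10 positively-worded items reverse-scored
(5 - x) before summing. The raw score (20-80) converts to the standard score
as floor(raw * 1.25) — the unique simple rule consistent with all the
published band anchors (20->25, 40->50, 48->60, 56->70). Severity bands on
the standard score: 25-49 normal, 50-59 mild-to-moderate, 60-69
moderate-to-severe, >=70 severe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .simulate import SDS_REVERSE_KEYED, ItemResponseTable

__all__ = [
    "MBIScore",
    "SDSScore",
    "score_mbi",
    "score_sds",
    "sds_standard_score",
    "cohort_summary",
    "percentage",
    "score_table",
    "MBI_SUBSCALE_ITEMS",
]

#: 0-based item indices of each MBI-GS subscale within the 15-item block.
MBI_SUBSCALE_ITEMS = {
    "emotional_exhaustion": tuple(range(0, 5)),
    "depersonalization": tuple(range(5, 9)),
    "reduced_professional_efficacy": tuple(range(9, 15)),
}

_MBI_CUTOFFS = {
    # subscale: (moderate lower bound, severe exclusive lower bound)
    "emotional_exhaustion": (11, 15),
    "depersonalization": (8, 12),
    "reduced_professional_efficacy": (18, 22),
}


@dataclass(frozen=True)
class MBIScore:
    emotional_exhaustion: int
    depersonalization: int
    reduced_professional_efficacy: int
    severity: dict

    def as_dict(self) -> dict:
        return {
            "emotional_exhaustion": self.emotional_exhaustion,
            "depersonalization": self.depersonalization,
            "reduced_professional_efficacy": self.reduced_professional_efficacy,
            **{f"severity_{k}": v for k, v in self.severity.items()},
        }


@dataclass(frozen=True)
class SDSScore:
    raw: int
    standard: int
    severity: str


def _mbi_severity(subscale: str, score: int) -> str:
    moderate_lo, severe_gt = _MBI_CUTOFFS[subscale]
    if score > severe_gt:
        return "severe"
    if score >= moderate_lo:
        return "moderate"
    return "mild"


def score_mbi(
    row: Sequence[int],
    item_map: dict[str, Sequence[int]] | None = None,
) -> MBIScore:
    """Score one respondent's 15 MBI-GS responses.

    ``item_map`` maps subscale name to 0-based item indices; defaults to the
    standard 5/4/6 layout.
    """
    item_map = item_map or MBI_SUBSCALE_ITEMS
    row = list(row)
    if len(row) != 15:
        raise ValueError(f"expected 15 MBI responses, got {len(row)}")
    for idx, value in enumerate(row):
        if not 0 <= int(value) <= 6:
            raise ValueError(f"MBI item {idx + 1}: response {value} outside 0-6")
    sums = {name: int(sum(row[i] for i in idxs)) for name, idxs in item_map.items()}
    severity = {name: _mbi_severity(name, s) for name, s in sums.items()}
    return MBIScore(
        emotional_exhaustion=sums["emotional_exhaustion"],
        depersonalization=sums["depersonalization"],
        reduced_professional_efficacy=sums["reduced_professional_efficacy"],
        severity=severity,
    )


def sds_standard_score(raw: int) -> int:
    """Convert an SDS raw score (20-80) to the standard score: floor(raw * 1.25)."""
    if not 20 <= raw <= 80:
        raise ValueError(f"SDS raw score {raw} outside 20-80")
    return math.floor(raw * 1.25)


def _sds_severity(standard: int) -> str:
    if standard >= 70:
        return "severe"
    if standard >= 60:
        return "moderate_to_severe"
    if standard >= 50:
        return "mild_to_moderate"
    return "normal"


def score_sds(
    row: Sequence[int],
    reverse_keyed: Iterable[int] = SDS_REVERSE_KEYED,
) -> SDSScore:
    """Score one respondent's 20 SDS responses (raw 1-4 codes as presented).

    Reverse-keyed items are recoded ``5 - x`` before summing; exactly 10 items
    must be flagged.
    """
    row = list(row)
    reverse = set(reverse_keyed)
    if len(row) != 20:
        raise ValueError(f"expected 20 SDS responses, got {len(row)}")
    if len(reverse) != 10:
        raise ValueError(f"SDS requires exactly 10 reverse-keyed items, got {len(reverse)}")
    for idx, value in enumerate(row):
        if not 1 <= int(value) <= 4:
            raise ValueError(f"SDS item {idx + 1}: response {value} outside 1-4")
    raw = int(sum((5 - x) if i in reverse else x for i, x in enumerate(row)))
    standard = sds_standard_score(raw)
    return SDSScore(raw=raw, standard=standard, severity=_sds_severity(standard))


def percentage(count: int, total: int) -> float:
    """Share of a cohort as a percentage rounded to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 2)


def score_table(table: ItemResponseTable | pd.DataFrame) -> pd.DataFrame:
    """Score every respondent of a combined MBI+SDS response table.

    Expects columns MBI-1..MBI-15 and D1..D20 (raw, as-presented codes).
    """
    df = table.responses if isinstance(table, ItemResponseTable) else table
    mbi_cols = [f"MBI-{i}" for i in range(1, 16)]
    sds_cols = [f"D{i}" for i in range(1, 21)]
    missing = [c for c in mbi_cols + sds_cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing item columns: {missing[:3]}...")
    records = []
    for _, r in df.iterrows():
        m = score_mbi([int(r[c]) for c in mbi_cols])
        s = score_sds([int(r[c]) for c in sds_cols])
        rec = m.as_dict()
        rec.update(sds_raw=s.raw, sds_standard=s.standard, sds_severity=s.severity)
        records.append(rec)
    return pd.DataFrame(records)


# Reporting thresholds used for cohort prevalence tables. The >52 / >62
# standard-score cutoffs are prevalence conventions distinct from the
# severity bands above; both are exposed.
COHORT_THRESHOLDS = {
    "emotional_exhaustion_gt10": ("emotional_exhaustion", 10),
    "depersonalization_gt7": ("depersonalization", 7),
    "reduced_professional_efficacy_gt17": ("reduced_professional_efficacy", 17),
    "sds_standard_gt62": ("sds_standard", 62),
    "sds_standard_gt52": ("sds_standard", 52),
}


def cohort_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of respondents above each reporting threshold.

    ``scores`` is the output of :func:`score_table`. Percentages are rounded
    to 2 decimals.
    """
    if len(scores) == 0:
        raise ValueError("empty cohort")
    n = len(scores)
    rows = []
    for label, (col, cut) in COHORT_THRESHOLDS.items():
        count = int((scores[col] > cut).sum())
        rows.append((label, count, percentage(count, n)))
    return pd.DataFrame(rows, columns=["measure", "count", "percent"])
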