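"""Clinical-recurrence categorization and rare-vs-frequent comparisons.

Translocations reported exactly once in a Mitelman-like registry are
"rare"; those reported more than once are "frequent".  Features (pair
contact frequency, 5' partner expression, 3' partner PII count, per-gene RT
and centrality) are compared between the two categories with two-sided
Mann-Whitney U tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class RecurrenceCategory:
    entry_id: str
    report_count: int
    category: str  # rare | frequent


def categorize_by_reports(report_counts: Mapping[str, int]) -> dict[str, RecurrenceCategory]:
    """Split entries into rare (one report) and frequent (more than one)."""
    out = {}
    for entry_id, count in report_counts.items():
        if count < 1:
            raise ValueError(f"{entry_id}: report count must be >= 1")
        out[entry_id] = RecurrenceCategory(
            entry_id=entry_id, report_count=count,
            category="rare" if count == 1 else "frequent",
        )
    return out


@dataclass
class RareFrequentComparison:
    feature_name: str
    n_rare: int
    n_frequent: int
    median_rare: float
    median_frequent: float
    u_statistic: float | None
    p_value: float | None
    direction: str | None   # 'frequent_higher' | 'rare_higher' | None
    skipped: bool = False
    small_group_warning: bool = False


def compare_rare_frequent(
    categories: Mapping[str, RecurrenceCategory],
    feature_values: Mapping[str, float],
    feature_name: str,
) -> RareFrequentComparison:
    """Two-sided Mann-Whitney U comparing a feature between rare and
    frequent entries; skipped (with flag) when either category is empty."""
    rare, freq = [], []
    for entry_id, cat in categories.items():
        if entry_id not in feature_values:
            continue
        v = feature_values[entry_id]
        (rare if cat.category == "rare" else freq).append(v)
    rare_arr, freq_arr = np.asarray(rare, float), np.asarray(freq, float)
    if rare_arr.size == 0 or freq_arr.size == 0:
        return RareFrequentComparison(
            feature_name=feature_name, n_rare=rare_arr.size, n_frequent=freq_arr.size,
            median_rare=float(np.median(rare_arr)) if rare_arr.size else float("nan"),
            median_frequent=float(np.median(freq_arr)) if freq_arr.size else float("nan"),
            u_statistic=None, p_value=None, direction=None, skipped=True,
        )
    small = min(rare_arr.size, freq_arr.size) < 5
    if small:
        warnings.warn(f"{feature_name}: very small group, test has wide variance")
    res = sps.mannwhitneyu(freq_arr, rare_arr, alternative="two-sided")
    med_r, med_f = float(np.median(rare_arr)), float(np.median(freq_arr))
    return RareFrequentComparison(
        feature_name=feature_name, n_rare=rare_arr.size, n_frequent=freq_arr.size,
        median_rare=med_r, median_frequent=med_f,
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        direction="frequent_higher" if med_f >= med_r else "rare_higher",
        small_group_warning=small,
    )
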