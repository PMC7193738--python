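"""Threshold classification and nonparametric two-condition statistics.

The classifier is deliberately minimal: the decision threshold is the
midpoint between the closest points of the two feature sets — the average of
the lower group's maximum and the upper group's minimum — and the margin
(upper minimum minus lower maximum) is positive exactly when the two sets
are completely separated.  Group orientation is decided by median, so the
rule is independent of the condition names.

Significance is assessed with the Wilcoxon rank-sum and Kruskal-Wallis
tests: rank-based, hence appropriate for the small, non-Gaussian samples a
handful of sessions provides.  The rank-sum p-value is exact (full
enumeration) for small tie-free samples and a continuity-corrected normal
approximation otherwise; Kruskal-Wallis uses the chi-square reference with
midrank tie correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signal_io import FeatureTable

__all__ = [
    "SeparationResult",
    "midpoint_threshold",
    "analyze_separation",
    "classify",
    "ranksum_test",
    "kruskal_test",
    "evaluate_methods",
]

#: largest per-group size at which the exact rank-sum distribution is used
EXACT_RANKSUM_MAX_N = 10


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


@dataclass
class SeparationResult:
    """Midpoint-threshold separation of two feature sets."""

    threshold: float
    margin: float
    upper_condition: str
    lower_condition: str
    labels: dict[str, str] = field(default_factory=dict)
    wilcoxon_p: float | None = None
    kruskal_p: float | None = None

    @property
    def complete_separation(self) -> bool:
        """True when every upper value exceeds every lower value."""
        return self.margin > 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "threshold": self.threshold,
            "margin": self.margin,
            "complete_separation": self.complete_separation,
            "upper_condition": self.upper_condition,
            "lower_condition": self.lower_condition,
            "wilcoxon_p": self.wilcoxon_p,
            "kruskal_p": self.kruskal_p,
            "labels": self.labels,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def midpoint_threshold(
    values_a: np.ndarray,
    values_b: np.ndarray,
    name_a: str = "A",
    name_b: str = "B",
) -> SeparationResult:
    """Midpoint decision threshold between two feature groups.

    The group with the larger median is the "upper" group (ties broken by
    mean); the threshold is the average of the upper group's minimum and
    the lower group's maximum, and the margin their difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    upper_is_b = np.median(b) > np.median(a) or (
        np.median(b) == np.median(a) and b.mean() >= a.mean()
    )
    if upper_is_b:
        lower, upper = a, b
        lower_name, upper_name = name_a, name_b
    else:
        lower, upper = b, a
        lower_name, upper_name = name_b, name_a
    lo_max = float(lower.max())
    up_min = float(upper.min())
    return SeparationResult(
        threshold=(up_min + lo_max) / 2.0,
        margin=up_min - lo_max,
        upper_condition=upper_name,
        lower_condition=lower_name,
    )


def analyze_separation(
    values_a: np.ndarray,
    values_b: np.ndarray,
    name_a: str = "A",
    name_b: str = "B",
) -> SeparationResult:
    """Midpoint threshold plus both nonparametric test p-values."""
    res = midpoint_threshold(values_a, values_b, name_a, name_b)
    res.wilcoxon_p = ranksum_test(values_a, values_b).pvalue
    res.kruskal_p = kruskal_test([values_a, values_b]).pvalue
    return res


def classify(value: float, result: SeparationResult) -> str:
    """Label a feature value by its side of the threshold.

    A value exactly at the threshold is assigned to the upper condition.
    """
    return (
        result.upper_condition
        if value >= result.threshold
        else result.lower_condition
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def ranksum_test(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution (full enumeration) when both samples
    have at most 10 observations and no ties occur; otherwise the normal
    approximation with continuity correction and midrank tie handling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    exact = (
        a.size <= EXACT_RANKSUM_MAX_N
        and b.size <= EXACT_RANKSUM_MAX_N
        and not _has_ties(a, b)
    )
    if exact:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), "normal_cc")


def kruskal_test(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    H uses midrank tie correction; p comes from the chi-square distribution
    with (number of groups - 1) degrees of freedom.  When every value in
    every group is identical there is no evidence of any effect: H = 0,
    p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "degenerate")
    res = stats.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue), "chi2")


def evaluate_methods(
    features: FeatureTable,
    methods: Sequence[str] | None = None,
    epoch_lengths_s: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-method, per-epoch-length separation report.

    Epochs are pooled across subjects within each condition (so 4 sessions
    of 13 three-minute epochs give 52 values per condition).  Each row
    reports both p-values, the margin, and whether separation is complete.
    Raises with an explicit list of gaps if any method lacks feature values
    for either condition.
    """
    df = features.df
    if methods is None:
        methods = sorted(df["method"].unique())
    if epoch_lengths_s is None:
        epoch_lengths_s = sorted(df["epoch_length_s"].unique())
    conditions = sorted(df["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {conditions}")
    cond_a, cond_b = conditions

    gaps = []
    rows = []
    for method in methods:
        for elen in epoch_lengths_s:
            sub = df[(df["method"] == method) & (df["epoch_length_s"] == elen)]
            a = sub.loc[sub["condition"] == cond_a, "value"].to_numpy(float)
            b = sub.loc[sub["condition"] == cond_b, "value"].to_numpy(float)
            if a.size == 0 or b.size == 0:
                gaps.append((method, elen, cond_a if a.size == 0 else cond_b))
                continue
            res = analyze_separation(a, b, cond_a, cond_b)
            rows.append(
                {
                    "method": method,
                    "epoch_length_s": elen,
                    f"n_{cond_a}": a.size,
                    f"n_{cond_b}": b.size,
                    "threshold": res.threshold,
                    "margin": res.margin,
                    "complete_separation": res.complete_separation,
                    "upper_condition": res.upper_condition,
                    "wilcoxon_p": res.wilcoxon_p,
                    "kruskal_p": res.kruskal_p,
                    "pooling": "epochs pooled across subjects per condition",
                }
            )
    if gaps:
        raise ValueError(
            "missing feature values for (method, epoch_length_s, condition): "
            f"{gaps}"
        )
    return pd.DataFrame(rows)
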