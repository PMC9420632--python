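"""Nonparametric group comparison, Bonferroni thresholds, and fold changes.

Two-group comparisons use the Mann-Whitney U test (exact two-sided p for
small tie-free samples, normal approximation with tie and continuity
corrections otherwise); three- and four-group comparisons use Mood's median
test (dichotomize at the pooled median, chi-square on the k x 2 table).
Fold changes are ratios of raw absolute-intensity summaries, never of the
scaled values. :func:`univariate_screen` combines these with VIP scores and
a Bonferroni-corrected p threshold into one record per feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chemometrics import VipScores
from .preprocess import FeatureTable

__all__ = [
    "UnivariateRecord",
    "ThresholdPolicy",
    "mann_whitney",
    "median_test",
    "bonferroni_threshold",
    "fold_change",
    "univariate_screen",
]


@dataclass
class ThresholdPolicy:
    """Family-wise error control: reject when p < alpha / family_size."""

    alpha: float = 0.05
    family_size: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")

    @property
    def corrected_threshold(self) -> float:
        return self.alpha / self.family_size


@dataclass
class UnivariateRecord:
    feature_id: str
    p_value: float
    statistic: float
    test_name: str  # "mann_whitney_u" | "median_test"
    fold_change: float  # NaN for >2-group comparisons
    vip: float
    passes_vip: bool
    passes_p: bool


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for the first group, p).

    Uses the exact null distribution when both samples have n <= 8 and the
    pooled data is tie-free, otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def median_test(groups: list) -> tuple[float, float]:
    """Mood's median test across k >= 3 groups.

    Counts above / at-or-below the pooled median form a k x 2 contingency
    table tested by Pearson chi-square with k - 1 degrees of freedom; values
    equal to the pooled median count in the "<= median" cell.
    """
    if len(groups) < 3:
        raise ValueError("median_test needs >= 3 groups; use mann_whitney for 2")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        raise ValueError("all values identical; median table is degenerate")
    stat, p, _med, _tbl = stats.median_test(*arrays, ties="below", correction=False)
    return float(stat), float(p)


def bonferroni_threshold(alpha: float, family_size: int) -> float:
    """Corrected per-test significance threshold alpha / family_size."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size


def fold_change(values_num, values_den, summary: str = "mean") -> float:
    """Ratio of group intensity summaries on the raw (absolute) scale."""
    num = np.asarray(values_num, dtype=float)
    den = np.asarray(values_den, dtype=float)
    if num.size == 0 or den.size == 0:
        raise ValueError("both samples must be non-empty")
    if summary == "mean":
        s_num, s_den = num.mean(), den.mean()
    elif summary == "median":
        s_num, s_den = np.median(num), np.median(den)
    else:
        raise ValueError("summary must be 'mean' or 'median'")
    if s_den <= 0:
        raise ValueError("denominator summary must be > 0")
    return float(s_num / s_den)


def univariate_screen(
    table: FeatureTable,
    vip: VipScores,
    policy: ThresholdPolicy | None = None,
    groups=None,
    case_label: str | None = None,
    fc_summary: str = "mean",
    allow_many_groups: bool = False,
) -> list[UnivariateRecord]:
    """Test every feature of an imputed table and attach VIP/p/FC flags.

    Two distinct labels route to the Mann-Whitney U test (fold change =
    case summary / control summary, ``case_label`` defaulting to the first
    label in sorted order); three or four labels route to Mood's median test
    with fold change undefined. When no ``policy`` is given, the Bonferroni
    family defaults to the number of VIP > 1 features (the subset that
    enters testing), with a floor of 1.
    """
    g = np.asarray(table.groups if groups is None else groups)
    labels = sorted(set(g.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if len(labels) > 4 and not allow_many_groups:
        raise ValueError("more than 4 groups; pass allow_many_groups=True to override")
    if table.intensities.isna().to_numpy().any():
        raise ValueError("table contains missing values; impute first")
    vip_s = vip.vip.reindex(table.feature_ids)
    if vip_s.isna().any():
        raise ValueError("VIP scores are not aligned with the table's features")

    if policy is None:
        family = max(int((vip_s > 1).sum()), 1)
        policy = ThresholdPolicy(alpha=0.05, family_size=family)
    thr = policy.corrected_threshold

    two_group = len(labels) == 2
    if two_group:
        case = case_label if case_label is not None else labels[0]
        if case not in labels:
            raise ValueError(f"case_label {case!r} not among group labels {labels}")
        control = [lab for lab in labels if lab != case][0]

    records: list[UnivariateRecord] = []
    X = table.intensities
    for fid in table.feature_ids:
        col = X[fid].to_numpy(dtype=float)
        if two_group:
            va, vb = col[g == case], col[g == control]
            stat, p = mann_whitney(va, vb)
            fc = fold_change(va, vb, summary=fc_summary)
            test = "mann_whitney_u"
        else:
            stat, p = median_test([col[g == lab] for lab in labels])
            fc = float("nan")
            test = "median_test"
        v = float(vip_s[fid])
        records.append(
            UnivariateRecord(
                feature_id=fid,
                p_value=p,
                statistic=stat,
                test_name=test,
                fold_change=fc,
                vip=v,
                passes_vip=v > 1.0,
                passes_p=p < thr,
            )
        )
    return records
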