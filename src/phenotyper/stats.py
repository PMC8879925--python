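"""Conventional endpoint statistics with a normality gate.

Two-group comparisons check each sample with Shapiro-Wilk at the gate
alpha; if both pass, a parametric test (unpaired pooled-variance t) is
used, otherwise the nonparametric fallback (Mann-Whitney U). The chosen
test is recorded in the result. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float


@dataclass
class GroupComparison:
    test: str
    statistic: float
    df: float | None
    p_value: float
    groups: list[GroupSummary]
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "groups": [vars(g) for g in self.groups],
            "flags": self.flags,
        }


def _summary(x: np.ndarray) -> GroupSummary:
    return GroupSummary(n=len(x), mean=float(np.mean(x)),
                        sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return True  # too small / degenerate to test; default to parametric
    return sps.shapiro(x).pvalue > alpha


def compare_unpaired(a, b, alpha: float = 0.05) -> GroupComparison:
    """Unpaired two-group comparison behind a Shapiro-Wilk normality gate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    flags: list[str] = []
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        flags.append("zero variance in both samples")
        equal = float(a[0] == b[0])
        return GroupComparison("degenerate", 0.0, None, 1.0 if equal else 0.0,
                               [_summary(a), _summary(b)], flags)
    if _is_normal(a, alpha) and _is_normal(b, alpha):
        res = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison("unpaired-t", float(res.statistic),
                               float(len(a) + len(b) - 2), float(res.pvalue),
                               [_summary(a), _summary(b)], flags)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    flags.append("normality gate failed: nonparametric fallback")
    return GroupComparison("mann-whitney-u", float(res.statistic), None,
                           float(res.pvalue), [_summary(a), _summary(b)], flags)


def compare_paired(before, after) -> GroupComparison:
    """Paired t-test on the differences (df = n - 1)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise ValueError("paired samples must have equal length")
    if len(before) < 2:
        raise ValueError("need n >= 2 pairs")
    diffs = after - before
    summaries = [_summary(before), _summary(after)]
    if np.ptp(diffs) == 0:
        if diffs[0] == 0:
            return GroupComparison("paired-t", 0.0, float(len(diffs) - 1), 1.0, summaries)
        return GroupComparison("paired-t", np.inf if diffs[0] > 0 else -np.inf,
                               float(len(diffs) - 1), 0.0, summaries,
                               flags=["zero-variance differences"])
    res = sps.ttest_rel(after, before)
    return GroupComparison("paired-t", float(res.statistic), float(len(diffs) - 1),
                           float(res.pvalue), summaries)


@dataclass
class Correlation:
    r: float | None
    df: int
    p_value: float | None
    flags: list[str] = field(default_factory=list)


def correlate(x, y) -> Correlation:
    """Pearson product-moment correlation with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return Correlation(None, len(x) - 2, None, flags=["zero variance: r undefined"])
    res = sps.pearsonr(x, y)
    return Correlation(float(res.statistic), len(x) - 2, float(res.pvalue))


def filter_nonavoiders(records: pd.DataFrame, cutoff: float = 180.0,
                       phase: str = "train_latency_s") -> tuple[pd.DataFrame, int]:
    """Drop fish that never entered within the cutoff on the given phase."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    keep = records[records[phase] <= cutoff]
    return keep.reset_index(drop=True), len(records) - len(keep)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float
    posthoc: list[dict] = field(default_factory=list)


def anova_lsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Fisher's LSD pairwise post-hoc on significant F."""
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_tot = sum(len(a) for a in arrays)
    dfw = n_tot - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / dfw
    posthoc = []
    if p < alpha:
        for i in range(k):
            for j in range(i + 1, k):
                a, b = arrays[i], arrays[j]
                se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
                t = (a.mean() - b.mean()) / se
                pp = 2.0 * sps.t.sf(abs(t), dfw)
                posthoc.append({"pair": (names[i], names[j]), "t": float(t),
                                "p_value": float(pp)})
    return AnovaResult(float(f), k - 1, dfw, float(p), posthoc)


def kruskal(groups: dict[str, np.ndarray]) -> GroupComparison:
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    res = sps.kruskal(*arrays)
    return GroupComparison("kruskal-wallis", float(res.statistic),
                           float(len(arrays) - 1), float(res.pvalue),
                           [_summary(a) for a in arrays])
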