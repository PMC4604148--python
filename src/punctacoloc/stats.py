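"""Cohort hypothesis testing: one-way ANOVA with Tukey's multiple comparison.

The fixed-effects one-way ANOVA partitions the total sum of squares into
between- and within-group components; F = MS_between / MS_within with
(k - 1, N - k) degrees of freedom. All-pairs comparisons use Tukey's HSD in
the Tukey-Kramer form for unequal group sizes,

    q_ij = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j)),

with adjusted p-values from the studentized range distribution with
(k, N - k) parameters. Significance stars follow the convention of the
GraphPad-style figure legends: * p < 0.05, ** p < 0.01, *** p < 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "GroupComparison",
    "one_way_anova",
    "tukey_hsd",
    "significance_stars",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class PairwiseComparison:
    label_i: str
    label_j: str
    mean_difference: float
    q: float
    p_adjusted: float
    significant: bool
    stars: str


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    anova: AnovaResult
    pairwise: tuple[PairwiseComparison, ...]
    alpha: float

    def pairwise_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_i": c.label_i,
                    "group_j": c.label_j,
                    "mean_difference": c.mean_difference,
                    "q": c.q,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                    "stars": c.stars,
                }
                for c in self.pairwise
            ]
        )


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _validate(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=np.float64).ravel()
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {label!r} contains non-finite values")
        clean[str(label)] = arr
    return clean


def _sums_of_squares(groups: dict[str, np.ndarray]):
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(
        len(v) * (v.mean() - grand) ** 2 for v in groups.values()
    )
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    return ss_between, ss_within, df_between, df_within


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA over per-cell values.

    With zero variance both between and within groups (all values identical)
    F is defined as 0 and p as 1.
    """
    groups = _validate(groups)
    ssb, ssw, dfb, dfw = _sums_of_squares(groups)
    if ssw == 0.0 and ssb == 0.0:
        return AnovaResult(F=0.0, df_between=dfb, df_within=dfw, p=1.0)
    if ssw == 0.0:
        return AnovaResult(F=float("inf"), df_between=dfb, df_within=dfw, p=0.0)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw, p=p)


@lru_cache(maxsize=128)
def _q_critical(k: int, df: int, alpha: float) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    p_values: bool = True,
) -> GroupComparison:
    """All-pairs Tukey (Tukey-Kramer) comparisons after a one-way ANOVA.

    Adjusted p-values come from the studentized range distribution with
    (n_groups, df_within) parameters; with two groups this reduces exactly
    to the pooled-variance two-sample t-test (q = sqrt(2) |t|).

    Significance is decided by comparing q against the cached critical value
    of the studentized range at ``alpha``, which is equivalent to
    ``p_adjusted < alpha``. With ``p_values=False`` the (expensive) tail
    probabilities are skipped and reported as NaN — useful in large
    simulation screens where only the reject/accept decision matters.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    groups = _validate(groups)
    anova = one_way_anova(groups)
    _, ssw, _, dfw = _sums_of_squares(groups)
    ms_within = ssw / dfw
    k = len(groups)
    labels = list(groups)
    comparisons = []
    for a in range(k):
        for b in range(a + 1, k):
            gi, gj = groups[labels[a]], groups[labels[b]]
            diff = gi.mean() - gj.mean()
            if ms_within == 0.0:
                q = float("inf") if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
                significant = diff != 0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
                q = float(abs(diff) / se)
                significant = q > _q_critical(k, dfw, alpha)
                if p_values:
                    p = float(sps.studentized_range.sf(q, k, dfw))
                else:
                    p = float("nan")
            if np.isfinite(p):
                p = min(max(p, 0.0), 1.0)
            comparisons.append(
                PairwiseComparison(
                    label_i=labels[a],
                    label_j=labels[b],
                    mean_difference=float(diff),
                    q=q,
                    p_adjusted=p,
                    significant=significant,
                    stars=significance_stars(p) if np.isfinite(p) else "",
                )
            )
    return GroupComparison(
        groups=tuple(labels), anova=anova, pairwise=tuple(comparisons), alpha=alpha
    )
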