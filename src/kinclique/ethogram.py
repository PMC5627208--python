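"""Behavioural-category tallies and the associated classical tests.

Covers the descriptive statistics applied to agonistic/submissive event
streams: category tallies with percentages, chi-squared goodness-of-fit
against uniform (or supplied) expectations, Holm's sequential Bonferroni
correction, and Mann–Whitney rank comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "tally_ethogram",
    "chisq_gof",
    "sequential_bonferroni",
    "rank_compare",
    "reconstruct_counts",
    "EthogramTally",
    "GofResult",
    "HolmResult",
]


@dataclass(frozen=True)
class EthogramTally:
    counts: dict[str, int]
    percents: dict[str, float]
    total: int
    n_rejected: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "count": pd.Series(self.counts),
            "percent": pd.Series(self.percents),
        })


def tally_ethogram(events: pd.DataFrame, categories: list[str],
                   column: str = "behaviour") -> EthogramTally:
    """Count events per behavioural category with percentages (2 dp).

    Events whose category is not listed are rejected (counted, not
    tallied), per the stated data policy.
    """
    if not categories:
        raise ValueError("categories must be non-empty")
    if column not in events.columns:
        raise ValueError(f"events table lacks column {column!r}")
    observed = events[column].astype(str)
    known = observed.isin(categories)
    n_rejected = int((~known).sum())
    vc = observed[known].value_counts()
    counts = {c: int(vc.get(c, 0)) for c in categories}
    total = sum(counts.values())
    if total == 0:
        percents = {c: 0.0 for c in categories}
    else:
        percents = {c: round(100.0 * counts[c] / total, 2) for c in categories}
    return EthogramTally(counts=counts, percents=percents, total=total,
                         n_rejected=n_rejected)


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p: float
    small_expected: bool


def chisq_gof(counts, expected_proportions=None) -> GofResult:
    """Pearson chi-squared goodness of fit; default expectation uniform."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    c = counts.size
    if expected_proportions is None:
        expected = np.full(c, total / c)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if props.size != c:
            raise ValueError("expected proportions length mismatch")
        if np.any(props <= 0):
            raise ValueError("expected proportion of zero in some cell")
        expected = total * props / props.sum()
    statistic, p = stats.chisquare(counts, expected)
    return GofResult(statistic=float(statistic), df=c - 1, p=float(p),
                     small_expected=bool(np.any(expected < 5)))


@dataclass(frozen=True)
class HolmResult:
    reject: list[bool]
    thresholds: list[float]
    order: list[int]


def sequential_bonferroni(pvalues, alpha: float = 0.05) -> HolmResult:
    """Holm's step-down sequential Bonferroni.

    Sort p ascending; reject while p_(i) < alpha / (m − i + 1); the first
    failure stops all further rejections.  Returns flags in the input
    order plus the per-rank adjusted thresholds (ascending-p order).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return HolmResult(reject=[], thresholds=[], order=[])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = [alpha / (m - i) for i in range(m)]
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] < thresholds[i]:
            reject[idx] = True
        else:
            break
    return HolmResult(reject=reject.tolist(), thresholds=thresholds,
                      order=order.tolist())


def rank_compare(sample_a, sample_b, alternative: str = "two-sided",
                 exact_max_n: int = 20):
    """Mann–Whitney U with tie correction.

    Exact enumeration for small samples (both sizes <= ``exact_max_n``,
    and no ties), normal approximation otherwise — mirroring standard
    practice for field-behaviour sample sizes.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n
                         and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def reconstruct_counts(percents, total: int) -> list[int]:
    """Integer category counts from printed percentages of a printed total.

    Rounds each percentage share, then repairs any off-by-rounding
    discrepancy on the largest-remainder cells so the counts sum exactly
    to the stated total.
    """
    percents = np.asarray(list(percents), dtype=float)
    raw = percents / 100.0 * total
    counts = np.rint(raw).astype(int)
    diff = total - counts.sum()
    if diff != 0:
        # adjust the cells whose rounding moved furthest, one unit each
        resid = raw - counts
        order = np.argsort(-np.sign(diff) * resid)
        for i in order[: abs(diff)]:
            counts[i] += int(np.sign(diff))
    return counts.tolist()
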