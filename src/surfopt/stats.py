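"""Summary-level statistics for assay tables.

Published assay results come as group summaries (mean ± SD, n), not raw
replicates, so every procedure here works from (mean, sd, n) triples:

* the oxidative stress index OSI = TOS / (TAS * 10), with TAS in mmol
  Trolox equiv./L and TOS in µmol H2O2 equiv./L;
* the independent two-sample t-test (pooled by default, Welch optional);
* one-way ANOVA with between/within sums of squares reconstructed from the
  summaries;
* Duncan's multiple range test with the conventional shared-letter display.

Duncan's test compares the ordered group means span by span: two means that
are p ranks apart differ when their gap exceeds the critical range

    R_p = q(alpha_p; p, df_w) * sqrt(MS_w / n_h),
    alpha_p = 1 - (1 - alpha)^(p - 1),

with q the upper studentized-range quantile at Duncan's protection level
alpha_p, MS_w the within-group mean square and n_h the harmonic mean group
size.  Letters start at "a" for the highest mean; groups sharing a letter
are not significantly different at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AssaySummary",
    "TTestResult",
    "AnovaResult",
    "LetterAssignment",
    "osi",
    "t_test_from_summary",
    "anova_from_summary",
    "duncan_critical_ranges",
    "duncan_letters",
]


@dataclass(frozen=True)
class AssaySummary:
    """A group's published summary: mean ± sd with n replicates."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.label}: sd must be nonnegative")
        if self.n < 1:
            raise ValueError(f"{self.label}: n must be positive")


def osi(tas: float, tos: float) -> float:
    """Oxidative stress index: TOS (µmol/L) over ten times TAS (mmol/L)."""
    if not tas > 0:
        raise ValueError(f"TAS must be positive, got {tas}")
    return tos / (tas * 10.0)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    flag: str = ""


def t_test_from_summary(a: AssaySummary, b: AssaySummary, welch: bool = False) -> TTestResult:
    """Two-sided independent-samples t-test from group summaries.

    Pooled-variance Student's t with df = n_a + n_b - 2 by default;
    ``welch=True`` uses the Welch-Satterthwaite version.  Zero pooled
    variance is degenerate: p = 1 for equal means, p = 0 (flagged) otherwise.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if a.sd == 0 and b.sd == 0:
        df = float(a.n + b.n - 2)
        if a.mean == b.mean:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float("inf") if a.mean > b.mean else float("-inf"), df, 0.0,
                           flag="zero variance with unequal means")
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch
    )
    if welch:  # Welch-Satterthwaite df
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    ms_within: float
    flag: str = ""


def anova_from_summary(groups: Sequence[AssaySummary]) -> AnovaResult:
    """One-way ANOVA with SS reconstructed from group means, SDs and ns."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"{g.label}: n >= 2 required")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    N = ns.sum()
    k = len(groups)
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, int(N - k)
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df1, df2, 1.0, 0.0)
        return AnovaResult(float("inf"), df1, df2, 0.0, 0.0, flag="zero within-group variance")
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df1, df2))
    if ss_between == 0:
        F, p = 0.0, 1.0
    return AnovaResult(float(F), df1, df2, p, ms_within)


def duncan_critical_ranges(
    groups: Sequence[AssaySummary], alpha: float = 0.05
) -> dict[int, float]:
    """Critical range R_p for each span p = 2..k (see module docstring)."""
    an = anova_from_summary(groups)
    if an.df2 < 1:
        raise ValueError("within-group df < 1")
    k = len(groups)
    n_h = k / np.sum([1.0 / g.n for g in groups])
    se = np.sqrt(an.ms_within / n_h)
    ranges = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = float(sps.studentized_range.ppf(1.0 - alpha_p, p, an.df2))
        ranges[p] = q * se
    return ranges


@dataclass(frozen=True)
class LetterAssignment:
    """Per-group letter codes; shared letter = not significantly different."""

    letters: dict[str, str]
    alpha: float
    critical_ranges: dict[int, float]

    def __getitem__(self, label: str) -> str:
        return self.letters[label]


def duncan_letters(groups: Sequence[AssaySummary], alpha: float = 0.05) -> LetterAssignment:
    """Duncan's multiple range test with shared-letter output.

    Groups are ordered by descending mean (the best group gets "a").  A run
    of adjacent ordered groups is non-significant when the gap between its
    endpoints does not exceed the critical range for its span; each maximal
    non-significant run receives one letter, shared by all its members.
    """
    cr = duncan_critical_ranges(groups, alpha)
    order = sorted(range(len(groups)), key=lambda i: -groups[i].mean)
    means = [groups[i].mean for i in order]
    k = len(groups)

    # maximal non-significant runs; largest span tested first so that a
    # non-significant range protects (covers) everything inside it
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        for cand in range(k - 1, i, -1):
            if means[i] - means[cand] <= cr[cand - i + 1]:
                j = cand
                break
        if not runs or j > runs[-1][1]:
            runs.append((i, j))

    letters: dict[str, list[str]] = {g.label: [] for g in groups}
    for code_idx, (i, j) in enumerate(runs):
        letter = chr(ord("a") + code_idx)
        for pos in range(i, j + 1):
            letters[groups[order[pos]].label].append(letter)
    return LetterAssignment(
        letters={lab: "".join(ls) for lab, ls in letters.items()},
        alpha=alpha,
        critical_ranges=cr,
    )
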