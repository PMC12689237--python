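"""Quality-control screens applied before tariff estimation.

Three screens: *illogical* level ratings (a more severe level rated
strictly better than a less severe one within a dimension), *extreme*
responses (free level ratings pinned at 0 or 100), and the single automatic
exclusion — the anchoring degeneracy where dead is rated equal to full
health, making the anchoring transform undefined. Illogical and extreme
responses are reported but retained; only the anchoring degeneracy removes
a respondent.

A timing analysis compares illogical-response counts between respondents
below the median completion time ("fast") and at-or-above it ("slow"),
using a two-sided Wilcoxon rank-sum test with mid-rank ties; for small
groups the p-value is an exact permutation enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .descriptive_system import DIMENSIONS, Dimension
from .respondent_io import AnchorPreference, LevelResponse, Respondent, duration_minutes

ANCHOR_DIV_ZERO = "anchor-division-by-zero"
FLAT_PUF_FLAG = "flat PUF: 55555 valued at full health"


@dataclass(frozen=True)
class IllogicalFinding:
    """One strict ordering violation: within ``dimension`` the more severe
    level ``pair[1]`` was rated strictly higher than ``pair[0]``."""

    respondent_id: str
    dimension: Dimension
    pair: tuple[int, int]  # (less severe, more severe), drawn from {2,3,4}


def detect_illogical(
    levels: LevelResponse, respondent_id: str = ""
) -> list[IllogicalFinding]:
    """All strict violations among the free ratings of one respondent.

    For each dimension, every pair (l, l') with 2 <= l < l' <= 4 where the
    rating of l' strictly exceeds that of l. Ties are tolerated, and the
    implied endpoints (r1 = 100, r5 = 0) cannot generate findings because
    ratings are bounded in [0, 100].
    """
    findings = []
    for d in DIMENSIONS:
        r = {lev: levels.rating(d, lev) for lev in (2, 3, 4)}
        for lo, hi in ((2, 3), (2, 4), (3, 4)):
            if r[hi] > r[lo]:
                findings.append(IllogicalFinding(respondent_id, d, (lo, hi)))
    return findings


def extreme_rate(cohort: list[Respondent]) -> float:
    """Fraction of the 15 stored level ratings per respondent equal to
    exactly 0 or 100, pooled over the cohort."""
    if not cohort:
        raise ValueError("extreme_rate requires a non-empty cohort")
    hits = sum(
        1
        for r in cohort
        for d in DIMENSIONS
        for v in r.levels.ratings[d]
        if v == 0.0 or v == 100.0
    )
    return hits / (15 * len(cohort))


def respondent_extreme_rate(r: Respondent) -> float:
    hits = sum(
        1 for d in DIMENSIONS for v in r.levels.ratings[d] if v in (0.0, 100.0)
    )
    return hits / 15


def find_exclusions(cohort: list[Respondent]) -> list[tuple[str, str]]:
    """Respondents that cannot enter the tariff.

    The only automatic exclusion is the anchoring degeneracy: dead preferred
    over 55555 with dead rated 100 (equal to full health), which makes the
    anchored coefficients undefined. Illogical and extreme responses are
    retained. Idempotent and order-independent.
    """
    return [
        (r.id, ANCHOR_DIV_ZERO)
        for r in cohort
        if r.anchor.preference is AnchorPreference.DEAD_OVER_PITS
        and r.anchor.vas == 100.0
    ]


def find_flags(cohort: list[Respondent]) -> list[tuple[str, str]]:
    """Non-excluding warnings: currently only the flat-PUF case (55555 rated
    at full health, b = 100), which zeroes every decrement but is retained."""
    return [
        (r.id, FLAT_PUF_FLAG)
        for r in cohort
        if r.anchor.preference is AnchorPreference.PITS_OVER_DEAD_OR_INDIFFERENT
        and r.anchor.vas == 100.0
    ]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum with exact small-sample permutation p-value

@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # sum of mid-ranks of the first sample
    p_value: float
    method: str       # "exact-permutation" or "normal-approximation"


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, exact_max: int = 10
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with mid-rank tie handling.

    The statistic is W, the sum of pooled mid-ranks of ``x``. When both
    groups have at most ``exact_max`` observations the p-value is the exact
    permutation probability P(|W' - E[W]| >= |W - E[W]|) over all
    C(n1+n2, n1) assignments; otherwise a tie-corrected normal
    approximation (no continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0

    if n1 <= exact_max and n2 <= exact_max:
        dev = abs(w - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n), n1):
            ws = ranks[list(combo)].sum()
            total += 1
            if abs(ws - mu) >= dev - 1e-9:
                hits += 1
        return RankSumResult(w, hits / total, "exact-permutation")

    # tie-corrected variance of W under the null
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return RankSumResult(w, 1.0, "normal-approximation")
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(w, min(p, 1.0), "normal-approximation")


@dataclass(frozen=True)
class TimingComparison:
    median_minutes: float
    n_fast: int
    n_slow: int
    statistic: float
    p_value: float
    method: str


def timing_comparison(cohort: list[Respondent]) -> TimingComparison:
    """Fast-vs-slow comparison of illogical-response counts.

    Respondents strictly below the median duration are "fast"; those at or
    above it are "slow" (respondents exactly at the median go to "slow").
    Counts of illogical findings are compared with :func:`rank_sum_test`.
    """
    if len(cohort) < 4:
        raise ValueError("timing_comparison requires a cohort of at least 4")
    durations = np.array([duration_minutes(r) for r in cohort])
    counts = np.array(
        [len(detect_illogical(r.levels, r.id)) for r in cohort], dtype=float
    )
    med = float(np.median(durations))
    fast = counts[durations < med]
    slow = counts[durations >= med]
    if len(fast) == 0 or len(slow) == 0:
        raise ValueError(
            "timing_comparison: one timing group is empty (degenerate "
            "duration distribution; all durations equal?)"
        )
    res = rank_sum_test(fast, slow)
    return TimingComparison(
        median_minutes=med,
        n_fast=len(fast),
        n_slow=len(slow),
        statistic=res.statistic,
        p_value=res.p_value,
        method=res.method,
    )


# ---------------------------------------------------------------------------
# Cohort-level report

@dataclass
class QCReport:
    n: int
    findings: list[IllogicalFinding]
    n_respondents_illogical: int          # >= 1 finding
    n_respondents_illogical_all_dims: int  # findings in all five dimensions
    extreme_rate_overall: float
    extreme_rate_by_respondent: dict[str, float]
    exclusions: list[tuple[str, str]]
    flags: list[tuple[str, str]]
    timing: TimingComparison | None
    timing_error: str | None = None

    def to_dict(self) -> dict:
        timing = None
        if self.timing is not None:
            timing = {
                "median_minutes": self.timing.median_minutes,
                "n_fast": self.timing.n_fast,
                "n_slow": self.timing.n_slow,
                "statistic": self.timing.statistic,
                "p_value": self.timing.p_value,
                "method": self.timing.method,
            }
        return {
            "n": self.n,
            "n_illogical_findings": len(self.findings),
            "n_respondents_illogical": self.n_respondents_illogical,
            "n_respondents_illogical_all_dims": self.n_respondents_illogical_all_dims,
            "illogical_findings": [
                {
                    "respondent_id": f.respondent_id,
                    "dimension": f.dimension.value,
                    "pair": list(f.pair),
                }
                for f in self.findings
            ],
            "extreme_rate_overall": self.extreme_rate_overall,
            "extreme_rate_by_respondent": self.extreme_rate_by_respondent,
            "exclusions": [list(e) for e in self.exclusions],
            "flags": [list(f) for f in self.flags],
            "timing": timing,
            "timing_error": self.timing_error,
        }


def qc_report(cohort: list[Respondent]) -> QCReport:
    """Run every screen on a cohort and collect the results."""
    if not cohort:
        raise ValueError("qc_report requires a non-empty cohort")
    findings: list[IllogicalFinding] = []
    per_resp_dims: dict[str, set[Dimension]] = {}
    for r in cohort:
        fs = detect_illogical(r.levels, r.id)
        findings.extend(fs)
        per_resp_dims[r.id] = {f.dimension for f in fs}
    timing = None
    timing_error = None
    try:
        timing = timing_comparison(cohort)
    except ValueError as e:
        timing_error = str(e)
    return QCReport(
        n=len(cohort),
        findings=findings,
        n_respondents_illogical=sum(1 for s in per_resp_dims.values() if s),
        n_respondents_illogical_all_dims=sum(
            1 for s in per_resp_dims.values() if len(s) == 5
        ),
        extreme_rate_overall=extreme_rate(cohort),
        extreme_rate_by_respondent={
            r.id: respondent_extreme_rate(r) for r in cohort
        },
        exclusions=find_exclusions(cohort),
        flags=find_flags(cohort),
        timing=timing,
        timing_error=timing_error,
    )
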