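"""Serious vs nonserious comparison of a report cohort.

Categorical attributes are compared with the continuity-corrected
Pearson χ² (one degree of freedom),

    χ² = N·(|ad − bc| − N/2)² / (R₁·R₂·C₁·C₂),

with the correction clamped to zero when |ad − bc| < N/2, falling back
to the two-sided Fisher exact test whenever any expected cell count is
below 5.  Continuous attributes (age, weight) are compared with both
the pooled-variance two-sample t test and the two-sided Mann–Whitney U
test; both results are reported because descriptive tables in this
field routinely print a t statistic next to a rank-test p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .faers import CaseReport
from .cohort import age_in_years, weight_in_kg


@dataclass(frozen=True)
class SeverityTable2x2:
    """Counts with rows = attribute levels, columns = (serious, nonserious)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> Tuple[float, float, float, float]:
        a, b, c, d = self.a, self.b, self.c, self.d
        n = self.n
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


@dataclass(frozen=True)
class TestResult:
    test_name: str  # pearson_yates | fisher | t_test | mann_whitney
    p_value: float
    statistic: Optional[float] = None
    error: Optional[str] = None


def yates_chi2(t: SeverityTable2x2) -> TestResult:
    """Continuity-corrected χ² test on a 2×2 table (1 df)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return TestResult("pearson_yates", math.nan, error="zero marginal")
    diff = abs(a * d - b * c) - n / 2
    stat = n * max(diff, 0.0) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult("pearson_yates", p, statistic=float(stat))


def fisher_exact_2x2(t: SeverityTable2x2) -> TestResult:
    """Two-sided Fisher exact test (point-probability rule)."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return TestResult("fisher", float(p))


def compare_continuous(
    x_serious: Sequence[float], x_nonserious: Sequence[float]
) -> Tuple[TestResult, TestResult]:
    """Pooled-variance t test and two-sided Mann–Whitney U.

    The U test uses the normal approximation with tie correction for
    samples larger than 20 and the exact distribution otherwise.
    """
    x = np.asarray(x_serious, dtype=float)
    y = np.asarray(x_nonserious, dtype=float)
    if len(x) < 2 or len(y) < 2:
        err = "each group needs >= 2 values"
        return (
            TestResult("t_test", math.nan, error=err),
            TestResult("mann_whitney", math.nan, error=err),
        )
    t_stat, t_p = stats.ttest_ind(x, y, equal_var=True)
    method = "asymptotic" if max(len(x), len(y)) > 20 else "exact"
    try:
        u_stat, u_p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties
        u_stat, u_p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
    return (
        TestResult("t_test", float(t_p), statistic=float(t_stat)),
        TestResult("mann_whitney", float(u_p), statistic=float(u_stat)),
    )


def choose_test(t: SeverityTable2x2) -> TestResult:
    """Fisher when any expected cell < 5, else continuity-corrected χ²."""
    if min(t.expected()) < 5:
        return fisher_exact_2x2(t)
    return yates_chi2(t)


def build_severity_table(
    cases: Sequence[CaseReport], pt_list: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-attribute serious/nonserious comparison (severity.csv schema).

    Rows: sex (categorical), age and weight (both tests each), then one
    row per PT counting distinct serious/nonserious cases mentioning
    it.  *pt_list* restricts and orders the PT rows; by default every
    PT in the cohort appears, ordered by descending total count.
    """
    serious = [c for c in cases if c.serious]
    nonserious = [c for c in cases if not c.serious]
    rows: List[Dict] = []

    def cat_row(label: str, a: int, b: int, c: int, d: int) -> None:
        try:
            t = SeverityTable2x2(a, b, c, d)
            res = choose_test(t)
        except ValueError as exc:
            res = TestResult("pearson_yates", math.nan, error=str(exc))
        rows.append(
            {
                "attribute": label,
                "n_serious": a,
                "n_nonserious": b,
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p_value,
                "error": res.error or "",
            }
        )

    sf = sum(1 for c in serious if c.demo.sex == "F")
    sm = sum(1 for c in serious if c.demo.sex == "M")
    nf = sum(1 for c in nonserious if c.demo.sex == "F")
    nm = sum(1 for c in nonserious if c.demo.sex == "M")
    cat_row("sex:F", sf, nf, sm, nm)

    for label, extractor in (
        ("age", lambda c: age_in_years(c.demo.age, c.demo.age_cod)),
        ("weight", lambda c: weight_in_kg(c.demo.wt, c.demo.wt_cod)),
    ):
        xs = [v for v in (extractor(c) for c in serious) if v is not None]
        ys = [v for v in (extractor(c) for c in nonserious) if v is not None]
        t_res, u_res = compare_continuous(xs, ys)
        for res in (t_res, u_res):
            rows.append(
                {
                    "attribute": label,
                    "n_serious": len(xs),
                    "n_nonserious": len(ys),
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "error": res.error or "",
                }
            )

    if pt_list is None:
        counts: Dict[str, int] = {}
        for c in cases:
            for pt in set(c.pts):
                counts[pt] = counts.get(pt, 0) + 1
        pt_list = sorted(counts, key=lambda p: (-counts[p], p))
    for pt in pt_list:
        a = sum(1 for c in serious if pt in c.pts)
        b = sum(1 for c in nonserious if pt in c.pts)
        if a + b == 0:
            continue  # PT absent from cohort
        cat_row(f"pt:{pt}", a, b, len(serious) - a, len(nonserious) - b)

    return pd.DataFrame(rows)
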