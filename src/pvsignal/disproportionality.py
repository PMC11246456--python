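"""Reporting odds ratio screening on 2×2 drug-by-event contingency tables.

The screen compares how often a Preferred Term is reported for the
target drug against how often it is reported for every other drug:

====================  ===========  ==============
                      PT of        all other
                      interest     PTs
====================  ===========  ==============
target drug           a            b
all other drugs       c            d
====================  ===========  ==============

ROR = (a·d)/(b·c) with a Wald 95% CI on the log scale,

    exp( ln ROR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d) ).

A PT is flagged as a signal when the lower CI bound exceeds 1 *and* at
least 5 target-drug events were reported.  Counting is event-level: a
case reporting several PTs contributes once per PT, the convention of
the underlying 2×2 (cells are numbers of PT occurrences, not cases).

No multiple-testing adjustment is applied — spontaneous-report screens
conventionally rely on the minimum-count rule alone, and so does this
implementation; treat flagged PTs as hypotheses, not confirmed risks.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

from .cohort import (
    CohortConfig,
    age_band,
    age_in_years,
    weight_band,
    weight_in_kg,
)
from .faers import CaseReport

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d event counts of the drug-by-event 2×2."""

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False  # Haldane–Anscombe +0.5 applied

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalEstimate:
    """ROR point estimate with Wald 95% CI for one term."""

    pt: str
    n: int  # a-cell: target-drug events for this PT
    ror: float
    ci_low: float
    ci_high: float
    significant: bool = False
    corrected: bool = False
    error: Optional[str] = None


@dataclass(frozen=True)
class StratumSpec:
    """One subgroup of a stratified screen (e.g. sex = F)."""

    variable: str  # sex | age_band | weight_band | reporter_class
    level: str


@dataclass(frozen=True)
class StratumEstimate:
    stratum: StratumSpec
    n: int  # target-SOC events for the drug in this stratum
    nl: int  # other events for the drug in this stratum
    estimate: Optional[SignalEstimate]
    error: Optional[str] = None


def build_pt_contingency(
    drug_events: Mapping[str, int],
    background_events: Mapping[str, int],
    pt: str,
) -> ContingencyTable:
    """2×2 for one PT from event tallies of the drug and the background."""
    a = drug_events.get(pt, 0)
    c = background_events.get(pt, 0)
    b = sum(drug_events.values()) - a
    d = sum(background_events.values()) - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def compute_ror(table: ContingencyTable, pt: str = "") -> SignalEstimate:
    """ROR with Wald 95% CI; Haldane–Anscombe 0.5 on zero cells.

    The a-cell count reported in ``n`` is always the uncorrected one.
    Returns an error estimate when a margin (a+b or c+d) is empty, in
    which case the ratio is undefined for any correction.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_events = int(a)
    if a + b == 0 or c + d == 0:
        return SignalEstimate(
            pt=pt, n=n_events, ror=math.nan, ci_low=math.nan, ci_high=math.nan,
            error="undefined: empty margin",
        )
    corrected = table.corrected
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return SignalEstimate(
        pt=pt,
        n=n_events,
        ror=ror,
        ci_low=math.exp(log_ror - Z_95 * se),
        ci_high=math.exp(log_ror + Z_95 * se),
        corrected=corrected,
    )


def evaluate_signal(est: SignalEstimate, min_events: int = 5) -> SignalEstimate:
    """Apply the signal rule: ci_low > 1 (strict) and n ≥ *min_events*."""
    if est.error is not None:
        return replace(est, significant=False)
    return replace(est, significant=bool(est.ci_low > 1.0 and est.n >= min_events))


# ---------------------------------------------------------------------------
# tallies and screens


def pt_tally(cases: Iterable[CaseReport]) -> Counter:
    """Event-level PT tally: one count per (case, PT) occurrence."""
    tally: Counter = Counter()
    for case in cases:
        tally.update(case.pts)
    return tally


def screen_pts(
    drug_events: Mapping[str, int],
    background_events: Mapping[str, int],
    pts: Iterable[str],
    min_events: int = 5,
) -> List[SignalEstimate]:
    """ROR screen over *pts*, sorted by descending lower CI bound."""
    out = []
    for pt in pts:
        table = build_pt_contingency(drug_events, background_events, pt)
        out.append(evaluate_signal(compute_ror(table, pt=pt), min_events))
    out.sort(key=lambda e: (-(e.ci_low if e.ci_low == e.ci_low else -math.inf), e.pt))
    return out


def screen_soc(
    drug_events: Mapping[str, int],
    background_events: Mapping[str, int],
    pt_to_soc: Mapping[str, str],
    soc: str,
    min_events: int = 5,
) -> Tuple[List[SignalEstimate], Optional[SignalEstimate]]:
    """Per-PT screen within one SOC plus a pooled SOC-level estimate.

    The SOC-level 2×2 pools every member PT's events into the a-cell
    (and the background's member-PT events into the c-cell).
    """
    soc = str(soc)
    norm = {pt.strip().lower(): str(code).strip() for pt, code in pt_to_soc.items()}
    member = lambda pt: norm.get(pt.strip().lower()) == soc  # noqa: E731
    soc_pts = sorted({pt for pt in drug_events if member(pt)})
    estimates = screen_pts(drug_events, background_events, soc_pts, min_events)

    a = sum(v for pt, v in drug_events.items() if member(pt))
    c = sum(v for pt, v in background_events.items() if member(pt))
    b = sum(drug_events.values()) - a
    d = sum(background_events.values()) - c
    soc_est: Optional[SignalEstimate] = None
    if a + b + c + d > 0:
        soc_est = evaluate_signal(
            compute_ror(ContingencyTable(a=a, b=b, c=c, d=d), pt=f"SOC:{soc}"),
            min_events,
        )
    return estimates, soc_est


def _stratum_value(case: CaseReport, variable: str) -> Optional[str]:
    d = case.demo
    if variable == "sex":
        return d.sex if d.sex in {"F", "M"} else None
    if variable == "age_band":
        years = age_in_years(d.age, d.age_cod)
        return None if years is None else age_band(years)
    if variable == "weight_band":
        kg = weight_in_kg(d.wt, d.wt_cod)
        return None if kg is None else weight_band(kg)
    if variable == "reporter_class":
        rc = case.reporter_class
        return rc if rc != "unknown" else None
    raise ValueError(f"unknown stratum variable {variable!r}")


def stratified_screen(
    cases: Sequence[CaseReport],
    background_cases: Sequence[CaseReport],
    strata: Sequence[StratumSpec],
    config: CohortConfig,
    min_events: int = 5,
) -> List[StratumEstimate]:
    """SOC-level ROR within demographic subgroups.

    For each stratum, only cases with a non-missing value of the
    stratum variable enter either side of the 2×2; the a-cell pools the
    drug cohort's target-SOC events in that stratum.  A stratum with no
    drug events yields an error entry and the screen continues.
    """
    from .cohort import soc_pts as _soc_pts

    out: List[StratumEstimate] = []
    for spec in strata:
        drug_sub = [c for c in cases if _stratum_value(c, spec.variable) == spec.level]
        bg_sub = [
            c
            for c in background_cases
            if _stratum_value(c, spec.variable) == spec.level
        ]
        drug_tally = pt_tally(drug_sub)
        bg_tally = pt_tally(bg_sub)
        a = sum(len(_soc_pts(c, config)) for c in drug_sub)
        b = sum(drug_tally.values()) - a
        if a == 0:
            out.append(
                StratumEstimate(
                    stratum=spec, n=0, nl=int(b), estimate=None,
                    error="no drug events in stratum",
                )
            )
            continue
        c_cell = sum(len(_soc_pts(c, config)) for c in bg_sub)
        d_cell = sum(bg_tally.values()) - c_cell
        est = evaluate_signal(
            compute_ror(
                ContingencyTable(a=a, b=b, c=c_cell, d=d_cell),
                pt=f"{spec.variable}={spec.level}",
            ),
            min_events,
        )
        out.append(StratumEstimate(stratum=spec, n=int(a), nl=int(b), estimate=est))
    return out


def signals_frame(estimates: Sequence[SignalEstimate]):
    """Signal estimates as a DataFrame (signals.csv schema)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pt": e.pt,
                "n": e.n,
                "ror": e.ror,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "significant": e.significant,
                "corrected": e.corrected,
                "error": e.error or "",
            }
            for e in estimates
        ]
    )
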