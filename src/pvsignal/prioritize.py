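"""Semi-quantitative clinical priority scoring of disproportionality signals.

Each significant signal is scored on five features — case count, lower
95% CI bound of the ROR (ROR025), case-fatality proportion, inclusion
on an Important/Designated Medical Event reference list, and a
literature-evidence grade — each worth 0–2 points, for a 0–10 total
banded as weak (0–4), moderate (5–7) or strong (8–10) clinical
priority.

The default point thresholds shipped in ``data/rubric.yaml`` are a
calibrated reconstruction: published applications of this scale keep
the exact cut-points in supplementary material, so the defaults here
were chosen to reproduce the published lacosamide cardiac-signal
scores, and should be reviewed before being applied to another drug.
The rubric is fully configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .disproportionality import SignalEstimate
from .faers import CaseReport

logger = logging.getLogger(__name__)

DATA_DIR = Path(__file__).parent / "data"

WEAK_MAX = 4
MODERATE_MAX = 7


@dataclass(frozen=True)
class PriorityFeatures:
    """The five scored features of one signal."""

    pt: str
    n_cases: int
    ror025: float
    n_deaths: int
    importance: str  # DME | IME | NA
    evidence_grade: str  # "+" | "++"

    def __post_init__(self) -> None:
        if self.n_deaths > self.n_cases:
            raise ValueError("n_deaths exceeds n_cases")
        if self.importance not in {"DME", "IME", "NA"}:
            raise ValueError(f"bad importance {self.importance!r}")
        if self.evidence_grade not in {"+", "++"}:
            raise ValueError(f"bad evidence grade {self.evidence_grade!r}")

    @property
    def death_proportion(self) -> float:
        return self.n_deaths / self.n_cases if self.n_cases else 0.0


@dataclass(frozen=True)
class PriorityResult:
    score: int
    level: str  # weak | moderate | strong


def band(score: int) -> str:
    if score <= WEAK_MAX:
        return "weak"
    if score <= MODERATE_MAX:
        return "moderate"
    return "strong"


@dataclass
class Rubric:
    """Threshold→points maps for the five features.

    ``cases``, ``ror025`` and ``death_proportion`` are lists of
    (lower_bound, points) pairs applied as step functions: the points of
    the highest bound not exceeding the value.  ``importance`` and
    ``evidence`` are direct label→points maps.  Per-feature maxima must
    sum to 10 so the weak/moderate/strong bands keep their meaning.
    """

    cases: List[Tuple[float, int]]
    ror025: List[Tuple[float, int]]
    death_proportion: List[Tuple[float, int]]
    importance: Dict[str, int]
    evidence: Dict[str, int]

    def __post_init__(self) -> None:
        for name in ("cases", "ror025", "death_proportion"):
            steps = sorted((float(t), int(p)) for t, p in getattr(self, name))
            if not steps:
                raise ValueError(f"rubric feature {name} is empty")
            setattr(self, name, steps)
        total_max = (
            max(p for _, p in self.cases)
            + max(p for _, p in self.ror025)
            + max(p for _, p in self.death_proportion)
            + max(self.importance.values())
            + max(self.evidence.values())
        )
        if total_max != 10:
            raise ValueError(f"per-feature maxima must sum to 10, got {total_max}")

    @staticmethod
    def _step(steps: List[Tuple[float, int]], value: float) -> int:
        pts = 0
        matched = False
        for bound, p in steps:
            if value >= bound:
                pts = p
                matched = True
        if not matched:
            raise ValueError(f"value {value} below lowest rubric bound {steps[0][0]}")
        return pts

    def score(self, f: PriorityFeatures) -> int:
        if f.importance not in self.importance:
            raise ValueError(f"importance {f.importance!r} outside rubric")
        if f.evidence_grade not in self.evidence:
            raise ValueError(f"evidence {f.evidence_grade!r} outside rubric")
        return (
            self._step(self.cases, f.n_cases)
            + self._step(self.ror025, f.ror025)
            + self._step(self.death_proportion, f.death_proportion)
            + self.importance[f.importance]
            + self.evidence[f.evidence_grade]
        )


def load_rubric(path: Optional[str | Path] = None) -> Rubric:
    """Load a rubric YAML; the shipped default when *path* is None."""
    path = Path(path) if path else DATA_DIR / "rubric.yaml"
    raw = yaml.safe_load(path.read_text())
    return Rubric(
        cases=[(d["min"], d["points"]) for d in raw["cases"]],
        ror025=[(d["min"], d["points"]) for d in raw["ror025"]],
        death_proportion=[(d["min"], d["points"]) for d in raw["death_proportion"]],
        importance={str(k): int(v) for k, v in raw["importance"].items()},
        evidence={str(k): int(v) for k, v in raw["evidence"].items()},
    )


def load_pt_list(path: str | Path) -> frozenset:
    """One PT per line, '#' comments allowed; lower-cased for matching."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line.lower())
    return frozenset(out)


def classify_importance(
    pt: str, ime_list: frozenset, dme_list: frozenset
) -> str:
    """DME / IME / NA for one PT; DME takes precedence over IME."""
    if not ime_list and not dme_list:
        logger.warning("empty IME and DME lists: every PT classed NA")
    key = pt.strip().lower()
    if key in dme_list:
        return "DME"
    if key in ime_list:
        return "IME"
    return "NA"


def score_signal(f: PriorityFeatures, rubric: Rubric) -> PriorityResult:
    """Total the five feature points and band the result."""
    s = rubric.score(f)
    return PriorityResult(score=s, level=band(s))


def count_deaths(pt: str, cases: Sequence[CaseReport]) -> int:
    """Distinct cases with a death (DE) outcome mentioning *pt*."""
    return sum(1 for c in cases if "DE" in c.outcome_codes and pt in c.pts)


def prioritize_screen(
    signals: Sequence[SignalEstimate],
    cases: Sequence[CaseReport],
    rubric: Rubric,
    ime_list: frozenset,
    dme_list: frozenset,
    label_pts: frozenset = frozenset(),
    evidence_grades: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Score significant signals (priorities.csv schema).

    Death counts come from distinct DE-outcome cases mentioning the PT;
    the novelty flag marks PTs absent from the drug-label list.
    Evidence grades are an input annotation (literature review), with
    '+' assumed when unannotated.  Rows are sorted by descending case
    count.
    """
    evidence_grades = {
        k.strip().lower(): v for k, v in (evidence_grades or {}).items()
    }
    rows = []
    for sig in signals:
        features = PriorityFeatures(
            pt=sig.pt,
            n_cases=sig.n,
            ror025=sig.ci_low,
            n_deaths=min(count_deaths(sig.pt, cases), sig.n),
            importance=classify_importance(sig.pt, ime_list, dme_list),
            evidence_grade=evidence_grades.get(sig.pt.strip().lower(), "+"),
        )
        result = score_signal(features, rubric)
        rows.append(
            {
                "pt": sig.pt,
                "n": features.n_cases,
                "ror025": features.ror025,
                "deaths": features.n_deaths,
                "importance": features.importance,
                "evidence": features.evidence_grade,
                "score": result.score,
                "level": result.level,
                "novel": sig.pt.strip().lower() not in label_pts,
            }
        )
    columns = [
        "pt", "n", "ror025", "deaths", "importance", "evidence",
        "score", "level", "novel",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if not df.empty:
        df = df.sort_values(["n", "pt"], ascending=[False, True]).reset_index(drop=True)
    return df
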