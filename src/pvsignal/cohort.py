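"""Cohort construction: dedup, suspect-drug selection, exclusions, SOC restriction.

Spontaneous-report databases contain multiple versions of the same case
(follow-up reports share a ``caseid`` under fresh ``primaryid`` values)
and free-text drug names.  This module applies the standard cleaning
sequence used in disproportionality studies:

1. keep one version per caseid (latest ``fda_dt``, ties broken by the
   higher ``primaryid``);
2. keep cases where the target drug appears with the required role code
   (default PS, primary suspect), matching generic names against
   ``drugname``/``prod_ai`` and trade names against ``drugname`` by
   case-insensitive substring;
3. strip administratively coded PTs (off-label use, product issues,
   medication errors, indication-disease terms) and drop cases whose
   event date precedes the therapy start date (data-entry errors);
4. restrict to a target MedDRA System Organ Class via a PT→SOC map,
   counting events at PT level (a case with several target-SOC PTs is
   deliberately counted once per PT).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .faers import CaseReport, DrugRecord

logger = logging.getLogger(__name__)

#: Age-unit → years conversion factors (FAERS age_cod values).
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

LBS_TO_KG = 0.4536

AGE_BANDS = ["<18", "18-64", ">64"]
WEIGHT_BANDS = ["<80", "80-100", ">100"]


@dataclass
class CohortConfig:
    """Drug and event selection rules for one analysis.

    ``excluded_pt_classes`` maps a class label (e.g. ``off_label``) to
    the set of PTs it removes; ``pt_to_soc`` maps each PT to its SOC
    code.  PT comparisons are case-insensitive on trimmed text.
    """

    generic_names: List[str]
    trade_names: List[str]
    pt_to_soc: Dict[str, str]
    target_soc_code: str
    required_role: str = "PS"
    excluded_pt_classes: Dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.generic_names and not self.trade_names:
            raise ValueError("at least one generic or trade name is required")
        self.generic_names = [g.strip().lower() for g in self.generic_names]
        self.trade_names = [t.strip().lower() for t in self.trade_names]
        self.pt_to_soc = {k.strip().lower(): str(v).strip() for k, v in self.pt_to_soc.items()}
        self.target_soc_code = str(self.target_soc_code).strip()
        if self.target_soc_code not in set(self.pt_to_soc.values()):
            raise ValueError(
                f"target SOC {self.target_soc_code} absent from pt_to_soc values"
            )
        self.excluded_pt_classes = {
            label: frozenset(p.strip().lower() for p in pts)
            for label, pts in self.excluded_pt_classes.items()
        }

    @property
    def excluded_pts(self) -> frozenset:
        out: set = set()
        for pts in self.excluded_pt_classes.values():
            out |= pts
        return frozenset(out)


def load_pt_to_soc(path: str | Path) -> Dict[str, str]:
    """Read a two-column CSV (pt, soc_code) into a PT→SOC map."""
    import csv

    mapping: Dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "pt" not in reader.fieldnames:
            raise ValueError(f"{path}: expected columns pt, soc_code")
        for row in reader:
            mapping[row["pt"].strip()] = row["soc_code"].strip()
    return mapping


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML file.

    Recognised keys: generic_names, trade_names, required_role,
    target_soc_code, pt_to_soc (path to CSV, relative to the YAML file),
    excluded_pt_classes (mapping label → list of PTs, or a path to a
    YAML of the same shape).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent
    pt_map_path = Path(raw["pt_to_soc"])
    if not pt_map_path.is_absolute():
        pt_map_path = base / pt_map_path
    excl = raw.get("excluded_pt_classes", {})
    if isinstance(excl, str):
        excl_path = Path(excl)
        if not excl_path.is_absolute():
            excl_path = base / excl_path
        excl = yaml.safe_load(excl_path.read_text())
    return CohortConfig(
        generic_names=raw.get("generic_names", []),
        trade_names=raw.get("trade_names", []),
        required_role=raw.get("required_role", "PS"),
        target_soc_code=str(raw["target_soc_code"]),
        pt_to_soc=load_pt_to_soc(pt_map_path),
        excluded_pt_classes={k: frozenset(v) for k, v in (excl or {}).items()},
    )


# ---------------------------------------------------------------------------
# deduplication


def _dedup_key(case: CaseReport) -> tuple:
    fda = case.demo.fda_dt.sort_key() if case.demo.fda_dt else (0, 0, 0)
    pid = case.primaryid
    try:
        pid_key: tuple = (0, int(pid), "")
    except ValueError:
        logger.warning("non-numeric primaryid %r: lexicographic tie-break", pid)
        pid_key = (1, 0, pid)
    return (fda, pid_key)


def deduplicate(cases: Sequence[CaseReport]) -> List[CaseReport]:
    """Keep one report version per caseid.

    The survivor maximises ``fda_dt``; among equal dates the higher
    numeric ``primaryid`` wins (lexicographic fallback for non-numeric
    ids, logged).  Output is sorted by caseid, so the operation is a
    deterministic function of the input *set*.
    """
    best: Dict[str, CaseReport] = {}
    for case in cases:
        cid = case.caseid or case.primaryid
        cur = best.get(cid)
        if cur is None or _dedup_key(case) > _dedup_key(cur):
            best[cid] = case
    return sorted(best.values(), key=lambda c: c.caseid)


# ---------------------------------------------------------------------------
# drug selection and exclusions


def _drug_matches(drug: DrugRecord, config: CohortConfig) -> bool:
    if drug.role_cod != config.required_role:
        return False
    name = drug.drugname.lower()
    ai = drug.prod_ai.lower()
    for g in config.generic_names:
        if g in name or g in ai:
            return True
    return any(t in name for t in config.trade_names)


def mentions_drug(case: CaseReport, config: CohortConfig) -> bool:
    """True when the target drug appears in *any* role on the case."""
    for drug in case.drugs:
        name, ai = drug.drugname.lower(), drug.prod_ai.lower()
        if any(g in name or g in ai for g in config.generic_names):
            return True
        if any(t in name for t in config.trade_names):
            return True
    return False


def select_drug_cases(
    cases: Sequence[CaseReport], config: CohortConfig
) -> List[CaseReport]:
    """Cases where the target drug carries the required role code."""
    return [c for c in cases if any(_drug_matches(d, config) for d in c.drugs)]


def suspect_drug_seqs(case: CaseReport, config: CohortConfig) -> List[int]:
    """drug_seq values of the matching suspect-drug rows on a case."""
    return [d.drug_seq for d in case.drugs if _drug_matches(d, config)]


def _earliest_start(case: CaseReport, config: CohortConfig):
    """Earliest full-precision therapy start date of the suspect drug."""
    seqs = set(suspect_drug_seqs(case, config))
    starts = [
        t.start_dt
        for t in case.therapies
        if t.dsg_drug_seq in seqs and t.start_dt is not None and t.start_dt.is_full
    ]
    return min(starts, key=lambda d: d.sort_key()) if starts else None


def apply_exclusions(
    cases: Sequence[CaseReport], config: CohortConfig
) -> List[CaseReport]:
    """Remove excluded PTs and date-error cases.

    PTs in any excluded class are filtered from each case's reaction
    list; a case whose PT list becomes empty is dropped.  A case is also
    dropped when its event date and the suspect drug's therapy start
    date are both full precision and the event precedes the start
    (input error).  Partial or missing dates are never treated as
    evidence of error.
    """
    excluded = config.excluded_pts
    out: List[CaseReport] = []
    n_pts_removed = 0
    n_date_errors = 0
    n_emptied = 0
    for case in cases:
        kept = [r for r in case.reactions if r.pt.lower() not in excluded]
        n_pts_removed += len(case.reactions) - len(kept)
        if not kept:
            n_emptied += 1
            continue
        event = case.demo.event_dt
        start = _earliest_start(case, config)
        if (
            event is not None
            and event.is_full
            and start is not None
            and event.to_date() < start.to_date()
        ):
            n_date_errors += 1
            continue
        case.reactions = kept
        out.append(case)
    logger.info(
        "apply_exclusions: removed %d excluded PTs, dropped %d emptied cases, "
        "%d date-error cases",
        n_pts_removed,
        n_emptied,
        n_date_errors,
    )
    return out


def restrict_to_soc(
    cases: Sequence[CaseReport], config: CohortConfig
) -> Tuple[List[CaseReport], int]:
    """Cases with ≥1 PT in the target SOC, plus the PT-level event tally.

    The tally counts (case, target-SOC PT) pairs, so a case reporting
    three target PTs contributes three events and one case — the
    event-level convention used throughout the screening stage.
    Unmapped PTs are excluded from the tally with a warning.
    """
    pt_to_soc = config.pt_to_soc
    target = config.target_soc_code
    kept: List[CaseReport] = []
    n_events = 0
    unmapped: Counter = Counter()
    for case in cases:
        n_target = 0
        for pt in case.pts:
            soc = pt_to_soc.get(pt.lower())
            if soc is None:
                unmapped[pt] += 1
                continue
            if soc == target:
                n_target += 1
        if n_target:
            kept.append(case)
            n_events += n_target
    if unmapped:
        logger.warning(
            "restrict_to_soc: %d PT occurrences unmapped (%d distinct)",
            sum(unmapped.values()),
            len(unmapped),
        )
    return kept, n_events


def soc_pts(case: CaseReport, config: CohortConfig) -> List[str]:
    """The case's PTs that map to the target SOC (with multiplicity)."""
    return [
        pt
        for pt in case.pts
        if config.pt_to_soc.get(pt.lower()) == config.target_soc_code
    ]


# ---------------------------------------------------------------------------
# demographic summaries


def age_in_years(age: Optional[float], age_cod: str) -> Optional[float]:
    """Convert a FAERS (age, age_cod) pair to years; None when unusable."""
    if age is None:
        return None
    factor = AGE_UNIT_TO_YEARS.get(age_cod.upper() or "YR")
    if factor is None:
        return None
    return age * factor


def weight_in_kg(wt: Optional[float], wt_cod: str) -> Optional[float]:
    """Convert a FAERS (wt, wt_cod) pair to kilograms; None when unusable."""
    if wt is None:
        return None
    code = wt_cod.upper() or "KG"
    if code == "KG":
        return wt
    if code in {"LBS", "LB"}:
        return wt * LBS_TO_KG
    logger.warning("unknown wt_cod %r: weight dropped", wt_cod)
    return None


def age_band(years: float) -> str:
    if years < 18:
        return "<18"
    if years <= 64:
        return "18-64"
    return ">64"


def weight_band(kg: float) -> str:
    if kg < 80:
        return "<80"
    if kg <= 100:
        return "80-100"
    return ">100"


def _median_iqr(values: Sequence[float]) -> Optional[Tuple[float, float, float]]:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return (
        float(np.median(arr)),
        float(np.percentile(arr, 25)),
        float(np.percentile(arr, 75)),
    )


@dataclass
class CohortSummary:
    """Descriptive table of a cohort (counts over available denominators).

    Each categorical entry maps level → count; the matching
    ``*_available`` attribute is the non-missing denominator over which
    percentages should be computed.
    """

    n_cases: int
    sex_counts: Dict[str, int]
    sex_available: int
    age_bands: Dict[str, int]
    age_available: int
    age_median_iqr: Optional[Tuple[float, float, float]]
    weight_bands: Dict[str, int]
    weight_available: int
    weight_median_iqr: Optional[Tuple[float, float, float]]
    country_counts: Dict[str, int]
    indication_counts: Dict[str, int]
    indication_available: int
    outcome_counts: Dict[str, int]
    n_serious: int
    n_nonserious: int
    reporter_counts: Dict[str, int]
    reporter_available: int
    year_counts: Dict[int, int]
    tto_median_iqr: Optional[Tuple[float, float, float]]
    tto_available: int

    def percentage(self, numerator: int, available: int) -> float:
        """Share of *numerator* in the available denominator, percent."""
        if available == 0:
            return float("nan")
        return 100.0 * numerator / available


def proportion_pct(numerator: int, denominator: int) -> float:
    """Percentage share, the convention used in descriptive tables."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


def summarize_cohort(
    cases: Sequence[CaseReport],
    config: Optional[CohortConfig] = None,
    tto_values: Optional[Sequence[float]] = None,
) -> CohortSummary:
    """Descriptive summary of a (deduplicated) cohort.

    Percentages are computed over available (non-missing) denominators;
    band counts partition the available set by construction.  When
    *config* is given, per-case time-to-onset values are derived from
    the suspect drug's therapy dates unless *tto_values* overrides them.
    """
    sex_counts: Counter = Counter()
    ages: List[float] = []
    weights: List[float] = []
    countries: Counter = Counter()
    indications: Counter = Counter()
    ind_avail = 0
    outcomes: Counter = Counter()
    reporters: Counter = Counter()
    years: Counter = Counter()
    n_serious = 0
    for case in cases:
        d = case.demo
        if d.sex in {"F", "M"}:
            sex_counts[d.sex] += 1
        years_val = age_in_years(d.age, d.age_cod)
        if years_val is not None:
            ages.append(years_val)
        kg = weight_in_kg(d.wt, d.wt_cod)
        if kg is not None:
            weights.append(kg)
        if d.occr_country:
            countries[d.occr_country] += 1
        if case.indications:
            ind_avail += 1
            for ind in {i.indi_pt for i in case.indications if i.indi_pt}:
                indications[ind] += 1
        if case.serious:
            n_serious += 1
            for code in case.outcome_codes:
                outcomes[code] += 1
        if case.reporter_class != "unknown":
            reporters[case.reporter_class] += 1
        if d.fda_dt is not None:
            years[d.fda_dt.year] += 1

    if tto_values is None and config is not None:
        from .tto import compute_tto

        tto_values = compute_tto(cases, config).values
    tto_values = list(tto_values) if tto_values is not None else []

    return CohortSummary(
        n_cases=len(cases),
        sex_counts=dict(sex_counts),
        sex_available=sum(sex_counts.values()),
        age_bands=dict(Counter(age_band(a) for a in ages)),
        age_available=len(ages),
        age_median_iqr=_median_iqr(ages),
        weight_bands=dict(Counter(weight_band(w) for w in weights)),
        weight_available=len(weights),
        weight_median_iqr=_median_iqr(weights),
        country_counts=dict(countries),
        indication_counts=dict(indications),
        indication_available=ind_avail,
        outcome_counts=dict(outcomes),
        n_serious=n_serious,
        n_nonserious=len(cases) - n_serious,
        reporter_counts=dict(reporters),
        reporter_available=sum(reporters.values()),
        year_counts=dict(years),
        tto_median_iqr=_median_iqr(tto_values),
        tto_available=len(tto_values),
    )
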