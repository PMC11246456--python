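"""Synthetic FAERS quarterly file generator with analytic ground truth.

Emits DEMO/DRUG/REAC/OUTC/THER/INDI files in the "$"-delimited FAERS
ASCII dialect so the whole pipeline — parsing, deduplication, cohort
selection, ROR screening, severity comparison and Weibull
time-to-onset fitting — can be exercised without downloading the real
database.

The statistical structure mirrors what the analysis assumes of
spontaneous reports:

* every case is a multi-table record keyed by primaryid/caseid, and a
  configurable fraction of cases is emitted as several versions
  (follow-up reports with older ``fda_dt`` and lower ``primaryid``), so
  deduplication has real work to do and an exact ground truth;
* adverse-event terms are drawn from a PT catalogue with background
  rates; for signal PTs the drug cohort's event probability is scaled
  so that the event-level odds ratio against background equals the
  configured target, giving each PT an analytic expected ROR;
* onset delays are drawn from per-group Weibull distributions and
  encoded as THER start dates plus DEMO event dates (a configurable
  fraction of event dates is degraded to month precision to exercise
  the partial-date path);
* seriousness, death outcomes, demographics, missingness, countries
  and reporter occupations follow configurable rates whose defaults
  match the descriptive profile of a large anticonvulsant cohort in
  FAERS (≈74% serious, ≈27% of reports with computable onset, heavy
  weight/age missingness).

All randomness flows from a single integer seed; regenerating with the
same configuration yields byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

CARDIAC_SOC = "10007541"

#: (pt, soc_code, background rate) — a miniature synthetic catalogue, not
#: the licensed MedDRA dictionary.  Cardiac PTs use the real SOC code for
#: cardiac disorders; other SOC codes are schema-valid stand-ins.
DEFAULT_PT_CATALOG: List[Tuple[str, str, float]] = [
    ("Bradycardia", CARDIAC_SOC, 0.0025),
    ("Cardiac arrest", CARDIAC_SOC, 0.0030),
    ("Atrioventricular block", CARDIAC_SOC, 0.0008),
    ("Atrial fibrillation", CARDIAC_SOC, 0.0060),
    ("Atrioventricular block complete", CARDIAC_SOC, 0.0005),
    ("Cardio-respiratory arrest", CARDIAC_SOC, 0.0012),
    ("Arrhythmia", CARDIAC_SOC, 0.0025),
    ("Sinus bradycardia", CARDIAC_SOC, 0.0008),
    ("Atrioventricular block second degree", CARDIAC_SOC, 0.0003),
    ("Ventricular tachycardia", CARDIAC_SOC, 0.0012),
    ("Sinus node dysfunction", CARDIAC_SOC, 0.0002),
    ("Ventricular fibrillation", CARDIAC_SOC, 0.0009),
    ("Sinus arrest", CARDIAC_SOC, 0.00015),
    ("Atrioventricular block first degree", CARDIAC_SOC, 0.0004),
    ("Atrial flutter", CARDIAC_SOC, 0.0008),
    ("Sinoatrial block", CARDIAC_SOC, 0.0001),
    ("Conduction disorder", CARDIAC_SOC, 0.0002),
    ("Palpitations", CARDIAC_SOC, 0.0040),
    ("Tachycardia", CARDIAC_SOC, 0.0040),
    ("Nausea", "10017947", 0.0900),
    ("Vomiting", "10017947", 0.0500),
    ("Diarrhoea", "10017947", 0.0500),
    ("Headache", "10029205", 0.0800),
    ("Dizziness", "10029205", 0.0800),
    ("Somnolence", "10029205", 0.0400),
    ("Seizure", "10029205", 0.0300),
    ("Fatigue", "10018065", 0.0700),
    ("Drug ineffective", "10018065", 0.0600),
    ("Rash", "10040785", 0.0500),
    ("Pruritus", "10040785", 0.0300),
    ("Insomnia", "10037175", 0.0300),
    ("Fall", "10022117", 0.0400),
    ("Off label use", "10022117", 0.0150),
    ("Medication error", "10022117", 0.0100),
    ("Product quality issue", "10077536", 0.0050),
]

DEFAULT_SIGNAL_SPEC: Dict[str, float] = {
    "Bradycardia": 8.0,
    "Atrioventricular block complete": 18.0,
    "Ventricular tachycardia": 3.0,
    "Atrial fibrillation": 1.5,
}

#: Onset-delay Weibull parameters per PT group (scale days, shape).
DEFAULT_TTO_SPEC: Dict[str, Tuple[float, float]] = {
    "moderate": (100.0, 0.48),
    "weak": (174.0, 0.52),
    "default": (120.0, 0.50),
}

DEFAULT_PT_GROUP: Dict[str, str] = {
    "Bradycardia": "moderate",
    "Atrioventricular block complete": "moderate",
    "Ventricular tachycardia": "moderate",
    "Atrial fibrillation": "weak",
}

BACKGROUND_DRUGS = [
    "LEVETIRACETAM",
    "VALPROIC ACID",
    "LAMOTRIGINE",
    "METFORMIN",
    "IBUPROFEN",
    "AMOXICILLIN",
]

COUNTRIES = ["US", "JP", "DE", "FR", "CO", "GB", "IT"]
COUNTRY_P = [0.55, 0.12, 0.08, 0.07, 0.04, 0.08, 0.06]

START_YEAR = 2013


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults emulate the study conditions."""

    n_background_cases: int = 5000
    n_drug_cases: int = 1000
    pt_catalog: List[Tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_PT_CATALOG)
    )
    signal_spec: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_SPEC)
    )
    serious_prob: float = 0.74
    death_prob_given_serious: float = 0.17
    tto_spec: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TTO_SPEC)
    )
    pt_group: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PT_GROUP))
    tto_available_rate: float = 0.27
    partial_date_fraction: float = 0.05
    female_prob: float = 0.546
    sex_missing: float = 0.11
    age_mean: float = 52.0
    age_sd: float = 22.0
    age_missing: float = 0.44
    weight_mean: float = 72.0
    weight_sd: float = 16.0
    weight_missing: float = 0.74
    professional_prob: float = 0.60
    extra_pts_rate: float = 0.3  # Poisson mean for PTs beyond the first
    duplicate_rate: float = 0.10
    n_quarters: int = 40
    drugname: str = "VIMPAT"
    prod_ai: str = "LACOSAMIDE"
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.serious_prob,
            self.death_prob_given_serious,
            self.tto_available_rate,
            self.partial_date_fraction,
            self.female_prob,
            self.sex_missing,
            self.age_missing,
            self.weight_missing,
            self.professional_prob,
            self.duplicate_rate,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(rate <= 0 for _, _, rate in self.pt_catalog):
            raise ValueError("background rates must be positive")
        if self.n_quarters < 1 or self.n_quarters > 60:
            raise ValueError("n_quarters out of range")
        catalog_pts = {pt for pt, _, _ in self.pt_catalog}
        unknown = set(self.signal_spec) - catalog_pts
        if unknown:
            raise ValueError(f"signal_spec PTs absent from catalogue: {unknown}")
        if "default" not in self.tto_spec:
            raise ValueError("tto_spec must define a 'default' group")
        # Fail fast on impossible signal strengths before any sampling.
        self.event_probabilities()

    def background_probs(self) -> Dict[str, float]:
        total = sum(rate for _, _, rate in self.pt_catalog)
        return {pt: rate / total for pt, _, rate in self.pt_catalog}

    def event_probabilities(self) -> Tuple[Dict[str, float], Dict[str, float]]:
        """(drug, background) per-PT event probability vectors.

        For a signal PT with target odds multiplier ρ, the drug-side
        probability solves p/(1−p) = ρ·q/(1−q); the remaining mass is
        spread over non-signal PTs proportionally to their background
        share, so non-signal odds stay near (but not exactly) 1.
        """
        q = self.background_probs()
        p: Dict[str, float] = {}
        for pt, rho in self.signal_spec.items():
            if rho <= 0:
                raise ValueError(f"signal multiplier for {pt} must be positive")
            odds = rho * q[pt] / (1 - q[pt])
            p[pt] = odds / (1 + odds)
        signal_mass = sum(p.values())
        if signal_mass >= 1:
            raise ValueError(
                f"signal_spec implies total event probability {signal_mass:.3f} >= 1"
            )
        rest = {pt: q[pt] for pt in q if pt not in p}
        rest_total = sum(rest.values())
        for pt, share in rest.items():
            p[pt] = (1 - signal_mass) * share / rest_total
        return p, q

    def expected_ror(self) -> Dict[str, float]:
        """Analytic event-level ROR per PT under the emitted design."""
        p, q = self.event_probabilities()
        return {
            pt: (p[pt] / (1 - p[pt])) / (q[pt] / (1 - q[pt])) for pt in q
        }


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    expected_ror: Dict[str, float]
    true_primaryids: Dict[str, str]  # caseid -> surviving primaryid
    tto_days: Dict[str, int]  # caseid -> raw onset delay (full precision only)
    serious: Dict[str, bool]  # caseid -> seriousness
    drug_caseids: List[str]
    pt_to_soc: Dict[str, str]


_HEADERS = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod",
        "wt", "wt_cod", "occr_country", "occp_cod",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}


def _quarter_bounds(qi: int) -> Tuple[_dt.date, _dt.date]:
    year = START_YEAR + qi // 4
    month = 3 * (qi % 4) + 1
    start = _dt.date(year, month, 1)
    if month == 10:
        end = _dt.date(year + 1, 1, 1)
    else:
        end = _dt.date(year, month + 3, 1)
    return start, end - _dt.timedelta(days=1)


def _fmt(d: _dt.date) -> str:
    return d.strftime("%Y%m%d")


def _quarter_of(d: _dt.date, n_quarters: int) -> int:
    qi = (d.year - START_YEAR) * 4 + (d.month - 1) // 3
    return min(max(qi, 0), n_quarters - 1)


class _Tables:
    def __init__(self, n_quarters: int) -> None:
        self.rows: Dict[str, Dict[int, List[List[str]]]] = {
            t: {q: [] for q in range(n_quarters)} for t in _HEADERS
        }

    def add(self, table: str, quarter: int, row: List[str]) -> None:
        self.rows[table][quarter].append(row)


def generate(
    config: SyntheticConfig, out_dir: str | Path
) -> Tuple[List[Path], GroundTruth]:
    """Emit a synthetic FAERS quarterly file set; returns (paths, truth).

    One file per table per quarter is written (empty quarters are
    skipped); duplicate case versions land in the quarter of their own
    ``fda_dt``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    p_drug, q_bg = config.event_probabilities()
    pt_names = [pt for pt, _, _ in config.pt_catalog]
    drug_p = np.array([p_drug[pt] for pt in pt_names])
    bg_p = np.array([q_bg[pt] for pt in pt_names])

    tables = _Tables(config.n_quarters)
    truth = GroundTruth(
        expected_ror=config.expected_ror(),
        true_primaryids={},
        tto_days={},
        serious={},
        drug_caseids=[],
        pt_to_soc={pt: soc for pt, soc, _ in config.pt_catalog},
    )

    n_total = config.n_drug_cases + config.n_background_cases
    for i in range(n_total):
        is_drug = i < config.n_drug_cases
        caseid = str(100000 + i)
        n_versions = 1
        if rng.random() < config.duplicate_rate:
            n_versions = 1 + int(rng.integers(1, 3))
        primaryid = f"{caseid}{n_versions}"
        truth.true_primaryids[caseid] = primaryid
        if is_drug:
            truth.drug_caseids.append(caseid)

        qi = int(rng.integers(0, config.n_quarters))
        q_start, q_end = _quarter_bounds(qi)
        fda = q_start + _dt.timedelta(
            days=int(rng.integers(0, (q_end - q_start).days + 1))
        )

        # --- adverse events -------------------------------------------------
        probs = drug_p if is_drug else bg_p
        k = 1 + int(rng.poisson(config.extra_pts_rate))
        k = min(k, len(pt_names))
        idx = rng.choice(len(pt_names), size=k, replace=False, p=probs)
        case_pts = [pt_names[j] for j in idx]

        # --- seriousness ----------------------------------------------------
        serious = bool(rng.random() < config.serious_prob)
        truth.serious[caseid] = serious
        outc_codes: List[str] = []
        if serious:
            if rng.random() < config.death_prob_given_serious:
                outc_codes.append("DE")
            outc_codes.append(str(rng.choice(["HO", "OT", "LT", "DS"], p=[0.45, 0.35, 0.15, 0.05])))

        # --- demographics ---------------------------------------------------
        sex = ""
        if rng.random() >= config.sex_missing:
            sex = "F" if rng.random() < config.female_prob else "M"
        age, age_cod = "", ""
        if rng.random() >= config.age_missing:
            years = max(0.5, rng.normal(config.age_mean, config.age_sd))
            if years < 3 and rng.random() < 0.5:
                age, age_cod = f"{round(years * 12):d}", "MON"
            else:
                age, age_cod = f"{years:.0f}", "YR"
        wt, wt_cod = "", ""
        if rng.random() >= config.weight_missing:
            kg = float(np.clip(rng.normal(config.weight_mean, config.weight_sd), 3, 200))
            if rng.random() < 0.05:
                wt, wt_cod = f"{kg / 0.4536:.1f}", "LBS"
            else:
                wt, wt_cod = f"{kg:.1f}", "KG"
        country = str(rng.choice(COUNTRIES, p=COUNTRY_P))
        occp = ""
        if rng.random() > 0.01:
            occp = (
                str(rng.choice(["MD", "PH", "HP", "OT"]))
                if rng.random() < config.professional_prob
                else str(rng.choice(["CN", "LW"]))
            )

        # --- onset dates ----------------------------------------------------
        event_dt_str = ""
        start_dt: Optional[_dt.date] = None
        if is_drug and rng.random() < config.tto_available_rate:
            group = "default"
            for pt in case_pts:
                if pt in config.pt_group:
                    group = config.pt_group[pt]
                    break
            alpha, beta = config.tto_spec[group]
            delay = int(round(alpha * rng.weibull(beta)))
            start_dt = fda - _dt.timedelta(days=delay + int(rng.integers(5, 60)))
            event = start_dt + _dt.timedelta(days=delay)
            if rng.random() < config.partial_date_fraction:
                event_dt_str = event.strftime("%Y%m")  # month precision
            else:
                event_dt_str = _fmt(event)
                truth.tto_days[caseid] = delay

        # --- emit all versions ---------------------------------------------
        version_dates = [fda]
        for v in range(n_versions - 1, 0, -1):
            version_dates.insert(
                0, fda - _dt.timedelta(days=int(rng.integers(30, 400)) * (n_versions - v))
            )
        for version, vdate in enumerate(version_dates, start=1):
            pid = f"{caseid}{version}"
            vq = _quarter_of(vdate, config.n_quarters)
            tables.add(
                "DEMO",
                vq,
                [pid, caseid, _fmt(vdate), event_dt_str, sex, age, age_cod,
                 wt, wt_cod, country, occp],
            )
            if is_drug:
                tables.add(
                    "DRUG", vq,
                    [pid, caseid, "1", "PS", config.drugname, config.prod_ai],
                )
                if rng.random() < 0.3:
                    other = str(rng.choice(BACKGROUND_DRUGS))
                    tables.add("DRUG", vq, [pid, caseid, "2", "C", other, other])
                if start_dt is not None:
                    tables.add("THER", vq, [pid, caseid, "1", _fmt(start_dt), ""])
                indi = "Epilepsy" if rng.random() < 0.73 else "Migraine"
                tables.add("INDI", vq, [pid, caseid, "1", indi])
            else:
                other = str(rng.choice(BACKGROUND_DRUGS))
                tables.add("DRUG", vq, [pid, caseid, "1", "PS", other, other])
            for pt in case_pts:
                tables.add("REAC", vq, [pid, caseid, pt])
            for code in outc_codes:
                tables.add("OUTC", vq, [pid, caseid, code])

    paths = _write_tables(tables, out_dir)
    return paths, truth


def _write_tables(tables: _Tables, out_dir: Path) -> List[Path]:
    paths: List[Path] = []
    for table, by_quarter in tables.rows.items():
        for qi, rows in by_quarter.items():
            if not rows:
                continue
            year = START_YEAR + qi // 4
            name = f"{table}{year % 100:02d}Q{qi % 4 + 1}.txt"
            path = out_dir / name
            with path.open("w", newline="\n", encoding="utf-8") as fh:
                fh.write("$".join(_HEADERS[table]) + "\n")
                for row in rows:
                    fh.write("$".join(row) + "\n")
            paths.append(path)
    return sorted(paths)


def write_pt_to_soc(
    path: str | Path, catalog: Optional[Sequence[Tuple[str, str, float]]] = None
) -> Path:
    """Write the catalogue's PT→SOC map as a two-column CSV."""
    catalog = catalog if catalog is not None else DEFAULT_PT_CATALOG
    path = Path(path)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("pt,soc_code\n")
        for pt, soc, _ in catalog:
            fh.write(f"{pt},{soc}\n")
    return path


def make_fixture_small(
    out_dir: str | Path, seed: int = 0
) -> Tuple[List[Path], GroundTruth]:
    """Deterministic miniature dataset (~200 cases) with every edge case.

    Beyond the stochastic content (duplicates, partial dates), four
    hand-built cases are appended to the last populated quarter:

    * ``900001`` — zero-day onset (event date equals therapy start);
    * ``900002`` — date error (event before therapy start), which the
      exclusion filter must drop;
    * ``900003`` — an excluded administrative PT next to a cardiac PT;
    * ``900004`` — a PT deliberately absent from the PT→SOC map.

    A ``pt_to_soc.csv`` covering the catalogue (but not the unmapped
    PT) is written alongside the quarterly files.
    """
    out_dir = Path(out_dir)
    config = SyntheticConfig(
        n_background_cases=160,
        n_drug_cases=40,
        duplicate_rate=0.3,
        tto_available_rate=0.6,
        n_quarters=4,
        seed=seed,
    )
    paths, truth = generate(config, out_dir)

    demo_path = sorted(out_dir.glob("DEMO*.txt"))[-1]
    suffix = demo_path.name[4:]  # e.g. "13Q4.txt"

    def _append(table: str, row: List[str]) -> None:
        path = out_dir / f"{table}{suffix}"
        if not path.exists():
            with path.open("w", newline="\n", encoding="utf-8") as fh:
                fh.write("$".join(_HEADERS[table]) + "\n")
        with path.open("a", newline="\n", encoding="utf-8") as fh:
            fh.write("$".join(row) + "\n")

    extras = [
        # caseid, event_dt, start_dt, pts
        ("900001", "20130901", "20130901", ["Bradycardia"]),
        ("900002", "20130810", "20130901", ["Cardiac arrest"]),
        ("900003", "20130910", "20130901", ["Off label use", "Atrial fibrillation"]),
        ("900004", "20130915", "20130901", ["Mystery reaction"]),
    ]
    for caseid, event, start, pts in extras:
        pid = f"{caseid}1"
        _append(
            "DEMO",
            [pid, caseid, "20131101", event, "F", "40", "YR", "", "", "US", "MD"],
        )
        _append("DRUG", [pid, caseid, "1", "PS", config.drugname, config.prod_ai])
        _append("THER", [pid, caseid, "1", start, ""])
        for pt in pts:
            _append("REAC", [pid, caseid, pt])
        _append("OUTC", [pid, caseid, "HO"])
        truth.true_primaryids[caseid] = pid
        truth.serious[caseid] = True
        if caseid != "900002":
            truth.drug_caseids.append(caseid)
    truth.tto_days["900001"] = 0

    write_pt_to_soc(out_dir / "pt_to_soc.csv", config.pt_catalog)
    return sorted(out_dir.glob("*.txt")), truth
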