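"""Readers for FAERS Quarterly Data Extract ASCII tables and case assembly.

The FDA Adverse Event Reporting System ships each quarter as seven
"$"-delimited ASCII tables (DEMO, DRUG, REAC, OUTC, THER, INDI, RPSR)
sharing the report key ``primaryid``.  This module parses those tables
into typed records, joins them into case-level :class:`CaseReport`
objects, and exports a flat per-(case, PT) CSV.

Readers map columns by header name, case-insensitively, and tolerate the
extra or reordered columns that appear across 2013–2022 quarters.
Malformed rows are skipped with a warning rather than aborting a whole
quarter.  Values are kept verbatim (no unit conversion); downstream
cohort building owns all transformations.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from ._dates import PartialDate, parse_faers_date

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: FAERS drug role codes: primary suspect, secondary suspect,
#: concomitant, interacting.
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: FAERS serious-outcome codes (OUTC table).
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: Reporter occupation → reporter class.  FAERS does not publish the
#: two-way professional/consumer split, so the grouping is configurable
#: in spirit but fixed here to the conventional reading of occp_cod.
PROFESSIONAL_OCCP = frozenset({"MD", "PH", "HP", "OT"})
CONSUMER_OCCP = frozenset({"CN", "LW"})


class TableKind(enum.Enum):
    DEMO = "demo"
    DRUG = "drug"
    REAC = "reac"
    OUTC = "outc"
    THER = "ther"
    INDI = "indi"
    RPSR = "rpsr"


@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: Optional[PartialDate]
    event_dt: Optional[PartialDate] = None
    sex: str = ""
    age: Optional[float] = None
    age_cod: str = ""
    wt: Optional[float] = None
    wt_cod: str = ""
    occr_country: str = ""
    occp_cod: str = ""


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    drug_seq: int
    role_cod: str
    drugname: str = ""
    prod_ai: str = ""


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    pt: str


@dataclass(frozen=True)
class OutcRecord:
    primaryid: str
    outc_cod: str


@dataclass(frozen=True)
class TherRecord:
    primaryid: str
    dsg_drug_seq: int
    start_dt: Optional[PartialDate] = None
    end_dt: Optional[PartialDate] = None


@dataclass(frozen=True)
class IndiRecord:
    primaryid: str
    indi_drug_seq: int
    indi_pt: str = ""


@dataclass(frozen=True)
class RpsrRecord:
    primaryid: str
    rpsr_cod: str = ""


@dataclass
class CaseReport:
    """One safety report: a DEMO row plus its child records.

    ``serious`` is derived: a report is serious iff it carries at least
    one OUTC row.  ``reporter_class`` groups occp_cod into the
    professional / consumer / unknown trichotomy used for stratified
    screening.
    """

    demo: DemoRecord
    drugs: List[DrugRecord] = field(default_factory=list)
    reactions: List[ReacRecord] = field(default_factory=list)
    outcomes: List[OutcRecord] = field(default_factory=list)
    therapies: List[TherRecord] = field(default_factory=list)
    indications: List[IndiRecord] = field(default_factory=list)

    @property
    def primaryid(self) -> str:
        return self.demo.primaryid

    @property
    def caseid(self) -> str:
        return self.demo.caseid

    @property
    def serious(self) -> bool:
        return len(self.outcomes) > 0

    @property
    def outcome_codes(self) -> frozenset:
        return frozenset(o.outc_cod for o in self.outcomes)

    @property
    def pts(self) -> List[str]:
        return [r.pt for r in self.reactions]

    @property
    def reporter_class(self) -> str:
        code = self.demo.occp_cod.strip().upper()
        if code in PROFESSIONAL_OCCP:
            return "professional"
        if code in CONSUMER_OCCP:
            return "consumer"
        return "unknown"


def _norm(value: Optional[str]) -> str:
    return (value or "").strip()


def _opt_float(value: Optional[str]) -> Optional[float]:
    s = _norm(value)
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"not a number: {s!r}")


def _opt_int(value: Optional[str]) -> Optional[int]:
    s = _norm(value)
    if not s:
        return None
    return int(float(s))


def _build_demo(row: Mapping[str, str]) -> DemoRecord:
    age = _opt_float(row.get("age"))
    wt = _opt_float(row.get("wt"))
    if age is not None and age < 0:
        raise ValueError("negative age")
    if wt is not None and wt < 0:
        raise ValueError("negative weight")
    return DemoRecord(
        primaryid=_norm(row.get("primaryid")),
        caseid=_norm(row.get("caseid")),
        fda_dt=parse_faers_date(row.get("fda_dt")),
        event_dt=parse_faers_date(row.get("event_dt")),
        sex=_norm(row.get("sex") or row.get("gndr_cod")).upper(),
        age=age,
        age_cod=_norm(row.get("age_cod")).upper(),
        wt=wt,
        wt_cod=_norm(row.get("wt_cod")).upper(),
        occr_country=_norm(row.get("occr_country")).upper(),
        occp_cod=_norm(row.get("occp_cod")).upper(),
    )


def _build_drug(row: Mapping[str, str]) -> DrugRecord:
    role = _norm(row.get("role_cod")).upper()
    if role and role not in ROLE_CODES:
        raise ValueError(f"unknown role_cod {role!r}")
    seq = _opt_int(row.get("drug_seq"))
    return DrugRecord(
        primaryid=_norm(row.get("primaryid")),
        drug_seq=seq if seq is not None else 0,
        role_cod=role,
        drugname=_norm(row.get("drugname")),
        prod_ai=_norm(row.get("prod_ai")),
    )


def _build_reac(row: Mapping[str, str]) -> ReacRecord:
    pt = " ".join(_norm(row.get("pt")).split())
    if not pt:
        raise ValueError("empty PT")
    return ReacRecord(primaryid=_norm(row.get("primaryid")), pt=pt)


def _build_outc(row: Mapping[str, str]) -> OutcRecord:
    code = _norm(row.get("outc_cod") or row.get("outc_code")).upper()
    if code not in OUTCOME_CODES:
        raise ValueError(f"unknown outc_cod {code!r}")
    return OutcRecord(primaryid=_norm(row.get("primaryid")), outc_cod=code)


def _build_ther(row: Mapping[str, str]) -> TherRecord:
    seq = _opt_int(row.get("dsg_drug_seq"))
    return TherRecord(
        primaryid=_norm(row.get("primaryid")),
        dsg_drug_seq=seq if seq is not None else 0,
        start_dt=parse_faers_date(row.get("start_dt")),
        end_dt=parse_faers_date(row.get("end_dt")),
    )


def _build_indi(row: Mapping[str, str]) -> IndiRecord:
    seq = _opt_int(row.get("indi_drug_seq"))
    return IndiRecord(
        primaryid=_norm(row.get("primaryid")),
        indi_drug_seq=seq if seq is not None else 0,
        indi_pt=" ".join(_norm(row.get("indi_pt")).split()),
    )


def _build_rpsr(row: Mapping[str, str]) -> RpsrRecord:
    return RpsrRecord(
        primaryid=_norm(row.get("primaryid")),
        rpsr_cod=_norm(row.get("rpsr_cod")).upper(),
    )


_BUILDERS = {
    TableKind.DEMO: _build_demo,
    TableKind.DRUG: _build_drug,
    TableKind.REAC: _build_reac,
    TableKind.OUTC: _build_outc,
    TableKind.THER: _build_ther,
    TableKind.INDI: _build_indi,
    TableKind.RPSR: _build_rpsr,
}


def read_table(path: str | Path, kind: TableKind) -> Tuple[list, int]:
    """Read one FAERS ASCII table.

    Parameters
    ----------
    path
        "$"-delimited file whose first line is the header.
    kind
        Which of the seven tables the file contains.

    Returns
    -------
    (records, n_skipped)
        Typed records, one per parseable data line, and the number of
        malformed lines that were skipped (each logged as a warning).

    Raises
    ------
    FileNotFoundError
        When the file does not exist.
    ValueError
        When the header lacks a ``primaryid`` column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    builder = _BUILDERS[kind]
    records: list = []
    n_skipped = 0
    with path.open(newline="", encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file")
        header = [h.strip().lower() for h in header_line.rstrip("\r\n").split(DELIMITER)]
        if "primaryid" not in header:
            raise ValueError(f"{path}: header lacks 'primaryid' column")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            values = line.split(DELIMITER)
            row = dict(zip(header, values))
            try:
                rec = builder(row)
                if not rec.primaryid:
                    raise ValueError("empty primaryid")
            except (ValueError, TypeError) as exc:
                n_skipped += 1
                logger.warning("%s line %d skipped: %s", path.name, lineno, exc)
                continue
            records.append(rec)
    return records, n_skipped


def read_quarter_dir(directory: str | Path) -> Dict[TableKind, list]:
    """Read every recognised FAERS table file under *directory*.

    Files are matched on name prefix (DEMO*, DRUG*, ...), case-
    insensitively, so one directory may hold several quarters.
    """
    directory = Path(directory)
    tables: Dict[TableKind, list] = {k: [] for k in TableKind}
    found = False
    for path in sorted(directory.glob("*.txt")):
        name = path.name.upper()
        for kind in TableKind:
            if name.startswith(kind.name):
                recs, _ = read_table(path, kind)
                tables[kind].extend(recs)
                found = True
                break
    if not found:
        raise FileNotFoundError(f"no FAERS tables (*.txt) found under {directory}")
    return tables


def assemble_cases(tables: Mapping[TableKind, Sequence]) -> List[CaseReport]:
    """Join per-table records into one :class:`CaseReport` per DEMO row.

    Child records attach by ``primaryid`` equality.  Children whose
    primaryid has no DEMO row are orphans: counted, logged, dropped.
    The result is sorted by (caseid, primaryid) so that assembly is
    independent of input row order.
    """
    demos = tables.get(TableKind.DEMO) or []
    cases: Dict[str, CaseReport] = {}
    for demo in demos:
        cases[demo.primaryid] = CaseReport(demo=demo)
    orphans = 0
    attach = [
        (TableKind.DRUG, "drugs"),
        (TableKind.REAC, "reactions"),
        (TableKind.OUTC, "outcomes"),
        (TableKind.THER, "therapies"),
        (TableKind.INDI, "indications"),
    ]
    for kind, attr in attach:
        for rec in tables.get(kind) or []:
            case = cases.get(rec.primaryid)
            if case is None:
                orphans += 1
                continue
            getattr(case, attr).append(rec)
    if orphans:
        logger.warning("assemble_cases: dropped %d orphan child records", orphans)
    return sorted(cases.values(), key=lambda c: (c.caseid, c.primaryid))


#: Columns of the flat cohort export, one row per (case, PT).
COHORT_COLUMNS = [
    "caseid",
    "primaryid",
    "pt",
    "serious",
    "outcome_codes",
    "sex",
    "age",
    "age_cod",
    "wt",
    "wt_cod",
    "occr_country",
    "reporter_class",
    "fda_dt",
    "event_dt",
]


def write_cohort(cases: Iterable[CaseReport], path: str | Path) -> int:
    """Write a flat per-(case, PT) CSV export; returns rows written.

    Dates are ISO-8601 at their native precision; a case with no PTs
    still contributes one row with an empty ``pt`` so no case silently
    disappears from the export.
    """
    path = Path(path)
    n = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for case in cases:
            d = case.demo
            base = [
                case.caseid,
                case.primaryid,
                None,  # pt placeholder
                "1" if case.serious else "0",
                ";".join(sorted(case.outcome_codes)),
                d.sex,
                "" if d.age is None else repr(d.age),
                d.age_cod,
                "" if d.wt is None else repr(d.wt),
                d.wt_cod,
                d.occr_country,
                case.reporter_class,
                d.fda_dt.isoformat() if d.fda_dt else "",
                d.event_dt.isoformat() if d.event_dt else "",
            ]
            for pt in case.pts or [""]:
                row = list(base)
                row[2] = pt
                writer.writerow(row)
                n += 1
    return n
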