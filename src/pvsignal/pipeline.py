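"""End-to-end orchestration: ingest → dedup → cohort → screen → severity
→ prioritize → tto, with a JSON manifest of counts at every filter step.

The pipeline is a deterministic function of its inputs: the manifest
embeds a hash of the configuration so any output bundle can be
regenerated exactly, and per-stage record counts let the selection
funnel (reports read → deduplicated → suspect-drug → post-exclusion →
target-SOC) be audited at a glance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    apply_exclusions,
    deduplicate,
    load_cohort_config,
    mentions_drug,
    restrict_to_soc,
    select_drug_cases,
    soc_pts,
    summarize_cohort,
)
from .disproportionality import (
    StratumSpec,
    pt_tally,
    screen_soc,
    signals_frame,
    stratified_screen,
)
from .faers import assemble_cases, read_quarter_dir
from .prioritize import (
    DATA_DIR,
    load_pt_list,
    load_rubric,
    prioritize_screen,
)
from .severity import build_severity_table
from .tto import compute_tto, summarize_tto_group

logger = logging.getLogger(__name__)

ALL_STAGES = ["ingest", "dedup", "cohort", "screen", "severity", "prioritize", "tto"]

STANDARD_STRATA = [
    StratumSpec("sex", "F"),
    StratumSpec("sex", "M"),
    StratumSpec("age_band", "<18"),
    StratumSpec("age_band", "18-64"),
    StratumSpec("age_band", ">64"),
    StratumSpec("weight_band", "<80"),
    StratumSpec("weight_band", "80-100"),
    StratumSpec("weight_band", ">100"),
    StratumSpec("reporter_class", "professional"),
    StratumSpec("reporter_class", "consumer"),
]


@dataclass
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    cohort: CohortConfig
    rubric_path: Optional[Path] = None
    ime_path: Path = DATA_DIR / "ime_list.txt"
    dme_path: Path = DATA_DIR / "dme_list.txt"
    label_path: Path = DATA_DIR / "label_pts.txt"
    evidence: Dict[str, str] = field(default_factory=dict)
    min_events: int = 5
    zero_handling: str = "shift"
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))


def validate_config(path: str | Path) -> Tuple[Optional[PipelineConfig], List[str]]:
    """Parse and cross-check a pipeline YAML; returns (config, errors).

    On any error the config is None and every detected problem is
    listed, so a user can fix them in one pass.
    """
    errors: List[str] = []
    path = Path(path)
    if not path.exists():
        return None, [f"config file not found: {path}"]
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        return None, [f"invalid YAML: {exc}"]
    base = path.parent

    def resolve(key: str, default: Optional[Path] = None) -> Optional[Path]:
        value = raw.get(key)
        if value is None:
            return default
        p = Path(value)
        return p if p.is_absolute() else base / p

    input_dir = resolve("input_dir")
    if input_dir is None:
        errors.append("missing key: input_dir")
    elif not input_dir.exists():
        errors.append(f"input_dir does not exist: {input_dir}")
    output_dir = resolve("output_dir")
    if output_dir is None:
        errors.append("missing key: output_dir")

    cohort_cfg: Optional[CohortConfig] = None
    cohort_path = resolve("cohort_config")
    if cohort_path is None:
        errors.append("missing key: cohort_config (path to cohort YAML)")
    elif not cohort_path.exists():
        errors.append(f"cohort_config does not exist: {cohort_path}")
    else:
        try:
            cohort_cfg = load_cohort_config(cohort_path)
        except (KeyError, ValueError, OSError) as exc:
            errors.append(f"cohort_config invalid: {exc}")

    rubric_path = resolve("rubric")
    try:
        load_rubric(rubric_path)
    except (KeyError, ValueError, OSError) as exc:
        errors.append(f"rubric invalid: {exc}")

    for key, default in (
        ("ime_list", DATA_DIR / "ime_list.txt"),
        ("dme_list", DATA_DIR / "dme_list.txt"),
        ("label_pts", DATA_DIR / "label_pts.txt"),
    ):
        p = resolve(key, default)
        if not p.exists():
            errors.append(f"{key} does not exist: {p}")

    stages = raw.get("stages", list(ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        errors.append(f"unknown stages: {unknown} (choose from {ALL_STAGES})")

    evidence = raw.get("evidence", {})
    if not isinstance(evidence, Mapping):
        errors.append("evidence must be a mapping pt -> '+'/'++'")
        evidence = {}

    if errors:
        return None, errors
    return (
        PipelineConfig(
            input_dir=input_dir,
            output_dir=output_dir,
            cohort=cohort_cfg,
            rubric_path=rubric_path,
            ime_path=resolve("ime_list", DATA_DIR / "ime_list.txt"),
            dme_path=resolve("dme_list", DATA_DIR / "dme_list.txt"),
            label_path=resolve("label_pts", DATA_DIR / "label_pts.txt"),
            evidence=dict(evidence),
            min_events=int(raw.get("min_events", 5)),
            zero_handling=raw.get("zero_handling", "shift"),
            stages=list(stages),
        ),
        [],
    )


def _summary_frame(summary) -> pd.DataFrame:
    rows = []

    def add(section: str, level: str, count, available) -> None:
        pct = 100.0 * count / available if available else float("nan")
        rows.append(
            {"section": section, "level": level, "count": count,
             "available": available, "percent": pct}
        )

    for sex, n in sorted(summary.sex_counts.items()):
        add("sex", sex, n, summary.sex_available)
    for band_label in ("<18", "18-64", ">64"):
        add("age_band", band_label, summary.age_bands.get(band_label, 0), summary.age_available)
    for band_label in ("<80", "80-100", ">100"):
        add("weight_band", band_label, summary.weight_bands.get(band_label, 0), summary.weight_available)
    for country, n in sorted(summary.country_counts.items(), key=lambda kv: -kv[1]):
        add("country", country, n, summary.n_cases)
    add("outcome", "serious", summary.n_serious, summary.n_cases)
    add("outcome", "nonserious", summary.n_nonserious, summary.n_cases)
    for code, n in sorted(summary.outcome_counts.items()):
        add("outcome_code", code, n, summary.n_serious)
    for rc, n in sorted(summary.reporter_counts.items()):
        add("reporter", rc, n, summary.reporter_available)
    for year, n in sorted(summary.year_counts.items()):
        add("year", str(year), n, summary.n_cases)
    for label, stats_tuple, avail in (
        ("age_years", summary.age_median_iqr, summary.age_available),
        ("weight_kg", summary.weight_median_iqr, summary.weight_available),
        ("tto_days", summary.tto_median_iqr, summary.tto_available),
    ):
        if stats_tuple is not None:
            med, q1, q3 = stats_tuple
            rows.append(
                {"section": "median_iqr", "level": label, "count": med,
                 "available": avail, "percent": float("nan"),
                 "q1": q1, "q3": q3}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run the configured stages and write the output bundle.

    Always computes the prerequisite stages in memory; writes only the
    CSVs of the stages listed in ``config.stages``.  Returns the run
    manifest (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "pvsignal_version": __version__,
        "stages": list(config.stages),
        "counts": {},
        "outputs": [],
        "failed_stage": None,
    }
    cfg_text = json.dumps(
        {"input_dir": str(config.input_dir), "min_events": config.min_events,
         "zero_handling": config.zero_handling,
         "generic_names": config.cohort.generic_names,
         "trade_names": config.cohort.trade_names,
         "required_role": config.cohort.required_role,
         "target_soc_code": config.cohort.target_soc_code},
        sort_keys=True,
    )
    manifest["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()
    counts = manifest["counts"]

    def emit(name: str, df: pd.DataFrame, stage: str) -> None:
        if stage in config.stages:
            df.to_csv(out / name, index=False)
            manifest["outputs"].append(name)

    try:
        # ingest -----------------------------------------------------------
        stage = "ingest"
        tables = read_quarter_dir(config.input_dir)
        cases = assemble_cases(tables)
        counts["reports_read"] = len(cases)

        # dedup ------------------------------------------------------------
        stage = "dedup"
        cases = deduplicate(cases)
        counts["cases_after_dedup"] = len(cases)

        # cohort -----------------------------------------------------------
        stage = "cohort"
        drug_cases = select_drug_cases(cases, config.cohort)
        counts["suspect_drug_cases"] = len(drug_cases)
        background = [c for c in cases if not mentions_drug(c, config.cohort)]
        counts["background_cases"] = len(background)
        drug_cases = apply_exclusions(drug_cases, config.cohort)
        counts["drug_cases_after_exclusions"] = len(drug_cases)
        soc_cases, soc_events = restrict_to_soc(drug_cases, config.cohort)
        counts["target_soc_cases"] = len(soc_cases)
        counts["target_soc_pt_events"] = soc_events
        summary = summarize_cohort(soc_cases, config.cohort)
        emit("cohort_summary.csv", _summary_frame(summary), "cohort")

        # screen -----------------------------------------------------------
        stage = "screen"
        drug_events = pt_tally(drug_cases)
        background_events = pt_tally(background)
        estimates, soc_est = screen_soc(
            drug_events,
            background_events,
            config.cohort.pt_to_soc,
            config.cohort.target_soc_code,
            config.min_events,
        )
        sig_df = signals_frame(estimates)
        counts["pts_screened"] = len(estimates)
        counts["significant_signals"] = int(sig_df["significant"].sum()) if len(sig_df) else 0
        if soc_est is not None:
            sig_df = pd.concat(
                [sig_df, signals_frame([soc_est])], ignore_index=True
            )
        emit("signals.csv", sig_df, "screen")
        strat = stratified_screen(
            soc_cases, background, STANDARD_STRATA, config.cohort, config.min_events
        )
        strat_rows = []
        for s in strat:
            row = {"variable": s.stratum.variable, "level": s.stratum.level,
                   "n": s.n, "nl": s.nl, "error": s.error or ""}
            if s.estimate is not None:
                row.update(ror=s.estimate.ror, ci_low=s.estimate.ci_low,
                           ci_high=s.estimate.ci_high,
                           significant=s.estimate.significant)
            strat_rows.append(row)
        emit("stratified.csv", pd.DataFrame(strat_rows), "screen")

        # severity ---------------------------------------------------------
        stage = "severity"
        sev_df = build_severity_table(soc_cases)
        emit("severity.csv", sev_df, "severity")

        # prioritize -------------------------------------------------------
        stage = "prioritize"
        rubric = load_rubric(config.rubric_path)
        significant = [e for e in estimates if e.significant]
        prio_df = prioritize_screen(
            significant,
            soc_cases,
            rubric,
            load_pt_list(config.ime_path),
            load_pt_list(config.dme_path),
            load_pt_list(config.label_path),
            config.evidence,
        )
        counts["prioritized_signals"] = len(prio_df)
        emit("priorities.csv", prio_df, "prioritize")

        # tto --------------------------------------------------------------
        stage = "tto"
        level_of = (
            dict(zip(prio_df["pt"].str.lower(), prio_df["level"]))
            if len(prio_df)
            else {}
        )
        tto_rows = []
        for level in ("moderate", "weak", "strong"):
            pts = {pt for pt, lvl in level_of.items() if lvl == level}
            if not pts:
                continue
            member_cases = [
                c
                for c in soc_cases
                if any(pt.lower() in pts for pt in soc_pts(c, config.cohort))
            ]
            values = compute_tto(member_cases, config.cohort).values
            tto_rows.append(
                summarize_tto_group(
                    level, len(pts), values, zero_handling=config.zero_handling
                )
            )
        all_values = compute_tto(soc_cases, config.cohort).values
        counts["tto_available_cases"] = len(all_values)
        tto_rows.append(
            summarize_tto_group(
                "all_target_soc",
                len({pt for c in soc_cases for pt in soc_pts(c, config.cohort)}),
                all_values,
                zero_handling=config.zero_handling,
            )
        )
        emit("tto.csv", pd.DataFrame(tto_rows), "tto")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", json.dumps(counts))
    return manifest
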