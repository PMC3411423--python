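"""Respondent records, cohorts, tabular I/O and descriptive summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank, GoalDefinition, NOT_SURE, MULTIPLE_CHOICE, default_item_bank, default_goal_bank

log = logging.getLogger(__name__)

GROUPS = ("patient", "provider", "control")
WAVES = ("test", "retest")
TREATMENTS = ("mastectomy", "lumpectomy", "lumpectomy_then_mastectomy", "none")
STAGES = ("I", "II", "none")
PREFERENCES = ("mastectomy", "lumpectomy_radiation", "not_sure", "none")
REGRET_LEVELS = ("definitely_yes", "probably_yes", "not_sure", "probably_no", "definitely_no")
EDUCATION_LEVELS = ("hs_or_less", "some_college", "college_plus")


@dataclass
class RespondentRecord:
    """One respondent-wave of instrument data.

    Providers and controls complete only the knowledge section; treatment,
    goals and the decision-appraisal items apply to patients.
    """

    respondent_id: str
    group: str
    wave: str = "test"
    item_responses: dict = field(default_factory=dict)  # key -> int | float | NOT_SURE
    goal_ratings: dict = field(default_factory=dict)    # goal_id -> int 0..10
    treatment: str = "none"
    stage: str = "none"
    preference: str = "none"
    confidence: Optional[float] = None
    regret: Optional[str] = None
    top3_goals: tuple = ()
    completion_minutes: Optional[float] = None
    education: Optional[str] = None
    demographics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.wave not in WAVES:
            raise ValueError(f"unknown wave {self.wave!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if len(set(self.top3_goals)) > 3:
            raise ValueError("top3_goals must contain at most 3 distinct goals")


@dataclass
class Cohort:
    """A set of respondent records plus the banks they are scored against."""

    records: list
    item_bank: ItemBank
    goal_bank: list
    provenance: dict = field(default_factory=dict)
    latents: dict = field(default_factory=dict)  # respondent_id -> generator latent state

    def __post_init__(self):
        seen = set()
        for r in self.records:
            key = (r.respondent_id, r.wave)
            if key in seen:
                raise ValueError(f"duplicate respondent_id {r.respondent_id!r} within wave {r.wave!r}")
            seen.add(key)
        goal_ids = {g.goal_id for g in self.goal_bank}
        keys = set(self.item_bank.response_keys)
        for r in self.records:
            bad = set(r.item_responses) - keys
            if bad:
                raise ValueError(f"{r.respondent_id}: unknown item response keys {sorted(bad)}")
            bad = set(r.goal_ratings) - goal_ids
            if bad:
                raise ValueError(f"{r.respondent_id}: unknown goal ids {sorted(bad)}")

    def subset(self, group: str = None, wave: str = None) -> list:
        recs = self.records
        if group is not None:
            recs = [r for r in recs if r.group == group]
        if wave is not None:
            recs = [r for r in recs if r.wave == wave]
        return recs

    def patients(self, wave: str = "test") -> list:
        return self.subset("patient", wave)

    def providers(self) -> list:
        return self.subset("provider", "test")

    def controls(self) -> list:
        return self.subset("control", "test")

    @property
    def goal_ids(self) -> list:
        return [g.goal_id for g in self.goal_bank]


# ---------------------------------------------------------------------------
# Tabular I/O

REQUIRED_COLUMNS = ("respondent_id", "group", "wave", "treatment")
SCALAR_COLUMNS = ("respondent_id", "group", "wave", "treatment", "stage", "preference",
                  "confidence", "regret", "top3_goals", "completion_minutes", "education")


def _is_missing(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    s = str(cell).strip()
    return s == "" or s.upper() == "NA" or s == "nan"


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to one row per respondent-wave."""
    item_keys = cohort.item_bank.response_keys
    goal_ids = cohort.goal_ids
    demo_keys = sorted({k for r in cohort.records for k in r.demographics})
    rows = []
    for r in cohort.records:
        row = {
            "respondent_id": r.respondent_id, "group": r.group, "wave": r.wave,
            "treatment": r.treatment, "stage": r.stage, "preference": r.preference,
            "confidence": r.confidence, "regret": r.regret,
            "top3_goals": ";".join(r.top3_goals),
            "completion_minutes": r.completion_minutes, "education": r.education,
        }
        for key in item_keys:
            row[f"item_{key}"] = r.item_responses.get(key)
        for gid in goal_ids:
            row[f"goal_{gid}"] = r.goal_ratings.get(gid)
        for k in demo_keys:
            row[f"demo_{k}"] = r.demographics.get(k)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    cohort_to_frame(cohort).to_csv(path, sep=sep, index=False)


def _parse_item_cell(cell, part, warnings: list, where: str):
    if _is_missing(cell):
        return None
    s = str(cell).strip()
    if s == NOT_SURE:
        return NOT_SURE
    try:
        if part.kind == MULTIPLE_CHOICE:
            idx = int(float(s))
            if not 0 <= idx < part.n_options:
                warnings.append(f"{where}: option index {idx} outside 0..{part.n_options - 1}")
                return None
            return idx
        return float(s)
    except ValueError:
        warnings.append(f"{where}: unparseable response {cell!r}")
        return None


def _parse_goal_cell(cell, warnings: list, where: str):
    if _is_missing(cell):
        return None
    try:
        v = float(str(cell).strip())
    except ValueError:
        warnings.append(f"{where}: unparseable rating {cell!r}")
        return None
    if not (v == int(v) and 0 <= v <= 10):
        warnings.append(f"{where}: rating {cell!r} outside the 0-10 scale")
        return None
    return int(v)


def _parse_float(cell, warnings: list, where: str):
    if _is_missing(cell):
        return None
    try:
        return float(str(cell).strip())
    except ValueError:
        warnings.append(f"{where}: unparseable number {cell!r}")
        return None


def _parse_category(cell, allowed, warnings: list, where: str, default=None):
    if _is_missing(cell):
        return default
    s = str(cell).strip()
    if s not in allowed:
        warnings.append(f"{where}: value {cell!r} not in {allowed}")
        return default
    return s


def read_cohort(path, item_bank: ItemBank = None, goal_bank: Sequence[GoalDefinition] = None) -> Cohort:
    """Read a delimited cohort file against the given banks.

    Unparseable or out-of-range cells become missing and are counted in
    ``provenance['n_parse_warnings']``; structural problems (missing required
    columns, duplicate respondent ids within a wave) raise.
    """
    item_bank = item_bank if item_bank is not None else default_item_bank()
    goal_bank = list(goal_bank) if goal_bank is not None else default_goal_bank()
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file {path} is missing required columns: {', '.join(missing_cols)}")

    goal_ids = [g.goal_id for g in goal_bank]
    warnings: list = []
    records = []
    for i, row in df.iterrows():
        where = f"row {i + 1} ({row['respondent_id']})"
        item_responses = {}
        for key in item_bank.response_keys:
            col = f"item_{key}"
            if col in df.columns:
                _, part = item_bank.resolve_key(key)
                val = _parse_item_cell(row[col], part, warnings, f"{where} {col}")
                if val is not None:
                    item_responses[key] = val
        goal_ratings = {}
        for gid in goal_ids:
            col = f"goal_{gid}"
            if col in df.columns:
                val = _parse_goal_cell(row[col], warnings, f"{where} {col}")
                if val is not None:
                    goal_ratings[gid] = val
        top3 = tuple(t for t in str(row.get("top3_goals", "")).split(";") if t and t in goal_ids)
        demo = {c[5:]: row[c] for c in df.columns if c.startswith("demo_") and not _is_missing(row[c])}
        records.append(RespondentRecord(
            respondent_id=str(row["respondent_id"]),
            group=str(row["group"]),
            wave=_parse_category(row.get("wave"), WAVES, warnings, where, default="test"),
            item_responses=item_responses,
            goal_ratings=goal_ratings,
            treatment=_parse_category(row.get("treatment"), TREATMENTS, warnings, where, default="none"),
            stage=_parse_category(row.get("stage"), STAGES, warnings, where, default="none"),
            preference=_parse_category(row.get("preference"), PREFERENCES, warnings, where, default="none"),
            confidence=_parse_float(row.get("confidence"), warnings, where),
            regret=_parse_category(row.get("regret"), REGRET_LEVELS, warnings, where),
            top3_goals=top3,
            completion_minutes=_parse_float(row.get("completion_minutes"), warnings, where),
            education=_parse_category(row.get("education"), EDUCATION_LEVELS, warnings, where),
            demographics=demo,
        ))
    for w in warnings:
        log.warning("read_cohort: %s", w)
    return Cohort(records=records, item_bank=item_bank, goal_bank=goal_bank,
                  provenance={"source": "file", "path": str(path),
                              "n_parse_warnings": len(warnings)})


# ---------------------------------------------------------------------------
# Validation and summary


@dataclass
class ValidationReport:
    field_missingness: dict       # field -> % missing among applicable records
    out_of_range: int             # count of parse/range warnings carried on the cohort
    orphan_retests: list          # retest respondent_ids with no matching test record

    @property
    def ok(self) -> bool:
        return self.out_of_range == 0 and not self.orphan_retests


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report per-field missingness, range problems and orphan retest rows."""
    patients = cohort.patients("test")
    missing = {}
    n = len(patients)
    if n:
        for key in cohort.item_bank.response_keys:
            missing[f"item_{key}"] = 100.0 * sum(key not in r.item_responses for r in patients) / n
        for gid in cohort.goal_ids:
            missing[f"goal_{gid}"] = 100.0 * sum(gid not in r.goal_ratings for r in patients) / n
        missing["confidence"] = 100.0 * sum(r.confidence is None for r in patients) / n
        missing["completion_minutes"] = 100.0 * sum(r.completion_minutes is None for r in patients) / n
    test_ids = {r.respondent_id for r in cohort.records if r.wave == "test"}
    orphans = [r.respondent_id for r in cohort.records
               if r.wave == "retest" and r.respondent_id not in test_ids]
    return ValidationReport(field_missingness=missing,
                            out_of_range=int(cohort.provenance.get("n_parse_warnings", 0)),
                            orphan_retests=orphans)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding, matching the reporting style of the tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _tabulate(values, denominator: int) -> dict:
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return {k: {"n": c, "pct": round_half_up(100.0 * c / denominator)}
            for k, c in sorted(counts.items())}


def summarize_cohort(cohort: Cohort) -> dict:
    """Demographic/treatment characteristic tables (counts and percentages).

    Percentages use the group N as denominator and are reported to one
    decimal, half-up, in the style of the demographics table.
    """
    out = {"group_sizes": {g: len(cohort.subset(g, "test")) for g in GROUPS}}
    patients = cohort.patients("test")
    n = len(patients)
    if n:
        surg = [r.treatment for r in patients if r.treatment in ("mastectomy", "lumpectomy")]
        out["patients"] = {
            "n": n,
            "treatment": _tabulate((r.treatment for r in patients), n),
            "mastectomy_vs_lumpectomy": _tabulate(surg, n),
            "stage": _tabulate((r.stage for r in patients if r.stage != "none"), n),
            "education": _tabulate((r.education for r in patients if r.education), n),
            "preference": _tabulate((r.preference for r in patients if r.preference != "none"), n),
        }
        demo_keys = sorted({k for r in patients for k in r.demographics
                            if isinstance(r.demographics.get(k), str)})
        for k in demo_keys:
            out["patients"][k] = _tabulate(
                (r.demographics[k] for r in patients if k in r.demographics), n)
    controls = cohort.controls()
    if controls:
        nc = len(controls)
        out["controls"] = {"n": nc,
                           "education": _tabulate((r.education for r in controls if r.education), nc)}
    return out
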