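"""Knowledge scoring and item-analysis diagnostics.

Scoring rules
-------------
Each item is worth one point, split over weighted parts for multi-part items.
A correct response scores the part weight; an incorrect response or an
explicit "I am not sure" scores 0; a *missing* response scores 1/k of the
part weight, where k counts every printed response choice including
"I am not sure" (the expected score of uniform guessing).  Open-ended answers
are correct iff they fall in the clinically pre-determined interval.

The respondent score is 100 x (sum of item scores) / (number of items in the
set) and is defined only for respondents who completed at least 50% of the
items in the set ("I am not sure" counts as completed; missing does not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank, KnowledgeItem, ItemPart, MULTIPLE_CHOICE, NOT_SURE
from .cohort import Cohort, RespondentRecord, GROUPS

ITEM_SETS = ("initial", "reduced", "screener")

# item-analysis thresholds
TOO_EASY_CONTROL_PCT = 80.0     # healthy controls answering correctly
TOO_HARD_PROVIDER_PCT = 50.0    # providers answering correctly
REDUNDANT_R = 0.8               # inter-item correlation
EXCESS_MISSING_PCT = 5.0


def _score_part(response, part: ItemPart) -> float:
    """Score one part on [0, 1] before weighting."""
    if response is None:
        return 1.0 / part.n_options
    if isinstance(response, str):
        if response == NOT_SURE:
            return 0.0
        raise ValueError(f"unexpected response token {response!r} for part {part.part_id}")
    if part.kind == MULTIPLE_CHOICE:
        idx = int(response)
        if not 0 <= idx < part.n_options:
            raise ValueError(f"option index {idx} outside bank range 0..{part.n_options - 1}")
        return 1.0 if idx == part.correct else 0.0
    lo, hi = part.interval
    return 1.0 if lo <= float(response) <= hi else 0.0


def score_item(responses: Mapping, item: KnowledgeItem) -> float:
    """Weight-adjusted item score on [0, 1].

    ``responses`` maps response keys (item_id, or item_id__part) to the typed
    response; keys absent from the map are treated as missing.
    """
    total = 0.0
    for key, part in zip(item.response_keys(), item.parts):
        total += part.weight * _score_part(responses.get(key), part)
    return total


def item_answered(responses: Mapping, item: KnowledgeItem) -> bool:
    """True if any part of the item carries a response (incl. "not sure")."""
    return any(responses.get(key) is not None for key in item.response_keys())


def score_respondent(record: RespondentRecord, bank: ItemBank,
                     item_set: str = "reduced") -> Optional[float]:
    """Knowledge score in [0, 100], or None if under the 50% completion floor."""
    items = bank.item_set(item_set)
    if not items:
        raise ValueError(f"item set {item_set!r} is empty")
    answered = sum(item_answered(record.item_responses, it) for it in items)
    if answered < 0.5 * len(items):
        return None
    return 100.0 * sum(score_item(record.item_responses, it) for it in items) / len(items)


@dataclass
class ScoreSet:
    """Per-respondent scores plus per-group summaries for one item set."""

    item_set: str
    scores: pd.DataFrame            # respondent_id, group, wave, score, n_answered
    group_summary: pd.DataFrame     # group, n_scored, n_unscorable, mean, sd
    histograms: dict                # group -> (bin_edges, counts), deciles of 0-100

    def group_mean(self, group: str) -> float:
        return float(self.group_summary.set_index("group").loc[group, "mean"])


def score_cohort(cohort: Cohort, item_set: str = "reduced", wave: str = "test") -> ScoreSet:
    """Score every respondent in a wave and summarise by group."""
    bank = cohort.item_bank
    items = bank.item_set(item_set)
    rows = []
    for r in cohort.subset(wave=wave):
        rows.append({
            "respondent_id": r.respondent_id, "group": r.group, "wave": r.wave,
            "score": score_respondent(r, bank, item_set),
            "n_answered": sum(item_answered(r.item_responses, it) for it in items),
        })
    scores = pd.DataFrame(rows)
    summaries, hists = [], {}
    edges = np.linspace(0.0, 100.0, 11)
    for g in GROUPS:
        sub = scores[scores["group"] == g] if len(scores) else scores
        vals = sub["score"].dropna().to_numpy(dtype=float) if len(sub) else np.array([])
        summaries.append({
            "group": g,
            "n_scored": len(vals),
            "n_unscorable": int(len(sub) - len(vals)) if len(sub) else 0,
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
        })
        counts, _ = np.histogram(vals, bins=edges) if len(vals) else (np.zeros(10, int), edges)
        hists[g] = (edges, counts)
    return ScoreSet(item_set=item_set, scores=scores,
                    group_summary=pd.DataFrame(summaries), histograms=hists)


# ---------------------------------------------------------------------------
# Item diagnostics


@dataclass
class ItemDiagnostics:
    """Per-item retention diagnostics and the recommended reduced set."""

    table: pd.DataFrame          # one row per item with rates, correlations, flags
    floor_pct: float             # patient scores at the bottom decile (0-10)
    ceiling_pct: float           # patient scores at the top decile (90-100)
    recommended_reduced_set: list
    notes: list = field(default_factory=list)


def _correct_pct(records, bank: ItemBank, item: KnowledgeItem) -> float:
    """Mean item score (as %) among respondents who answered the item."""
    vals = [score_item(r.item_responses, item) for r in records
            if item_answered(r.item_responses, item)]
    return 100.0 * float(np.mean(vals)) if vals else np.nan


def item_diagnostics(cohort: Cohort, item_set: str = "initial") -> ItemDiagnostics:
    """Item-retention analysis over the full bank (or a named subset).

    Flags follow fixed thresholds: too easy when healthy controls exceed 80%
    correct; too hard when providers fall below 50%; redundant when any
    inter-item correlation exceeds 0.8; negative corrected item-total
    correlation; problematic missingness above 5%.  Item-total and inter-item
    correlations and missingness are computed on patients.
    """
    bank = cohort.item_bank
    items = bank.item_set(item_set)
    patients = cohort.patients("test")
    providers = cohort.providers()
    controls = cohort.controls()
    notes = []
    for g, recs in (("provider", providers), ("control", controls)):
        if not recs:
            notes.append(f"group {g!r} absent: difficulty flags not evaluable")

    # patient item-score matrix (missing scored 1/k, as in the total score)
    n_pat = len(patients)
    mat = np.full((n_pat, len(items)), np.nan)
    answered = np.zeros((n_pat, len(items)), dtype=bool)
    for i, r in enumerate(patients):
        for j, it in enumerate(items):
            mat[i, j] = score_item(r.item_responses, it)
            answered[i, j] = item_answered(r.item_responses, it)

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat, rowvar=False) if n_pat > 2 else np.full((len(items),) * 2, np.nan)

    rows = []
    for j, it in enumerate(items):
        control_pct = _correct_pct(controls, bank, it) if controls else np.nan
        provider_pct = _correct_pct(providers, bank, it) if providers else np.nan
        patient_pct = _correct_pct(patients, bank, it) if patients else np.nan
        total_minus = mat.sum(axis=1) - mat[:, j]
        if n_pat > 2 and np.std(mat[:, j]) > 0 and np.std(total_minus) > 0:
            item_total = float(np.corrcoef(mat[:, j], total_minus)[0, 1])
        else:
            item_total = np.nan
        other = np.delete(corr[j], j)
        max_inter = float(np.nanmax(np.abs(other))) if other.size and not np.all(np.isnan(other)) else np.nan
        missing_pct = 100.0 * float(np.mean(~answered[:, j])) if n_pat else np.nan
        rows.append({
            "item_id": it.item_id,
            "control_correct_pct": control_pct,
            "provider_correct_pct": provider_pct,
            "patient_correct_pct": patient_pct,
            "item_total_corr": item_total,
            "max_inter_item_corr": max_inter,
            "missing_pct": missing_pct,
            "too_easy": bool(control_pct > TOO_EASY_CONTROL_PCT) if not np.isnan(control_pct) else None,
            "too_hard": bool(provider_pct < TOO_HARD_PROVIDER_PCT) if not np.isnan(provider_pct) else None,
            "redundant": bool(max_inter > REDUNDANT_R) if not np.isnan(max_inter) else None,
            "negative_item_total": bool(item_total < 0) if not np.isnan(item_total) else None,
            "excess_missing": bool(missing_pct > EXCESS_MISSING_PCT) if not np.isnan(missing_pct) else None,
        })
    table = pd.DataFrame(rows)

    flag_cols = ["too_easy", "too_hard", "redundant", "negative_item_total", "excess_missing"]
    flagged = table[flag_cols].fillna(False).any(axis=1)
    recommended = [it.item_id for it, f in zip(items, flagged) if not f]

    pat_scores = [score_respondent(r, bank, item_set) for r in patients]
    pat_scores = np.array([s for s in pat_scores if s is not None], dtype=float)
    floor = 100.0 * float(np.mean(pat_scores <= 10)) if pat_scores.size else np.nan
    ceiling = 100.0 * float(np.mean(pat_scores >= 90)) if pat_scores.size else np.nan
    return ItemDiagnostics(table=table, floor_pct=floor, ceiling_pct=ceiling,
                           recommended_reduced_set=recommended, notes=notes)
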