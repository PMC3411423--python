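"""Reliability, validity and feasibility evaluation of the instrument.

Reliability uses the two-way random-effects, absolute-agreement,
single-measurement intraclass correlation (ICC(2,1)), the standard choice for
test-retest designs, with an a-priori target of 0.7.  Validity covers content
(provider coverage ratings, patient top-three goal selections), discriminant
(knowledge by respondent group with planned comparisons; goals by surgery via
one-sided t-tests; predicted probability by stated preference) and predictive
(decision confidence and regret by concordance status) hypotheses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bank import GoalDefinition, TOWARD_MASTECTOMY
from .cohort import Cohort, EDUCATION_LEVELS
from .concordance import ConcordanceResult
from .scoring import score_respondent, item_answered

log = logging.getLogger(__name__)

ICC_TARGET = 0.7
CONTENT_PROVIDER_TARGET_PCT = 70.0
CONTENT_TOP3_TARGET_PCT = 20.0
FEASIBILITY_MISSING_PCT = 5.0


# ---------------------------------------------------------------------------
# ICC


def icc(test, retest) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of an n x 2 table of paired
    measurements as (MSR - MSE) / (MSR + MSE + 2 (MSC - MSE) / n).  Incomplete
    pairs must be removed beforehand; at least three pairs are required.  When
    both the between-subject and residual variation vanish (all measurements
    identical) the coefficient is defined as 1.  The value is clipped below
    at -1.
    """
    x = np.asarray(test, dtype=float)
    y = np.asarray(retest, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("test and retest must be 1-D arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("icc requires complete pairs; drop incomplete pairs first")
    n = len(x)
    if n < 3:
        raise ValueError(f"icc requires at least 3 complete pairs, got {n}")
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    k = 2
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + mse + 2.0 * (msc - mse) / n
    if denom <= 0:
        return 1.0 if np.allclose(data, data[0, 0]) else -1.0
    return float(max((msr - mse) / denom, -1.0))


def _paired(values_by_id_test: dict, values_by_id_retest: dict) -> tuple:
    ids = sorted(set(values_by_id_test) & set(values_by_id_retest))
    a = [values_by_id_test[i] for i in ids]
    b = [values_by_id_retest[i] for i in ids]
    keep = [(u, v) for u, v in zip(a, b) if u is not None and v is not None
            and not (isinstance(u, float) and np.isnan(u))
            and not (isinstance(v, float) and np.isnan(v))]
    if not keep:
        return np.array([]), np.array([]), 0
    a, b = map(np.asarray, zip(*keep))
    return a.astype(float), b.astype(float), len(keep)


def retest_report(cohort: Cohort, retest: Optional[Cohort] = None) -> pd.DataFrame:
    """Test-retest ICC for the knowledge scores and each goal.

    ``retest`` may be a separate cohort of retest-wave records; otherwise
    retest records are taken from ``cohort`` itself.  Pairs are linked by
    respondent_id; incomplete pairs are dropped listwise per measure.
    """
    test_recs = {r.respondent_id: r for r in cohort.patients("test")}
    retest_src = retest if retest is not None else cohort
    retest_recs = {r.respondent_id: r for r in retest_src.subset("patient", "retest")}
    if not retest_recs or not (set(test_recs) & set(retest_recs)):
        raise ValueError("no linked test/retest pairs")

    bank = cohort.item_bank
    rows = []
    for label, item_set in (("knowledge_full", "reduced"), ("knowledge_screener", "screener")):
        a, b, n = _paired({i: score_respondent(r, bank, item_set) for i, r in test_recs.items()},
                          {i: score_respondent(r, bank, item_set) for i, r in retest_recs.items()})
        val = icc(a, b) if n >= 3 else np.nan
        rows.append({"measure": label, "icc": val, "n_pairs": n,
                     "meets_target": bool(val > ICC_TARGET) if n >= 3 else None})
    for g in cohort.goal_bank:
        a, b, n = _paired({i: r.goal_ratings.get(g.goal_id) for i, r in test_recs.items()},
                          {i: r.goal_ratings.get(g.goal_id) for i, r in retest_recs.items()})
        val = icc(a, b) if n >= 3 else np.nan
        rows.append({"measure": f"goal_{g.goal_id}", "icc": val, "n_pairs": n,
                     "meets_target": bool(val > ICC_TARGET) if n >= 3 else None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Content validity


def content_validity(provider_ratings: Sequence[float], patients,
                     goal_bank: Sequence[GoalDefinition]) -> dict:
    """Content-validity evaluation.

    ``provider_ratings`` are 1-4 ratings of how well the knowledge items cover
    the essential content (3-4 = "very or extremely well"); the hypothesis
    passes when more than 70% rate 3-4.  Per goal, the share of patients
    naming it among their top three issues is compared with the 20% target,
    overall and by surgical arm.
    """
    ratings = np.asarray([r for r in provider_ratings if r is not None], dtype=float)
    coverage_pct = 100.0 * float(np.mean(ratings >= 3)) if ratings.size else np.nan
    out = {
        "provider_coverage_pct": coverage_pct,
        "provider_coverage_pass": bool(coverage_pct > CONTENT_PROVIDER_TARGET_PCT)
        if ratings.size else None,
        "n_providers": int(ratings.size),
        "goals": {},
    }
    selectors = [r for r in patients if r.top3_goals]
    arms = {"mastectomy": [r for r in selectors if r.treatment == "mastectomy"],
            "lumpectomy": [r for r in selectors if r.treatment == "lumpectomy"]}
    for g in goal_bank:
        def pct(records):
            if not records:
                return np.nan
            return 100.0 * float(np.mean([g.goal_id in r.top3_goals for r in records]))
        overall = pct(selectors)
        out["goals"][g.goal_id] = {
            "top3_pct": overall,
            "top3_pct_mastectomy": pct(arms["mastectomy"]),
            "top3_pct_lumpectomy": pct(arms["lumpectomy"]),
            "pass": bool(overall >= CONTENT_TOP3_TARGET_PCT) if selectors else None,
        }
    return out


# ---------------------------------------------------------------------------
# Discriminant validity


def _planned_contrast(a: np.ndarray, b: np.ndarray, groups: list) -> dict:
    """One-sided contrast (mean(a) > mean(b)) using the pooled ANOVA error."""
    pooled = np.concatenate(groups)
    ns = [len(g) for g in groups]
    dfe = sum(ns) - len(groups)
    mse = sum(np.sum((g - g.mean()) ** 2) for g in groups) / dfe
    se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
    t = (a.mean() - b.mean()) / se
    p = float(stats.t.sf(t, dfe))
    return {"diff": float(a.mean() - b.mean()), "t": float(t), "df": dfe, "p_one_sided": p}


def discriminant_validity(score_set, cohort: Cohort) -> dict:
    """Knowledge-score group discrimination and per-goal arm discrimination.

    Knowledge: one-way ANOVA over providers/patients/controls with planned
    one-sided comparisons (providers > patients, patients > controls).  Goals:
    one-sided Welch t-test per goal in its expected direction (high rating
    favours mastectomy or lumpectomy as declared in the goal bank).
    """
    sc = score_set.scores
    by_group = {g: sc.loc[(sc["group"] == g) & sc["score"].notna(), "score"].to_numpy(dtype=float)
                for g in ("provider", "patient", "control")}
    report = {"knowledge": {}, "goals": {}, "notes": []}
    groups = [v for v in by_group.values() if len(v) > 1]
    if len(groups) >= 2:
        f, p = stats.f_oneway(*groups)
        report["knowledge"]["anova"] = {"F": float(f), "p": float(p)}
    else:
        report["notes"].append("fewer than two scored groups: ANOVA skipped")
    for name, hi, lo in (("provider_gt_patient", "provider", "patient"),
                         ("patient_gt_control", "patient", "control")):
        if len(by_group[hi]) > 1 and len(by_group[lo]) > 1:
            report["knowledge"][name] = _planned_contrast(by_group[hi], by_group[lo], groups)
        else:
            report["notes"].append(f"contrast {name} skipped: group absent")

    analyzable = [r for r in cohort.patients("test")
                  if r.treatment in ("mastectomy", "lumpectomy")]
    for g in cohort.goal_bank:
        a = np.array([r.goal_ratings[g.goal_id] for r in analyzable
                      if r.treatment == "mastectomy" and g.goal_id in r.goal_ratings], dtype=float)
        b = np.array([r.goal_ratings[g.goal_id] for r in analyzable
                      if r.treatment == "lumpectomy" and g.goal_id in r.goal_ratings], dtype=float)
        if len(a) < 2 or len(b) < 2:
            report["notes"].append(f"goal {g.goal_id} skipped: arm with n<2")
            continue
        # one-sided Welch t in the direction declared by the goal bank
        toward_mast = g.expected_direction == TOWARD_MASTECTOMY
        t, p = stats.ttest_ind(a, b, equal_var=False,
                               alternative="greater" if toward_mast else "less")
        report["goals"][g.goal_id] = {
            "mean_mastectomy": float(a.mean()), "mean_lumpectomy": float(b.mean()),
            "expected_direction": g.expected_direction,
            "t": float(t), "p_one_sided": float(p),
            "direction_as_expected": bool(t > 0 if toward_mast else t < 0),
        }
    return report


def preference_gradient(concordance: ConcordanceResult,
                        preferences: Sequence[str]) -> dict:
    """Model-predicted probability of mastectomy by stated treatment preference.

    Expects the ordering mastectomy > not sure > lumpectomy-and-radiation in
    mean predicted probability; tested with one-way ANOVA plus ordered planned
    comparisons.
    """
    p = concordance.per_patient["p_mastectomy"].to_numpy(dtype=float)
    prefs = np.asarray(list(preferences), dtype=object)
    if len(prefs) != len(p):
        raise ValueError("preferences do not align with concordance result")
    levels = ("mastectomy", "not_sure", "lumpectomy_radiation")
    by = {lv: p[prefs == lv] for lv in levels}
    present = [lv for lv in levels if len(by[lv]) > 1]
    if len(present) < 2:
        raise ValueError("preference gradient needs at least two preference levels")
    groups = [by[lv] for lv in present]
    f, pv = stats.f_oneway(*groups)
    out = {"means": {lv: float(by[lv].mean()) if len(by[lv]) else np.nan for lv in levels},
           "n": {lv: int(len(by[lv])) for lv in levels},
           "anova": {"F": float(f), "p": float(pv)}, "contrasts": {}}
    for hi, lo in (("mastectomy", "not_sure"), ("not_sure", "lumpectomy_radiation"),
                   ("mastectomy", "lumpectomy_radiation")):
        if len(by[hi]) > 1 and len(by[lo]) > 1:
            out["contrasts"][f"{hi}_gt_{lo}"] = _planned_contrast(by[hi], by[lo], groups)
    return out


# ---------------------------------------------------------------------------
# Predictive validity


def dichotomize_regret(regret: Optional[str]) -> Optional[bool]:
    """True when the patient would definitely/probably choose the same surgery."""
    if regret is None:
        return None
    return regret in ("definitely_yes", "probably_yes")


def predictive_validity(concordance: ConcordanceResult, cohort: Cohort) -> dict:
    """Confidence (two-sided Welch t) and regret (chi-square) by concordance."""
    recs = {r.respondent_id: r for r in cohort.patients("test")}
    conf = {True: [], False: []}
    same = {True: [], False: []}
    for _, row in concordance.per_patient.iterrows():
        r = recs.get(row["respondent_id"])
        if r is None:
            continue
        flag = bool(row["concordant"])
        if r.confidence is not None:
            conf[flag].append(float(r.confidence))
        d = dichotomize_regret(r.regret)
        if d is not None:
            same[flag].append(d)
    out = {"n_concordant": len(conf[True]) or len(same[True]),
           "n_discordant": len(conf[False]) or len(same[False]), "notes": []}
    if len(conf[True]) > 1 and len(conf[False]) > 1:
        t, p = stats.ttest_ind(conf[True], conf[False], equal_var=False)
        out["confidence"] = {"mean_concordant": float(np.mean(conf[True])),
                             "mean_discordant": float(np.mean(conf[False])),
                             "t": float(t), "p": float(p)}
    else:
        out["notes"].append("confidence test skipped: a concordance class is empty")
    if same[True] and same[False]:
        table = np.array([[sum(same[True]), len(same[True]) - sum(same[True])],
                          [sum(same[False]), len(same[False]) - sum(same[False])]])
        if (table.sum(axis=0) > 0).all():
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            out["regret"] = {"same_again_pct_concordant": 100.0 * float(np.mean(same[True])),
                             "same_again_pct_discordant": 100.0 * float(np.mean(same[False])),
                             "chi2": float(chi2), "p": float(p)}
        else:
            out["notes"].append("regret test skipped: degenerate table")
    else:
        out["notes"].append("regret test skipped: a concordance class is empty")
    return out


# ---------------------------------------------------------------------------
# Acceptability and feasibility


def feasibility_report(cohort: Cohort) -> dict:
    """Missing-data rates, problematic items (>5% missing) and completion time.

    Completion time is summarised overall and compared across the three
    education levels with one-way ANOVA.
    """
    patients = cohort.patients("test")
    n = len(patients)
    items = {}
    for it in cohort.item_bank:
        items[it.item_id] = 100.0 * float(
            np.mean([not item_answered(r.item_responses, it) for r in patients])) if n else np.nan
    goals = {}
    for g in cohort.goal_bank:
        goals[g.goal_id] = 100.0 * float(
            np.mean([g.goal_id not in r.goal_ratings for r in patients])) if n else np.nan
    item_vals = np.array(list(items.values()), dtype=float)
    goal_vals = np.array(list(goals.values()), dtype=float)
    offenders = sorted([k for k, v in {**items, **goals}.items() if v > FEASIBILITY_MISSING_PCT])

    times = np.array([r.completion_minutes for r in patients
                      if r.completion_minutes is not None], dtype=float)
    out = {
        "item_missing_pct": items,
        "goal_missing_pct": goals,
        "item_missing_mean_pct": float(np.mean(item_vals)) if item_vals.size else np.nan,
        "item_missing_range_pct": (float(item_vals.min()), float(item_vals.max()))
        if item_vals.size else (np.nan, np.nan),
        "goal_missing_median_pct": float(np.median(goal_vals)) if goal_vals.size else np.nan,
        "goal_missing_range_pct": (float(goal_vals.min()), float(goal_vals.max()))
        if goal_vals.size else (np.nan, np.nan),
        "problematic": offenders,
        "completion_minutes_mean": float(times.mean()) if times.size else np.nan,
        "completion_minutes_range": (float(times.min()), float(times.max()))
        if times.size else (np.nan, np.nan),
    }
    by_edu = []
    means = {}
    for lv in EDUCATION_LEVELS:
        vals = np.array([r.completion_minutes for r in patients
                         if r.education == lv and r.completion_minutes is not None], dtype=float)
        means[lv] = float(vals.mean()) if vals.size else np.nan
        if len(vals) > 1:
            by_edu.append(vals)
    out["completion_by_education"] = means
    if len(by_edu) >= 2:
        f, p = stats.f_oneway(*by_edu)
        out["completion_education_anova"] = {"F": float(f), "p": float(p)}
    return out
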