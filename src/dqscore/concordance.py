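"""Goals-treatment concordance: EM imputation, logistic model, c-statistic.

Concordance asks whether each patient's received surgery (mastectomy vs
lumpectomy) matches the surgery predicted by a logistic regression of
treatment on disease stage and the importance ratings of the treatment goals.
A patient is concordant when the model-predicted probability of mastectomy is
>= 0.5 and she had mastectomy, or < 0.5 and she had lumpectomy.  The summary
concordance score is the percentage of analyzable patients who are
concordant; it is an in-sample goodness-of-fit summary, interpreted at the
group level.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .cohort import Cohort, RespondentRecord

log = logging.getLogger(__name__)

SEPARATION_BETA = 15.0
PROBABILITY_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Exclusions


def apply_exclusions(cohort_or_records) -> tuple:
    """Analyzable patient subset for the concordance model.

    Patients who had lumpectomy followed by mastectomy were not clinically
    eligible for both options and are excluded, as are patients without a
    definitive mastectomy/lumpectomy treatment on record.  Returns
    ``(analyzable_records, exclusion_counts)``.
    """
    if isinstance(cohort_or_records, Cohort):
        records = cohort_or_records.patients("test")
    else:
        records = [r for r in cohort_or_records if r.group == "patient" and r.wave == "test"]
    excl = {"lumpectomy_then_mastectomy": 0, "no_treatment": 0}
    keep = []
    for r in records:
        if r.treatment == "lumpectomy_then_mastectomy":
            excl["lumpectomy_then_mastectomy"] += 1
        elif r.treatment not in ("mastectomy", "lumpectomy"):
            excl["no_treatment"] += 1
        else:
            keep.append(r)
    if not keep:
        raise ValueError("no analyzable patients after exclusions")
    log.info("apply_exclusions: kept %d of %d patients (%s)", len(keep), len(records), excl)
    return keep, excl


# ---------------------------------------------------------------------------
# EM imputation under a joint multivariate normal model


@dataclass
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    n_iter: int
    loglik: list
    converged: bool
    all_missing_rows: list


def _observed_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Observed-data log-likelihood of rows with arbitrary missingness."""
    total = 0.0
    for row in x:
        o = ~np.isnan(row)
        if not o.any():
            continue
        mu_o = mean[o]
        cov_oo = cov[np.ix_(o, o)]
        diff = row[o] - mu_o
        sign, logdet = np.linalg.slogdet(cov_oo)
        if sign <= 0:
            cov_oo = cov_oo + 1e-8 * np.eye(o.sum())
            sign, logdet = np.linalg.slogdet(cov_oo)
        total += -0.5 * (o.sum() * np.log(2 * np.pi) + logdet
                         + diff @ np.linalg.solve(cov_oo, diff))
    return float(total)


def em_impute_goals(goal_matrix, *, max_iter: int = 500, tol: float = 1e-6,
                    clip: tuple = (0.0, 10.0)) -> tuple:
    """EM imputation of missing goal ratings under joint normality.

    E-step: missing entries are replaced by their conditional expectation
    given the observed entries and the current mean/covariance; the M-step
    updates the mean and covariance using the conditional second moments.
    Iterates until the largest parameter change falls below ``tol``.  The
    observed-data log-likelihood is tracked and asserted non-decreasing at
    every iteration.  Imputed values are finally clipped to the rating scale;
    observed entries are never altered.

    Returns ``(completed_matrix, EMResult)``.
    """
    x = np.asarray(goal_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("goal matrix must be 2-D with at least two goal columns")
    n, p = x.shape
    miss = np.isnan(x)
    all_missing = [int(i) for i in np.where(miss.all(axis=1))[0]]
    if all_missing:
        _warnings.warn(f"{len(all_missing)} patient(s) with every goal missing; "
                       "imputed at the estimated mean", stacklevel=2)

    mean = np.nanmean(x, axis=0)
    var = np.nanvar(x, axis=0, ddof=0)
    var = np.where(var > 1e-8, var, 1.0)
    cov = np.diag(var)

    logliks = [_observed_loglik(x, mean, cov)]
    completed = np.where(miss, mean, x)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        completed = x.copy()
        correction = np.zeros((p, p))
        for i in range(n):
            m = miss[i]
            if not m.any():
                continue
            o = ~m
            if not o.any():
                completed[i] = mean
                correction += cov
                continue
            cov_oo = cov[np.ix_(o, o)]
            cov_mo = cov[np.ix_(m, o)]
            try:
                w = np.linalg.solve(cov_oo, (x[i, o] - mean[o]))
                gain = np.linalg.solve(cov_oo, cov_mo.T).T
            except np.linalg.LinAlgError:
                cov_oo = cov_oo + 1e-8 * np.eye(int(o.sum()))
                w = np.linalg.solve(cov_oo, (x[i, o] - mean[o]))
                gain = np.linalg.solve(cov_oo, cov_mo.T).T
            completed[i, m] = mean[m] + cov_mo @ w
            cond_cov = cov[np.ix_(m, m)] - gain @ cov_mo.T
            idx = np.where(m)[0]
            correction[np.ix_(idx, idx)] += cond_cov
        # M-step
        new_mean = completed.mean(axis=0)
        centred = completed - new_mean
        new_cov = (centred.T @ centred + correction) / n

        delta = max(np.max(np.abs(new_mean - mean)), np.max(np.abs(new_cov - cov)))
        mean, cov = new_mean, new_cov
        ll = _observed_loglik(x, mean, cov)
        if ll < logliks[-1] - 1e-6 * (1.0 + abs(logliks[-1])):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {n_iter}: {logliks[-1]} -> {ll}")
        logliks.append(ll)
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations; log-likelihood trace: "
            f"{logliks[:3]} ... {logliks[-3:]}")

    out = x.copy()
    out[miss] = np.clip(completed[miss], clip[0], clip[1])
    return out, EMResult(mean=mean, cov=cov, n_iter=n_iter, loglik=logliks,
                         converged=converged, all_missing_rows=all_missing)


# ---------------------------------------------------------------------------
# c-statistic


def c_statistic(probabilities, outcomes) -> float:
    """Rank-based c-statistic (AUC): the proportion of case-control pairs in
    which the case carries the higher predicted probability, ties counted 1/2.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and outcomes must be 1-D and equal length")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic needs at least one case and one control")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Treatment model


@dataclass
class TreatmentModel:
    """Fitted logistic model of mastectomy on stage and goal importances."""

    terms: list                       # design column names (excl. intercept)
    params: pd.Series                 # coefficients incl. 'intercept'
    conf_int: pd.DataFrame            # Wald 95% CI on the coefficient scale
    pvalues: pd.Series
    predicted: np.ndarray             # p_i per analyzable patient, model order
    c_statistic: float
    threshold: float = PROBABILITY_THRESHOLD
    converged: bool = True
    separation_flag: bool = False
    n: int = 0
    n_cases: int = 0

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def or_table(self) -> pd.DataFrame:
        """Odds ratios with 95% CIs, one row per non-intercept term."""
        tab = pd.DataFrame({
            "OR": np.exp(self.params), "ci_low": np.exp(self.conf_int["low"]),
            "ci_high": np.exp(self.conf_int["high"]), "p": self.pvalues,
        })
        return tab.drop(index="intercept")


def _design_matrix(records: Sequence[RespondentRecord], goal_ids: Sequence[str],
                   goal_matrix: Optional[np.ndarray], include_stage: bool) -> tuple:
    if goal_matrix is None:
        goal_matrix = np.array([[r.goal_ratings.get(g, np.nan) for g in goal_ids]
                                for r in records], dtype=float)
    goal_matrix = np.asarray(goal_matrix, dtype=float)
    cols = list(goal_ids)
    X = goal_matrix
    if include_stage:
        stage2 = np.array([1.0 if r.stage == "II" else 0.0 for r in records])
        X = np.column_stack([stage2, X])
        cols = ["stage_II"] + cols
    y = np.array([1 if r.treatment == "mastectomy" else 0 for r in records], dtype=int)
    return X, y, cols


def fit_treatment_model(records: Sequence[RespondentRecord], goal_ids: Sequence[str],
                        *, goal_matrix: Optional[np.ndarray] = None,
                        include_stage: bool = True, tol: float = 1e-8,
                        maxiter: int = 100) -> TreatmentModel:
    """Maximum-likelihood logistic regression of mastectomy on stage + goals.

    ``goal_matrix`` (rows aligned with ``records``) supplies EM-completed
    ratings; without it, observed ratings are used and must be complete.
    Newton/IRLS fit with Wald 95% intervals; quasi-separation is flagged when
    any |coefficient| exceeds 15.
    """
    X, y, cols = _design_matrix(records, goal_ids, goal_matrix, include_stage)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; impute goals first")
    if y.min() == y.max():
        raise ValueError("treatment is constant; cannot fit a logistic model")
    n, k = X.shape
    if n <= 10 * (k + 1):
        _warnings.warn(f"only {n} patients for {k + 1} parameters "
                       "(fewer than 10 per parameter)", stacklevel=2)
    design = sm.add_constant(X, prepend=True)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # near-separation convergence chatter
        fit = sm.Logit(y, design).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
    names = ["intercept"] + cols
    params = pd.Series(fit.params, index=names)
    ci = pd.DataFrame(fit.conf_int(), index=names, columns=["low", "high"])
    predicted = np.asarray(fit.predict(design), dtype=float)
    separation = bool(np.any(np.abs(fit.params) > SEPARATION_BETA))
    if separation:
        _warnings.warn("possible separation: a coefficient exceeds 15 in absolute value",
                       stacklevel=2)
    return TreatmentModel(
        terms=cols, params=params, conf_int=ci,
        pvalues=pd.Series(fit.pvalues, index=names),
        predicted=predicted, c_statistic=c_statistic(predicted, y),
        converged=bool(fit.mle_retvals.get("converged", True)),
        separation_flag=separation, n=n, n_cases=int(y.sum()))


# ---------------------------------------------------------------------------
# Concordance classification


@dataclass
class ConcordanceResult:
    """Concordance between received treatment and model-predicted treatment."""

    per_patient: pd.DataFrame        # respondent_id, treatment, p_mastectomy, concordant
    overall_pct: float
    by_arm_pct: dict                 # treatment arm -> % concordant
    n_analyzable: int
    excluded: dict = field(default_factory=dict)


def classify_concordance(model: TreatmentModel, records: Sequence[RespondentRecord],
                         excluded: Optional[dict] = None) -> ConcordanceResult:
    """Classify each analyzable patient as concordant or discordant.

    Concordant iff predicted probability of mastectomy >= 0.5 and she had
    mastectomy, or < 0.5 and she had lumpectomy (boundary counts as predicted
    mastectomy).
    """
    if len(records) != len(model.predicted):
        raise ValueError("records do not align with the model's predicted probabilities")
    rows = []
    for r, p in zip(records, model.predicted):
        predicted_mast = p >= model.threshold
        had_mast = r.treatment == "mastectomy"
        rows.append({"respondent_id": r.respondent_id, "treatment": r.treatment,
                     "p_mastectomy": float(p),
                     "concordant": bool(predicted_mast == had_mast)})
    df = pd.DataFrame(rows)
    by_arm = {arm: 100.0 * float(sub["concordant"].mean())
              for arm, sub in df.groupby("treatment")}
    return ConcordanceResult(per_patient=df,
                             overall_pct=100.0 * float(df["concordant"].mean()),
                             by_arm_pct=by_arm, n_analyzable=len(df),
                             excluded=dict(excluded or {}))


# ---------------------------------------------------------------------------
# Univariate screen


def univariate_screen(records: Sequence[RespondentRecord], goal_ids: Sequence[str],
                      *, goal_matrix: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-factor univariate tests of association with mastectomy.

    Goals: Welch two-sample t-test with arm means reported; stage: chi-square
    without continuity correction, with % stage II by arm.  Arms with fewer
    than two patients yield a note instead of a test.
    """
    X, y, _ = _design_matrix(records, goal_ids, goal_matrix, include_stage=False)
    mast, lump = y == 1, y == 0
    rows = []
    small = mast.sum() < 2 or lump.sum() < 2

    stage2 = np.array([1 if r.stage == "II" else 0 for r in records])
    if small:
        rows.append({"factor": "stage_II", "mast": np.nan, "lump": np.nan,
                     "p": np.nan, "test": "skipped: arm with n<2"})
    else:
        table = np.array([[np.sum(stage2[mast] == 1), np.sum(stage2[mast] == 0)],
                          [np.sum(stage2[lump] == 1), np.sum(stage2[lump] == 0)]])
        if (table.sum(axis=0) == 0).any():
            rows.append({"factor": "stage_II",
                         "mast": 100.0 * float(np.mean(stage2[mast])),
                         "lump": 100.0 * float(np.mean(stage2[lump])),
                         "p": np.nan, "test": "skipped: stage is constant"})
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append({"factor": "stage_II",
                         "mast": 100.0 * float(np.mean(stage2[mast])),
                         "lump": 100.0 * float(np.mean(stage2[lump])),
                         "p": float(p), "test": "chi-square"})
    for j, gid in enumerate(goal_ids):
        a, b = X[mast, j], X[lump, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append({"factor": gid, "mast": np.nan, "lump": np.nan,
                         "p": np.nan, "test": "skipped: arm with n<2"})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"factor": gid, "mast": float(np.mean(a)), "lump": float(np.mean(b)),
                     "p": float(p), "test": "welch-t"})
    return pd.DataFrame(rows)
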