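"""Synthetic cohort generator calibrated to the published study conditions.

The study surveyed 440 early-stage breast cancer survivors, 88 providers and
35 healthy controls; raw responses were never deposited.  This module
generates cohorts with the statistical structure the analysis assumes so the
whole pipeline can be exercised and its estimators validated:

* Knowledge: each respondent carries a latent ability; item correctness is a
  thresholded Gaussian (probit/copula) with a common loading, so that item
  marginals match configured per-group correct rates while test-retest
  reliability of the score is governed by the loading.
* Goals: a 6-dimensional latent normal vector per patient (plus two
  independent placeholder goals), re-measured with per-goal wave noise, then
  rounded and clipped to the 0-10 grid.  The keep-breast/remove-breast
  latent correlation is negative by design.
* Treatment: mastectomy is drawn Bernoulli(logistic(b0 + b'x)) from the
  *observed* (discretised) goal ratings plus a stage-II indicator, with
  log-odds-ratio coefficients taken from the published multivariable model.
  Because treatment is generated from the same family the analysis fits,
  refitting the model is a fair parameter-recovery test.
* Missingness: a small per-item knowledge rate, a handful of low-completers
  who fall under the 50% scoring floor, and goal missingness concentrated on
  the remove-breast item among lumpectomy patients.

Default numeric values were fixed once by calibrating Monte-Carlo summaries
against the published group means, arm-conditional goal means, mastectomy
fraction, correlations and retest ICCs (see ``calibrate_generator``).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm, pearsonr

from .bank import (CANONICAL_GOALS, MULTIPLE_CHOICE, NOT_SURE,
                   default_goal_bank, default_item_bank)
from .cohort import Cohort, RespondentRecord
from .concordance import apply_exclusions
from .psychometrics import icc as _icc
from .scoring import score_respondent

log = logging.getLogger(__name__)

PLACEHOLDER_GOALS = ("placeholder_goal_1", "placeholder_goal_2")
GENERATOR_VERSION = "1.0"

# Per-group correct-response probabilities. The five screener items use the
# published response tables (correct count / group N); the remaining items are
# synthetic, calibrated so the reduced 12-item score means hit the published
# group means (patients 52.7%, providers 87.7%, controls 49.3%).
DEFAULT_ITEM_PROFILES = {
    #                         patient control provider
    "delay_survival":        {"patient": 0.60, "control": 0.37, "provider": 0.97},
    "die_of_bc":             {"patient": 0.71, "control": 0.69, "provider": 0.985},
    "reoperation":           {"patient": 0.70, "control": 0.86, "provider": 0.995},
    "survival_equivalence":  {"patient": 0.57, "control": 0.31, "provider": 0.96},
    "local_recurrence":      {"patient": 0.46, "control": 0.68, "provider": 0.77},
    "radiation_duration":    {"patient": 0.40, "control": 0.30, "provider": 0.78},
    "recovery_time":         {"patient": 0.52, "control": 0.46, "provider": 0.84},
    "margins_reexcision":    {"patient": 0.38, "control": 0.36, "provider": 0.82},
    "hormone_therapy":       {"patient": 0.55, "control": 0.50, "provider": 0.88},
    "chemo_need":            {"patient": 0.47, "control": 0.44, "provider": 0.86},
    "recurrence_rate_pct":   {"patient": 0.45, "control": 0.42, "provider": 0.85},
    "survival_rate_pct":     {"patient": 0.555, "control": 0.561, "provider": 0.914},
    "easy_radiation_machine": {"patient": 0.92, "control": 0.90, "provider": 0.99},
    "easy_surgery_removes":  {"patient": 0.90, "control": 0.88, "provider": 0.995},
    "reverse_keyed":         {"patient": 0.45, "control": 0.50, "provider": 0.60},
}

# goal order: keep_breast, remove_breast, avoid_recurrence, avoid_radiation,
#             avoid_radiation_side_effects, avoid_radiation_hassle
DEFAULT_GOAL_MU = (5.864, 5.338, 17.549, 1.682, 5.805, 2.343)
DEFAULT_GOAL_SD = (5.091, 6.548, 5.962, 4.900, 3.0, 3.2)
DEFAULT_GOAL_CORR = (
    (1.000, -0.585, -0.158, -0.150, -0.037, -0.329),
    (-0.585, 1.000, 0.313, 0.573, 0.111, 0.492),
    (-0.158, 0.313, 1.000, 0.158, 0.100, 0.050),
    (-0.150, 0.573, 0.158, 1.000, 0.294, 0.893),
    (-0.037, 0.111, 0.100, 0.294, 1.000, 0.350),
    (-0.329, 0.492, 0.050, 0.893, 0.350, 1.000),
)
DEFAULT_GOAL_WAVE_SD = (1.695, 2.533, 2.632, 2.375, 2.090, 2.290)
# multivariable log odds ratios per unit goal importance (mastectomy vs lumpectomy)
DEFAULT_TREAT_COEFS = (math.log(0.79), math.log(1.88), 0.0, math.log(1.23), 0.0, 0.0)


def _default_profiles():
    return copy.deepcopy(DEFAULT_ITEM_PROFILES)


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic cohort generator."""

    # sample sizes
    n_patients: int = 440
    n_providers: int = 88
    n_controls: int = 35
    n_lump_then_mast: int = 29     # excluded: not clinically eligible for both options
    n_no_treatment: int = 28       # excluded: no definitive surgery on record
    retest_n: int = 100

    # knowledge model
    item_profiles: dict = field(default_factory=_default_profiles)
    reversed_items: tuple = ("reverse_keyed",)
    item_loading: float = 0.52     # ability loading; drives score retest ICC
    trait_wave_sd: float = 0.0     # extra between-wave ability drift
    knowledge_missing_rate: float = 0.008
    low_completer_rate: float = 4.0 / 440.0
    low_completer_n_items: int = 5

    # goal model (order = CANONICAL_GOALS)
    goal_mu: tuple = DEFAULT_GOAL_MU
    goal_sd: tuple = DEFAULT_GOAL_SD
    goal_corr: tuple = DEFAULT_GOAL_CORR
    goal_wave_sd: tuple = DEFAULT_GOAL_WAVE_SD
    placeholder_mu: tuple = (4.0, 4.5)
    placeholder_sd: tuple = (2.5, 2.5)
    placeholder_wave_sd: tuple = (1.5, 1.5)

    # goal missingness
    goal_missing_rate: float = 0.033
    remove_breast_missing_rate: float = 0.109
    remove_breast_missing_lump_share: float = 0.94

    # treatment model
    treat_intercept: float = -5.3991
    treat_coefs: tuple = DEFAULT_TREAT_COEFS
    stage_coef: float = math.log(1.81)
    stage2_prev: float = 0.398

    # stated preference: monotone in the true mastectomy probability
    pref_noise_sd: float = 1.3
    pref_hi: float = 0.40
    pref_lo: float = 0.15

    # appraisal items
    confidence_mean_concordant: float = 9.45
    confidence_mean_discordant: float = 9.40
    confidence_sd: float = 1.3
    regret_same_concordant: float = 0.91
    regret_same_discordant: float = 0.85

    # feasibility model
    completion_mean_by_education: tuple = (6.8, 6.4, 5.3)
    completion_sd: float = 2.0
    completion_range: tuple = (1.4, 19.0)
    education_probs: tuple = (0.125, 0.241, 0.634)

    version: str = GENERATOR_VERSION

    def goal_cov(self) -> np.ndarray:
        sd = np.asarray(self.goal_sd, dtype=float)
        corr = np.asarray(self.goal_corr, dtype=float)
        if corr.shape != (len(sd), len(sd)):
            raise ValueError("goal_corr shape does not match goal_sd")
        cov = corr * np.outer(sd, sd)
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("goal covariance is not positive semi-definite")
        return cov

    def validate(self) -> None:
        for item, prof in self.item_profiles.items():
            for g, p in prof.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"item profile {item}/{g} = {p} outside [0, 1]")
        for name in ("knowledge_missing_rate", "goal_missing_rate",
                     "remove_breast_missing_rate", "stage2_prev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if not all(np.isfinite(self.treat_coefs)) or not np.isfinite(self.treat_intercept):
            raise ValueError("treatment coefficients must be finite")
        self.goal_cov()

    def copy(self) -> "GeneratorConfig":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# knowledge-response generation


def _draw_item_responses(rng, bank, items, traits, group, cfg: GeneratorConfig):
    """Responses for one group: list (per respondent) of key->response dicts."""
    n = len(traits)
    lam = cfg.item_loading
    resid = math.sqrt(max(0.0, 1.0 - lam * lam))
    out = [dict() for _ in range(n)]
    for it in items:
        p = float(np.clip(cfg.item_profiles[it.item_id][group], 0.005, 0.995))
        sign = -1.0 if it.item_id in cfg.reversed_items else 1.0
        thresh = norm.ppf(1.0 - p)
        for key, part in zip(it.response_keys(), it.parts):
            z = sign * lam * traits + resid * rng.standard_normal(n)
            correct = z > thresh
            if part.kind == MULTIPLE_CHOICE:
                wrong = [i for i in range(part.n_options) if i != part.correct]
                picks = rng.choice(wrong, size=n)
                for i in range(n):
                    out[i][key] = int(part.correct) if correct[i] else int(picks[i])
            else:
                lo, hi = part.interval
                inside = rng.uniform(lo, hi, size=n)
                below = rng.uniform(max(0.0, lo - 0.6 * (hi - lo) - 5.0), lo, size=n)
                above = rng.uniform(hi, hi + 0.6 * (hi - lo) + 5.0, size=n)
                side = rng.random(n)
                for i in range(n):
                    if correct[i]:
                        out[i][key] = round(float(inside[i]), 1)
                    elif side[i] < 0.35:
                        out[i][key] = NOT_SURE
                    elif side[i] < 0.675:
                        out[i][key] = round(float(below[i]), 1)
                    else:
                        out[i][key] = round(float(above[i]), 1)
    return out


def _apply_item_missingness(rng, responses, bank, cfg: GeneratorConfig,
                            low_completers: Optional[np.ndarray] = None):
    items = list(bank)
    for i, resp in enumerate(responses):
        if low_completers is not None and low_completers[i]:
            keep_items = set(rng.choice([it.item_id for it in items],
                                        size=min(cfg.low_completer_n_items, len(items)),
                                        replace=False))
            for it in items:
                if it.item_id not in keep_items:
                    for key in it.response_keys():
                        resp.pop(key, None)
        else:
            for it in items:
                if rng.random() < cfg.knowledge_missing_rate:
                    for key in it.response_keys():
                        resp.pop(key, None)


def _discretize(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), 0, 10).astype(int)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: GeneratorConfig, seed: int) -> Cohort:
    """Generate a full three-group cohort; deterministic given the seed.

    Patients additionally carry goals, treatment, stage, preference,
    confidence/regret and completion time.  Latent states (ability, latent
    goal vector, true mastectomy probability) are retained on the cohort for
    retest generation.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    bank = default_item_bank()
    goal_bank = default_goal_bank()
    items = list(bank)
    cov = config.goal_cov()
    mu = np.asarray(config.goal_mu, dtype=float)
    wave_sd = np.asarray(config.goal_wave_sd, dtype=float)
    beta = np.asarray(config.treat_coefs, dtype=float)

    records = []
    latents = {}

    # ---- patients
    n = config.n_patients
    traits = rng.standard_normal(n)
    responses = _draw_item_responses(rng, bank, items, traits, "patient", config)
    n_low = int(round(config.low_completer_rate * n))
    low_mask = np.zeros(n, dtype=bool)
    if n_low:
        low_mask[rng.choice(n, size=n_low, replace=False)] = True
    _apply_item_missingness(rng, responses, bank, config, low_mask)

    goals_latent = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    ph_latent = (np.asarray(config.placeholder_mu)
                 + rng.standard_normal((n, 2)) * np.asarray(config.placeholder_sd))
    ratings = _discretize(goals_latent + rng.standard_normal((n, 6)) * wave_sd)
    ph_ratings = _discretize(ph_latent + rng.standard_normal((n, 2))
                             * np.asarray(config.placeholder_wave_sd))

    stage2 = rng.random(n) < config.stage2_prev
    eta = config.treat_intercept + ratings @ beta + config.stage_coef * stage2
    p_true = expit(eta)
    mast = rng.random(n) < p_true
    treatment = np.where(mast, "mastectomy", "lumpectomy").astype(object)

    # non-analyzable patients: lumpectomy-then-mastectomy and no definitive surgery
    n_excl = config.n_lump_then_mast + config.n_no_treatment
    if n_excl > n:
        raise ValueError("more exclusions configured than patients")
    excl_idx = rng.choice(n, size=n_excl, replace=False)
    treatment[excl_idx[:config.n_lump_then_mast]] = "lumpectomy_then_mastectomy"
    treatment[excl_idx[config.n_lump_then_mast:]] = "none"

    # goal missingness: remove-breast skips concentrate among lumpectomy
    # patients; conditional rates use the realized arm sizes so the marginal
    # rate converges to the configured value
    r = config.remove_breast_missing_rate
    share = config.remove_breast_missing_lump_share
    is_lumpish = ~np.isin(treatment, ("mastectomy",))
    n_lumpish = max(int(is_lumpish.sum()), 1)
    n_mastish = max(n - n_lumpish, 1)
    p_miss_remove = {"lump": min(1.0, r * share * n / n_lumpish),
                     "mast": min(1.0, r * (1 - share) * n / n_mastish)}
    goal_ids = list(CANONICAL_GOALS)
    goal_missing = np.zeros((n, 6), dtype=bool)
    for j, gid in enumerate(goal_ids):
        if gid == "remove_breast":
            pm = np.where(is_lumpish, p_miss_remove["lump"], p_miss_remove["mast"])
        else:
            pm = np.full(n, config.goal_missing_rate)
        goal_missing[:, j] = rng.random(n) < pm
    ph_missing = rng.random((n, 2)) < config.goal_missing_rate

    # stated preference: noisy monotone map of the true probability
    u = expit(logit(np.clip(p_true, 1e-9, 1 - 1e-9))
              + config.pref_noise_sd * rng.standard_normal(n))
    preference = np.where(u >= config.pref_hi, "mastectomy",
                          np.where(u <= config.pref_lo, "lumpectomy_radiation", "not_sure"))

    concordant_true = (p_true >= 0.5) == mast
    conf_mu = np.where(concordant_true, config.confidence_mean_concordant,
                       config.confidence_mean_discordant)
    confidence = np.clip(np.rint(conf_mu + config.confidence_sd * rng.standard_normal(n)), 0, 10)
    p_same = np.where(concordant_true, config.regret_same_concordant,
                      config.regret_same_discordant)
    same = rng.random(n) < p_same
    regret = np.empty(n, dtype=object)
    rdraw = rng.random(n)
    regret[same] = np.where(rdraw[same] < 0.72, "definitely_yes", "probably_yes")
    neg = ~same
    regret[neg] = np.select(
        [rdraw[neg] < 0.60, rdraw[neg] < 0.85], ["not_sure", "probably_no"], "definitely_no")

    edu_levels = ("hs_or_less", "some_college", "college_plus")
    edu = rng.choice(edu_levels, size=n, p=np.asarray(config.education_probs)
                     / np.sum(config.education_probs))
    edu_mean = dict(zip(edu_levels, config.completion_mean_by_education))
    minutes = np.clip(np.array([edu_mean[e] for e in edu])
                      + config.completion_sd * rng.standard_normal(n),
                      *config.completion_range).round(1)

    race = rng.choice(("white", "black", "other"), size=n, p=(0.83, 0.08, 0.09))
    marital = rng.choice(("married_partnered", "other"), size=n, p=(0.678, 0.322))
    age = np.rint(56.9 + 11.3 * rng.standard_normal(n)).clip(28, 95)

    tiebreak = rng.random((n, 8)) * 1e-6
    all_goal_ids = goal_ids + list(PLACEHOLDER_GOALS)
    for i in range(n):
        rid = f"P{i + 1:04d}"
        gr = {}
        for j, gid in enumerate(goal_ids):
            if not goal_missing[i, j]:
                gr[gid] = int(ratings[i, j])
        for j, gid in enumerate(PLACEHOLDER_GOALS):
            if not ph_missing[i, j]:
                gr[gid] = int(ph_ratings[i, j])
        observed = [(gid, gr[gid] + tiebreak[i, k]) for k, gid in enumerate(all_goal_ids)
                    if gid in gr]
        top3 = tuple(gid for gid, _ in sorted(observed, key=lambda t: -t[1])[:3])
        records.append(RespondentRecord(
            respondent_id=rid, group="patient", wave="test",
            item_responses=responses[i], goal_ratings=gr,
            treatment=str(treatment[i]),
            stage="II" if stage2[i] else "I",
            preference=str(preference[i]),
            confidence=float(confidence[i]), regret=str(regret[i]),
            top3_goals=top3,
            completion_minutes=float(minutes[i]), education=str(edu[i]),
            demographics={"age": float(age[i]), "race": str(race[i]),
                          "marital": str(marital[i])},
        ))
        latents[rid] = {"trait": float(traits[i]),
                        "goals": goals_latent[i].copy(),
                        "placeholders": ph_latent[i].copy(),
                        "p_true": float(p_true[i])}

    # ---- providers and controls (knowledge section only)
    for group, count, prefix in (("provider", config.n_providers, "H"),
                                 ("control", config.n_controls, "C")):
        t = rng.standard_normal(count)
        resp = _draw_item_responses(rng, bank, items, t, group, config)
        _apply_item_missingness(rng, resp, bank, config)
        for i in range(count):
            rid = f"{prefix}{i + 1:04d}"
            demo = {}
            if group == "provider":
                demo["coverage_rating"] = int(rng.choice((1, 2, 3, 4),
                                                         p=(0.04, 0.20, 0.44, 0.32)))
                demo["age"] = float(np.rint(45 + 9 * rng.standard_normal()))
            else:
                demo["age"] = float(np.rint(42.4 + 10.9 * rng.standard_normal()))
            records.append(RespondentRecord(
                respondent_id=rid, group=group, wave="test",
                item_responses=resp[i],
                education=str(rng.choice(edu_levels, p=(0.0, 0.229, 0.771)))
                if group == "control" else None,
                demographics=demo))
            latents[rid] = {"trait": float(t[i])}

    return Cohort(records=records, item_bank=bank, goal_bank=goal_bank,
                  provenance={"source": "synthetic", "seed": int(seed),
                              "generator_version": GENERATOR_VERSION},
                  latents=latents)


def generate_retest(cohort: Cohort, config: GeneratorConfig, seed: int,
                    group: str = "patient") -> Cohort:
    """Retest wave for a patient subsample: same latent state, fresh noise.

    The retest survey was sent to patients only; asking for any other group is
    an error.  Knowledge responses are re-drawn conditional on the (possibly
    drifted) ability; goal ratings are re-measured around the latent goal
    vector with the per-goal wave noise.
    """
    if group != "patient":
        raise ValueError("retest waves are generated for patients only")
    if not cohort.latents:
        raise ValueError("cohort has no latent state; generate it with generate_cohort")
    rng = np.random.default_rng(seed)
    patients = [r for r in cohort.patients("test") if r.respondent_id in cohort.latents]
    if not patients:
        raise ValueError("no patients with retained latent traits")
    k = min(config.retest_n, len(patients))
    chosen = [patients[i] for i in rng.choice(len(patients), size=k, replace=False)]

    bank = cohort.item_bank
    items = list(bank)
    traits = np.array([cohort.latents[r.respondent_id]["trait"] for r in chosen])
    if config.trait_wave_sd > 0:
        drift = config.trait_wave_sd
        traits = (traits + drift * rng.standard_normal(k)) / math.sqrt(1.0 + drift ** 2)
    responses = _draw_item_responses(rng, bank, items, traits, "patient", config)
    _apply_item_missingness(rng, responses, bank, config)

    wave_sd = np.asarray(config.goal_wave_sd, dtype=float)
    ph_wave_sd = np.asarray(config.placeholder_wave_sd, dtype=float)
    records = []
    for i, src in enumerate(chosen):
        lat = cohort.latents[src.respondent_id]
        ratings = _discretize(lat["goals"] + wave_sd * rng.standard_normal(6))
        ph = _discretize(lat["placeholders"] + ph_wave_sd * rng.standard_normal(2))
        gr = {gid: int(v) for gid, v in zip(CANONICAL_GOALS, ratings)}
        gr.update({gid: int(v) for gid, v in zip(PLACEHOLDER_GOALS, ph)})
        # retest goal missingness mirrors the test wave's base rate
        for gid in list(gr):
            if rng.random() < config.goal_missing_rate:
                del gr[gid]
        records.append(RespondentRecord(
            respondent_id=src.respondent_id, group="patient", wave="retest",
            item_responses=responses[i], goal_ratings=gr,
            treatment=src.treatment, stage=src.stage, preference=src.preference,
            education=src.education, demographics=dict(src.demographics)))
    return Cohort(records=records, item_bank=bank, goal_bank=cohort.goal_bank,
                  provenance={"source": "synthetic", "seed": int(seed),
                              "generator_version": GENERATOR_VERSION,
                              "wave": "retest"})


# ---------------------------------------------------------------------------
# calibration


def _measure(config: GeneratorConfig, names, n_seeds: int, base_seed: int) -> dict:
    """Monte-Carlo estimates of the named calibration summaries."""
    acc = {name: [] for name in names}
    need_retest = any(n.endswith("_icc") or n.startswith("goal_icc") for n in names)
    for s in range(n_seeds):
        cohort = generate_cohort(config, base_seed + s)
        bank = cohort.item_bank
        scores = {}
        for g in ("patient", "provider", "control"):
            vals = [score_respondent(r, bank, "reduced") for r in cohort.subset(g, "test")]
            vals = [v for v in vals if v is not None]
            scores[g] = float(np.mean(vals)) if vals else np.nan
        for g in ("patient", "provider", "control"):
            key = f"{g}_mean_knowledge"
            if key in acc:
                acc[key].append(scores[g])
        if "mastectomy_fraction" in acc:
            analyzable, _ = apply_exclusions(cohort)
            acc["mastectomy_fraction"].append(
                float(np.mean([r.treatment == "mastectomy" for r in analyzable])))
        if "keep_remove_corr" in acc:
            pairs = [(r.goal_ratings["keep_breast"], r.goal_ratings["remove_breast"])
                     for r in cohort.patients("test")
                     if "keep_breast" in r.goal_ratings and "remove_breast" in r.goal_ratings]
            a, b = map(np.asarray, zip(*pairs))
            acc["keep_remove_corr"].append(float(pearsonr(a, b)[0]))
        if need_retest:
            retest = generate_retest(cohort, config, base_seed + 10_000 + s)
            from .psychometrics import retest_report
            rep = retest_report(cohort, retest).set_index("measure")["icc"]
            if "knowledge_icc" in acc:
                acc["knowledge_icc"].append(float(rep["knowledge_full"]))
            for gid in CANONICAL_GOALS:
                key = f"goal_icc_{gid}"
                if key in acc:
                    acc[key].append(float(rep[f"goal_{gid}"]))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def calibrate_generator(config: GeneratorConfig, targets: dict, *,
                        n_seeds: int = 20, max_iter: int = 30,
                        base_seed: int = 20_000) -> tuple:
    """Coordinate search tuning free generator parameters to named targets.

    ``targets`` maps a summary name to ``(value, tolerance)``.  Supported
    summaries: ``{patient,provider,control}_mean_knowledge`` (adjusts the
    synthetic, non-screener item profiles), ``knowledge_icc`` (ability
    loading), ``mastectomy_fraction`` (model intercept), ``keep_remove_corr``
    (latent correlation) and ``goal_icc_<goal_id>`` (per-goal wave noise).
    Returns ``(calibrated_config, calibration_log)``; raises if any target is
    still outside tolerance after ``max_iter`` rounds, naming the worst
    offender.
    """
    cfg = config.copy()
    free_items = [iid for iid, it in ((i.item_id, i) for i in default_item_bank())
                  if it.in_reduced_set and not it.in_screener]
    goal_index = {gid: j for j, gid in enumerate(CANONICAL_GOALS)}
    logbook = []
    for it_round in range(1, max_iter + 1):
        est = _measure(cfg, list(targets), n_seeds, base_seed + 100 * it_round)
        errors = {k: est[k] - targets[k][0] for k in targets}
        logbook.append({"iteration": it_round, "estimates": est,
                        "errors": {k: round(v, 4) for k, v in errors.items()}})
        if all(abs(errors[k]) <= targets[k][1] for k in targets):
            log.info("calibration converged after %d iterations", it_round)
            return cfg, logbook
        for name, (target, tol) in targets.items():
            err = errors[name]
            if abs(err) <= tol:
                continue
            if name.endswith("_mean_knowledge"):
                group = name.split("_")[0]
                step = -err / 100.0 * (12.0 / max(len(free_items), 1)) * 0.9
                for iid in free_items:
                    p = cfg.item_profiles[iid][group]
                    cfg.item_profiles[iid][group] = float(np.clip(p + step, 0.02, 0.995))
            elif name == "knowledge_icc":
                lam2 = float(np.clip(cfg.item_loading ** 2 - 0.8 * err, 0.01, 0.95))
                cfg.item_loading = math.sqrt(lam2)
            elif name == "mastectomy_fraction":
                cfg.treat_intercept += float(logit(np.clip(target, 0.01, 0.99))
                                             - logit(np.clip(est[name], 0.01, 0.99)))
            elif name == "keep_remove_corr":
                corr = np.asarray(cfg.goal_corr, dtype=float)
                corr[0, 1] = corr[1, 0] = float(np.clip(corr[0, 1] - err, -0.95, 0.95))
                cfg.goal_corr = tuple(map(tuple, corr))
            elif name.startswith("goal_icc_"):
                gid = name[len("goal_icc_"):]
                j = goal_index[gid]
                e, t = np.clip(est[name], 0.02, 0.98), np.clip(target, 0.02, 0.98)
                factor = math.sqrt(((1 - t) / t) * (e / (1 - e)))
                ws = list(cfg.goal_wave_sd)
                ws[j] = float(np.clip(ws[j] * factor, 0.01, 10.0))
                cfg.goal_wave_sd = tuple(ws)
            else:
                raise KeyError(f"unsupported calibration target {name!r}")
        try:
            cfg.validate()
        except ValueError:
            # correlation nudge broke positive semi-definiteness: shrink it back
            corr = np.asarray(cfg.goal_corr, dtype=float)
            cfg.goal_corr = tuple(map(tuple, 0.95 * corr + 0.05 * np.eye(len(corr))))
    worst = max(targets, key=lambda k: abs(logbook[-1]["errors"][k]) / max(targets[k][1], 1e-9))
    raise RuntimeError(
        f"calibration failed after {max_iter} iterations; worst offender {worst!r}: "
        f"estimate error {logbook[-1]['errors'][worst]} vs tolerance {targets[worst][1]}")
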