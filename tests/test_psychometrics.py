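import numpy as np
import pytest
from scipy import stats

import dqscore as dq
from dqscore.cohort import Cohort, RespondentRecord
from dqscore.psychometrics import (content_validity, dichotomize_regret,
                                   discriminant_validity, feasibility_report,
                                   icc, predictive_validity, preference_gradient,
                                   retest_report)


# ---------------------------------------------------------------------------
# ICC estimator


def _icc_oracle(x, y):
    """Explicit two-way ANOVA decomposition, independent of the implementation."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - data.mean(axis=1, keepdims=True)
            - data.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + mse + 2 * (msc - mse) / n)


def test_icc_identical_vectors_is_one():
    x = np.array([10.0, 30.0, 50.0, 70.0])
    assert icc(x, x) == pytest.approx(1.0)


def test_icc_independent_noise_is_near_zero():
    rng = np.random.default_rng(1)
    assert abs(icc(rng.normal(size=500), rng.normal(size=500))) < 0.1


def test_icc_matches_anova_oracle_on_hand_table():
    x, y = [1.0, 3.0, 5.0, 7.0], [2.0, 3.0, 4.0, 8.0]
    assert icc(x, y) == pytest.approx(_icc_oracle(x, y), abs=1e-12)


def test_icc_matches_pingouin_two_way_random_single():
    pg = pytest.importorskip("pingouin")
    import pandas as pd
    rng = np.random.default_rng(2)
    latent = rng.normal(50, 10, 60)
    x = latent + rng.normal(0, 5, 60)
    y = latent + rng.normal(0, 5, 60)
    df = pd.DataFrame({
        "targets": np.tile(np.arange(60), 2),
        "raters": np.repeat(["t", "r"], 60),
        "score": np.concatenate([x, y])})
    ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="score")
    # two-way random effects, absolute agreement, single rater
    labels = ref["Type"].astype(str)
    row = ref[(labels == "ICC2") | (labels == "ICC(A,1)")]
    assert icc(x, y) == pytest.approx(float(row["ICC"].iloc[0]), abs=1e-9)


def test_icc_symmetric_in_wave_labels():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=30), rng.normal(size=30)
    assert icc(x, y) == pytest.approx(icc(y, x))


def test_icc_requires_three_complete_pairs():
    with pytest.raises(ValueError, match="at least 3"):
        icc([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="complete"):
        icc([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
def test_icc_parameter_recovery(rho):
    """Simulated reliability rho, n=300, 50 reps: mean estimate within 0.04."""
    rng = np.random.default_rng(int(rho * 100))
    ests = []
    for _ in range(50):
        latent = rng.normal(0, np.sqrt(rho), 300)
        noise_sd = np.sqrt(1 - rho)
        ests.append(icc(latent + rng.normal(0, noise_sd, 300),
                        latent + rng.normal(0, noise_sd, 300)))
    assert np.mean(ests) == pytest.approx(rho, abs=0.04)


# ---------------------------------------------------------------------------
# retest report


def test_retest_report_perfect_stability_gives_icc_one(small_cohort, small_config):
    cfg = small_config
    retest = dq.generate_retest(small_cohort, cfg, seed=99)
    # overwrite retest goal ratings with the test-wave values
    test = {r.respondent_id: r for r in small_cohort.patients("test")}
    for r in retest.records:
        r.goal_ratings = dict(test[r.respondent_id].goal_ratings)
    rep = retest_report(small_cohort, retest).set_index("measure")
    assert rep.loc["goal_keep_breast", "icc"] == pytest.approx(1.0)
    assert bool(rep.loc["goal_keep_breast", "meets_target"])


def test_retest_report_requires_linked_pairs(small_cohort):
    empty = Cohort(records=[], item_bank=small_cohort.item_bank,
                   goal_bank=small_cohort.goal_bank)
    with pytest.raises(ValueError, match="pairs"):
        retest_report(small_cohort, empty)


def test_screener_icc_below_full_icc(default_cohort, default_retest):
    """Fewer items -> noisier score -> lower retest reliability."""
    rep = retest_report(default_cohort, default_retest).set_index("measure")
    assert rep.loc["knowledge_screener", "icc"] < rep.loc["knowledge_full", "icc"]


# ---------------------------------------------------------------------------
# content validity


def test_provider_coverage_pass():
    # 67 of 88 providers rating 3-4 -> 76.1%, above the 70% target
    ratings = [3] * 40 + [4] * 27 + [2] * 15 + [1] * 6
    out = content_validity(ratings, [], dq.default_goal_bank())
    assert out["provider_coverage_pct"] == pytest.approx(76.1, abs=0.05)
    assert out["provider_coverage_pass"]


def test_goal_top3_pass_and_fail():
    goals = dq.default_goal_bank()
    patients = []
    for i in range(100):
        top = ("keep_breast", "avoid_recurrence", "remove_breast")
        if i < 16:  # only 16% pick the hassle goal
            top = ("keep_breast", "avoid_recurrence", "avoid_radiation_hassle")
        patients.append(RespondentRecord(
            f"p{i}", "patient", top3_goals=top,
            treatment="mastectomy" if i % 3 == 0 else "lumpectomy"))
    out = content_validity([], patients, goals)
    assert out["goals"]["keep_breast"]["top3_pct"] == 100.0
    assert out["goals"]["keep_breast"]["pass"]
    assert not out["goals"]["avoid_radiation_hassle"]["pass"]


def test_content_validity_on_calibrated_cohort(default_cohort):
    ratings = [r.demographics.get("coverage_rating") for r in default_cohort.providers()]
    out = content_validity(ratings, default_cohort.patients("test"),
                           default_cohort.goal_bank)
    assert out["provider_coverage_pct"] == pytest.approx(76, abs=10)
    # recurrence goal has near-ceiling importance: always selected
    assert out["goals"]["avoid_recurrence"]["top3_pct"] > 50
    # hassle-of-radiation is the weak goal, as in the validation study
    assert out["goals"]["avoid_radiation_hassle"]["top3_pct"] < 20


# ---------------------------------------------------------------------------
# discriminant validity


def test_group_discrimination_on_calibrated_cohort(default_cohort):
    ss = dq.score_cohort(default_cohort, "reduced")
    rep = discriminant_validity(ss, default_cohort)
    contrast = rep["knowledge"]["provider_gt_patient"]
    assert contrast["diff"] == pytest.approx(35.0, abs=5.0)
    assert contrast["p_one_sided"] < 0.001
    assert rep["knowledge"]["anova"]["p"] < 0.001
    # patients vs controls: small, same-direction difference
    assert rep["knowledge"]["patient_gt_control"]["diff"] == pytest.approx(3.4, abs=8)
    # each goal separates the arms in its declared direction
    goals = rep["goals"]
    assert goals["avoid_radiation"]["p_one_sided"] < 1e-4
    assert goals["keep_breast"]["p_one_sided"] < 1e-4
    assert all(g["direction_as_expected"] for g in goals.values()
               if g["p_one_sided"] < 0.01)


def test_identical_groups_not_significant():
    rng = np.random.default_rng(5)
    import pandas as pd
    scores = pd.DataFrame({
        "respondent_id": [f"r{i}" for i in range(90)],
        "group": ["provider"] * 30 + ["patient"] * 30 + ["control"] * 30,
        "wave": "test",
        "score": rng.normal(50, 10, 90),
        "n_answered": 12})
    ss = dq.ScoreSet(item_set="reduced", scores=scores, group_summary=None, histograms={})
    cohort = Cohort(records=[], item_bank=dq.default_item_bank(),
                    goal_bank=dq.default_goal_bank())
    rep = discriminant_validity(ss, cohort)
    assert rep["knowledge"]["anova"]["p"] > 0.05


def test_one_sided_p_is_half_of_two_sided_when_direction_matches():
    rng = np.random.default_rng(6)
    a = rng.normal(6, 2, 80)
    b = rng.normal(5, 2, 80)
    t2, p2 = stats.ttest_ind(a, b, equal_var=False)
    t1, p1 = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    assert t2 > 0
    assert p1 == pytest.approx(p2 / 2)


# ---------------------------------------------------------------------------
# preference gradient


def test_preference_gradient_on_calibrated_cohort(default_cohort):
    from dqscore.pipeline import run_concordance
    conc = run_concordance(default_cohort)
    out = preference_gradient(conc["result"],
                              [r.preference for r in conc["analyzable"]])
    m = out["means"]
    assert m["mastectomy"] > m["not_sure"] > m["lumpectomy_radiation"]
    assert out["anova"]["p"] < 1e-4
    assert all(c["p_one_sided"] < 1e-4 for c in out["contrasts"].values())


def test_preference_gradient_null_when_independent():
    rng = np.random.default_rng(7)
    import pandas as pd
    probs = rng.random(300)
    res = dq.ConcordanceResult(
        per_patient=pd.DataFrame({"respondent_id": range(300), "treatment": "lumpectomy",
                                  "p_mastectomy": probs, "concordant": True}),
        overall_pct=100.0, by_arm_pct={}, n_analyzable=300)
    prefs = rng.choice(["mastectomy", "not_sure", "lumpectomy_radiation"], 300)
    out = preference_gradient(res, prefs)
    assert out["anova"]["p"] > 0.01


def test_preference_gradient_single_level_errors():
    import pandas as pd
    res = dq.ConcordanceResult(
        per_patient=pd.DataFrame({"respondent_id": range(10), "treatment": "lumpectomy",
                                  "p_mastectomy": np.linspace(0, 1, 10), "concordant": True}),
        overall_pct=100.0, by_arm_pct={}, n_analyzable=10)
    with pytest.raises(ValueError, match="two preference levels"):
        preference_gradient(res, ["mastectomy"] * 10)


# ---------------------------------------------------------------------------
# predictive validity


def _cohort_with_confidence(conf_by_flag, n=200, seed=8):
    import pandas as pd
    rng = np.random.default_rng(seed)
    flags = rng.random(n) < 0.8
    records, rows = [], []
    for i, f in enumerate(flags):
        conf = float(np.clip(rng.normal(conf_by_flag[bool(f)], 1.2), 0, 10))
        regret = "probably_yes" if rng.random() < 0.88 else "probably_no"
        records.append(RespondentRecord(f"p{i}", "patient", treatment="lumpectomy",
                                        confidence=conf, regret=regret))
        rows.append({"respondent_id": f"p{i}", "treatment": "lumpectomy",
                     "p_mastectomy": 0.2, "concordant": bool(f)})
    cohort = Cohort(records=records, item_bank=dq.default_item_bank(),
                    goal_bank=dq.default_goal_bank())
    res = dq.ConcordanceResult(per_patient=pd.DataFrame(rows), overall_pct=0.0,
                               by_arm_pct={}, n_analyzable=n)
    return cohort, res


def test_confidence_difference_detected_when_injected():
    cohort, res = _cohort_with_confidence({True: 9.0, False: 6.0})
    out = predictive_validity(res, cohort)
    assert out["confidence"]["p"] < 0.001
    assert out["confidence"]["mean_concordant"] > out["confidence"]["mean_discordant"]


def test_no_difference_when_distributions_identical():
    cohort, res = _cohort_with_confidence({True: 9.1, False: 9.1}, n=400)
    out = predictive_validity(res, cohort)
    assert out["confidence"]["p"] > 0.05
    assert out["regret"]["p"] > 0.01


def test_regret_dichotomy():
    assert dichotomize_regret("definitely_yes") and dichotomize_regret("probably_yes")
    assert not dichotomize_regret("not_sure") and not dichotomize_regret("definitely_no")
    assert dichotomize_regret(None) is None


# ---------------------------------------------------------------------------
# feasibility


def test_feasibility_on_calibrated_cohort(default_cohort):
    out = feasibility_report(default_cohort)
    assert out["item_missing_mean_pct"] == pytest.approx(1.4, abs=0.7)
    assert out["goal_missing_pct"]["remove_breast"] == pytest.approx(10.9, abs=3.5)
    assert out["problematic"] == ["remove_breast"]
    assert out["completion_education_anova"]["p"] < 0.001
    means = out["completion_by_education"]
    assert means["hs_or_less"] > means["some_college"] > means["college_plus"]


def test_zero_missingness_gives_no_offenders():
    bank = dq.default_item_bank()
    resp = {}
    for it in bank:
        for key, part in zip(it.response_keys(), it.parts):
            resp[key] = part.correct if part.kind == "multiple_choice" else 85.0
    goals = {g.goal_id: 5 for g in dq.default_goal_bank()}
    records = [RespondentRecord(f"p{i}", "patient", item_responses=dict(resp),
                                goal_ratings=dict(goals)) for i in range(20)]
    out = feasibility_report(Cohort(records=records, item_bank=bank,
                                    goal_bank=dq.default_goal_bank()))
    assert out["problematic"] == []
    assert out["item_missing_mean_pct"] == 0.0
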