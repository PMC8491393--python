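import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matchscore.analysis import (
    DC_NO,
    DC_YES,
    NOT_EVALUABLE,
    classify_disease_control,
    dcr_contingency,
    feasibility_summary,
    fisher_exact_2x2,
    fit_models,
    grade_trend,
    km_median,
    logrank,
    power_exact,
    power_normal_approx,
    power_simulation,
    roc_cutoff,
    sensitivity_exclude_tp53,
)
from matchscore.cohort import Cohort, PatientRecord, ResponseRecord, SurvivalRecord, score_cohort
from matchscore.scoring import BiomarkerProfile, TreatmentPlan, assign_grade
from matchscore.simulate import SimulationParams, simulate_cohort


# ---------------------------------------------------------------------------
# disease control

@pytest.mark.parametrize("response, expected", [
    (ResponseRecord("CR"), DC_YES),
    (ResponseRecord("PR"), DC_YES),
    (ResponseRecord("SD", sd_duration_months=7.2), DC_YES),
    (ResponseRecord("SD", sd_duration_months=6.0), DC_YES),
    (ResponseRecord("SD", sd_duration_months=3.0, sd_ongoing=True), NOT_EVALUABLE),
    (ResponseRecord("SD", sd_duration_months=3.0, sd_ongoing=False), DC_NO),
    (ResponseRecord("PD"), DC_NO),
    (ResponseRecord("too_early"), NOT_EVALUABLE),
    (ResponseRecord("not_evaluable"), NOT_EVALUABLE),
])
def test_classify_disease_control(response, expected):
    assert classify_disease_control(response) == expected


def test_sd_without_duration_is_an_error():
    with pytest.raises(ValueError, match="duration"):
        classify_disease_control(ResponseRecord("SD"))


# ---------------------------------------------------------------------------
# Fisher exact

def fisher_oracle(table):
    """Exhaustive hypergeometric enumeration with the two-sided <= observed rule."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c

    def pr(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = pr(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(pr(x) for x in range(lo, hi + 1) if pr(x) <= p_obs * (1 + 1e-9))


@settings(max_examples=150, derandomize=True)
@given(st.tuples(*[st.integers(min_value=0, max_value=15)] * 4))
def test_fisher_matches_enumeration_oracle(cells):
    a, b, c, d = cells
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return  # degenerate margins: hypergeometric support is a single table
    table = [[a, b], [c, d]]
    assert fisher_exact_2x2(table) == pytest.approx(fisher_oracle(table), abs=1e-9)


def test_identical_proportions_give_p_one():
    assert fisher_exact_2x2([[10, 10], [10, 10]]) == pytest.approx(1.0)


def test_dcr_contingency_strata(demo_cohort, kb):
    cohort, _ = score_cohort(demo_cohort, kb)
    res = dcr_contingency(cohort, "ge60_vs_lt60")
    # evaluable: P1 PR, P2 SD 8mo, P3 CR, P4 PD, P5 SD 3mo ended; P6 ongoing SD <6mo excluded
    assert res["strata"]["ge60"] == {"dc": 2, "no_dc": 0, "n": 2, "rate": 1.0}
    assert res["strata"]["lt60"] == {"dc": 1, "no_dc": 2, "n": 3, "rate": pytest.approx(1 / 3)}
    assert res["fisher_p"] == pytest.approx(fisher_oracle(res["table"]), abs=1e-9)


# ---------------------------------------------------------------------------
# ROC

def test_perfect_separation_auc_one():
    res = roc_cutoff([10, 20, 80, 90], [False, False, True, True])
    assert res["auc"] == 1.0
    assert res["cutoff"] == 80


def test_auc_equals_scaled_mann_whitney_u():
    rng = np.random.default_rng(7)
    scores = rng.integers(0, 10, size=60).astype(float)  # heavy ties on purpose
    labels = rng.random(60) < 0.4
    if labels.all() or (~labels).all():
        pytest.skip("degenerate draw")
    from scipy.stats import mannwhitneyu
    u = mannwhitneyu(scores[labels], scores[~labels], alternative="two-sided").statistic
    expected = u / (labels.sum() * (~labels).sum())
    assert roc_cutoff(scores, labels)["auc"] == pytest.approx(expected, abs=1e-12)


def test_independent_labels_auc_near_half():
    rng = np.random.default_rng(11)
    scores = rng.random(4000)
    labels = rng.random(4000) < 0.5
    assert roc_cutoff(scores, labels)["auc"] == pytest.approx(0.5, abs=0.03)


def test_youden_ties_break_toward_higher_cutoff():
    # cutoffs 2 and 4 both reach J = 0.5; the higher one must win
    res = roc_cutoff([1, 2, 3, 4], [False, True, False, True])
    table = res["per_cutoff_table"].set_index("cutoff")["youden_j"]
    assert table[2.0] == pytest.approx(0.5) and table[4.0] == pytest.approx(0.5)
    assert res["cutoff"] == 4


def test_single_class_input_raises():
    with pytest.raises(ValueError):
        roc_cutoff([1, 2, 3], [True, True, True])


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank

def test_km_no_censoring_reduces_to_sample_median():
    _, median = km_median([1, 2, 3, 4, 5], [True] * 5)
    assert median == 3


def test_km_all_censored_is_not_reached():
    _, median = km_median([1, 2, 3], [False] * 3)
    assert median is None


def test_km_matches_hand_computed_product_limit_table():
    # subjects: 1, 2+, 3, 4, 4+, 5  (+ = censored)
    times = [1, 2, 3, 4, 4, 5]
    events = [True, False, True, True, False, True]
    curve, median = km_median(times, events)
    lookup = dict(zip(curve["time"], curve["survival"]))
    assert lookup[1.0] == pytest.approx(5 / 6)
    assert lookup[3.0] == pytest.approx(5 / 6 * 3 / 4)
    assert lookup[4.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
    assert median == 4  # earliest time the curve falls to <= 0.5


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(3)
    times = np.round(rng.exponential(5, size=80), 1)
    curve, _ = km_median(times, [True] * 80)
    for t, s in zip(curve["time"], curve["survival"]):
        assert s == pytest.approx((times > t).mean(), abs=1e-12)


def test_logrank_duplicated_dataset_gives_zero_statistic():
    times, events = [1, 3, 5, 7, 9], [True, True, False, True, True]
    res = logrank({"a": (times, events), "b": (times, events)})
    assert res["statistic"] == pytest.approx(0, abs=1e-9)
    assert res["p"] == pytest.approx(1, abs=1e-9)


def test_logrank_detects_strong_separation():
    rng = np.random.default_rng(5)
    fast = rng.exponential(1, 60)
    slow = rng.exponential(8, 60)
    res = logrank({"fast": (fast, [True] * 60), "slow": (slow, [True] * 60)})
    assert res["p"] < 1e-6


def test_logrank_requires_two_nonempty_strata():
    with pytest.raises(ValueError):
        logrank({"a": ([1, 2], [True, True])})


# ---------------------------------------------------------------------------
# regression models

def test_entry_rule_and_null_covariate_behavior(kb):
    sim = simulate_cohort(SimulationParams(seed=42), kb=kb)
    res = fit_models(sim.cohort, "dcr")
    # the multivariate covariate set is exactly the univariate p < 0.15 set
    expected = [c for c, r in res["univariate"].items() if r["p"] < 0.15]
    assert res["entered"] == expected
    if res["multivariate"]:
        assert set(res["multivariate"]) == set(res["entered"])
    # sex is generated independently of outcome: OR near 1, not entered
    male = res["univariate"].get("male")
    if male is not None:
        assert 0.3 < male["estimate"] < 3.5
        assert math.isfinite(male["p"])
    for endpoint in ("pfs", "os"):
        cox = fit_models(sim.cohort, endpoint)
        assert "high_score" in cox["univariate"]
        hs = cox["univariate"]["high_score"]
        assert hs["ci_low"] <= hs["estimate"] <= hs["ci_high"]
        assert hs["measure"] == "HR"


# ---------------------------------------------------------------------------
# grade trend

def _trend_cohort(dc_rates, pfs_medians, n_per_grade=10):
    """Patients with manually assigned grades and outcomes, one block per fine grade."""
    scores = [0, 20, 50, 80, 100]
    patients = []
    for g, (rate, med) in enumerate(zip(dc_rates, pfs_medians)):
        n_dc = round(rate * n_per_grade)
        for i in range(n_per_grade):
            response = (ResponseRecord("PR") if i < n_dc else ResponseRecord("PD"))
            p = PatientRecord(
                patient_id=f"G{g}_{i}", treated=True,
                treatment=TreatmentPlan(frozenset({"gemcitabine"})),
                biomarkers=BiomarkerProfile(),
                response=response,
                survival=SurvivalRecord(med, True, med * 2, True))
            p.grade = assign_grade(scores[g])
            patients.append(p)
    return Cohort(patients=patients)


def test_exactly_linear_trend_gives_r2_one():
    cohort = _trend_cohort([0.1, 0.3, 0.5, 0.7, 0.9], [2, 4, 6, 8, 10])
    res = grade_trend(cohort)
    assert res["dcr"]["r2"] == pytest.approx(1.0, abs=1e-9)
    assert res["pfs"]["r2"] == pytest.approx(1.0, abs=1e-9)


def test_constant_rate_reports_undefined_correlation():
    cohort = _trend_cohort([0.5] * 5, [5] * 5)
    res = grade_trend(cohort)
    assert res["dcr"]["r2"] is None and res["dcr"]["note"] == "zero variance"


def test_fewer_than_three_grades_is_an_error():
    cohort = _trend_cohort([0.2, 0.8], [2, 8])  # only two blocks
    # keep only two populated grades
    cohort = Cohort(patients=[p for p in cohort.patients
                              if p.grade.fine.value in ("g0", "g100")])
    with pytest.raises(ValueError, match="3 populated"):
        grade_trend(cohort)


def test_simulated_linear_design_recovers_strong_trend(kb):
    # five-bin design with monotone DC probabilities via the stratum model
    sim = simulate_cohort(SimulationParams(n_patients=500, seed=9), kb=kb)
    res = grade_trend(sim.cohort)
    assert res["dcr"]["n_grades"] >= 3


# ---------------------------------------------------------------------------
# TP53 sensitivity

def test_tp53_sensitivity_excludes_and_rescores(demo_cohort, kb):
    cohort, _ = score_cohort(demo_cohort, kb)
    res = sensitivity_exclude_tp53(cohort, kb)
    assert res["excluded_ids"] == ["P5"]
    # rescoring the excluded patient with the rule disabled drops them to 0
    p5 = next(p for p in cohort.treated if p.patient_id == "P5")
    from matchscore.scoring import matching_score
    rescored = matching_score(p5.alterations, p5.biomarkers, p5.treatment,
                              kb.with_rule_disabled("tp53_vegf"))
    assert rescored.score == 0


def test_tp53_sensitivity_is_noop_without_tp53_matches(demo_cohort, kb):
    cohort, _ = score_cohort(demo_cohort, kb)
    no_tp53 = Cohort(patients=[p for p in cohort.patients if p.patient_id != "P5"])
    res = sensitivity_exclude_tp53(no_tp53, kb)
    assert res["n_excluded"] == 0
    assert res["dcr"]["strata"] == dcr_contingency(no_tp53, "ge60_vs_lt60")["strata"]


# ---------------------------------------------------------------------------
# power

def test_power_null_size_matches_exact_enumeration():
    sim = power_simulation(20, 30, 0.3, 0.3, alpha=0.05, reps=4000, seed=12)
    exact = power_exact(20, 30, 0.3, 0.3, alpha=0.05)
    assert exact <= 0.05  # the exact conditional test never exceeds its level
    assert abs(sim["power"] - exact) < 3 * max(sim["se"], 1e-3)


def test_power_simulation_matches_exact_enumeration_under_alternative():
    sim = power_simulation(15, 30, 0.7, 0.3, alpha=0.05, reps=4000, seed=12)
    exact = power_exact(15, 30, 0.7, 0.3, alpha=0.05)
    assert abs(sim["power"] - exact) < 3 * max(sim["se"], 1e-3)


def test_power_rejects_invalid_proportions():
    with pytest.raises(ValueError):
        power_simulation(10, 10, 0.0, 0.5)


def test_normal_approximation_is_monotone_in_n():
    lo = power_normal_approx(20, 40, 0.65, 0.30)
    hi = power_normal_approx(40, 80, 0.65, 0.30)
    assert hi > lo


# ---------------------------------------------------------------------------
# feasibility

def test_feasibility_three_of_six_matched(demo_cohort, kb):
    cohort, _ = score_cohort(demo_cohort, kb)
    # demo: P1, P2, P3, P5, P6 matched (score > 0); P4 unmatched
    res = feasibility_summary(cohort)
    assert res["matched_of_treated"]["count"] == 5
    assert res["matched_of_treated"]["n"] == 6
    lo, hi = res["matched_of_treated"]["ci_low"], res["matched_of_treated"]["ci_high"]
    assert lo <= 5 / 6 <= hi
    assert res["score_bin_counts"]["g0"] == 1
    assert res["score_bin_counts"]["g100"] == 1


def test_feasibility_all_unmatched(demo_cohort, kb):
    cohort, _ = score_cohort(demo_cohort, kb)
    for p in cohort.treated:  # pretend nothing matched
        p.breakdown.score = type(p.breakdown.score)(0)
        p.grade = assign_grade(0)
    res = feasibility_summary(cohort)
    assert res["matched_of_treated"]["count"] == 0
    assert res["matched_of_treated"]["proportion"] == 0
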