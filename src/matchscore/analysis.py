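"""Trial-style outcome analyses for a scored cohort.

Covers the analyses run against the Matching Score in an N-of-1 combination
trial: disease-control classification (SD ≥ 6 months or PR/CR), Fisher exact
contingency comparisons across score strata, ROC-based cutoff selection,
Kaplan–Meier medians and log-rank comparisons, logistic and Cox models with a
univariate P < 0.15 entry rule, the grade-trend correlation, the TP53→VEGF
sensitivity analysis, the two-arm Fisher power simulation, and the feasibility
summary. No multiple-testing correction is applied anywhere, matching common
exploratory trial practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, PatientRecord, ResponseRecord
from .knowledge_base import KnowledgeBase, SpecialRuleId
from .scoring import FineGrade, PrimaryStratum, AlternateStratum

logger = logging.getLogger(__name__)

__all__ = [
    "classify_disease_control",
    "dcr_contingency",
    "roc_cutoff",
    "km_median",
    "logrank",
    "fit_models",
    "grade_trend",
    "sensitivity_exclude_tp53",
    "power_simulation",
    "power_normal_approx",
    "feasibility_summary",
    "analyze_cohort",
]

DC_YES, DC_NO, NOT_EVALUABLE = "dc_yes", "dc_no", "not_evaluable"

# tumor-type covariate groupings used in the regression models
GI_HPB_TYPES = frozenset({"colorectal", "gastrointestinal_non_colorectal",
                          "appendiceal", "hepatobiliary", "pancreatic"})


def classify_disease_control(response: ResponseRecord) -> str:
    """Disease control = SD ≥ 6 months or PR/CR.

    SD that is still ongoing below 6 months cannot yet be classified and is
    excluded from evaluability, as is a too-early or non-evaluable response.
    """
    r = response.best_response
    if r in ("CR", "PR"):
        return DC_YES
    if r == "PD":
        return DC_NO
    if r == "SD":
        if response.sd_duration_months is None:
            raise ValueError("SD response requires sd_duration_months")
        if response.sd_duration_months >= 6:
            return DC_YES
        return NOT_EVALUABLE if response.sd_ongoing else DC_NO
    return NOT_EVALUABLE  # not_evaluable, too_early


def _dc_status(p: PatientRecord) -> str:
    if p.response is None:
        return NOT_EVALUABLE
    return classify_disease_control(p.response)


def _stratum_label(p: PatientRecord, stratification: str) -> str:
    if p.grade is None:
        raise ValueError(f"patient {p.patient_id!r} is unscored; run score_cohort first")
    if stratification == "ge60_vs_lt60":
        return "ge60" if p.grade.primary is PrimaryStratum.GE60 else "lt60"
    if stratification == "three_group":
        return p.grade.primary.value
    if stratification == "gt50_vs_le50":
        return p.grade.alternate.value
    if stratification == "fine":
        return p.grade.fine.value
    raise ValueError(f"unknown stratification {stratification!r}")


STRATUM_ORDER = {
    "ge60_vs_lt60": ["ge60", "lt60"],
    "three_group": ["ge60", "s1_59", "unmatched"],
    "gt50_vs_le50": ["gt50", "le50"],
    "fine": [g.value for g in FineGrade],
}


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric table probabilities ≤ observed."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def dcr_contingency(cohort: Cohort, stratification: str = "ge60_vs_lt60") -> dict:
    """Disease-control counts and rates per stratum, with Fisher exact p-values.

    Only DC-evaluable patients enter the table. For two strata a single 2×2
    Fisher p is reported (with the logistic-regression p as a labelled
    alternative); for more strata, all pairwise Fisher p-values.
    """
    strata: dict[str, list[str]] = {}
    for p in cohort.treated:
        status = _dc_status(p)
        if status is NOT_EVALUABLE or status == NOT_EVALUABLE:
            continue
        strata.setdefault(_stratum_label(p, stratification), []).append(status)
    order = [s for s in STRATUM_ORDER[stratification] if s in strata]
    if any(len(v) == 0 for v in strata.values()) or not order:
        raise ValueError("every stratum must contain at least one evaluable patient")
    result = {"stratification": stratification, "strata": {}}
    for label in order:
        dc = sum(1 for s in strata[label] if s == DC_YES)
        n = len(strata[label])
        result["strata"][label] = {"dc": dc, "no_dc": n - dc, "n": n, "rate": dc / n}
    if len(order) == 2:
        a, b = order
        table = [[result["strata"][a]["dc"], result["strata"][a]["no_dc"]],
                 [result["strata"][b]["dc"], result["strata"][b]["no_dc"]]]
        result["table"] = table
        result["fisher_p"] = fisher_exact_2x2(table)
        result["logistic_p"] = _binary_logistic_p(strata, a, b)
    else:
        result["pairwise_fisher_p"] = {}
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                table = [[result["strata"][a]["dc"], result["strata"][a]["no_dc"]],
                         [result["strata"][b]["dc"], result["strata"][b]["no_dc"]]]
                result["pairwise_fisher_p"][f"{a}_vs_{b}"] = fisher_exact_2x2(table)
    return result


def _binary_logistic_p(strata: dict[str, list[str]], a: str, b: str) -> Optional[float]:
    """Wald p from a binary logistic regression of DC on stratum membership."""
    import statsmodels.api as sm

    import warnings

    y = [1 if s == DC_YES else 0 for s in strata[a]] + \
        [1 if s == DC_YES else 0 for s in strata[b]]
    x = [1.0] * len(strata[a]) + [0.0] * len(strata[b])
    X = sm.add_constant(np.asarray(x))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # advisory p only; tiny tables may separate
            fit = sm.Logit(np.asarray(y), X).fit(disp=0)
        p = float(fit.pvalues[1])
        return p if math.isfinite(p) else None
    except Exception:  # separation / non-convergence: logistic p is advisory only
        return None


# ---------------------------------------------------------------------------
# ROC cutoff

def roc_cutoff(scores: Sequence[float], dc_flags: Sequence[bool]) -> dict:
    """ROC of the score against disease control, with Youden-optimal cutoff.

    AUC uses the rank (midrank-tied Mann–Whitney) definition. Candidate cutoffs
    are the observed score values; the selected cutoff maximizes Youden's J
    (sensitivity + specificity − 1), ties broken toward the higher cutoff. A
    max-rate-difference alternative is reported alongside, and the full
    per-cutoff table is returned for audit.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(dc_flags, dtype=bool)
    if flags.all() or (~flags).all():
        raise ValueError("both outcome classes must be present")
    auc = float(roc_auc_score(flags.astype(int), scores))
    n_pos, n_neg = int(flags.sum()), int((~flags).sum())
    rows = []
    for cut in np.unique(scores):
        high = scores >= cut
        tp = int((high & flags).sum())
        fp = int((high & ~flags).sum())
        sens = tp / n_pos
        spec = 1 - fp / n_neg
        rate_high = tp / high.sum() if high.any() else float("nan")
        rate_low = ((~high) & flags).sum() / (~high).sum() if (~high).any() else float("nan")
        rows.append({"cutoff": float(cut), "sensitivity": sens, "specificity": spec,
                     "youden_j": sens + spec - 1,
                     "rate_ge_cutoff": rate_high, "rate_lt_cutoff": rate_low,
                     "rate_difference": rate_high - rate_low
                     if not (math.isnan(rate_high) or math.isnan(rate_low)) else float("nan")})
    table = pd.DataFrame(rows)
    best_j = table["youden_j"].max()
    youden_cut = table.loc[table["youden_j"] >= best_j - 1e-12, "cutoff"].max()
    finite = table.dropna(subset=["rate_difference"])
    alt_cut = None
    if not finite.empty:
        best_d = finite["rate_difference"].max()
        alt_cut = float(finite.loc[finite["rate_difference"] >= best_d - 1e-12, "cutoff"].max())
    return {"auc": auc, "cutoff": float(youden_cut), "cutoff_criterion": "youden_j",
            "cutoff_max_rate_difference": alt_cut, "per_cutoff_table": table}


# ---------------------------------------------------------------------------
# survival

def km_median(times: Sequence[float], events: Sequence[bool],
              label: str = "KM") -> tuple[pd.DataFrame, Optional[float]]:
    """Product-limit curve and median (earliest time the curve reaches ≤ 0.5).

    Returns ``(curve, median)`` with ``median=None`` when the curve never
    reaches 0.5 ("not reached").
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(times, np.asarray(events, dtype=bool))
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    return curve, (None if math.isinf(median) else median)


def logrank(groups: dict[str, tuple[Sequence[float], Sequence[bool]]]) -> dict:
    """Log-rank test across ≥ 2 nonempty strata of (times, event flags)."""
    if len(groups) < 2 or any(len(t) == 0 for t, _ in groups.values()):
        raise ValueError("log-rank needs at least two nonempty strata")
    if not any(np.asarray(e, dtype=bool).any() for _, e in groups.values()):
        raise ValueError("no events in any stratum")
    times, events, labels = [], [], []
    for label, (t, e) in groups.items():
        times.extend(t)
        events.extend(np.asarray(e, dtype=bool))
        labels.extend([label] * len(t))
    res = multivariate_logrank_test(times, labels, events)
    return {"statistic": float(res.test_statistic), "p": float(res.p_value),
            "df": int(res.degrees_of_freedom)}


def survival_by_stratum(cohort: Cohort, endpoint: str,
                        stratification: str = "ge60_vs_lt60") -> dict:
    """KM medians per stratum plus the log-rank comparison for PFS or OS."""
    assert endpoint in ("pfs", "os")
    groups: dict[str, tuple[list, list]] = {}
    for p in cohort.treated:
        if p.survival is None:
            continue
        label = _stratum_label(p, stratification)
        t = p.survival.pfs_months if endpoint == "pfs" else p.survival.os_months
        e = p.survival.pfs_event if endpoint == "pfs" else p.survival.os_event
        groups.setdefault(label, ([], []))[0].append(t)
        groups[label][1].append(e)
    order = [s for s in STRATUM_ORDER[stratification] if s in groups]
    out = {"endpoint": endpoint, "stratification": stratification, "strata": {}}
    for label in order:
        t, e = groups[label]
        _, median = km_median(t, e, label=label)
        out["strata"][label] = {"n": len(t), "events": int(sum(e)), "median_months": median}
    if len(order) >= 2:
        out["logrank"] = logrank({k: groups[k] for k in order})
    return out


# ---------------------------------------------------------------------------
# regression models

MODEL_COVARIATES = ("high_score", "matched", "age_ge_median", "male",
                    "multi_drug", "gi_or_hpb", "cup", "breast")

UNIVARIATE_ENTRY_P = 0.15


def _covariate_frame(cohort: Cohort) -> pd.DataFrame:
    treated = [p for p in cohort.treated if p.grade is not None]
    ages = [p.age for p in treated if p.age is not None]
    age_median = float(np.median(ages)) if ages else float("nan")
    rows = []
    for p in treated:
        status = _dc_status(p)
        rows.append({
            "patient_id": p.patient_id,
            "dc": {DC_YES: 1, DC_NO: 0}.get(status, np.nan),
            "pfs_months": p.survival.pfs_months if p.survival else np.nan,
            "pfs_event": p.survival.pfs_event if p.survival else np.nan,
            "os_months": p.survival.os_months if p.survival else np.nan,
            "os_event": p.survival.os_event if p.survival else np.nan,
            "high_score": int(p.grade.primary is PrimaryStratum.GE60),
            "matched": int(p.grade.primary is not PrimaryStratum.UNMATCHED),
            "age_ge_median": (np.nan if p.age is None or math.isnan(age_median)
                              else int(p.age >= age_median)),
            "male": np.nan if p.sex is None else int(p.sex == "male"),
            "multi_drug": int(len(p.treatment.drugs) >= 2),
            "gi_or_hpb": int(p.tumor_type in GI_HPB_TYPES),
            "cup": int(p.tumor_type == "carcinoma_unknown_primary"),
            "breast": int(p.tumor_type == "breast"),
        })
    return pd.DataFrame(rows)


def _fit_logistic(df: pd.DataFrame, covariates: list[str]) -> dict:
    import warnings

    import statsmodels.api as sm

    data = df.dropna(subset=["dc"] + covariates)
    X = sm.add_constant(data[covariates].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(data["dc"].astype(float), X).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (possible separation)")
    ci = fit.conf_int()

    def _exp(v):
        with np.errstate(over="ignore"):
            out = float(np.exp(v))
        return out if math.isfinite(out) else None

    return {c: {"estimate": _exp(fit.params[c]),
                "ci_low": _exp(ci.loc[c, 0]), "ci_high": _exp(ci.loc[c, 1]),
                "p": float(fit.pvalues[c]), "measure": "OR", "n": int(len(data))}
            for c in covariates}


def _fit_cox(df: pd.DataFrame, covariates: list[str], endpoint: str) -> dict:
    dur, ev = f"{endpoint}_months", f"{endpoint}_event"
    data = df.dropna(subset=[dur, ev] + covariates)[[dur, ev] + covariates].astype(float)
    cph = CoxPHFitter()
    cph.fit(data, duration_col=dur, event_col=ev)  # Efron tie handling (lifelines default)
    summ = cph.summary
    return {c: {"estimate": float(summ.loc[c, "exp(coef)"]),
                "ci_low": float(summ.loc[c, "exp(coef) lower 95%"]),
                "ci_high": float(summ.loc[c, "exp(coef) upper 95%"]),
                "p": float(summ.loc[c, "p"]), "measure": "HR", "n": int(len(data))}
            for c in covariates}


def fit_models(cohort: Cohort, endpoint: str,
               covariates: Iterable[str] = MODEL_COVARIATES) -> dict:
    """Univariate screens plus one multivariate model per endpoint.

    ``endpoint``: ``"dcr"`` (logistic regression, odds ratios) or ``"pfs"`` /
    ``"os"`` (Cox partial likelihood with Efron ties, hazard ratios). Each
    candidate covariate is fit alone; those with univariate Wald P < 0.15 enter
    the single multivariate model. Separation or non-convergence is reported
    per covariate rather than aborting the batch.
    """
    if endpoint not in ("dcr", "pfs", "os"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = _covariate_frame(cohort)
    covariates = [c for c in covariates]
    fitter = (_fit_logistic if endpoint == "dcr"
              else lambda d, c: _fit_cox(d, c, endpoint))
    univariate, errors = {}, {}
    for cov in covariates:
        if df[cov].dropna().nunique() < 2:
            errors[cov] = "constant covariate"
            continue
        try:
            univariate[cov] = fitter(df, [cov])[cov]
        except Exception as exc:  # separation / non-convergence
            errors[cov] = str(exc)
    entered = [c for c, r in univariate.items() if r["p"] < UNIVARIATE_ENTRY_P]
    logger.info("%s: univariate p<%.2f entered multivariate: %s",
                endpoint, UNIVARIATE_ENTRY_P, entered or "none")
    multivariate = {}
    if entered:
        try:
            multivariate = fitter(df, entered)
        except Exception as exc:
            errors["__multivariate__"] = str(exc)
    return {"endpoint": endpoint, "univariate": univariate, "entered": entered,
            "multivariate": multivariate, "errors": errors,
            "entry_rule": f"univariate p < {UNIVARIATE_ENTRY_P}"}


# ---------------------------------------------------------------------------
# grade trend

def grade_trend(cohort: Cohort, x_encoding: str = "ordinal") -> dict:
    """Linear trend of DC rate and KM-median PFS against the five fine grades.

    Per populated fine grade, the DC rate (evaluable patients) and the
    KM-median PFS are computed and correlated (Pearson) with the grade's
    x-value: its ordinal index 0–4 by default, or the score-bin midpoint with
    ``x_encoding="midpoint"``. R² values are reported; grades whose PFS median
    is not reached are dropped from the PFS correlation (and listed). A
    constant outcome across grades has no defined correlation and is reported
    as ``None``.
    """
    if x_encoding not in ("ordinal", "midpoint"):
        raise ValueError(f"unknown x_encoding {x_encoding!r}")
    midpoints = {FineGrade.G0: 0.0, FineGrade.G1_39: 20.0, FineGrade.G40_59: 50.0,
                 FineGrade.G60_99: 80.0, FineGrade.G100: 100.0}
    per_grade = {}
    for g in FineGrade:
        members = [p for p in cohort.treated if p.grade is not None and p.grade.fine is g]
        if not members:
            continue
        statuses = [_dc_status(p) for p in members]
        evaluable = [s for s in statuses if s != NOT_EVALUABLE]
        dc_rate = (sum(1 for s in evaluable if s == DC_YES) / len(evaluable)
                   if evaluable else None)
        surv = [(p.survival.pfs_months, p.survival.pfs_event)
                for p in members if p.survival is not None]
        median = None
        if surv:
            _, median = km_median([t for t, _ in surv], [e for _, e in surv], label=g.value)
        per_grade[g] = {"n": len(members), "dc_rate": dc_rate, "median_pfs": median,
                        "x": g.ordinal if x_encoding == "ordinal" else midpoints[g]}
    if len(per_grade) < 3:
        raise ValueError("grade trend requires at least 3 populated fine grades")

    def corr(pairs):
        xs = [x for x, y in pairs if y is not None]
        ys = [y for _, y in pairs if y is not None]
        if len(xs) < 3:
            return {"r2": None, "p": None, "n_grades": len(xs), "note": "fewer than 3 points"}
        if len(set(ys)) == 1 or len(set(xs)) == 1:
            return {"r2": None, "p": None, "n_grades": len(xs), "note": "zero variance"}
        r, p = stats.pearsonr(xs, ys)
        return {"r2": float(r * r), "p": float(p), "n_grades": len(xs)}

    dcr_pairs = [(v["x"], v["dc_rate"]) for v in per_grade.values()]
    pfs_pairs = [(v["x"], v["median_pfs"]) for v in per_grade.values()]
    return {
        "x_encoding": x_encoding,
        "per_grade": {g.value: v for g, v in per_grade.items()},
        "dcr": corr(dcr_pairs),
        "pfs": corr(pfs_pairs),
        "pfs_grades_not_reached": [g.value for g, v in per_grade.items()
                                   if v["median_pfs"] is None],
    }


# ---------------------------------------------------------------------------
# TP53 sensitivity analysis

def tp53_only_matched_patients(cohort: Cohort) -> list[str]:
    """Patients with ≥ 1 unit whose every matching drug fired only the TP53→VEGF rule."""
    ids = []
    for p in cohort.treated:
        if p.breakdown is None:
            continue
        for u in p.breakdown.units:
            if u.matched and u.matched_tags == {SpecialRuleId.TP53_VEGF.value}:
                ids.append(p.patient_id)
                break
    return ids


def sensitivity_exclude_tp53(cohort: Cohort, kb: KnowledgeBase) -> dict:
    """Re-run the stratified DCR and survival analyses without TP53→VEGF matches.

    Removes every patient with at least one unit matched solely through the
    TP53→VEGF rule, then reruns the ≥60 vs <60 contingency and survival
    comparisons on the remaining subcohort. The removed IDs are listed.
    """
    excluded = set(tp53_only_matched_patients(cohort))
    sub = Cohort(patients=[p for p in cohort.patients if p.patient_id not in excluded],
                 metadata=dict(cohort.metadata))
    out = {"excluded_ids": sorted(excluded), "n_excluded": len(excluded),
           "n_remaining_treated": len(sub.treated)}
    try:
        out["dcr"] = dcr_contingency(sub, "ge60_vs_lt60")
    except ValueError as exc:
        out["dcr"] = {"error": str(exc)}
    for endpoint in ("pfs", "os"):
        try:
            out[endpoint] = survival_by_stratum(sub, endpoint, "ge60_vs_lt60")
        except ValueError as exc:
            out[endpoint] = {"error": str(exc)}
    return out


# ---------------------------------------------------------------------------
# design power

def power_simulation(n_high: int, n_low: int, p_high: float, p_low: float,
                     alpha: float = 0.05, reps: int = 10_000,
                     seed: Optional[int] = None) -> dict:
    """Monte-Carlo power of the two-sided Fisher exact test for a two-arm design.

    Fisher p-values are precomputed on the full (n_high+1) × (n_low+1) grid of
    possible outcomes and looked up per replicate, which is equivalent to
    testing each simulated table and makes 10,000 replicates run in seconds.
    The standard error of the power estimate is reported.
    """
    for p in (p_high, p_low):
        if not 0 < p < 1:
            raise ValueError("response proportions must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.empty((n_high + 1, n_low + 1))
    for i in range(n_high + 1):
        for j in range(n_low + 1):
            grid[i, j] = stats.fisher_exact([[i, n_high - i], [j, n_low - j]])[1]
    x = rng.binomial(n_high, p_high, size=reps)
    y = rng.binomial(n_low, p_low, size=reps)
    reject = grid[x, y] <= alpha
    power = float(reject.mean())
    se = math.sqrt(power * (1 - power) / reps)
    return {"power": power, "se": se, "reps": reps, "alpha": alpha,
            "n_high": n_high, "n_low": n_low, "p_high": p_high, "p_low": p_low}


def power_exact(n_high: int, n_low: int, p_high: float, p_low: float,
                alpha: float = 0.05) -> float:
    """Exact power of the two-sided Fisher test by full binomial enumeration."""
    grid = np.empty((n_high + 1, n_low + 1))
    for i in range(n_high + 1):
        for j in range(n_low + 1):
            grid[i, j] = stats.fisher_exact([[i, n_high - i], [j, n_low - j]])[1]
    w_high = stats.binom.pmf(np.arange(n_high + 1), n_high, p_high)
    w_low = stats.binom.pmf(np.arange(n_low + 1), n_low, p_low)
    return float((w_high[:, None] * w_low[None, :] * (grid <= alpha)).sum())


def power_normal_approx(n_high: int, n_low: int, p_high: float, p_low: float,
                        alpha: float = 0.05) -> float:
    """Closed-form two-proportion power (normal approximation, unpooled SE).

    Anticonservative relative to the exact conditional Fisher test; useful as a
    design-stage anchor, not as the test's true power.
    """
    delta = abs(p_high - p_low)
    se = math.sqrt(p_high * (1 - p_high) / n_high + p_low * (1 - p_low) / n_low)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(delta / se - z))


# ---------------------------------------------------------------------------
# feasibility

def feasibility_summary(cohort: Cohort) -> dict:
    """Treated/matched proportions with exact (Clopper–Pearson) binomial CIs."""
    n_enrolled = len(cohort)
    treated = cohort.treated
    n_treated = len(treated)
    scored = [p for p in treated if p.breakdown is not None]
    n_matched = sum(1 for p in scored if p.breakdown.score > 0)
    bins = {g.value: 0 for g in FineGrade}
    for p in scored:
        bins[p.grade.fine.value] += 1

    def prop(k, n):
        if n == 0:
            return {"count": k, "n": n, "proportion": None}
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        return {"count": k, "n": n, "proportion": k / n,
                "ci_low": float(lo), "ci_high": float(hi)}

    return {"treated_of_enrolled": prop(n_treated, n_enrolled),
            "matched_of_treated": prop(n_matched, len(scored)),
            "score_bin_counts": bins}


# ---------------------------------------------------------------------------
# full report

def analyze_cohort(cohort: Cohort, kb: Optional[KnowledgeBase] = None,
                   run_sensitivity: bool = True) -> dict:
    """Run the full analysis battery on a scored cohort; returns a JSON-able report."""
    report = {"n_patients": len(cohort), "n_treated": len(cohort.treated),
              "feasibility": feasibility_summary(cohort)}
    for strat in ("ge60_vs_lt60", "three_group", "gt50_vs_le50"):
        try:
            report.setdefault("dcr", {})[strat] = dcr_contingency(cohort, strat)
        except ValueError as exc:
            report.setdefault("dcr", {})[strat] = {"error": str(exc)}
    rows = [(float(p.breakdown.score), _dc_status(p)) for p in cohort.treated
            if p.breakdown is not None and _dc_status(p) != NOT_EVALUABLE]
    if rows:
        try:
            roc = roc_cutoff([s for s, _ in rows], [d == DC_YES for _, d in rows])
            roc = {k: v for k, v in roc.items() if k != "per_cutoff_table"}
            report["roc"] = roc
        except ValueError as exc:
            report["roc"] = {"error": str(exc)}
    for endpoint in ("pfs", "os"):
        try:
            report[endpoint] = survival_by_stratum(cohort, endpoint, "ge60_vs_lt60")
        except ValueError as exc:
            report[endpoint] = {"error": str(exc)}
    for endpoint in ("dcr", "pfs", "os"):
        report.setdefault("models", {})[endpoint] = fit_models(cohort, endpoint)
    try:
        report["grade_trend"] = grade_trend(cohort)
    except ValueError as exc:
        report["grade_trend"] = {"error": str(exc)}
    if run_sensitivity and kb is not None:
        report["tp53_sensitivity"] = sensitivity_exclude_tp53(cohort, kb)
    return report
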