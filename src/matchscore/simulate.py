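"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the marginal structure of a treatment-naïve N-of-1
precision-oncology cohort: per-patient characterized-alteration counts with
median 5 (range 0–15), a five-bin Matching Score distribution (defaults
13:14:14:13:22 over bins 100 / 60–99 / 40–59 / 1–39 / 0 out of 76 patients),
score-dependent disease control (defaults 0.68 high stratum vs 0.30 low), and
exponential PFS/OS with stratum-specific medians under independent exponential
censoring.

Bin membership is generated *constructively*: the generator picks the number of
matched and unmatched countable units needed to land the engine-computed score
in the intended bin, draws matched genes from the seed knowledge base's
drug–target pairs and unmatched genes from a pool no seed drug targets, then
verifies each patient's bin by actually scoring it with the real engine. There
is no rejection sampling and no separate re-implementation of the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord, ResponseRecord, SurvivalRecord
from .knowledge_base import KnowledgeBase, load_seed_knowledge_base
from .scoring import (
    Alteration,
    AlterationClass,
    BiomarkerProfile,
    FineGrade,
    MsiStatus,
    Pathogenicity,
    Pdl1Category,
    TmbCategory,
    TreatmentPlan,
    assign_grade,
    matching_score,
)

__all__ = ["SimulationParams", "SimulatedCohort", "simulate_cohort", "recover_parameters"]


# genes the seed knowledge base matches with a single, non-synergy drug
MATCHED_GENE_DRUG = (
    ("BRAF", "dabrafenib"),
    ("ERBB2", "trastuzumab"),
    ("FGFR2", "erdafitinib"),
    ("PIK3CA", "alpelisib"),
    ("EGFR", "erlotinib"),
    ("ALK", "crizotinib"),
    ("CDK4", "palbociclib"),
    ("MTOR", "everolimus"),
    ("BRCA1", "olaparib"),
    ("MET", "crizotinib"),
)

# genes no seed drug targets and no special rule triggers: always unmatched
UNMATCHED_GENES = (
    "SMAD4", "APC", "ARID1A", "MYC", "RB1", "CTNNB1", "SMARCA4", "GNAS",
    "FBXW7", "SOX9", "TERT", "NOTCH1", "KEAP1", "ASXL1", "KMT2D", "NFE2L2",
)

TUMOR_TYPE_COUNTS = {
    "gastrointestinal_non_colorectal": 12, "carcinoma_unknown_primary": 10,
    "hepatobiliary": 9, "colorectal": 7, "pancreatic": 7, "head_and_neck": 5,
    "appendiceal": 4, "gynecologic": 4, "breast": 3, "lung_non_small_cell": 3,
    "genitourinary": 2, "skin_melanoma": 2, "neuroendocrine": 2, "adrenocortical": 1,
    "erdheim_chester": 1, "ewing_sarcoma": 1, "myxofibrosarcoma": 1, "pecoma": 1,
    "pleomorphic_sarcoma": 1,
}

DEFAULT_BIN_PROPORTIONS = {
    FineGrade.G100: 13 / 76, FineGrade.G60_99: 14 / 76, FineGrade.G40_59: 14 / 76,
    FineGrade.G1_39: 13 / 76, FineGrade.G0: 22 / 76,
}

HIGH_BINS = (FineGrade.G100, FineGrade.G60_99)


@dataclass
class SimulationParams:
    """Study-condition parameters for one synthetic cohort.

    Survival is exponential per stratum (high = score ≥ 60) with the stated
    medians in months; censoring is an independent exponential clock whose
    default rate yields roughly 20% administrative censoring for OS.
    """

    n_patients: int = 76
    # alteration counts: negative binomial (size, mean) truncated to [0, 15];
    # these values put the truncated median at 5
    alteration_nb_size: float = 5.0
    alteration_nb_mean: float = 5.5
    alteration_max: int = 15
    vus_fraction: float = 0.25           # extra VUS rows relative to characterized count
    bin_proportions: dict = field(default_factory=lambda: dict(DEFAULT_BIN_PROPORTIONS))
    io_probability: float = 14 / 54      # checkpoint blockade among matched patients
    tp53_vegf_fraction: float = 16 / 54  # matched patients with a TP53->VEGFi match
    dc_prob_high: float = 0.68
    dc_prob_low: float = 0.30
    pfs_median_high: float = 11.6
    pfs_median_low: float = 2.8
    os_median_high: float = 18.7
    os_median_low: float = 11.6
    censoring_rate: float = 0.015        # per month
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for p in (self.vus_fraction, self.io_probability, self.tp53_vegf_fraction,
                  self.dc_prob_high, self.dc_prob_low):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for m in (self.pfs_median_high, self.pfs_median_low,
                  self.os_median_high, self.os_median_low):
            if m <= 0:
                raise ValueError("survival medians must be positive")
        total = sum(self.bin_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"bin proportions must sum to 1 (got {total})")

    @property
    def true_dc_odds_ratio(self) -> float:
        return (self.dc_prob_high / (1 - self.dc_prob_high)) / \
               (self.dc_prob_low / (1 - self.dc_prob_low))

    @property
    def true_pfs_hazard_ratio(self) -> float:
        return self.pfs_median_low / self.pfs_median_high

    @property
    def true_os_hazard_ratio(self) -> float:
        return self.os_median_low / self.os_median_high


@dataclass
class SimulatedCohort:
    cohort: Cohort
    ground_truth: pd.DataFrame
    params: SimulationParams


def _draw_alteration_count(rng: np.random.Generator, params: SimulationParams,
                           minimum: int = 0) -> int:
    size, mean = params.alteration_nb_size, params.alteration_nb_mean
    p = size / (size + mean)
    while True:
        n = int(rng.negative_binomial(size, p))
        if minimum <= n <= params.alteration_max:
            return n


def _feasible_matched_counts(n: int, bin_: FineGrade, io_half: bool) -> list[int]:
    """Matched-unit counts m that land score(m, n) in the bin."""
    if bin_ is FineGrade.G0:
        return [0]
    if io_half:
        # score = 50 + 50 m/n must land in [60, 100): m/n in [0.2, 1)
        lo, hi = math.ceil(0.2 * n), n - 1
        return [m for m in range(max(lo, 0), hi + 1)]
    if bin_ is FineGrade.G100:
        return [n] if n >= 1 else []
    if bin_ is FineGrade.G60_99:
        return [m for m in range(1, n) if 0.6 <= m / n < 1]
    if bin_ is FineGrade.G40_59:
        return [m for m in range(1, n + 1) if 0.4 <= m / n < 0.6]
    if bin_ is FineGrade.G1_39:
        return [m for m in range(1, n) if m / n < 0.4]
    raise AssertionError(bin_)


def _exp_time(rng: np.random.Generator, median: float) -> float:
    return float(rng.exponential(median / math.log(2)))


def simulate_cohort(params: SimulationParams,
                    kb: Optional[KnowledgeBase] = None) -> SimulatedCohort:
    """Generate one synthetic cohort; every patient's bin is verified by the engine."""
    if kb is None:
        kb = load_seed_knowledge_base()
    rng = np.random.default_rng(params.seed)
    bins = list(params.bin_proportions.keys())
    probs = np.array([params.bin_proportions[b] for b in bins], dtype=float)
    tumor_types = list(TUMOR_TYPE_COUNTS)
    tumor_probs = np.array(list(TUMOR_TYPE_COUNTS.values()), dtype=float)
    tumor_probs /= tumor_probs.sum()

    patients, truth_rows = [], []
    for i in range(params.n_patients):
        pid = f"S{i + 1:04d}"
        bin_ = bins[rng.choice(len(bins), p=probs)]
        matched_patient = bin_ is not FineGrade.G0
        io = matched_patient and bin_ in HIGH_BINS and rng.random() < params.io_probability
        io_mode = "none"
        if io:
            io_mode = "full" if bin_ is FineGrade.G100 else "half"

        n_units = _draw_alteration_count(rng, params,
                                         minimum=1 if matched_patient else 0)
        if io_mode == "full":
            # engine returns 100 regardless of X; any m in [0, n] works
            feasible = list(range(0, n_units + 1))
        else:
            feasible = _feasible_matched_counts(n_units, bin_, io_mode == "half")
            while not feasible:
                if params.io_probability == 0 and matched_patient and n_units == 0:
                    raise ValueError("matched bins are infeasible with zero units")
                n_units += 1
                if n_units > params.alteration_max:
                    raise ValueError(f"no feasible unit count for bin {bin_.value}")
                feasible = _feasible_matched_counts(n_units, bin_, io_mode == "half")
        m = int(feasible[rng.integers(len(feasible))])

        use_tp53 = (matched_patient and m >= 1 and not io
                    and rng.random() < params.tp53_vegf_fraction)
        matched_pool = list(MATCHED_GENE_DRUG)
        rng.shuffle(matched_pool)
        n_direct = m - 1 if use_tp53 else m
        chosen = matched_pool[:n_direct]
        genes = [g for g, _ in chosen]
        drugs = {d for _, d in chosen}
        if use_tp53:
            genes.append("TP53")
            drugs.add("pazopanib")
        unmatched = [g for g in UNMATCHED_GENES if g not in genes]
        rng.shuffle(unmatched)
        genes.extend(unmatched[:n_units - m])

        biomarkers = BiomarkerProfile()
        if io_mode == "full":
            choice = rng.integers(3)
            biomarkers = BiomarkerProfile(
                msi_status=MsiStatus.MSI_HIGH if choice == 0 else MsiStatus.UNKNOWN,
                tmb_category=TmbCategory.HIGH if choice == 1 else TmbCategory.UNKNOWN,
                pdl1_category=Pdl1Category.HIGH_POSITIVE if choice == 2 else Pdl1Category.UNKNOWN)
        elif io_mode == "half":
            if rng.random() < 0.5:
                biomarkers = BiomarkerProfile(tmb_category=TmbCategory.INTERMEDIATE)
            else:
                biomarkers = BiomarkerProfile(pdl1_category=Pdl1Category.LOW_POSITIVE)
        if io:
            drugs.add("pembrolizumab" if rng.random() < 0.5 else "nivolumab")
        if not drugs:
            drugs = {"gemcitabine"}  # untargeted cytotoxic backbone

        alterations = [Alteration(gene=g) for g in genes]
        n_vus = int(rng.binomial(max(n_units, 1), params.vus_fraction))
        vus_pool = [g for g in UNMATCHED_GENES if g not in genes] + ["MUC16", "TTN"]
        for k in range(n_vus):
            alterations.append(Alteration(gene=vus_pool[k % len(vus_pool)],
                                          pathogenicity=Pathogenicity.VUS))

        breakdown = matching_score(alterations, biomarkers, TreatmentPlan(frozenset(drugs)), kb)
        grade = assign_grade(breakdown.score)
        if grade.fine is not bin_:
            raise AssertionError(
                f"generator bug: {pid} intended {bin_.value} but engine scored "
                f"{float(breakdown.score):g} ({grade.fine.value})")

        high = grade.fine in HIGH_BINS
        p_dc = params.dc_prob_high if high else params.dc_prob_low
        dc = rng.random() < p_dc
        if dc:
            u = rng.random()
            if u < 0.15:
                response = ResponseRecord("CR")
            elif u < 0.55:
                response = ResponseRecord("PR")
            else:
                response = ResponseRecord("SD", sd_duration_months=float(rng.uniform(6, 24)))
        else:
            if rng.random() < 0.7:
                response = ResponseRecord("PD")
            else:
                response = ResponseRecord("SD", sd_duration_months=float(rng.uniform(1, 5.9)),
                                          sd_ongoing=False)

        pfs_med = params.pfs_median_high if high else params.pfs_median_low
        os_med = params.os_median_high if high else params.os_median_low
        pfs_t = _exp_time(rng, pfs_med)
        os_t = _exp_time(rng, os_med)
        c1 = (float(rng.exponential(1 / params.censoring_rate))
              if params.censoring_rate > 0 else math.inf)
        c2 = (float(rng.exponential(1 / params.censoring_rate))
              if params.censoring_rate > 0 else math.inf)
        survival = SurvivalRecord(
            pfs_months=round(min(pfs_t, c1), 4), pfs_event=pfs_t <= c1,
            os_months=round(min(os_t, c2), 4), os_event=os_t <= c2)

        age = float(np.clip(rng.normal(62, 13), 23, 93))
        patient = PatientRecord(
            patient_id=pid,
            tumor_type=tumor_types[rng.choice(len(tumor_types), p=tumor_probs)],
            age=round(age, 1),
            sex="female" if rng.random() < 0.526 else "male",
            treated=True,
            alterations=alterations,
            biomarkers=biomarkers,
            treatment=TreatmentPlan(frozenset(drugs)),
            response=response,
            survival=survival,
        )
        patient.breakdown = breakdown
        patient.grade = grade
        patients.append(patient)
        truth_rows.append({
            "patient_id": pid, "true_bin": bin_.value,
            "true_stratum": "high" if high else "low",
            "true_dc_prob": p_dc, "true_pfs_median": pfs_med, "true_os_median": os_med,
            "io_component": io_mode, "tp53_vegf_match": use_tp53,
            "engine_score": float(breakdown.score),
        })

    cohort = Cohort(patients=patients, metadata={
        "generator": "matchscore.simulate", "seed": params.seed,
        "n_patients": params.n_patients})
    return SimulatedCohort(cohort=cohort, ground_truth=pd.DataFrame(truth_rows),
                           params=params)


# ---------------------------------------------------------------------------
# parameter recovery

def recover_parameters(params: SimulationParams, n_replicates: int = 200,
                       seed: int = 0, kb: Optional[KnowledgeBase] = None) -> dict:
    """Simulate–score–refit ``n_replicates`` cohorts and audit estimator quality.

    Per replicate (seeded ``seed + r``): generate a cohort, score it with the
    real engine, fit the univariate logistic model for disease control and Cox
    models for PFS/OS on the high-score indicator, and test the stratified
    Fisher and log-rank comparisons. Reports bias, RMSE and 95% Wald CI
    coverage on the log scale against the truths implied by ``params``, plus
    rejection rates (the type-I error when ``params`` encodes a null design).
    Fit failures are counted, not fatal.
    """
    import statsmodels.api as sm
    from lifelines import CoxPHFitter

    from .analysis import DC_YES, NOT_EVALUABLE, _dc_status, fisher_exact_2x2, logrank

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if kb is None:
        kb = load_seed_knowledge_base()
    truths = {"dc_or": math.log(params.true_dc_odds_ratio),
              "pfs_hr": math.log(params.true_pfs_hazard_ratio),
              "os_hr": math.log(params.true_os_hazard_ratio)}
    est = {k: [] for k in truths}
    cover = {k: [] for k in truths}
    fisher_rej, logrank_rej, failures = [], [], {k: 0 for k in truths}

    for r in range(n_replicates):
        sim = simulate_cohort(replace(params, seed=seed + r), kb=kb)
        rows = []
        for p in sim.cohort.treated:
            status = _dc_status(p)
            rows.append({
                "high": int(float(p.breakdown.score) >= 60),
                "dc": np.nan if status == NOT_EVALUABLE else int(status == DC_YES),
                "pfs_months": p.survival.pfs_months, "pfs_event": float(p.survival.pfs_event),
                "os_months": p.survival.os_months, "os_event": float(p.survival.os_event)})
        df = pd.DataFrame(rows)

        sub = df.dropna(subset=["dc"])
        try:
            X = sm.add_constant(sub[["high"]].astype(float), has_constant="add")
            fit = sm.Logit(sub["dc"].astype(float), X).fit(disp=0)
            lo, hi = fit.conf_int().loc["high"]
            est["dc_or"].append(float(fit.params["high"]))
            cover["dc_or"].append(lo <= truths["dc_or"] <= hi)
        except Exception:
            failures["dc_or"] += 1
        for key, endpoint in (("pfs_hr", "pfs"), ("os_hr", "os")):
            try:
                cph = CoxPHFitter()
                cph.fit(df[[f"{endpoint}_months", f"{endpoint}_event", "high"]],
                        duration_col=f"{endpoint}_months", event_col=f"{endpoint}_event")
                beta = float(cph.summary.loc["high", "coef"])
                se = float(cph.summary.loc["high", "se(coef)"])
                est[key].append(beta)
                cover[key].append(beta - 1.96 * se <= truths[key] <= beta + 1.96 * se)
            except Exception:
                failures[key] += 1

        a = sub[sub["high"] == 1]["dc"]
        b = sub[sub["high"] == 0]["dc"]
        if len(a) and len(b):
            p_val = fisher_exact_2x2([[int(a.sum()), int(len(a) - a.sum())],
                                      [int(b.sum()), int(len(b) - b.sum())]])
            fisher_rej.append(p_val < 0.05)
        hi_mask = df["high"] == 1
        if hi_mask.any() and (~hi_mask).any():
            lr = logrank({
                "high": (df[hi_mask]["os_months"].tolist(),
                         df[hi_mask]["os_event"].astype(bool).tolist()),
                "low": (df[~hi_mask]["os_months"].tolist(),
                        df[~hi_mask]["os_event"].astype(bool).tolist())})
            logrank_rej.append(lr["p"] < 0.05)

    report = {"n_replicates": n_replicates, "seed": seed,
              "fisher_rejection_rate": float(np.mean(fisher_rej)) if fisher_rej else None,
              "logrank_rejection_rate": float(np.mean(logrank_rej)) if logrank_rej else None,
              "parameters": {}}
    for key in truths:
        e = np.asarray(est[key])
        entry = {"truth_log": truths[key], "truth": math.exp(truths[key]),
                 "n_ok": int(e.size), "n_failed": failures[key]}
        if e.size:
            entry.update({
                "mean_log_estimate": float(e.mean()),
                "bias_log": float(e.mean() - truths[key]),
                "relative_bias_log": (float((e.mean() - truths[key]) / truths[key])
                                      if truths[key] != 0 else None),
                "rmse_log": float(np.sqrt(((e - truths[key]) ** 2).mean())),
                "se_log": float(e.std(ddof=1) / math.sqrt(e.size)) if e.size > 1 else None,
                "coverage": float(np.mean(cover[key])) if cover[key] else None,
            })
        report["parameters"][key] = entry
    return report
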