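# Methods notes

## The scoring model

The Matching Score treats a genomic report as a set of *countable units* and a
regimen as a set of match verdicts over those units. The engine applies, in
order:

1. **Filtering.** Only `characterized` alterations count; VUS rows are dropped
   before anything else happens, so they can never dilute or inflate a score.
2. **Collapsing.** Units are keyed by (report, gene, structural class, impact
   group). Two same-gene events with the same key collapse to one unit;
   an amplification plus a mutation in the same gene stay separate. When no
   impact-group annotation is supplied, the structural class stands in for it —
   a conservative default that collapses same-gene same-class events. Reports
   are counted independently by default (tumor heterogeneity between tissue and
   blood is real signal); `dedupe_across_reports=True` gives the stricter
   reading in which an identical variant seen twice counts once.
3. **Matching.** A unit is matched when any administered drug lists its gene
   among curated targets (which may include the immediate downstream effector
   relationship, e.g. a MEK inhibitor listing upstream MAPK genes), or when a
   special rule fires: BRCA-pathway gene → platinum/PARP inhibitor, or TP53 →
   any drug with VEGF/VEGFR activity. Each verdict carries exactly one
   provenance tag, with direct targets taking precedence over special rules,
   so the audit trail distinguishes a *bona fide* VEGFR inhibitor match from a
   TP53-rule match. The potency criterion behind a drug's target list
   (preclinical IC50, generally < 100 nM, for the target or its immediate
   downstream effector) is a *curation* criterion: the rule base stores its
   outcome, the software never computes potency.
4. **Weighting.** A matched unit co-targeted by an administered synergistic
   pair gets weight 2 in numerator and denominator. A hormone-receptor-positive
   tumor given a hormone modulator contributes one extra matched unit to both
   sides. Both enter the denominator only when they fire, so an untargeted
   ER-positive status does not drag the score down.
5. **Immunotherapy component.** Earned only when checkpoint blockade is
   actually administered: full (score pinned at 100) for MSI-high, TMB ≥ 20
   Muts/Mb or PD-L1 ≥ 30%; half (score 50 + X·100/2) for TMB 6–19 or PD-L1
   low-positive. A checkpoint inhibitor without a qualifying biomarker
   contributes nothing — unless the report carries a *CD274* (PD-L1)
   amplification, which is treated as an ordinary genomic unit directly
   targeted by the checkpoint inhibitor rather than as an IO-component
   trigger; the rule base encodes that by listing CD274 among the
   checkpoint inhibitors' targets.

Scores are exact `fractions.Fraction`s until binning (half-components produce
values like 50 + 50/3 that must not be rounded before stratification). The
stratifications are: primary ≥ 60 / 1–59 / 0; alternate > 50 / ≤ 50; fine bins
0, 1–39, 40–59, 60–99, 100 with inclusive integer endpoints (fractional scores
fall in the bin whose labeled range contains them).

Useful consequences, all property-tested: the score is bounded in [0, 100];
adding a drug never lowers it; adding an untargeted characterized alteration
never raises it; VUS are inert; a full IO component forces exactly 100.

## The knowledge base

A single JSON document (`drugs`, `synergy_pairs`, `special_rules`, `version`)
validated on load: unique drug names, nonempty target sets for small molecules
and antibodies, synergy pairs must reference known drugs and a target shared by
both, and both built-in special rules must be present (each individually
disableable — the TP53 toggle powers the sensitivity analysis). The packaged
seed covers the drugs and genes used in the documentation, examples and
simulator; real analyses will extend it, since no published trial enumerates
its full curation table. A drug–target TSV export is provided for review.
Gene symbols are HGNC-style, compared case-insensitively after trimming.

## Cohort dialect

Five TSV tables (`patients`, `alterations`, `biomarkers`, `treatments`,
`outcomes`) joined on `patient_id`; one row per alteration and per drug;
survival supplied as durations in months with event flags (no dates).
Validation rejects orphan keys, duplicate IDs and unknown categorical levels
with row numbers. Batch scoring collects per-patient failures into an error
report instead of aborting.

## Analysis choices

- **Disease control** is SD ≥ 6 months or PR/CR. SD still ongoing below six
  months, too-early and not-evaluable responses are excluded from DCR
  evaluability (they are neither success nor failure yet). A patient recorded
  as clinically deteriorated without imaging enters as best_response = PD.
- **Fisher exact test** (two-sided, p = sum of hypergeometric table
  probabilities ≤ the observed one) is the anchor for 2×2 comparisons; a
  binary-logistic Wald p is reported alongside, labelled, because both appear
  in trial reporting practice. The test suite checks the Fisher p against an
  exhaustive enumeration oracle.
- **ROC cutoff**: midrank AUC; candidate cutoffs are the observed scores;
  Youden's J selects the cutoff, ties broken toward the higher cutoff; a
  maximal rate-difference criterion is reported as an alternative and the full
  per-cutoff table is returned so any criterion can be audited.
- **Survival**: product-limit KM with the median defined as the earliest time
  the curve reaches ≤ 0.5 ("not reached" when it never does); log-rank across
  strata; Cox partial likelihood with Efron tie handling (the lifelines
  default, and the common choice when the tie convention is unstated).
- **Model entry rule**: every candidate covariate (high score ≥ 60, matched
  vs unmatched, age ≥ cohort median, sex, ≥ 2 drugs, GI/hepatobiliary
  grouping, unknown-primary, breast) is screened univariately; those with
  Wald *P* < 0.15 enter the single multivariate model. Separation or
  non-convergence is reported per covariate, never fatal. The multivariate
  covariate set is asserted equal to the univariate-entry set.
- **Grade trend**: DC rate and KM-median PFS per fine grade, Pearson-correlated
  against the grade's ordinal index 0–4 by default (bin midpoints available);
  grades whose PFS median is not reached are dropped from the PFS correlation
  and listed; a constant outcome reports an undefined correlation rather than
  a number.
- **TP53 sensitivity**: a patient is flagged when at least one unit's *only*
  matching route is the TP53→VEGF rule (the provenance tags make "only"
  well-defined); flagged patients are removed and the stratified contingency
  and survival analyses rerun.
- **Power**: the Monte-Carlo estimator precomputes Fisher p-values on the full
  (n₁+1)×(n₂+1) outcome grid and looks up each replicate — mathematically
  identical to testing every simulated table. An exact-enumeration power
  (binomial-weighted sum over the grid) serves as the oracle, and a closed-form
  normal-approximation power (unpooled SE) is provided as the design-stage
  anchor. The two disagree by construction: for 25 vs 50 patients at 0.65 vs
  0.30 the approximation gives ≈ 0.86 while the exact conditional test's power
  is ≈ 0.81 — the conservatism of Fisher's test, not an implementation gap.
  For the same reason the simulated type-I error under the null is compared
  against the exact enumerated size (which sits below the nominal level)
  rather than against α itself.
- **No multiple-testing correction** is applied anywhere; the analyses are
  exploratory and are reported as such.

## The synthetic cohort generator

The generator emulates the *marginal* structure these analyses consume, with a
known ground truth:

- alteration counts: negative binomial (size 5, mean 5.5) truncated to [0, 15],
  whose truncated median is 5;
- score bins drawn from target proportions (defaults 13:14:14:13:22 across
  100 / 60–99 / 40–59 / 1–39 / 0 per 76 patients);
- bin membership is **constructive**: the generator enumerates the
  matched-unit counts m whose engine score lands in the drawn bin, picks one,
  assembles matched genes from the seed rule base's drug–target pairs and
  unmatched genes from a pool no seed drug targets, then *scores the patient
  with the real engine and asserts the intended bin*. There is no rejection
  sampling and no second implementation of the score;
- checkpoint blockade is placed (probability 14/54 among matched patients) in
  the two high bins only: full-component biomarkers in the 100% bin,
  half-component biomarkers with a compatible genomic fraction in 60–99%;
- a configurable fraction of matched patients (default 16/54) carries a
  TP53 alteration matched only via pazopanib, feeding the sensitivity analysis;
- outcomes: disease control is Bernoulli per stratum (defaults 0.68 for score
  ≥ 60 vs 0.30 below); PFS and OS are exponential with stratum medians
  (defaults 11.6/2.8 and 18.7/11.6 months) under independent exponential
  censoring at 0.015/month (roughly 20–30% administrative censoring for OS, a
  free parameter since trial reports rarely state one). OS and PFS are drawn
  independently, so OS < PFS can occur in a simulated patient; the analyses
  never rely on their joint ordering.

What the generator does **not** emulate: mutational signatures, gene-level
co-occurrence, panel composition, correlated PFS/OS, non-proportional hazards,
informative censoring, or any link between specific drugs and outcomes beyond
the stratum. Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes — not that real cohorts satisfy those assumptions.

`recover_parameters` runs the full simulate → score → refit loop (replicate r
uses seed + r) and reports log-scale bias, RMSE and 95% Wald CI coverage for
the DC odds ratio and PFS/OS hazard ratios against the truths implied by the
parameters, plus Fisher/log-rank rejection rates (the type-I error when the
design is null). The test suite runs 200 replicates at n = 76 for the recovery
audit and 120 replicates for the √n-scaling check — sizes chosen to keep
Monte-Carlo error well inside the asserted bands while the whole suite stays
in the low minutes.

## Known limitations

- The seed rule base is a small, documented curation; scores on real cohorts
  depend on extending it, and the score's denominator depends on the gene
  panel, so scores are comparable only within one panel and one rule base.
- "Same signal/pathway impact" for the collapse rule is operationalized via
  the `impact_group` annotation (defaulting to structural class); richer
  pathway semantics are deliberately out of scope.
- Whether identical variants across tissue and blood reports should be
  double-counted is genuinely ambiguous in trial practice; both behaviors are
  implemented and the default (count per report) is a switch away from the
  alternative.
- The regression battery reports Wald intervals; at n ≈ 76 with rare
  covariates, profile-likelihood or exact methods would be preferable for the
  smallest cells.
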