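# matchscore

Tools for quantifying how completely an individualized ("N-of-1") cancer drug
combination covers a patient's tumor molecular profile, and for analyzing how
that degree of matching relates to treatment outcomes in a cohort.

In precision-oncology trials that tailor a drug combination to each patient's
genomic report, treatment is not simply "matched" or "unmatched": a regimen may
target one of eight alterations or all of them. The **Matching Score** makes
this a number,

> MS = 100 · (countable alterations targeted by administered drugs) /
> (all countable characterized alterations),

with counting rules: variants of unknown significance are excluded; same-gene
aberrations with the same structural class and functional impact collapse to
one unit while structurally distinct ones (e.g. amplification *plus* mutation)
count separately; an established synergistic pair hitting one aberration (e.g.
dabrafenib + trametinib on *BRAF*) counts twice in numerator **and**
denominator; ER/AR-positive IHC targeted by a hormone modulator adds one
matched unit to both sides. Checkpoint blockade earns an immunotherapy
component: score 100 for MSI-high, TMB ≥ 20 Muts/Mb or PD-L1 ≥ 30% IHC, and
50 + X·100/2 (X the genomic fraction) for TMB 6–19 or PD-L1 low-positive.
*BRCA*-pathway alterations are matched by platinum agents or PARP inhibitors,
and *TP53* by anti-VEGF/VEGFR drugs (a rule that can be disabled for
sensitivity analyses). No score exceeds 100.

The package is aimed at trial statisticians and translational researchers who
want the score, the drug–target rule base that feeds it, and the downstream
cohort analyses (disease-control contingency tables with Fisher exact tests,
ROC-based cutoff selection, Kaplan–Meier / log-rank / Cox survival analysis
with a univariate *P* < 0.15 model-entry rule, grade-trend correlation, and
design power simulation) as tested, auditable code — plus a synthetic-cohort
generator so everything runs without access to per-patient clinical data.

## Worked example

```python
from matchscore import (Alteration, BiomarkerProfile, TreatmentPlan,
                        assign_grade, load_seed_knowledge_base, matching_score)

kb = load_seed_knowledge_base()
alts = [Alteration(gene=g) for g in ["BRAF", "ERBB2", "FGFR2", "SMAD4", "APC", "MYC"]]
bd = matching_score(alts, BiomarkerProfile(),
                    TreatmentPlan(frozenset({"dabrafenib", "trastuzumab", "erdafitinib"})), kb)
print(f"score = {float(bd.score):g}%  ({bd.numerator} of {bd.denominator} units matched)")
for u in bd.units:
    print(f"  {u.gene:6s} matched={u.matched!s:5s} weight={u.weight} via {[t for _, t in u.provenance]}")
grade = assign_grade(bd.score)
print(f"strata: {grade.primary.value} / {grade.alternate.value} / {grade.fine.value}")
```

prints

```
score = 50%  (3 of 6 units matched)
  BRAF   matched=True  weight=1 via ['direct_target']
  ERBB2  matched=True  weight=1 via ['direct_target']
  FGFR2  matched=True  weight=1 via ['direct_target']
  SMAD4  matched=False weight=1 via []
  APC    matched=False weight=1 via []
  MYC    matched=False weight=1 via []
strata: s1_59 / le50 / g40_59
```

Three of six characterized alterations are targeted, so the score is 50% and
the patient falls in the 1–59% stratum (40–59% fine bin). The per-unit rows are
the audit trail: which drug rule matched each alteration and with what weight.

The same engine drives the command line:

```bash
matchscore simulate --out cohort/ --seed 7        # synthetic five-table cohort
matchscore score    --tables cohort/ --out scored/ # scores.tsv + audit.tsv
matchscore analyze  --tables cohort/ --out report.json
matchscore power    --n-high 25 --n-low 50 --p-high 0.65 --p-low 0.30
```

`analyze` writes a JSON report with the stratified disease-control tables and
Fisher p-values, ROC cutoff, KM medians with log-rank tests, univariate and
multivariate odds/hazard ratios, the grade-trend R², the TP53→VEGF sensitivity
analysis, and the feasibility summary.

## Layout

- `matchscore.knowledge_base` — drug–target rule base (JSON schema, seed rules,
  match verdicts with provenance tags, special-rule toggles)
- `matchscore.scoring` — the Matching Score engine and grade stratification
- `matchscore.cohort` — five-table TSV cohort dialect, validation, batch scoring
- `matchscore.analysis` — contingency, ROC, survival, regression, trend,
  sensitivity and power analyses
- `matchscore.simulate` — synthetic cohort generator and parameter-recovery harness
- `docs/methods.md` — modeling assumptions, defaults and limitations
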