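import pytest

from matchscore import (
    Alteration,
    AlterationClass,
    BiomarkerProfile,
    Cohort,
    MsiStatus,
    PatientRecord,
    Pathogenicity,
    ResponseRecord,
    SurvivalRecord,
    TmbCategory,
    TreatmentPlan,
    load_seed_knowledge_base,
)


@pytest.fixture(scope="session")
def kb():
    return load_seed_knowledge_base()


def _patient(pid, alterations, drugs, biomarkers=None, tumor_type="other",
             response=None, survival=None, age=None, sex=None):
    return PatientRecord(
        patient_id=pid, tumor_type=tumor_type, age=age, sex=sex, treated=True,
        alterations=alterations,
        biomarkers=biomarkers or BiomarkerProfile(),
        treatment=TreatmentPlan(frozenset(drugs)),
        response=response or ResponseRecord("PD"),
        survival=survival or SurvivalRecord(3.0, True, 8.0, True),
    )


@pytest.fixture()
def demo_cohort():
    """Six treated patients spanning the score bins, including both worked examples."""
    mut = AlterationClass.MUTATION
    patients = [
        # 3 of 6 alterations targeted -> 50
        _patient(
            "P1",
            [Alteration(gene=g) for g in ["BRAF", "ERBB2", "FGFR2", "SMAD4", "APC", "MYC"]],
            ["dabrafenib", "trastuzumab", "erdafitinib"],
            response=ResponseRecord("PR"),
            survival=SurvivalRecord(11.0, True, 19.0, False),
        ),
        # TMB-intermediate + checkpoint blockade + FGFR inhibitor over {PIK3CA, FGFR1} -> 75
        _patient(
            "P2",
            [Alteration(gene="PIK3CA"), Alteration(gene="FGFR1")],
            ["pembrolizumab", "erdafitinib"],
            biomarkers=BiomarkerProfile(tmb_category=TmbCategory.INTERMEDIATE),
            response=ResponseRecord("SD", sd_duration_months=8.0),
            survival=SurvivalRecord(9.0, True, 15.0, True),
        ),
        # MSI-high + checkpoint blockade, untargeted alterations -> 100 (cap)
        _patient(
            "P3",
            [Alteration(gene=g) for g in ["SMAD4", "APC", "MYC", "RB1"]],
            ["nivolumab"],
            biomarkers=BiomarkerProfile(msi_status=MsiStatus.MSI_HIGH),
            response=ResponseRecord("CR"),
            survival=SurvivalRecord(14.0, False, 20.0, False),
        ),
        # nothing matched -> 0
        _patient(
            "P4",
            [Alteration(gene="SMAD4"), Alteration(gene="APC")],
            ["gemcitabine"],
            response=ResponseRecord("PD"),
            survival=SurvivalRecord(2.0, True, 6.0, True),
        ),
        # sole match is TP53 -> VEGFi (sensitivity-analysis target); 1 of 3 -> ~33.3
        _patient(
            "P5",
            [Alteration(gene="TP53"), Alteration(gene="SMAD4"), Alteration(gene="MYC")],
            ["pazopanib"],
            response=ResponseRecord("SD", sd_duration_months=3.0, sd_ongoing=False),
            survival=SurvivalRecord(3.5, True, 9.0, True),
        ),
        # BRCA1 + platinum via the special rule; 1 of 2 -> 50
        _patient(
            "P6",
            [Alteration(gene="BRCA1"), Alteration(gene="MYC", alteration_class=AlterationClass.AMPLIFICATION)],
            ["carboplatin"],
            response=ResponseRecord("SD", sd_duration_months=2.0, sd_ongoing=True),
            survival=SurvivalRecord(4.0, False, 10.0, False),
        ),
    ]
    return Cohort(patients=patients)
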