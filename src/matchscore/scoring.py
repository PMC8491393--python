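"""The Matching Score: how completely a drug regimen covers a tumor's alterations.

The score is the percentage of a patient's countable molecular aberrations that
are targeted by the administered drugs, on a 0–100% scale, built from:

* a genomic fraction X = (matched countable units) / (all countable units),
  after collapsing same-gene aberrations with the same class and functional
  impact into one unit, double-counting units hit by an established synergistic
  drug pair (in numerator *and* denominator), and adding one fully-matched unit
  when a hormone-receptor-positive tumor receives a hormone modulator; and
* an immunotherapy component earned only when checkpoint blockade is actually
  administered: *full* (score 100) for MSI-high, TMB-high (≥ 20 Muts/Mb) or
  PD-L1 high-positive IHC (≥ 30%); *half* for TMB-intermediate (6–19) or PD-L1
  low-positive, giving score 50 + X·100/2.

Variants of unknown significance never enter the count, and no score exceeds
100. Fractions are kept exact (`fractions.Fraction`) until binning so that
half-scores such as 50 + 100/6 never flip a stratum through rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .knowledge_base import (
    DrugClass,
    KnowledgeBase,
    drug_matches_alteration,
    hormone_match,
    normalize_gene,
)

__all__ = [
    "AlterationClass",
    "Pathogenicity",
    "Alteration",
    "TmbCategory",
    "MsiStatus",
    "Pdl1Category",
    "BiomarkerProfile",
    "TreatmentPlan",
    "CountableUnit",
    "IoComponent",
    "MatchBreakdown",
    "PrimaryStratum",
    "AlternateStratum",
    "FineGrade",
    "MatchingGrade",
    "tmb_category_from_value",
    "pdl1_category_from_percent",
    "collapse_alterations",
    "genomic_fraction",
    "immunotherapy_component",
    "matching_score",
    "assign_grade",
    "HORMONE_UNIT_GENE",
]


class AlterationClass(str, Enum):
    MUTATION = "mutation"
    AMPLIFICATION = "amplification"
    DELETION = "deletion"
    FUSION = "fusion"
    OTHER = "other"


class Pathogenicity(str, Enum):
    CHARACTERIZED = "characterized"
    VUS = "vus"


@dataclass(frozen=True)
class Alteration:
    """One characterized genomic aberration from one report (tissue or blood).

    ``impact_group`` labels the functional signal/pathway impact used by the
    same-gene collapse rule; when unannotated it defaults to the alteration
    class, so two same-gene events of the same structural class collapse.
    """

    gene: str
    alteration_class: AlterationClass = AlterationClass.MUTATION
    report_id: str = "r1"
    impact_group: Optional[str] = None
    pathogenicity: Pathogenicity = Pathogenicity.CHARACTERIZED

    def __post_init__(self) -> None:
        if not self.gene or not self.gene.strip():
            raise ValueError("alteration gene must be nonempty")
        object.__setattr__(self, "gene", normalize_gene(self.gene))


class TmbCategory(str, Enum):
    HIGH = "high"          # >= 20 Muts/Mb
    INTERMEDIATE = "intermediate"  # 6-19 Muts/Mb
    LOW = "low"            # <= 5 Muts/Mb
    UNKNOWN = "unknown"


class MsiStatus(str, Enum):
    MSI_HIGH = "msi_high"
    STABLE = "stable"
    UNKNOWN = "unknown"


class Pdl1Category(str, Enum):
    HIGH_POSITIVE = "high_positive"  # >= 30% tumor-cell staining
    LOW_POSITIVE = "low_positive"    # >= 1% and < 30%
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


def tmb_category_from_value(muts_per_mb: float) -> TmbCategory:
    """Map a numeric tumor mutational burden onto the assay's categories."""
    if muts_per_mb < 0:
        raise ValueError("TMB cannot be negative")
    if muts_per_mb >= 20:
        return TmbCategory.HIGH
    if muts_per_mb >= 6:
        return TmbCategory.INTERMEDIATE
    return TmbCategory.LOW


def pdl1_category_from_percent(staining_percent: float) -> Pdl1Category:
    if not 0 <= staining_percent <= 100:
        raise ValueError("PD-L1 staining percentage must be in [0, 100]")
    if staining_percent >= 30:
        return Pdl1Category.HIGH_POSITIVE
    if staining_percent >= 1:
        return Pdl1Category.LOW_POSITIVE
    return Pdl1Category.NEGATIVE


@dataclass(frozen=True)
class BiomarkerProfile:
    tmb_category: TmbCategory = TmbCategory.UNKNOWN
    msi_status: MsiStatus = MsiStatus.UNKNOWN
    pdl1_category: Pdl1Category = Pdl1Category.UNKNOWN
    er_positive: Optional[bool] = None  # None = unknown
    ar_positive: Optional[bool] = None


@dataclass(frozen=True)
class TreatmentPlan:
    drugs: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))


HORMONE_UNIT_GENE = "ER/AR"  # pseudo-gene label for the hormone IHC unit


@dataclass
class CountableUnit:
    """One countable aberration after same-gene collapsing.

    ``weight`` is 2 only when an administered synergy pair co-targets the gene
    (the doubling applies to numerator and denominator alike); ``provenance``
    records the (drug, rule-tag) pairs that matched the unit.
    """

    gene: str
    alteration_class: Optional[AlterationClass]
    impact_group: str
    report_id: Optional[str]
    n_collapsed: int = 1
    matched: bool = False
    weight: int = 1
    provenance: tuple[tuple[str, str], ...] = ()

    @property
    def matched_tags(self) -> frozenset[str]:
        return frozenset(tag for _, tag in self.provenance)


class IoComponent(str, Enum):
    FULL = "full"
    HALF = "half"
    NONE = "none"


@dataclass
class MatchBreakdown:
    """Full audit of one patient's score: units, weights, io component, score."""

    units: list[CountableUnit]
    numerator: int
    denominator: int
    genomic_fraction: Fraction
    io_component: IoComponent
    score: Fraction  # percentage points, exact

    @property
    def score_percent(self) -> float:
        return float(self.score)


class PrimaryStratum(str, Enum):
    GE60 = "ge60"
    S1_59 = "s1_59"
    UNMATCHED = "unmatched"


class AlternateStratum(str, Enum):
    GT50 = "gt50"
    LE50 = "le50"


class FineGrade(str, Enum):
    G0 = "g0"
    G1_39 = "g1_39"
    G40_59 = "g40_59"
    G60_99 = "g60_99"
    G100 = "g100"

    @property
    def ordinal(self) -> int:
        return [FineGrade.G0, FineGrade.G1_39, FineGrade.G40_59,
                FineGrade.G60_99, FineGrade.G100].index(self)


@dataclass(frozen=True)
class MatchingGrade:
    primary: PrimaryStratum
    alternate: AlternateStratum
    fine: FineGrade


# ---------------------------------------------------------------------------
# counting rules

def collapse_alterations(
    alterations: Sequence[Alteration],
    dedupe_across_reports: bool = False,
) -> list[CountableUnit]:
    """Collapse same-gene, same-impact, same-class aberrations into countable units.

    Within one report, two or more aberrations in the same gene with the same
    impact group and the same structural class count as one unit; structurally
    distinct same-gene events (e.g. amplification plus mutation) stay separate.
    Aberrations from different reports count independently by default, because
    tissue and blood samples can genuinely differ; ``dedupe_across_reports``
    collapses identical variants across reports for the stricter reading.
    VUS alterations are dropped before counting.
    """
    units: dict[tuple, CountableUnit] = {}
    for alt in alterations:
        if alt.pathogenicity is not Pathogenicity.CHARACTERIZED:
            continue
        impact = alt.impact_group if alt.impact_group else alt.alteration_class.value
        report = None if dedupe_across_reports else alt.report_id
        key = (report, alt.gene, alt.alteration_class, impact)
        if key in units:
            units[key].n_collapsed += 1
        else:
            units[key] = CountableUnit(
                gene=alt.gene, alteration_class=alt.alteration_class,
                impact_group=impact, report_id=report)
    return list(units.values())


def genomic_fraction(
    alterations: Sequence[Alteration],
    biomarkers: BiomarkerProfile,
    drugs: Iterable[str],
    kb: KnowledgeBase,
    dedupe_across_reports: bool = False,
) -> tuple[int, int, Fraction, list[CountableUnit]]:
    """Matched / total countable units, with synergy doubling and the hormone unit.

    Returns ``(numerator, denominator, X, units)`` where X is exact and 0 when
    the denominator is 0. Synergy doubling applies only when both drugs of a
    pair were administered and the unit is matched; the hormone unit enters
    numerator and denominator only when it fires, so an untargeted ER-positive
    status does not dilute the score.
    """
    drugs = set(drugs)
    units = collapse_alterations(alterations, dedupe_across_reports)
    firing_pairs = kb.firing_synergy_pairs(drugs)
    for unit in units:
        provenance = []
        for drug in sorted(drugs):
            verdict = drug_matches_alteration(kb, drug, unit.gene)
            if verdict.matched:
                provenance.append((drug, verdict.tag))
        unit.matched = bool(provenance)
        unit.provenance = tuple(provenance)
        if unit.matched and any(p.shared_target == unit.gene for p in firing_pairs):
            unit.weight = 2
    if hormone_match(kb, biomarkers, drugs):
        units.append(CountableUnit(
            gene=HORMONE_UNIT_GENE, alteration_class=None, impact_group="hormone_ihc",
            report_id=None, matched=True, weight=1,
            provenance=(("hormone_modulator", "hormone_ihc"),)))
    numerator = sum(u.weight for u in units if u.matched)
    denominator = sum(u.weight for u in units)
    x = Fraction(numerator, denominator) if denominator else Fraction(0)
    return numerator, denominator, x, units


def immunotherapy_component(
    biomarkers: BiomarkerProfile,
    drugs: Iterable[str],
    kb: KnowledgeBase,
) -> IoComponent:
    """Immunotherapy credit, earned only if checkpoint blockade was administered."""
    if not any(kb.drug(d).drug_class is DrugClass.CHECKPOINT_INHIBITOR for d in drugs):
        return IoComponent.NONE
    if (biomarkers.msi_status is MsiStatus.MSI_HIGH
            or biomarkers.tmb_category is TmbCategory.HIGH
            or biomarkers.pdl1_category is Pdl1Category.HIGH_POSITIVE):
        return IoComponent.FULL
    if (biomarkers.tmb_category is TmbCategory.INTERMEDIATE
            or biomarkers.pdl1_category is Pdl1Category.LOW_POSITIVE):
        return IoComponent.HALF
    return IoComponent.NONE


def matching_score(
    alterations: Sequence[Alteration],
    biomarkers: BiomarkerProfile,
    treatment: TreatmentPlan | Iterable[str],
    kb: KnowledgeBase,
    dedupe_across_reports: bool = False,
) -> MatchBreakdown:
    """Compute the Matching Score with its full audit breakdown.

    score = 100 with a full immunotherapy component; 50 + 100·X/2 with a half
    component; 100·X otherwise — always capped at 100.
    """
    drugs = treatment.drugs if isinstance(treatment, TreatmentPlan) else frozenset(treatment)
    num, den, x, units = genomic_fraction(
        alterations, biomarkers, drugs, kb, dedupe_across_reports)
    io = immunotherapy_component(biomarkers, drugs, kb)
    if io is IoComponent.FULL:
        score = Fraction(100)
    elif io is IoComponent.HALF:
        score = 50 + 100 * x / 2
    else:
        score = 100 * x
    score = min(score, Fraction(100))
    return MatchBreakdown(units=units, numerator=num, denominator=den,
                          genomic_fraction=x, io_component=io, score=score)


def assign_grade(score) -> MatchingGrade:
    """Stratify a score three ways: ≥60/1–59/0, >50/≤50, and five fine bins."""
    score = Fraction(score)
    if not 0 <= score <= 100:
        raise ValueError(f"score {float(score)} outside [0, 100]")
    if score >= 60:
        primary = PrimaryStratum.GE60
    elif score == 0:
        primary = PrimaryStratum.UNMATCHED
    else:
        primary = PrimaryStratum.S1_59
    alternate = AlternateStratum.GT50 if score > 50 else AlternateStratum.LE50
    if score == 0:
        fine = FineGrade.G0
    elif score < 40:
        fine = FineGrade.G1_39
    elif score < 60:
        fine = FineGrade.G40_59
    elif score < 100:
        fine = FineGrade.G60_99
    else:
        fine = FineGrade.G100
    return MatchingGrade(primary=primary, alternate=alternate, fine=fine)
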