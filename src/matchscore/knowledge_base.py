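"""Drug–target matching rules.

The knowledge base externalizes the curation a molecular tumor board performs
when it declares a drug "matched" to a genomic alteration: each drug carries the
set of genes (or immediate downstream effectors) it inhibits with curated
potency, plus two special rules — BRCA-pathway alterations matched by platinum
agents or PARP inhibitors, and TP53 alterations matched by drugs with
anti-VEGF/VEGFR activity (individually disableable for sensitivity analyses).

The on-disk format is a single JSON document with top-level keys ``drugs``,
``synergy_pairs``, ``special_rules`` and ``version``; a packaged seed covers
the drugs and rules used throughout the documentation and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "DrugClass",
    "DrugRecord",
    "SynergyPair",
    "SpecialRuleId",
    "SpecialMatchRule",
    "KnowledgeBase",
    "MatchVerdict",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "load_seed_knowledge_base",
    "write_knowledge_base",
    "export_targets_tsv",
    "drug_matches_alteration",
    "hormone_match",
]


class KnowledgeBaseError(ValueError):
    """Raised when a rules file violates the documented schema or its invariants."""


class DrugClass(str, Enum):
    SMALL_MOLECULE = "small_molecule"
    ANTIBODY = "antibody"
    CHECKPOINT_INHIBITOR = "checkpoint_inhibitor"
    PLATINUM_CHEMO = "platinum_chemo"
    PARP_INHIBITOR = "parp_inhibitor"
    HORMONE_MODULATOR = "hormone_modulator"
    CYTOTOXIC_OTHER = "cytotoxic_other"


class SpecialRuleId(str, Enum):
    BRCA_PLATINUM_PARP = "brca_platinum_parp"
    TP53_VEGF = "tp53_vegf"


def normalize_gene(symbol: str) -> str:
    """HGNC-style symbols are compared case-insensitively after trimming."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class DrugRecord:
    name: str
    drug_class: DrugClass
    targets: frozenset[str]  # normalized gene symbols, incl. downstream effectors
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise KnowledgeBaseError("drug name must be nonempty")
        object.__setattr__(self, "targets",
                           frozenset(normalize_gene(g) for g in self.targets))
        if self.drug_class in (DrugClass.SMALL_MOLECULE, DrugClass.ANTIBODY) and not self.targets:
            raise KnowledgeBaseError(
                f"drug {self.name!r}: {self.drug_class.value} requires a nonempty target set"
            )


@dataclass(frozen=True)
class SynergyPair:
    """Two drugs that co-target one aberration in an established synergistic combination."""

    drug_a: str
    drug_b: str
    shared_target: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "shared_target", normalize_gene(self.shared_target))


@dataclass(frozen=True)
class SpecialMatchRule:
    rule_id: SpecialRuleId
    trigger_genes: frozenset[str]
    satisfying_drug_classes: frozenset[DrugClass]
    satisfying_targets: frozenset[str]
    enabled: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "trigger_genes",
                           frozenset(normalize_gene(g) for g in self.trigger_genes))
        object.__setattr__(self, "satisfying_targets",
                           frozenset(normalize_gene(g) for g in self.satisfying_targets))

    def drug_satisfies(self, drug: DrugRecord) -> bool:
        return (drug.drug_class in self.satisfying_drug_classes
                or bool(drug.targets & self.satisfying_targets))


@dataclass
class KnowledgeBase:
    drugs: dict[str, DrugRecord]
    synergy_pairs: list[SynergyPair]
    special_rules: dict[SpecialRuleId, SpecialMatchRule]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rid in SpecialRuleId:
            if rid not in self.special_rules:
                raise KnowledgeBaseError(f"built-in special rule {rid.value!r} is missing")
        for pair in self.synergy_pairs:
            for name in (pair.drug_a, pair.drug_b):
                if name not in self.drugs:
                    raise KnowledgeBaseError(
                        f"synergy pair ({pair.drug_a}, {pair.drug_b}) references unknown drug {name!r}"
                    )
            for name in (pair.drug_a, pair.drug_b):
                if pair.shared_target not in self.drugs[name].targets:
                    raise KnowledgeBaseError(
                        f"synergy pair ({pair.drug_a}, {pair.drug_b}): shared target "
                        f"{pair.shared_target!r} is not a target of {name!r}"
                    )

    def drug(self, name: str) -> DrugRecord:
        try:
            return self.drugs[name]
        except KeyError:
            raise KeyError(f"unknown drug name {name!r}") from None

    def with_rule_disabled(self, rule_id: SpecialRuleId | str) -> "KnowledgeBase":
        """Copy of this knowledge base with one special rule switched off."""
        rid = SpecialRuleId(rule_id)
        rules = dict(self.special_rules)
        rules[rid] = replace(rules[rid], enabled=False)
        return KnowledgeBase(drugs=dict(self.drugs), synergy_pairs=list(self.synergy_pairs),
                             special_rules=rules, version=self.version)

    def firing_synergy_pairs(self, administered: Iterable[str]) -> list[SynergyPair]:
        given = set(administered)
        return [p for p in self.synergy_pairs if p.drug_a in given and p.drug_b in given]


@dataclass(frozen=True)
class MatchVerdict:
    """Boolean match verdict with exactly one provenance tag."""

    matched: bool
    tag: str  # direct_target | brca_platinum_parp | tp53_vegf | no_match

    def __bool__(self) -> bool:
        return self.matched


# ---------------------------------------------------------------------------
# serialization

def _parse_drug(rec: dict, idx: int) -> DrugRecord:
    try:
        return DrugRecord(
            name=rec["name"],
            drug_class=DrugClass(rec["drug_class"]),
            targets=frozenset(rec.get("targets", [])),
            notes=rec.get("notes", ""),
        )
    except (KeyError, ValueError) as exc:
        ident = rec.get("name", f"#{idx}")
        raise KnowledgeBaseError(f"drug record {ident!r}: {exc}") from exc


def _parse_rule(rec: dict) -> SpecialMatchRule:
    try:
        return SpecialMatchRule(
            rule_id=SpecialRuleId(rec["rule_id"]),
            trigger_genes=frozenset(rec["trigger_genes"]),
            satisfying_drug_classes=frozenset(
                DrugClass(c) for c in rec.get("satisfying_drug_classes", [])),
            satisfying_targets=frozenset(rec.get("satisfying_targets", [])),
            enabled=bool(rec.get("enabled", True)),
        )
    except (KeyError, ValueError) as exc:
        raise KnowledgeBaseError(f"special rule record {rec.get('rule_id')!r}: {exc}") from exc


def knowledge_base_from_dict(doc: dict) -> KnowledgeBase:
    drugs: dict[str, DrugRecord] = {}
    for i, rec in enumerate(doc.get("drugs", [])):
        drug = _parse_drug(rec, i)
        if drug.name in drugs:
            raise KnowledgeBaseError(f"duplicate drug name {drug.name!r}")
        drugs[drug.name] = drug
    pairs = [SynergyPair(p["drug_a"], p["drug_b"], p["shared_target"])
             for p in doc.get("synergy_pairs", [])]
    rules = {r.rule_id: r for r in map(_parse_rule, doc.get("special_rules", []))}
    return KnowledgeBase(drugs=drugs, synergy_pairs=pairs, special_rules=rules,
                         version=str(doc.get("version", "unversioned")))


def knowledge_base_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "version": kb.version,
        "drugs": [
            {"name": d.name, "drug_class": d.drug_class.value,
             "targets": sorted(d.targets), "notes": d.notes}
            for d in kb.drugs.values()
        ],
        "synergy_pairs": [
            {"drug_a": p.drug_a, "drug_b": p.drug_b, "shared_target": p.shared_target}
            for p in kb.synergy_pairs
        ],
        "special_rules": [
            {"rule_id": r.rule_id.value, "trigger_genes": sorted(r.trigger_genes),
             "satisfying_drug_classes": sorted(c.value for c in r.satisfying_drug_classes),
             "satisfying_targets": sorted(r.satisfying_targets), "enabled": r.enabled}
            for r in kb.special_rules.values()
        ],
    }


def load_knowledge_base(path: Union[str, Path]) -> KnowledgeBase:
    """Load and validate a rules file (JSON; see module docstring for the schema)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"rules file not found: {path}")
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise KnowledgeBaseError(f"rules file {path} is not valid JSON: {exc}") from exc
    return knowledge_base_from_dict(doc)


def write_knowledge_base(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(knowledge_base_to_dict(kb), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_seed_knowledge_base() -> KnowledgeBase:
    """The packaged seed rules: every drug and rule used in the worked examples."""
    with resources.files("matchscore.data").joinpath("seed_rules.json").open() as fh:
        return knowledge_base_from_dict(json.load(fh))


def export_targets_tsv(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    """One drug–target pair per row, for manual review of the curation."""
    with open(path, "w") as fh:
        fh.write("drug\tdrug_class\ttarget\n")
        for d in kb.drugs.values():
            for t in sorted(d.targets):
                fh.write(f"{d.name}\t{d.drug_class.value}\t{t}\n")


# ---------------------------------------------------------------------------
# matching

def drug_matches_alteration(kb: KnowledgeBase, drug: str, alteration) -> MatchVerdict:
    """Decide whether one administered drug is matched to one alteration.

    ``alteration`` may be anything with a ``gene`` attribute, or a bare gene
    symbol. A direct target hit takes precedence over the special rules, so the
    returned tag identifies the clause that actually fired.
    """
    record = kb.drug(drug)
    gene = normalize_gene(getattr(alteration, "gene", alteration))
    if gene in record.targets:
        return MatchVerdict(True, "direct_target")
    for rule in kb.special_rules.values():
        if rule.enabled and gene in rule.trigger_genes and rule.drug_satisfies(record):
            return MatchVerdict(True, rule.rule_id.value)
    return MatchVerdict(False, "no_match")


def hormone_match(kb: KnowledgeBase, biomarkers, drugs: Iterable[str]) -> bool:
    """ER- or AR-positive IHC targeted by an administered hormone modulator."""
    positive = bool(getattr(biomarkers, "er_positive", False)) or bool(
        getattr(biomarkers, "ar_positive", False))
    if not positive:
        return False
    return any(kb.drug(d).drug_class is DrugClass.HORMONE_MODULATOR for d in drugs)
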