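"""Chemical-class assignment by parent-scaffold substructure matching.

Each psychoactive is assigned to the class of the highest-priority
scaffold rule whose SMARTS pattern occurs as a subgraph of its structure;
molecules matching no rule fall into "other".  The default rules encode
the parent molecules of the classes analysed here:

* cathinone    — beta-keto alpha-methyl phenethylamine (highest priority)
* amphetamine  — alpha-methyl phenethylamine
* phenethylamine — the 2-phenylethylamine parent chain (benzylic carbon
  may be sp3 or a carbonyl so the beta-keto family stays inside it)
* tryptamine   — 3-(2-aminoethyl)indole
* cannabinoid  — two patterns: the 5-alkylresorcinol core shared by the
  classical cannabinoids, and the fused benzopyran core

The patterns are reconstructions from the parent-molecule definitions of
the classes (the published pattern files are not reproduced here); they
are data, not code — pass a custom rule set to override.  The default
set is nested by construction: every cathinone match is an amphetamine
match is a phenethylamine match, and priority resolves the overlap.
"""

from __future__ import annotations

import pathlib
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import yaml

from .data_model import CHEM_CLASSES, CompoundRecord, ValidationError

__all__ = [
    "ScaffoldRule",
    "DEFAULT_RULES",
    "classify",
    "classify_library",
    "load_rules",
    "save_rules",
]


@dataclass(frozen=True)
class ScaffoldRule:
    class_label: str
    pattern: str  # SMARTS
    priority: int  # higher wins

    def __post_init__(self) -> None:
        if self.class_label not in CHEM_CLASSES or self.class_label == "none":
            raise ValidationError(
                f"rule class must be a psychoactive class, got {self.class_label!r}"
            )
        from rdkit import Chem

        if Chem.MolFromSmarts(self.pattern) is None:
            raise ValidationError(
                f"SMARTS pattern does not parse: {self.pattern!r}"
            )


DEFAULT_RULES: tuple[ScaffoldRule, ...] = (
    ScaffoldRule("cathinone", "c1ccccc1[CX3](=O)[CX4]([CH3])[NX3]", 50),
    ScaffoldRule("amphetamine", "c1ccccc1[#6X3,#6X4][CX4]([CH3])[NX3]", 40),
    ScaffoldRule("phenethylamine", "c1ccccc1[#6X3,#6X4][CX4][NX3]", 30),
    ScaffoldRule("tryptamine", "c1ccc2c(c1)c(c[nX3]2)[CX4][CX4][NX3]", 20),
    ScaffoldRule("cannabinoid", "[OX2]c1cc([OX2])cc([#6X4])c1", 11),
    ScaffoldRule("cannabinoid", "[OX2]1[CX4]c2ccccc2[#6]~[#6]1", 10),
)


def _check_rules(rules: Sequence[ScaffoldRule]) -> list[ScaffoldRule]:
    rules = list(rules)
    if not rules:
        raise ValidationError("empty scaffold rule set")
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValidationError("rule priorities must be unique")
    return sorted(rules, key=lambda r: -r.priority)


def classify(smiles: str, rules: Sequence[ScaffoldRule] = DEFAULT_RULES) -> str:
    """Class label of the highest-priority rule matching the molecule.

    Returns "other" when no rule matches.  Unparseable structures raise.
    Matching is on the molecular graph, so any SMILES writing of the same
    molecule classifies identically.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable structure: {smiles!r}")
    for rule in _check_rules(rules):
        patt = Chem.MolFromSmarts(rule.pattern)
        if mol.HasSubstructMatch(patt):
            return rule.class_label
    return "other"


def classify_library(
    compounds: Iterable[CompoundRecord],
    rules: Sequence[ScaffoldRule] = DEFAULT_RULES,
) -> tuple[list[CompoundRecord], dict[str, int], list[tuple[str, str]]]:
    """Fill chem_class for every structure-bearing psychoactive.

    Returns (updated records, per-class tally, parse failures).  Records
    without structures, and non-psychoactives, are left untouched; parse
    failures are collected, not raised.  Idempotent: re-running on
    already-classified records yields the same output.
    """
    _check_rules(rules)
    updated: list[CompoundRecord] = []
    tally: Counter[str] = Counter()
    failures: list[tuple[str, str]] = []
    for rec in compounds:
        if not rec.is_psychoactive or not rec.smiles:
            updated.append(rec)
            continue
        try:
            label = classify(rec.smiles, rules)
        except ValidationError as exc:
            failures.append((rec.compound_id, str(exc)))
            updated.append(rec)
            continue
        tally[label] += 1
        updated.append(replace(rec, chem_class=label))
    return updated, dict(tally), failures


def load_rules(path: str | pathlib.Path) -> tuple[ScaffoldRule, ...]:
    """Read a rule set from YAML: a list of {class_label, pattern, priority}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError("rules file must hold a list of rules")
    rules = tuple(
        ScaffoldRule(
            class_label=item["class_label"],
            pattern=item["pattern"],
            priority=int(item["priority"]),
        )
        for item in raw
    )
    _check_rules(rules)
    return rules


def save_rules(
    rules: Sequence[ScaffoldRule], path: str | pathlib.Path
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {
                    "class_label": r.class_label,
                    "pattern": r.pattern,
                    "priority": r.priority,
                }
                for r in rules
            ],
            fh,
            sort_keys=False,
        )
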