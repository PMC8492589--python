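"""Phase-I biotransformation rules and candidate-metabolite enumeration.

Rules are net elemental deltas, not structure-graph transforms: in vitro
metabolite identification by LC-HRMS/MS works at the level of elemental
composition and fragment shifts, so a composition-level catalogue is both
sufficient and honest about what the data can distinguish.  Rule order
within a pathway is irrelevant to the resulting formula, so rule sequences
are stored in canonical sorted order and duplicate formulas collapse to the
shallowest pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .compounds import Compound
from .formula import (
    ElementalFormula,
    InfeasibleDeltaError,
    MassDelta,
    apply_delta,
    protonated_mz,
)

__all__ = [
    "BiotransformationRule",
    "MetaboliteCandidate",
    "default_catalog",
    "load_catalog",
    "enumerate_candidates",
    "explain_candidate",
    "candidates_to_frame",
]

ANY_BLOCK = "any"


@dataclass(frozen=True)
class BiotransformationRule:
    """A named reaction as a net elemental delta with block applicability."""

    name: str
    delta: MassDelta
    applicable_blocks: Union[str, FrozenSet[str]] = ANY_BLOCK
    max_applications: int = 1

    def applies_to(self, block_names: FrozenSet[str]) -> bool:
        if self.applicable_blocks == ANY_BLOCK:
            return True
        return bool(frozenset(self.applicable_blocks) & block_names)


@dataclass(frozen=True)
class MetaboliteCandidate:
    """A candidate phase-I metabolite: parent + an unordered rule multiset."""

    parent_id: str
    rules: Tuple[str, ...]  # canonical (sorted) order
    formula: ElementalFormula
    predicted_mz: float  # [M+H]+
    depth: int

    @property
    def candidate_id(self) -> str:
        return f"{self.parent_id}|{'+'.join(self.rules) if self.rules else 'parent'}"

    @property
    def is_parent(self) -> bool:
        return not self.rules


def _parse_rule(entry: Mapping) -> BiotransformationRule:
    blocks = entry.get("blocks", ANY_BLOCK)
    if blocks != ANY_BLOCK:
        blocks = frozenset(blocks)
    return BiotransformationRule(
        name=entry["name"],
        delta=MassDelta.from_terms(entry["name"], entry["delta"]),
        applicable_blocks=blocks,
        max_applications=int(entry.get("max_applications", 1)),
    )


def load_catalog(path: Optional[str] = None) -> Dict[str, List[BiotransformationRule]]:
    """Load a rule catalogue keyed by structural class from YAML."""
    if path is None:
        text = resources.files("scmetox").joinpath("data/catalog.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        cls: [_parse_rule(e) for e in entries]
        for cls, entries in raw["classes"].items()
    }


def default_catalog(parent_class: str) -> List[BiotransformationRule]:
    """The shipped rule set for one structural class."""
    catalog = load_catalog()
    try:
        return catalog[parent_class]
    except KeyError:
        raise KeyError(
            f"unknown parent class {parent_class!r}; shipped: {sorted(catalog)}"
        ) from None


def enumerate_candidates(
    parent: Compound,
    rules: Optional[Sequence[BiotransformationRule]] = None,
    max_depth: int = 2,
) -> List[MetaboliteCandidate]:
    """Enumerate candidate metabolite formulas up to ``max_depth`` rule steps.

    Applies every multiset of applicable rules (respecting each rule's
    ``max_applications``) to the parent formula.  Multisets whose deltas
    would drive an element count negative are skipped.  Duplicate formulas
    collapse keeping the shallowest pathway (ties: lexicographically first
    rule multiset).  Output is deterministically ordered by
    ``(depth, predicted m/z, rules)``; depth 0 is the parent itself.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if rules is None:
        rules = default_catalog(parent.parent_class)
    usable = sorted(
        (r for r in rules if r.applies_to(parent.block_names)),
        key=lambda r: r.name,
    )

    best: Dict[tuple, MetaboliteCandidate] = {}

    def visit(formula: ElementalFormula, names: Tuple[str, ...]) -> None:
        cand = MetaboliteCandidate(
            parent_id=parent.compound_id,
            rules=names,
            formula=formula,
            predicted_mz=protonated_mz(formula),
            depth=len(names),
        )
        key = formula.key()
        prev = best.get(key)
        if prev is None or (cand.depth, cand.rules) < (prev.depth, prev.rules):
            best[key] = cand

    def recurse(
        formula: ElementalFormula, names: Tuple[str, ...], start: int, left: int
    ) -> None:
        visit(formula, names)
        if left == 0:
            return
        for i in range(start, len(usable)):
            rule = usable[i]
            used = names.count(rule.name)
            if used >= rule.max_applications:
                continue
            try:
                nxt = apply_delta(formula, rule.delta)
            except InfeasibleDeltaError:
                continue
            recurse(nxt, tuple(sorted(names + (rule.name,))), i, left - 1)

    recurse(parent.formula, (), 0, max_depth)
    return sorted(best.values(), key=lambda c: (c.depth, c.predicted_mz, c.rules))


def explain_candidate(
    c: MetaboliteCandidate, rules: Optional[Sequence[BiotransformationRule]] = None
) -> str:
    """Human-readable pathway: rule names with their mass shifts in u."""
    if not c.rules:
        return "parent"
    if rules is None:
        try:
            from .compounds import get_compound

            rules = default_catalog(get_compound(c.parent_id).parent_class)
        except KeyError:
            rules = []
    by_name = {r.name: r for r in rules}
    parts = []
    for name in c.rules:
        rule = by_name.get(name)
        if rule is None:
            parts.append(name)
        else:
            m = rule.delta.mass
            parts.append(f"{name} ({'+' if m >= 0 else '-'}{abs(m):.4f})")
    return ", ".join(parts)


def candidates_to_frame(candidates: Iterable[MetaboliteCandidate]):
    """Candidates as a pandas DataFrame (CSV-export layout)."""
    import pandas as pd

    rows = [
        {
            "parent": c.parent_id,
            "rules": "+".join(c.rules) if c.rules else "parent",
            "formula": str(c.formula),
            "predicted_mz": round(c.predicted_mz, 4),
            "depth": c.depth,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=["parent", "rules", "formula", "predicted_mz", "depth"])
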