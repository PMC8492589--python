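"""Shipped compound definitions: formulas, structural blocks, templates.

The three synthetic cannabinoids covered out of the box are JWH-200
(naphthoylindole), A-796260 (tetramethylcyclopropanoylindole) and
5F-EMB-PINACA (indazole carboxamide ester).  Each is described by its
elemental formula, a block model (head / core / tail / sidechain
substructures whose compositions sum, with documented linkage hydrogens,
to the parent formula), and curated fragment templates used for shift-based
annotation.  Definitions live in ``data/compounds.yaml`` and can be extended
with user config files of the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import yaml

from .formula import ElementalFormula, cation_mz, parse_formula, protonated_mz

__all__ = [
    "BlockModel",
    "FragmentTemplate",
    "Compound",
    "get_compound",
    "list_compounds",
    "load_compounds",
]

TEMPLATE_MZ_TOL = 0.0005  # templates must reproduce printed FIs to 4 decimals


class CompoundConfigError(ValueError):
    """Inconsistent compound definition (block sums, template masses)."""


@dataclass(frozen=True)
class BlockModel:
    """Named substructure blocks of one compound.

    Block formulas are the compositions the blocks contribute to the neutral
    molecule; ``linkage_hydrogens`` accounts for hydrogens that sit on bonds
    broken when the molecule is partitioned, so that
    ``sum(blocks) + H*linkage_hydrogens == parent``.
    """

    compound_id: str
    blocks: Mapping[str, ElementalFormula]
    linkage_hydrogens: int = 0

    @property
    def block_names(self) -> FrozenSet[str]:
        return frozenset(self.blocks)

    def check_against(self, parent: ElementalFormula) -> None:
        total = ElementalFormula({"H": self.linkage_hydrogens})
        for f in self.blocks.values():
            total = total + f
        if total.key() != parent.key():
            raise CompoundConfigError(
                f"{self.compound_id}: blocks sum to {total}, parent is {parent}"
            )


@dataclass(frozen=True)
class FragmentTemplate:
    """A parent fragment: even-electron cation composition + retained blocks."""

    parent_id: str
    label: str
    formula: ElementalFormula
    blocks: FrozenSet[str]

    @property
    def mz(self) -> float:
        return cation_mz(self.formula)


@dataclass(frozen=True)
class Compound:
    compound_id: str
    formula: ElementalFormula
    parent_class: str
    block_model: BlockModel
    templates: Tuple[FragmentTemplate, ...] = field(default_factory=tuple)

    @property
    def mz(self) -> float:
        """[M+H]+ of the parent."""
        return protonated_mz(self.formula)

    @property
    def block_names(self) -> FrozenSet[str]:
        return self.block_model.block_names


def _build_compound(cid: str, spec: Mapping) -> Compound:
    formula = parse_formula(spec["formula"])
    blocks = {
        name: parse_formula(entry["formula"])
        for name, entry in spec.get("blocks", {}).items()
    }
    model = BlockModel(cid, blocks, int(spec.get("linkage_hydrogens", 0)))
    model.check_against(formula)
    templates: List[FragmentTemplate] = []
    for entry in spec.get("templates", []):
        tpl = FragmentTemplate(
            parent_id=cid,
            label=entry["label"],
            formula=parse_formula(entry["formula"]),
            blocks=frozenset(entry["blocks"]),
        )
        unknown = tpl.blocks - model.block_names
        if unknown:
            raise CompoundConfigError(
                f"{cid}/{tpl.label}: unknown blocks {sorted(unknown)}"
            )
        expected = entry.get("mz")
        if expected is not None and abs(tpl.mz - float(expected)) > TEMPLATE_MZ_TOL:
            raise CompoundConfigError(
                f"{cid}/{tpl.label}: formula {tpl.formula} gives m/z "
                f"{tpl.mz:.4f}, config says {expected}"
            )
        templates.append(tpl)
    return Compound(cid, formula, spec["parent_class"], model, tuple(templates))


def load_compounds(path: Optional[str] = None) -> Dict[str, Compound]:
    """Load compound definitions from a YAML file (default: shipped set)."""
    if path is None:
        text = (
            resources.files("scmetox").joinpath("data/compounds.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {cid: _build_compound(cid, spec) for cid, spec in raw["compounds"].items()}


_REGISTRY: Optional[Dict[str, Compound]] = None


def _registry() -> Dict[str, Compound]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_compounds()
    return _REGISTRY


def get_compound(compound_id: str) -> Compound:
    try:
        return _registry()[compound_id]
    except KeyError:
        raise KeyError(
            f"unknown compound {compound_id!r}; shipped: {sorted(_registry())}"
        ) from None


def list_compounds() -> List[str]:
    return sorted(_registry())
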