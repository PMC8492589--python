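"""Shift-based fragment annotation and block-level modification localization.

The identification idiom for designer-drug metabolites in HRMS2 data is
template-plus-shift reasoning: a metabolite's fragment either matches a
parent fragment unchanged (the fragment's substructure does not carry the
modification), or matches it shifted by the reaction's mass delta or by a
common neutral loss.  A fragment observed *shifted by the reaction delta*
restricts the modification to the blocks that fragment retains; a fragment
observed *unshifted* excludes its blocks.  Intersecting those constraints
localizes the modification, exactly as a mass spectrometrist argues from a
printed spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .compounds import BlockModel, Compound, FragmentTemplate
from .formula import MassDelta
from .rules import BiotransformationRule, MetaboliteCandidate, default_catalog
from .spectra import SpectrumRecord

__all__ = [
    "FragmentAssignment",
    "LocalizationResult",
    "NEUTRAL_LOSSES",
    "build_templates",
    "annotate_spectrum",
    "localize",
    "assignments_to_frame",
    "annotation_report",
]

# Common even-electron neutral losses seen in positive-mode HRMS2 of small
# molecules.  Ethanol covers ester cleavage of ethyl esters.
NEUTRAL_LOSSES: Tuple[MassDelta, ...] = (
    MassDelta.from_terms("loss of H2O", "-H2O"),
    MassDelta.from_terms("loss of CO", "-CO"),
    MassDelta.from_terms("loss of HF", "-HF"),
    MassDelta.from_terms("loss of C2H4O", "-C2H4O"),
    MassDelta.from_terms("loss of C2H4", "-C2H4"),
    MassDelta.from_terms("loss of C2H6O", "-C2H6O"),
)

DEFAULT_TOL_MDA = 5.0


@dataclass(frozen=True)
class FragmentAssignment:
    """One observed fragment explained as template (+ optional shift)."""

    observed_mz: float
    intensity: float
    template: FragmentTemplate
    shift: Optional[MassDelta]  # None = template matched unshifted
    error_mda: float

    @property
    def blocks(self) -> FrozenSet[str]:
        return self.template.blocks

    @property
    def shifted(self) -> bool:
        return self.shift is not None


@dataclass(frozen=True)
class LocalizationResult:
    """Blocks consistent with all shifted/unshifted fragment evidence."""

    candidate_id: str
    consistent_blocks: FrozenSet[str]
    status: str  # "localized" | "ambiguous" | "conflict"

    def __post_init__(self) -> None:
        n = len(self.consistent_blocks)
        expected = "localized" if n == 1 else ("conflict" if n == 0 else "ambiguous")
        if self.status != expected:
            raise ValueError(f"status {self.status!r} inconsistent with {n} blocks")


def build_templates(compound: Compound) -> List[FragmentTemplate]:
    """The compound's curated fragment templates (validated at load time)."""
    return list(compound.templates)


def _candidate_shifts(
    candidate: MetaboliteCandidate,
    rules: Optional[Sequence[BiotransformationRule]],
) -> List[MassDelta]:
    if rules is None:
        try:
            from .compounds import get_compound

            rules = default_catalog(get_compound(candidate.parent_id).parent_class)
        except KeyError:
            rules = []
    by_name = {r.name: r for r in rules}
    shifts: List[MassDelta] = []
    seen: Set[tuple] = set()
    for name in candidate.rules:
        rule = by_name.get(name)
        if rule is not None and rule.delta.key() not in seen:
            seen.add(rule.delta.key())
            shifts.append(rule.delta)
    return shifts


def annotate_spectrum(
    spectrum: SpectrumRecord,
    templates: Sequence[FragmentTemplate],
    candidate: MetaboliteCandidate,
    allowed_shifts: Optional[Sequence[MassDelta]] = None,
    tol_mda: float = DEFAULT_TOL_MDA,
    rules: Optional[Sequence[BiotransformationRule]] = None,
) -> Tuple[List[FragmentAssignment], List[float]]:
    """Assign each observed fragment to the best (template, shift) pair.

    ``allowed_shifts`` defaults to the candidate's own rule deltas plus the
    standard neutral losses; at most one shift is applied per fragment.
    Ties break by smaller |error|, then an empty shift is preferred over any
    shifted explanation, then alphabetically by template label.  Returns the
    assignments and the list of unassigned fragment m/z values.
    """
    if allowed_shifts is None:
        allowed_shifts = _candidate_shifts(candidate, rules) + list(NEUTRAL_LOSSES)
    options: List[Tuple[float, FragmentTemplate, Optional[MassDelta]]] = []
    for tpl in templates:
        options.append((tpl.mz, tpl, None))
        for shift in allowed_shifts:
            options.append((tpl.mz + shift.mass, tpl, shift))

    assignments: List[FragmentAssignment] = []
    unassigned: List[float] = []
    for mz, intensity in spectrum.fragments:
        scored = []
        for expected, tpl, shift in options:
            err = 1e3 * (mz - expected)
            if abs(err) <= tol_mda:
                scored.append((abs(err), shift is not None, tpl.label, err, tpl, shift))
        if not scored:
            unassigned.append(mz)
            continue
        scored.sort(key=lambda t: t[:3])
        _, _, _, err, tpl, shift = scored[0]
        assignments.append(
            FragmentAssignment(
                observed_mz=mz, intensity=intensity,
                template=tpl, shift=shift, error_mda=err,
            )
        )
    return assignments, unassigned


def localize(
    assignments: Iterable[FragmentAssignment],
    block_model: BlockModel,
    rule_delta: MassDelta,
    candidate_id: str = "",
) -> LocalizationResult:
    """Constrain the modified block from shifted/unshifted fragment evidence.

    Only two kinds of evidence bear on localization: fragments shifted by
    exactly the reaction delta (the modification sits in their blocks) and
    fragments matched with no shift at all (their blocks are unmodified).
    Fragments explained by unrelated neutral losses are informative about
    fragmentation, not about the modification site, and are ignored here.
    With no evidence, every block remains possible (ambiguous); an empty
    intersection means the evidence is self-contradictory (conflict).
    """
    consistent: Set[str] = set(block_model.block_names)
    for a in assignments:
        if a.shift is not None and a.shift.key() == rule_delta.key():
            consistent &= set(a.blocks)
        elif a.shift is None:
            consistent -= set(a.blocks)
    status = (
        "localized" if len(consistent) == 1
        else "conflict" if not consistent
        else "ambiguous"
    )
    return LocalizationResult(candidate_id, frozenset(consistent), status)


def assignments_to_frame(
    assignments: Iterable[FragmentAssignment],
) -> pd.DataFrame:
    rows = [
        {
            "observed_mz": round(a.observed_mz, 4),
            "template": a.template.label,
            "shift": a.shift.label if a.shift else "",
            "error_mda": round(a.error_mda, 4),
        }
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=["observed_mz", "template", "shift", "error_mda"])


def annotation_report(
    assignments: Iterable[FragmentAssignment],
    unassigned: Iterable[float] = (),
) -> str:
    """Prose-style report: 'FI x corresponds to FI y by shift z'."""
    lines = []
    for a in assignments:
        if a.shift is None:
            lines.append(
                f"FI at m/z {a.observed_mz:.4f} corresponds to {a.template.label} "
                f"at m/z {a.template.mz:.4f} (unshifted, {a.error_mda:+.2f} mDa)"
            )
        else:
            m = a.shift.mass
            lines.append(
                f"FI at m/z {a.observed_mz:.4f} corresponds to {a.template.label} "
                f"at m/z {a.template.mz:.4f} by {a.shift.label} "
                f"({'+' if m >= 0 else '-'}{abs(m):.4f} u, {a.error_mda:+.2f} mDa)"
            )
    for mz in unassigned:
        lines.append(f"FI at m/z {mz:.4f} unassigned")
    return "\n".join(lines)
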