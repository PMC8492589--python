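"""Isozyme mapping: presence/absence of initial metabolites per enzyme.

Single-enzyme (Supersome) incubations tell which CYP or FMO isoforms can
catalyze each initial metabolic step; pooled human liver microsomes (pHLM)
contain the full enzyme complement including carboxylesterases.  A step seen
in pHLM but in no single-enzyme incubation therefore implicates a non-CYP,
non-FMO enzyme — for ester substrates typically a carboxylesterase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .spectra import PeakMatch

__all__ = [
    "ENZYME_PANEL",
    "PHLM",
    "NEGATIVE_CONTROL",
    "POSITIVE_CONTROL",
    "IncubationPanel",
    "StepSummary",
    "MappingSummary",
    "build_panel",
    "summarize_mapping",
]

# Single-enzyme incubation vocabulary (cDNA-expressed Supersomes).
ENZYME_PANEL: Tuple[str, ...] = (
    "CYP1A2", "CYP2A6", "CYP2B6", "CYP2C8", "CYP2C9", "CYP2C19",
    "CYP2D6", "CYP2E1", "CYP3A4", "CYP3A5", "FMO3",
)
PHLM = "pHLM"
NEGATIVE_CONTROL = "negative control"
POSITIVE_CONTROL = "positive control"
PANEL_VOCABULARY: Tuple[str, ...] = ENZYME_PANEL + (PHLM, NEGATIVE_CONTROL, POSITIVE_CONTROL)


@dataclass
class IncubationPanel:
    """Boolean detection matrix: metabolite (row) x incubation (column)."""

    detections: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = [c for c in self.detections.columns if c not in PANEL_VOCABULARY]
        if unknown:
            raise ValueError(f"unknown incubation labels {unknown}")

    @property
    def analytes(self) -> List[str]:
        return list(self.detections.index)

    def to_table(self) -> pd.DataFrame:
        """Check-mark table mirroring a supplementary-style layout."""
        return self.detections.map(lambda v: "✓" if v else "")


@dataclass(frozen=True)
class StepSummary:
    analyte_id: str
    contributors: Tuple[str, ...]  # single enzymes that form the metabolite
    in_phlm: bool
    phlm_only: bool
    note: str = ""


@dataclass
class MappingSummary:
    steps: List[StepSummary] = field(default_factory=list)
    top_isozymes: Tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "analyte_id": s.analyte_id,
                "contributors": ";".join(s.contributors),
                "in_phlm": s.in_phlm,
                "phlm_only": s.phlm_only,
                "note": s.note,
            }
            for s in self.steps
        ]
        return pd.DataFrame(
            rows, columns=["analyte_id", "contributors", "in_phlm", "phlm_only", "note"]
        )


def build_panel(
    matches_by_incubation: Mapping[str, Iterable[PeakMatch]],
    min_intensity: float = 0.0,
) -> IncubationPanel:
    """Collapse per-incubation precursor matches into a detection matrix.

    Detection is qualitative: at least one match with precursor intensity
    above ``min_intensity`` (default 0, i.e. any match counts).  Duplicate
    matches of the same metabolite in one incubation are idempotent.
    Metabolites are keyed by candidate id; the parent compound row (depth 0)
    is dropped since it is present in every incubation by construction.
    """
    unknown = [lab for lab in matches_by_incubation if lab not in PANEL_VOCABULARY]
    if unknown:
        raise ValueError(
            f"unknown incubation labels {unknown}; expected one of {list(PANEL_VOCABULARY)}"
        )
    detected: Dict[str, Dict[str, bool]] = {}
    for label, matches in matches_by_incubation.items():
        for m in matches:
            if m.depth == 0:
                continue
            if m.precursor_intensity < min_intensity:
                continue
            detected.setdefault(m.candidate_id, {})[label] = True
    columns = [lab for lab in PANEL_VOCABULARY if lab in matches_by_incubation]
    rows = sorted(detected)
    frame = pd.DataFrame(False, index=rows, columns=columns)
    for cid, cells in detected.items():
        for label in cells:
            frame.loc[cid, label] = True
    return IncubationPanel(frame)


def summarize_mapping(panel: IncubationPanel) -> MappingSummary:
    """Contributing isozymes per step, pHLM-only flags, top contributors.

    Invariant to row and column order of the panel.  The pHLM-only flag is
    set exactly when a step is detected in pHLM and in no single-enzyme
    incubation, and is annotated as consistent with a non-CYP/FMO enzyme
    (carboxylesterase) since pHLM is the only preparation containing those.
    """
    frame = panel.detections
    enzymes = [e for e in ENZYME_PANEL if e in frame.columns]
    steps: List[StepSummary] = []
    counts: Dict[str, int] = {e: 0 for e in enzymes}
    for analyte in sorted(frame.index):
        row = frame.loc[analyte]
        contributors = tuple(e for e in enzymes if bool(row.get(e, False)))
        in_phlm = bool(row.get(PHLM, False))
        phlm_only = in_phlm and not contributors
        note = (
            "pHLM-only: consistent with a non-CYP/FMO enzyme (carboxylesterase)"
            if phlm_only
            else ""
        )
        for e in contributors:
            counts[e] += 1
        steps.append(StepSummary(analyte, contributors, in_phlm, phlm_only, note))
    best = max(counts.values(), default=0)
    top = tuple(sorted(e for e, n in counts.items() if n == best and n > 0))
    return MappingSummary(steps=steps, top_isozymes=top)
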