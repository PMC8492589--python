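"""Well-level HCSA pipeline: normalization, testing, verdict classification.

Six parameters per well: cell count, nuclear size, nuclear intensity,
mitochondrial membrane potential, cytosolic calcium, plasma membrane
integrity.  The cell count is normalized to the number of quality-passing
fields; every other parameter is the per-well mean channel total divided by
the cell count.  The prescreen incubates a compound at a low (7.81 uM) and a
high (125 uM) concentration, with and without the broad CYP inhibitor ABT,
against blank incubations; per parameter the six groups are compared by
one-way ANOVA + Tukey post hoc, and the verdict follows the rule:

* **strong** — at least two parameters significant at the low concentration;
* **moderate** — at least two parameters significant in total, at least one
  of them at the low concentration (and not strong);
* **negative** — otherwise (significances only at the high concentration,
  or none at all).

The published wording of the moderate rule ("two parameters ... and one of
these at 7.81 uM") is ambiguous between exactly-two and at-least-two; this
implementation reads it as at-least-two and says so in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .imaging import FieldSummary
from .posthoc import DEFAULT_ALPHA, StatResult, tukey_test

__all__ = [
    "PARAMETERS",
    "WellRecord",
    "ClassificationResult",
    "PrescreenReport",
    "summarize_well",
    "classify_prescreen",
    "run_prescreen",
    "abt_effect",
    "wells_to_frame",
    "frame_to_wells",
]

PARAMETERS: Tuple[str, ...] = (
    "cell_count",
    "nuclear_size",
    "nuclear_intensity",
    "mito_potential",
    "calcium",
    "membrane_integrity",
)

#: channel feeding each intensity parameter
_CHANNEL_FOR = {"mito_potential": "mito", "calcium": "calcium",
                "membrane_integrity": "membrane"}

LOW_UM = 7.81
HIGH_UM = 125.0
CONCENTRATION_GRID: Tuple[float, ...] = (0.0, 1.95, 3.91, 7.81, 15.6, 31.3, 62.5, 125.0)

MODERATE_RULE_NOTE = (
    "moderate rule read as: >=2 parameters significant in total with >=1 at "
    "the low concentration, not meeting the strong rule (the published "
    "wording is ambiguous between exactly two and at least two)"
)


@dataclass
class WellRecord:
    """Treatment metadata plus the six normalized parameters of one well."""

    well_id: str
    compound: str
    concentration: float  # uM; 0 = blank
    abt: bool = False
    control_type: Optional[str] = None  # "blank" | "untreated" | "positive" | None
    replicate: int = 1
    parameters: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [p for p in PARAMETERS if p not in self.parameters]
        if missing:
            raise ValueError(f"well {self.well_id}: missing parameters {missing}")


@dataclass(frozen=True)
class ClassificationResult:
    compound: str
    verdict: str  # "strong" | "moderate" | "negative"
    significant_low: Tuple[str, ...]
    significant_high: Tuple[str, ...]
    note: str = MODERATE_RULE_NOTE


@dataclass
class PrescreenReport:
    classification: ClassificationResult
    tests: Dict[str, List[StatResult]]  # per parameter, all Tukey pairs
    abt_comparisons: List[StatResult] = field(default_factory=list)

    def summary(self) -> str:
        c = self.classification
        lines = [
            f"compound: {c.compound}",
            f"verdict: {c.verdict}",
            f"significant at {LOW_UM} uM: {', '.join(c.significant_low) or 'none'}",
            f"significant at {HIGH_UM} uM: {', '.join(c.significant_high) or 'none'}",
            f"note: {c.note}",
        ]
        flagged = [r.label for r in self.abt_comparisons if r.significant]
        lines.append(f"ABT-sensitive comparisons: {', '.join(flagged) or 'none'}")
        return "\n".join(lines)


def summarize_well(
    fields: Sequence[FieldSummary],
    well_id: str = "",
    compound: str = "",
    concentration: float = 0.0,
    abt: bool = False,
    control_type: Optional[str] = None,
    replicate: int = 1,
) -> Optional[WellRecord]:
    """Aggregate quality-passing fields of one well into the six parameters.

    Cell count is the total region count divided by the number of passing
    fields; nuclear size (mean region area), nuclear intensity, and the
    three dye totals are per-well means divided by the cell count — nuclear
    size included, for consistency with the other parameters, even though
    area-per-nucleus is already count-independent.  A well with no passing
    fields or no detected nuclei is excluded (returns None with a warning).
    """
    passing = [f for f in fields if f.qc_pass]
    if not passing:
        warnings.warn(f"well {well_id or '?'}: no quality-passing fields; excluded")
        return None
    n = len(passing)
    cell_count = sum(f.region_count for f in passing) / n
    if cell_count <= 0:
        warnings.warn(f"well {well_id or '?'}: no nuclei detected; excluded")
        return None
    mean_area = float(np.mean([f.mean_region_area for f in passing]))
    mean_nuc_int = float(np.mean([f.total_nuclei_intensity for f in passing]))
    params = {
        "cell_count": cell_count,
        "nuclear_size": mean_area / cell_count,
        "nuclear_intensity": mean_nuc_int / cell_count,
    }
    for pname, channel in _CHANNEL_FOR.items():
        total = float(np.mean([f.channel_totals.get(channel, 0.0) for f in passing]))
        params[pname] = total / cell_count
    return WellRecord(
        well_id=well_id, compound=compound, concentration=concentration,
        abt=abt, control_type=control_type, replicate=replicate, parameters=params,
    )


def classify_prescreen(
    significant_low: Mapping[str, bool],
    significant_high: Mapping[str, bool],
    compound: str = "",
) -> ClassificationResult:
    """Apply the strong/moderate/negative decision rule to significance flags.

    ``significant_low``/``significant_high`` map each of the six parameters
    to whether it differed significantly from blank incubations at the low
    (7.81 uM) and high (125 uM) concentration, respectively.
    """
    for table, which in ((significant_low, "low"), (significant_high, "high")):
        missing = [p for p in PARAMETERS if p not in table]
        if missing:
            raise ValueError(f"missing {which}-concentration significance for {missing}")
    low = tuple(p for p in PARAMETERS if significant_low[p])
    high = tuple(p for p in PARAMETERS if significant_high[p])
    affected = set(low) | set(high)
    if len(low) >= 2:
        verdict = "strong"
    elif len(affected) >= 2 and len(low) >= 1:
        verdict = "moderate"
    else:
        verdict = "negative"
    return ClassificationResult(
        compound=compound, verdict=verdict,
        significant_low=low, significant_high=high,
    )


def _group_key(w: WellRecord) -> Tuple[float, bool]:
    return (w.concentration, w.abt)


def run_prescreen(
    wells: Iterable[WellRecord],
    alpha: float = DEFAULT_ALPHA,
    low: float = LOW_UM,
    high: float = HIGH_UM,
    pvalues: bool = True,
) -> PrescreenReport:
    """Test and classify one compound's prescreen plate.

    Per parameter, all treatment groups present — blank and the two
    concentrations, each with and without ABT where available — enter a
    one-way ANOVA with Tukey's post hoc test; significance at a
    concentration means the (concentration, no ABT) vs (blank, no ABT) pair
    is significant.  ABT comparisons (each treatment against its ABT arm,
    and ABT blank against plain blank) are reported alongside.
    """
    wells = [w for w in wells if w.control_type in (None, "blank")]
    if not wells:
        raise ValueError("no treatment or blank wells supplied")
    compounds = {w.compound for w in wells if w.concentration > 0}
    compound = compounds.pop() if len(compounds) == 1 else "/".join(sorted(compounds))
    groups_present = sorted({_group_key(w) for w in wells})
    for needed in ((0.0, False), (low, False), (high, False)):
        if needed not in groups_present:
            raise ValueError(f"missing prescreen group {needed} (concentration, abt)")

    def label(key: Tuple[float, bool]) -> str:
        conc, abt = key
        base = "blank" if conc == 0 else f"{conc:g} uM"
        return base + (" +ABT" if abt else "")

    tests: Dict[str, List[StatResult]] = {}
    sig_low: Dict[str, bool] = {}
    sig_high: Dict[str, bool] = {}
    abt_rows: List[StatResult] = []
    for param in PARAMETERS:
        data = {
            label(key): [w.parameters[param] for w in wells if _group_key(w) == key]
            for key in groups_present
        }
        results = tukey_test(data, alpha=alpha, pvalues=pvalues)
        tests[param] = results
        by_pair = {frozenset(r.label.split(" vs ")): r for r in results}

        def pair(a: str, b: str) -> Optional[StatResult]:
            return by_pair.get(frozenset((a, b)))

        low_res = pair("blank", label((low, False)))
        high_res = pair("blank", label((high, False)))
        sig_low[param] = bool(low_res and low_res.significant)
        sig_high[param] = bool(high_res and high_res.significant)
        for conc, _abt in groups_present:
            r = pair(label((conc, False)), label((conc, True)))
            if r is not None:
                abt_rows.append(
                    StatResult(
                        label=f"{param}: {r.label}", test=r.test,
                        statistic=r.statistic, p_adjusted=r.p_adjusted,
                        significant=r.significant, alpha=r.alpha,
                    )
                )
    classification = classify_prescreen(sig_low, sig_high, compound=compound)
    return PrescreenReport(classification=classification, tests=tests,
                           abt_comparisons=abt_rows)


def abt_effect(
    with_abt: Iterable[WellRecord],
    without_abt: Iterable[WellRecord],
    alpha: float = DEFAULT_ALPHA,
) -> List[StatResult]:
    """Compare matched treatments between the ABT and no-ABT arms.

    For every (compound, concentration) present in both arms and every
    parameter, the two replicate sets are compared with the same studentized
    machinery as the post hoc pairs (Tukey with two groups reduces to the
    two-sample comparison).  Unmatched treatments raise; empty arms raise.
    """
    abt_wells = list(with_abt)
    plain_wells = list(without_abt)
    if not abt_wells or not plain_wells:
        raise ValueError("both arms must contain wells")
    if any(not w.abt for w in abt_wells) or any(w.abt for w in plain_wells):
        raise ValueError("arms are mislabelled: check the abt flags")

    def keyed(ws: List[WellRecord]) -> Dict[Tuple[str, float], List[WellRecord]]:
        out: Dict[Tuple[str, float], List[WellRecord]] = {}
        for w in ws:
            out.setdefault((w.compound, w.concentration), []).append(w)
        return out

    abt_map, plain_map = keyed(abt_wells), keyed(plain_wells)
    if set(abt_map) != set(plain_map):
        raise ValueError(
            f"unmatched treatments: {sorted(set(abt_map) ^ set(plain_map))}"
        )
    out: List[StatResult] = []
    for key in sorted(abt_map):
        compound, conc = key
        for param in PARAMETERS:
            data = {
                "without ABT": [w.parameters[param] for w in plain_map[key]],
                "with ABT": [w.parameters[param] for w in abt_map[key]],
            }
            for r in tukey_test(data, alpha=alpha):
                out.append(
                    StatResult(
                        label=f"{compound} {conc:g} uM {param}: {r.label}",
                        test=r.test, statistic=r.statistic,
                        p_adjusted=r.p_adjusted, significant=r.significant,
                        alpha=r.alpha,
                    )
                )
    return out


# -- tabular interchange ------------------------------------------------------

_FRAME_COLUMNS = [
    "well_id", "compound", "concentration_um", "abt", "control_type", "replicate",
    *PARAMETERS,
]


def wells_to_frame(wells: Iterable[WellRecord]) -> pd.DataFrame:
    rows = []
    for w in wells:
        row = {
            "well_id": w.well_id, "compound": w.compound,
            "concentration_um": w.concentration, "abt": w.abt,
            "control_type": w.control_type or "", "replicate": w.replicate,
        }
        row.update({p: w.parameters[p] for p in PARAMETERS})
        rows.append(row)
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_wells(frame: pd.DataFrame) -> List[WellRecord]:
    missing = [c for c in _FRAME_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"well table missing columns {missing}")
    def as_bool(value) -> bool:
        if isinstance(value, str):
            return value.strip().lower() in ("true", "1", "yes")
        return bool(value)

    wells = []
    for _, row in frame.iterrows():
        control = row["control_type"]
        control = "" if pd.isna(control) else str(control)
        wells.append(
            WellRecord(
                well_id=str(row["well_id"]), compound=str(row["compound"]),
                concentration=float(row["concentration_um"]),
                abt=as_bool(row["abt"]),
                control_type=(control or None),
                replicate=int(row["replicate"]),
                parameters={p: float(row[p]) for p in PARAMETERS},
            )
        )
    return wells
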