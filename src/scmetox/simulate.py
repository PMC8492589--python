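"""Synthetic incubation peak lists and screening plates with known truth.

The generators emulate the statistical shape of the study's two data
streams so every pipeline stage runs — and can be scored against planted
ground truth — without any instrument data:

* **Incubations**: per-incubation HRMS2 peak lists containing the parent,
  planted true metabolites (with Gaussian precursor mass error and
  template-derived fragments carrying the metabolite's rule shift on the
  modified block), low-intensity noise peaks, and artifact peaks present in
  negative controls at a treated-like intensity ratio.
* **Plates**: five replicate wells per treatment group with six parameters
  drawn as Hill-function dose-responses times multiplicative log-normal
  noise; shipped presets are calibrated so the strong / moderate / negative
  verdicts are recovered by the classification rule with >= 95% probability
  at n = 5 and the default noise level.  Optional image mode renders nuclei
  as Gaussian blobs whose count and channel totals encode the parameters.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .compounds import Compound, FragmentTemplate, get_compound
from .formula import ElementalFormula, InfeasibleDeltaError, MassDelta, apply_delta, protonated_mz
from .imaging import CHANNELS, FieldImage
from .isozymes import ENZYME_PANEL, NEGATIVE_CONTROL, PHLM
from .rules import BiotransformationRule, MetaboliteCandidate, default_catalog
from .screen import LOW_UM, HIGH_UM, PARAMETERS, WellRecord
from .spectra import SpectrumRecord

__all__ = [
    "PlantedMetabolite",
    "PlantedArtifact",
    "IncubationSimConfig",
    "study_incubation_config",
    "simulate_incubations",
    "HillEffect",
    "PlateSimConfig",
    "preset_dose_response",
    "simulate_plate",
    "make_field_image",
    "BASELINES",
]


# -- incubation peak lists ----------------------------------------------------

@dataclass(frozen=True)
class PlantedMetabolite:
    """Ground truth: rule names, the block each rule modified, contributors."""

    rules: Tuple[str, ...]
    blocks: Tuple[str, ...]  # modified block per rule, parallel to `rules`
    contributors: FrozenSet[str] = frozenset()  # single enzymes forming it

    def __post_init__(self) -> None:
        if len(self.rules) != len(self.blocks):
            raise ValueError("rules and blocks must be parallel")


@dataclass(frozen=True)
class PlantedArtifact:
    """A non-enzymatic degradation peak present in negative controls too."""

    rules: Tuple[str, ...]
    blocks: Tuple[str, ...]
    control_ratio: float = 1.1  # control intensity / treated intensity


@dataclass(frozen=True)
class IncubationSimConfig:
    compound_id: str
    metabolites: Tuple[PlantedMetabolite, ...]
    artifacts: Tuple[PlantedArtifact, ...] = ()
    mass_error_sd_mda: float = 0.5
    log_intensity_mu: float = 13.0  # median precursor intensity ~ 4.4e5
    log_intensity_sigma: float = 1.0
    n_noise_peaks: int = 5
    seed: int = 0


def study_incubation_config(compound_id: str, seed: int = 0) -> IncubationSimConfig:
    """Planted truth mirroring each compound's reported initial steps.

    Contributor sets follow the reported isozyme mapping; the 5F-EMB-PINACA
    ester hydrolysis is planted with an empty contributor set so that it
    appears in pHLM only (carboxylesterase-mediated, absent from the
    CYP/FMO panel).  JWH-200 and A-796260 carry a hydroxy artifact present
    in negative controls at a similar intensity.
    """
    cyp = frozenset
    if compound_id == "JWH-200":
        mets = (
            PlantedMetabolite(("morpholine_N_dealkylation",), ("tail",),
                              cyp({"CYP1A2", "CYP3A4", "CYP3A5"})),
            PlantedMetabolite(("oxidative_morpholine_cleavage",), ("tail",),
                              cyp({"CYP3A4", "CYP3A5"})),
            PlantedMetabolite(("hydroxylation",), ("head",),
                              cyp({"CYP1A2", "CYP2C8", "CYP2C9", "CYP2C19",
                                   "CYP2D6", "CYP3A4", "CYP3A5"})),
            PlantedMetabolite(("dihydrodiol_formation",), ("head",),
                              cyp({"CYP1A2", "CYP2C19", "CYP3A4", "CYP3A5"})),
        )
        arts = (PlantedArtifact(("hydroxylation",), ("head",), 1.1),)
    elif compound_id == "A-796260":
        mets = (
            PlantedMetabolite(("morpholine_N_dealkylation",), ("tail",),
                              cyp({"CYP1A2", "CYP3A4", "CYP3A5"})),
            PlantedMetabolite(("oxidative_morpholine_cleavage",), ("tail",),
                              cyp({"CYP3A4", "CYP3A5"})),
            PlantedMetabolite(("hydroxylation",), ("head",),
                              cyp({"CYP1A2", "CYP2C8", "CYP2C9", "CYP2D6",
                                   "CYP3A4", "CYP3A5"})),
        )
        arts = (PlantedArtifact(("hydroxylation",), ("head",), 1.1),)
    elif compound_id == "5F-EMB-PINACA":
        mets = (
            PlantedMetabolite(("N_dealkylation",), ("tail",),
                              cyp({"CYP1A2", "CYP2B6", "CYP2C19", "CYP3A4", "CYP3A5"})),
            PlantedMetabolite(("ester_hydrolysis",), ("sidechain",), cyp(())),
            PlantedMetabolite(("oxidative_defluorination",), ("tail",),
                              cyp({"CYP1A2", "CYP2B6", "CYP2C8", "CYP2C9",
                                   "CYP2C19", "CYP2D6", "CYP3A5"})),
            PlantedMetabolite(("hydroxylation",), ("tail",),
                              cyp({"CYP1A2", "CYP2B6", "CYP2C8", "CYP2C9",
                                   "CYP2C19", "CYP3A4", "CYP3A5"})),
        )
        arts = ()
    else:
        raise KeyError(f"no study configuration for compound {compound_id!r}")
    return IncubationSimConfig(compound_id=compound_id, metabolites=mets,
                               artifacts=arts, seed=seed)


def _rule_map(compound: Compound) -> Dict[str, BiotransformationRule]:
    return {r.name: r for r in default_catalog(compound.parent_class)}


def _metabolite_formula(
    compound: Compound, rules: Sequence[str], by_name: Mapping[str, BiotransformationRule]
) -> ElementalFormula:
    f = compound.formula
    for name in rules:
        f = apply_delta(f, by_name[name].delta)
    return f


def _shifted_fragments(
    compound: Compound,
    planted_rules: Sequence[str],
    planted_blocks: Sequence[str],
    by_name: Mapping[str, BiotransformationRule],
) -> List[Tuple[float, FragmentTemplate]]:
    """Theoretical fragment m/z for a planted metabolite.

    Each parent template keeps its m/z unless it covers a modified block, in
    which case the rule delta is applied to the template composition; a
    delta that cannot apply to the fragment (e.g. a cleavage that removed
    the whole substructure) drops the fragment instead.
    """
    out = []
    for tpl in compound.templates:
        formula = tpl.formula
        ok = True
        for name, block in zip(planted_rules, planted_blocks):
            if block in tpl.blocks:
                try:
                    formula = apply_delta(formula, by_name[name].delta)
                except InfeasibleDeltaError:
                    ok = False
                    break
        if ok:
            shifted = replace(tpl, formula=formula)
            out.append((shifted.mz, tpl))
    return out


def _analyte_record(
    rng: np.random.Generator,
    analyte_id: str,
    incubation: str,
    precursor_mz: float,
    fragment_mzs: Sequence[float],
    base_intensity: float,
    rt: float,
    frag_profile: Sequence[float],
    config: IncubationSimConfig,
) -> SpectrumRecord:
    sd = config.mass_error_sd_mda / 1e3
    obs_precursor = precursor_mz + rng.normal(0.0, sd) if sd > 0 else precursor_mz
    obs_frag = [mz + (rng.normal(0.0, sd) if sd > 0 else 0.0) for mz in fragment_mzs]
    # modest run-to-run intensity variability on top of the per-analyte level
    intensity = base_intensity * math.exp(rng.normal(0.0, 0.1))
    noise_mz = rng.uniform(60.0, precursor_mz + 50.0, size=config.n_noise_peaks)
    noise_int = rng.uniform(0.5, 15.0, size=config.n_noise_peaks)
    return SpectrumRecord.with_relative_fragments(
        analyte_id, incubation, obs_precursor,
        list(obs_frag) + noise_mz.tolist(),
        list(frag_profile) + noise_int.tolist(),
        rt_min=rt, precursor_intensity=intensity,
    )


def simulate_incubations(
    config: IncubationSimConfig,
) -> Dict[str, List[SpectrumRecord]]:
    """Generate peak lists for pHLM, every panel enzyme, and the control.

    Returns a mapping from incubation label to spectra.  The parent appears
    in every incubation; planted metabolites appear in pHLM and in each of
    their contributing single-enzyme incubations; artifacts appear in every
    treated incubation and in the negative control at the configured
    intensity ratio.  Identical seeds give identical output.
    """
    compound = get_compound(config.compound_id)
    by_name = _rule_map(compound)
    rng = np.random.default_rng(config.seed)

    # Per-analyte fixed properties (identity, theory, chromatography).
    analytes = []
    parent_frags = [(tpl.mz, tpl) for tpl in compound.templates]
    analytes.append({
        "id": f"{compound.compound_id}|parent",
        "mz": compound.mz,
        "frags": parent_frags,
        "labels": [PHLM, *ENZYME_PANEL, NEGATIVE_CONTROL],
        "ratio": None,
    })
    for met in config.metabolites:
        cand = MetaboliteCandidate(
            parent_id=compound.compound_id,
            rules=tuple(sorted(met.rules)),
            formula=_metabolite_formula(compound, met.rules, by_name),
            predicted_mz=0.0, depth=len(met.rules),
        )
        analytes.append({
            "id": cand.candidate_id,
            "mz": protonated_mz(cand.formula),
            "frags": _shifted_fragments(compound, met.rules, met.blocks, by_name),
            "labels": [PHLM, *sorted(met.contributors)],
            "ratio": None,
        })
    for art in config.artifacts:
        formula = _metabolite_formula(compound, art.rules, by_name)
        analytes.append({
            "id": f"{compound.compound_id}|{'+'.join(sorted(art.rules))}#artifact",
            "mz": protonated_mz(formula),
            "frags": _shifted_fragments(compound, art.rules, art.blocks, by_name),
            "labels": [PHLM, *ENZYME_PANEL, NEGATIVE_CONTROL],
            "ratio": art.control_ratio,
        })

    # Distinct analytes elute as resolved peaks: enforce >= 0.6 min spacing
    # so retention time can disambiguate isobaric isomers downstream.
    taken: List[float] = []
    for a in analytes:
        rt = float(rng.uniform(1.0, 12.0))
        for _ in range(200):
            if all(abs(rt - other) >= 0.6 for other in taken):
                break
            rt = float(rng.uniform(1.0, 12.0))
        taken.append(rt)
        a["rt"] = rt
        a["base_intensity"] = float(
            np.exp(rng.normal(config.log_intensity_mu, config.log_intensity_sigma))
        )
        n_frag = len(a["frags"])
        profile = np.exp(rng.normal(3.0, 1.0, size=n_frag)) if n_frag else np.empty(0)
        a["frag_profile"] = profile.tolist()

    out: Dict[str, List[SpectrumRecord]] = {
        label: [] for label in (PHLM, *ENZYME_PANEL, NEGATIVE_CONTROL)
    }
    for label in out:
        for a in analytes:
            if label not in a["labels"]:
                continue
            base = a["base_intensity"]
            if a["ratio"] is not None and label == NEGATIVE_CONTROL:
                base = base * a["ratio"]
            out[label].append(
                _analyte_record(
                    rng, a["id"], label, a["mz"],
                    [mz for mz, _ in a["frags"]], base, a["rt"],
                    a["frag_profile"], config,
                )
            )
    return out


# -- screening plates ---------------------------------------------------------

@dataclass(frozen=True)
class HillEffect:
    """Fractional dose effect: emax * c^h / (ec50^h + c^h), emax signed."""

    emax: float
    ec50: float  # uM
    hill: float = 2.0

    def fraction(self, concentration: float) -> float:
        if concentration <= 0:
            return 0.0
        ch = concentration ** self.hill
        return self.emax * ch / (self.ec50 ** self.hill + ch)


#: Blank-well parameter levels in the normalized units the pipeline reports
#: (cell count per image; other parameters are intensity per cell count).
BASELINES: Dict[str, float] = {
    "cell_count": 100.0,
    "nuclear_size": 0.6,
    "nuclear_intensity": 5.0,
    "mito_potential": 2.0,
    "calcium": 1.5,
    "membrane_integrity": 0.8,
}

#: Preset dose-responses.  Effect sizes are calibrated so that, with n = 5
#: replicates, 8% multiplicative noise and six-group Tukey testing, the
#: classification rule recovers the preset verdict with >= 95% probability:
#: "strong" impairs two parameters already at 7.81 uM, "moderate" impairs
#: one at 7.81 uM and a second only at 125 uM, "negative" shifts parameters
#: only at 125 uM.
_PRESETS: Dict[str, Dict[str, HillEffect]] = {
    "strong": {
        "mito_potential": HillEffect(-0.6, 3.0, 2.0),
        "calcium": HillEffect(+0.8, 4.0, 2.0),
        "cell_count": HillEffect(-0.5, 60.0, 3.0),
    },
    "moderate": {
        "mito_potential": HillEffect(-0.5, 3.0, 2.0),
        "cell_count": HillEffect(-0.4, 80.0, 4.0),
    },
    "negative": {
        "cell_count": HillEffect(-0.35, 90.0, 5.0),
        "calcium": HillEffect(+0.5, 90.0, 5.0),
    },
}


def preset_dose_response(preset: str) -> Dict[str, HillEffect]:
    try:
        return dict(_PRESETS[preset])
    except KeyError:
        raise KeyError(f"unknown preset {preset!r}; options: {sorted(_PRESETS)}") from None


@dataclass(frozen=True)
class PlateSimConfig:
    compound: str = "TEST-SC"
    preset: Optional[str] = None  # "strong" | "moderate" | "negative"
    dose_response: Optional[Mapping[str, HillEffect]] = None
    concentrations: Tuple[float, ...] = (0.0, LOW_UM, HIGH_UM)
    abt_arms: bool = True
    n_replicates: int = 5
    noise_cv: float = 0.08
    abt_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def effects(self) -> Dict[str, HillEffect]:
        if self.dose_response is not None:
            return dict(self.dose_response)
        if self.preset is not None:
            return preset_dose_response(self.preset)
        return {}


def simulate_plate(config: PlateSimConfig) -> List[WellRecord]:
    """Draw well records for every treatment group of the design.

    Each well's parameter is baseline x (1 + Hill effect) x log-normal noise
    with unit mean and the configured coefficient of variation.  The
    optional ``abt_effects`` mapping applies a fractional change to the ABT
    arm at every concentration (including blanks), emulating an inhibitor
    that itself perturbs a parameter.  Zero noise and no effects gives
    identical wells.
    """
    rng = np.random.default_rng(config.seed)
    effects = config.effects()
    sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2)) if config.noise_cv > 0 else 0.0
    arms = (False, True) if config.abt_arms else (False,)
    wells: List[WellRecord] = []
    idx = 0
    for conc in config.concentrations:
        for abt in arms:
            for rep in range(1, config.n_replicates + 1):
                idx += 1
                params = {}
                for p in PARAMETERS:
                    level = BASELINES[p]
                    eff = effects.get(p)
                    if eff is not None:
                        level *= 1.0 + eff.fraction(conc)
                    if abt:
                        level *= 1.0 + config.abt_effects.get(p, 0.0)
                    if sigma > 0:
                        level *= math.exp(rng.normal(-0.5 * sigma ** 2, sigma))
                    params[p] = level
                wells.append(
                    WellRecord(
                        well_id=f"W{idx:03d}",
                        compound=config.compound,
                        concentration=conc,
                        abt=abt,
                        control_type="blank" if conc == 0 else None,
                        replicate=rep,
                        parameters=params,
                    )
                )
    return wells


# -- field images -------------------------------------------------------------

def make_field_image(
    n_nuclei: int,
    rng: np.random.Generator,
    shape: Tuple[int, int] = (160, 160),
    nucleus_sigma: float = 3.0,
    nucleus_peak: float = 800.0,
    background: float = 15.0,
    noise_sd: float = 2.0,
    per_cell: Optional[Mapping[str, float]] = None,
    blur_sigma: float = 0.0,
    well_id: str = "",
    field_index: int = 1,
) -> FieldImage:
    """Render one four-channel field with ``n_nuclei`` disjoint nuclei.

    Nuclei are Gaussian blobs placed on a jittered grid so they never merge;
    the generator therefore knows the exact region count the segmentation
    should recover.  ``per_cell`` sets the total intensity each cell
    contributes to the non-nuclear channels.  ``blur_sigma`` defocuses the
    whole field (for quality-control tests).
    """
    from scipy import ndimage

    h, w = shape
    margin = int(4 * nucleus_sigma) + 2
    step = int(math.ceil(8 * nucleus_sigma))
    ys = np.arange(margin, h - margin, step)
    xs = np.arange(margin, w - margin, step)
    slots = [(y, x) for y in ys for x in xs]
    if n_nuclei > len(slots):
        raise ValueError(
            f"cannot place {n_nuclei} disjoint nuclei on a {shape} field "
            f"(max {len(slots)})"
        )
    order = rng.permutation(len(slots))[:n_nuclei]
    jitter = nucleus_sigma / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    unit = np.zeros((h, w))
    for k in order:
        y0, x0 = slots[k]
        y0 = y0 + rng.uniform(-jitter, jitter)
        x0 = x0 + rng.uniform(-jitter, jitter)
        unit += np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * nucleus_sigma ** 2))
    blob_sum = 2 * math.pi * nucleus_sigma ** 2  # integral of one unit blob
    nuclei = background + nucleus_peak * unit
    if noise_sd > 0:
        nuclei = np.clip(nuclei + rng.normal(0.0, noise_sd, size=(h, w)), 0.0, None)
    per_cell = dict(per_cell or {})
    channels: Dict[str, np.ndarray] = {"nuclei": nuclei}
    # Non-nuclear channels carry no additive background so their field
    # totals encode per-cell amounts exactly: total = n_nuclei * per_cell.
    for name in CHANNELS:
        if name == "nuclei":
            continue
        amount = per_cell.get(name, 100.0)
        channels[name] = unit * (amount / blob_sum)
    if blur_sigma > 0:
        channels = {
            name: ndimage.gaussian_filter(img, blur_sigma)
            for name, img in channels.items()
        }
    return FieldImage(channels=channels, well_id=well_id, field_index=field_index)
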