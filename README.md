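# scmetox

**In vitro metabolism and high-content cytotoxicity screening of synthetic
cannabinoids, as a tested, reusable pipeline.**

New psychoactive substances reach the drug market faster than their
toxicology can be characterized. For a synthetic cannabinoid (SC) the two
first questions a clinical or forensic laboratory asks are: *which
metabolites should a urine screen target, and how toxic is the compound to
liver cells?* `scmetox` implements the desk side of both workflows for three
SC from different structural subclasses — JWH-200 (naphthoylindole),
A-796260 (tetramethylcyclopropanoylindole) and 5F-EMB-PINACA (indazole
carboxamide ester) — and is extensible to further compounds through plain
YAML definitions.

## What it computes

**Metabolite identification (LC–HRMS/MS arm).** Phase-I biotransformations
are modelled as net elemental deltas on the parent's elemental formula. For
a parent M with monoisotopic mass *m*(M), a candidate metabolite after rules
r₁…r_k has

    m/z [M+H]+ = m(M) + Σᵢ Δm(rᵢ) + 1.007276 u

and fragment ions are *templates with block coverage*: an even-electron
cation of composition F observed at *m*(F) − *m*(e⁻), either unshifted or
shifted by a rule delta / neutral loss. A fragment shifted by the reaction
delta restricts the modification to the blocks it retains; an unshifted
fragment excludes its blocks; the intersection localizes the modification
(head / core / tail / sidechain). Presence/absence of each initial
metabolite across single-enzyme (Supersome) incubations versus pooled human
liver microsomes (pHLM) yields the CYP/FMO reaction phenotyping matrix,
with a pHLM-only flag marking carboxylesterase-consistent steps.

**Cytotoxicity screen (HCSA arm).** Six parameters per well — cell count,
nuclear size, nuclear intensity, mitochondrial membrane potential,
cytosolic calcium, plasma membrane integrity — are computed from segmented
nuclei and dye totals, normalized to cell count, and tested per parameter
by one-way ANOVA with Dunnett's (many-to-one) or Tukey's (all-pairs) post
hoc procedure at familywise α = 0.05. The verdict rule: **strong** if ≥2
parameters are significantly affected at 7.81 µM; **moderate** if ≥2 in
total with ≥1 at 7.81 µM; **negative** otherwise. A synthetic-plate
generator with Hill-function dose-responses and log-normal noise provides
ground truth for end-to-end validation.

## Worked example

```python
>>> from scmetox import get_compound, enumerate_candidates, explain_candidate
>>> emb = get_compound("5F-EMB-PINACA")
>>> round(emb.mz, 4)                     # [M+H]+ of the parent
378.2187
>>> cands = enumerate_candidates(emb, max_depth=1)
>>> ester = next(c for c in cands if c.rules == ("ester_hydrolysis",))
>>> round(ester.predicted_mz, 4), str(ester.formula)
(350.1874, 'C18H24FN3O3')
>>> explain_candidate(ester)
'ester_hydrolysis (-28.0313)'
```

The ester-hydrolysis candidate sits 28.0313 u below the parent — the ethyl
ester lost as ethylene — and its predicted precursor matches the metabolite
observed in microsomal incubations. Localizing a hydroxylation from a
fragment pattern:

```python
>>> from scmetox import SpectrumRecord, annotate_spectrum, localize
>>> from scmetox.formula import MassDelta
>>> jwh = get_compound("JWH-200")
>>> cand = next(c for c in enumerate_candidates(jwh, max_depth=1)
...             if c.rules == ("hydroxylation",))
>>> spec = SpectrumRecord("M", "pHLM", 401.1860,
...                       fragments=[(171.0440, 100.0), (114.0913, 70.0)])
>>> asg, _ = annotate_spectrum(spec, jwh.templates, cand)
>>> res = localize(asg, jwh.block_model, MassDelta.from_terms("oh", "+O"))
>>> res.status, sorted(res.consistent_blocks)
('localized', ['head'])
```

The naphthoyl fragment appears shifted by one oxygen (155.0491 → 171.0440)
while the morpholinoethyl fragment (114.0913) is unshifted, so the hydroxyl
sits on the naphthalene head group.

On the screening side:

```sh
$ scmetox simulate plate --preset strong --seed 1 --out wells.csv
30 wells -> wells.csv
$ scmetox hcsa-score --wells wells.csv
compound: TEST-SC
verdict: strong
significant at 7.81 uM: mito_potential, calcium
significant at 125.0 uM: cell_count, mito_potential, calcium
...
```

## Layout

| module | contents |
|---|---|
| `scmetox.formula` | elemental formulas, monoisotopic masses, ion m/z, deltas |
| `scmetox.compounds` | shipped compound/block/template definitions (YAML) |
| `scmetox.rules` | biotransformation catalogs, candidate enumeration |
| `scmetox.spectra` | MGF/CSV peak lists, matching, artifact flags, ranking |
| `scmetox.fragments` | shift annotation and modification localization |
| `scmetox.isozymes` | reaction-phenotyping matrices and summaries |
| `scmetox.imaging` | nuclei segmentation and focus QC |
| `scmetox.posthoc` | Dunnett/Tukey tests, FWER verification |
| `scmetox.screen` | well normalization, prescreen, verdict classification |
| `scmetox.simulate` | synthetic incubations, plates, field images |

See `docs/methods.md` for the underlying models, defaults and limitations.
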