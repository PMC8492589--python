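# Methods

This note documents the models, defaults and numerical choices behind
`scmetox`, what the synthetic-data generators do and do not emulate, and the
design decisions taken where more than one reasonable option existed.

## Exact-mass arithmetic

All identification logic reduces to integer element bookkeeping over an
embedded monoisotopic atomic-mass table (IUPAC values, ≥6 decimals). Two ion
conventions are supported, both singly charged positive:

* protonated molecule: m/z = neutral mass + 1.007276 u (proton);
* even-electron fragment cation: m/z = cation composition − 0.000549 u
  (electron).

Literature values for these compounds are printed to 4 decimals; atoms must
carry at least 5 decimals for those to round-trip, which is why the table is
embedded rather than truncated. Comparisons against printed values use a
±0.0005 u band (4-decimal rounding leaves ≤0.0001 u slack, the rest is
headroom). A handful of published fragment values are internally
inconsistent with their own stated compositions by ~0.0005–0.02 u
(98.0607, 144.0647, 189.0551, 304.1825, 332.1775, and the 40.0302 u figure
for a C₃H₄ loss); these are treated as typographical and are not used as
reference values anywhere. Negative-mode ions, multiple charges and isotope
patterns are out of scope.

## Biotransformation catalog and enumeration

Rules are **composition-level** net deltas (e.g. hydroxylation +O, oxidative
defluorination −F +O +H, oxidative morpholine cleavage −C₄H₇N), not
structure-graph transforms: HRMS² identification distinguishes metabolites
by elemental composition and fragment shifts only, so a graph model would
claim resolution the data does not provide. Each rule carries a block
applicability (morpholine rules act on the morpholinoethyl tail, ester rules
on the ester-valine sidechain) and a `max_applications` cap — 2 for
hydroxylation (dihydroxylation is real), 1 for everything else. Two variants
of the mechanistically unsettled oxidative morpholine ring opening are
shipped (−C₂H₂ and −CH₂ +O), matching the two fragment-level observations;
further variants can be added in the catalog file. Composite one-step
reactions (ketone +O −H₂, carboxylic acid +2O −H₂, lactone −C₂H₄ −H₂) are
listed alongside their stepwise equivalents; since rule order does not
change the resulting formula, multisets are stored sorted and duplicate
formulas collapse to the shallowest pathway (ties: lexicographic). The
enumerator is exhaustive over rule multisets up to `max_depth` and its
output is deterministically ordered by (depth, predicted m/z). Where one
formula is reachable by distinct mechanisms (lactone formation vs ester
hydrolysis + dehydrogenation), the collapsed candidate is still annotatable
with either pathway text — the composition cannot distinguish them.

## Spectral matching and artifact flagging

Precursor matching uses a 5 mDa default tolerance (~13 ppm at m/z 385).
Printed values agree with theory to ≤0.7 mDa, so 5 mDa leaves generous
headroom for instrument error while staying far below the ~2 mDa spacing of
the closest confusable compositions in the shipped candidate sets (F vs OH
differs by 2.0 mDa). The tolerance is a documented package default, not a
literature value. Ties rank by |error|, then pathway depth.

Artifact flagging mirrors the negative-control argument: a peak present in
the enzyme-free control at 0.5–2.0× the treated intensity is flagged as
non-enzymatic ("similar signal intensities" is not quantified in the
literature; the symmetric factor-2 band is this package's reading). The
check is a ratio, hence invariant to common intensity rescaling. Retention
time is carried through all records but not used for matching by default
(no RT model exists for these analytes); an optional RT gate
(`rt_tol_min`) disambiguates isobaric isomers, and is what the end-to-end
tests use to keep a genuine hydroxy metabolite distinct from a co-isobaric
hydroxy artifact.

## Fragment templates and localization

Fragments are curated **templates with block coverage**, not outputs of a
bond-breaking simulator — the identification idiom being modelled reasons
entirely by "fragment x corresponds to fragment y shifted by z".
Rearrangement products whose masses are not substructure masses (the
+18.0106 u water-rearrangement series 251.1190/163.0502, and the acyl
fluoride 177.0458 whose mechanism is explicitly unsettled) ship as literal
templates with their own compositions. A fragment may cover several blocks
(233.1084 covers indazole-carbonyl + fluoropentyl).

Annotation assigns each observed fragment the (template, shift) pair
minimizing |error| with at most one shift per fragment, the shift drawn
from the candidate's own rule deltas plus standard neutral losses (H₂O, CO,
HF, C₂H₄O, C₂H₄, and C₂H₆O for ethyl esters). Tie-break: smaller |error|,
then the unshifted explanation, then template label. The observed 213.1022
fragment is deliberately *not* a template: it is reached from 233.1084 by
HF loss, and shipping it as a template would mask that explanation under
the empty-shift preference.

Localization is pure set logic: fragments shifted by exactly the reaction
delta intersect their covered blocks into the consistent set; unshifted
fragments subtract theirs; fragments explained by unrelated neutral losses
carry no site information and are ignored. Exactly one remaining block =
localized; none = conflict (self-contradictory evidence); otherwise
ambiguous. No intensity weighting is applied — a weighting scheme would
imply a fragmentation-efficiency model the data does not support.

## Isozyme mapping

Detection is qualitative (any precursor match above an optional intensity
floor, default 0), matching the presence/absence layout of reaction
phenotyping tables: rows are metabolites, columns the eleven cDNA-expressed
enzymes (CYP1A2/2A6/2B6/2C8/2C9/2C19/2D6/2E1/3A4/3A5, FMO3) plus pHLM and
controls. The summary lists contributors per step, the isozymes shared
across the most steps, and a `pHLM_only` flag set exactly when a step is
seen in pHLM but in no single-enzyme incubation — the signature of an
enzyme absent from the panel, for ester substrates typically a
carboxylesterase. FMO3 is an ordinary column with no special handling.
Kinetic phenotyping (K_m/V_max, relative activity factors) is out of scope.

## Imaging

Nuclei segmentation is deliberately minimal: Gaussian smoothing (σ = 2 px),
global Otsu threshold, 8-connected components, minimum area 20 px. Because
Otsu always splits an image, a contrast guard (foreground mean ≥ 1.5×
background mean) returns zero regions for blank or noise-only fields.
Touching nuclei count as one component — a documented limitation shared
with the automated software being emulated; no watershed splitting is
attempted. Field quality control replaces manual blur inspection with a
focus score, Var(∇²I)/mean(I)² (intensity-scale invariant); the default
threshold 10⁻² was calibrated on the synthetic field generator, where sharp
renders score ≳0.15 and σ=8 defocus drops below ~3·10⁻⁴ — more than an
order of magnitude of margin on both sides. It has no claim to validity on
real micrographs without recalibration.

Per well: cell count = total region count / number of passing fields;
every other parameter is the per-well mean (nuclear area, nuclear
intensity, dye channel totals) divided by the cell count. Nuclear size is
divided by cell count too, although area-per-nucleus is already
count-independent — the convention normalizes *all* non-count parameters
uniformly, and consistency was preferred over parsimony. Wells with no
passing fields or no detected nuclei are excluded with a warning.

## Statistics

Dunnett's many-to-one test uses `scipy.stats.dunnett` (exact
multivariate-t, seeded QMC integration); Tukey's all-pairs uses
`scipy.stats.tukey_hsd`. Both are two-sided at familywise α = 0.05 —
"significantly impaired" includes increases (calcium, membrane dye), so
one-sided testing would be wrong. Degenerate inputs (n < 2, zero variance)
raise rather than silently passing.

For simulation at scale, the balanced-design decision "any adjusted
p < α" is evaluated as "max |t| > critical value": the Dunnett critical
value is obtained by root-finding on scipy's public p-value for an
engineered unit-variance dataset (so it is exactly the value the per-dataset
test uses), Tukey's from the studentized-range quantile. A unit test pins
the fast decisions to per-dataset scipy calls. The null FWER of both
procedures, estimated on 10⁴ simulated balanced datasets (8 groups, n = 5),
sits within [0.045, 0.055] — both procedures are exact in this setting, so
the band is Monte Carlo error around α.

The prescreen analyses all six treatment groups (blank, 7.81 µM, 125 µM,
each ± ABT) per parameter with Tukey's procedure, and reads significance at
a concentration off the (blank, no-ABT) vs (concentration, no-ABT) pair.
ABT comparisons are emitted both ways: each treatment against its ABT arm
*and* the ABT blank against the plain blank, since the published design
leaves the intended baseline open. The verdict rule is: strong ⇔ ≥2
parameters significant at 7.81 µM; moderate ⇔ ≥2 in total, ≥1 at 7.81 µM,
not strong; negative otherwise. The moderate wording is ambiguous between
"exactly two" and "at least two" affected parameters; the at-least-two
reading is implemented and flagged in every report rather than silently
chosen.

## Synthetic-data generators

**Incubations.** Per analyte: precursor at theoretical m/z plus Gaussian
error (SD 0.5 mDa — printed agreement with theory is ≤0.7 mDa); per-analyte
log-normal base intensity (median ~4×10⁵ counts, σ_log = 1) with modest
(σ_log = 0.1) run-to-run jitter; retention times uniform over 1–12 min with
≥0.6 min spacing (distinct analytes present as resolved peaks); fragments
derived from the parent templates with the planted rule delta applied to
templates covering the modified block (infeasible deltas drop the
fragment); five uniform noise peaks per spectrum. Fragment intensities are
log-normal, so only the *ranking* of fragments is meaningful, not absolute
values. Planted contributor sets follow the reported mapping for the three
compounds, including the pHLM-only ester hydrolysis and the hydroxy
artifacts present in negative controls at ratio 1.1. Not emulated:
chromatographic peak shape, isotope clusters, in-source fragmentation,
matrix effects — so passing tests demonstrate the *logic* of
identification, not robustness to real instrument artifacts.

**Plates.** Parameters are baseline × (1 + Hill(c)) × LogNormal(CV 8%),
n = 5 replicates per group, the standard two-fold concentration grid.
Preset effect sizes were chosen from a power analysis of the six-group
Tukey design so each preset's verdict is recovered ≥95% of seeded runs:
"strong" impairs mitochondrial potential (−60% max, EC₅₀ 3 µM) and calcium
(+80%, EC₅₀ 4 µM) well below 7.81 µM; "moderate" impairs only mitochondrial
potential at low concentration with cell count (−40%, EC₅₀ 80 µM, Hill 4)
emerging only at 125 µM; "negative" shifts cell count and calcium only near
125 µM (EC₅₀ 90 µM, Hill 5). The residual misclassification (~2–4%) is the
familywise false-positive rate at the low-dose comparisons — irreducible at
α = 0.05 — plus a small power deficit. Image mode renders nuclei as
grid-jittered Gaussian blobs (never merging, so the generator knows the
exact region count) with non-nuclear channel totals encoding per-cell
amounts exactly; optical point-spread, uneven illumination and cell
morphology are not modelled.

## Problem sizes

Default verification runs use 10⁴ datasets for the FWER estimate and 100
plates per preset for verdict recovery; both complete in seconds to a few
minutes on one CPU, and larger runs only narrow the Monte Carlo error
around the same values.

## Known limitations

* Composition-level rules cannot place a modification more finely than a
  block, and cannot distinguish isomeric pathways reaching one formula.
* The published per-figure numeric effect sizes and the full metabolite
  inventories (28/22/23 across the three compounds) depend on unpublished
  raw images and supplementary tables; they are covered here by
  property-level validation on synthetic data with planted truth, not by
  numeric reproduction.
* The QC threshold, artifact band and mass tolerance are package defaults
  chosen for the synthetic generators; real-instrument deployments should
  recalibrate all three.
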