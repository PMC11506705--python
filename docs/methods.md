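# Methods

## The quantification model

A PRM assay observes, for each target peptide, the integrated
extracted-ion-chromatogram (XIC) areas of a handful of b/y fragment ions in
two isotopic channels: light (endogenous) and heavy (synthetic standard
spiked at a known amount). The toolkit's response variable is

    L/H = Σ light areas / Σ heavy areas,

summed over the *intersection* of fragments observed in both channels — a
fragment present in only one channel would bias the ratio, so it is
excluded rather than imputed. Because the heavy standard is chemically
identical to the analyte up to isotopes, L/H is proportional to the light
amount at fixed spike, which motivates both the linear calibration model
and the through-origin single-point rule.

Assumptions: 1:1 peptide:protein stoichiometry (complete digestion of the
quantified form, or explicit accounting of incomplete forms, below);
identical fragmentation and recovery for light and heavy isotopologues;
linear detector response over the calibrated range.

### Calibration, LOD and LOQ

`fit_calibration` is ordinary least squares of L/H on the spiked light
amount. The detection limits follow the calibration-curve (ICH-style)
method: LOD = 3.3·s_yx/slope and LOQ = 10·s_yx/slope with s_yx =
√(SS_res/(n−2)) the residual standard error. This makes LOQ/LOD = 10/3.3
≈ 3.03 identically, and both limits invariant to rescaling the response —
properties the test suite asserts. Weighted regression, blank-based
limits and inter-day drift models are deliberately out of scope; external
(different-day) curves carry only a provenance flag. Adjusted r² is
reported for n ≥ 3 (plain r² at n = 2, where the adjustment is undefined).

### Single-point quantification

When sample material does not permit a full curve per run, one calibration
point is reused. The default is the proportional (through-origin) rule
amount = L/H · ref_amount / ref_L/H, which needs no intercept estimate; a
`curve` mode inverting a previously fitted line is available, with
negative inversions censored to zero and flagged. Both conventions are
kept because either is defensible; the choice is a documented parameter,
not an inference.

### Correction rules for incomplete forms

Two distinct rules, matching where the information lives:

- **Met oxidation** — the oxidized form shares the heavy standard's
  chemistry, so light and heavy areas of oxidized + unmodified forms are
  summed *per label before ratioing*: (L_unox+L_ox)/(H_unox+H_ox). With no
  oxidized signal this reduces exactly to the plain ratio.
- **Miscleavage** — a miscleaved sibling is a different molecule with its
  own response; it is quantified against its *own* external
  (light-peptide) calibration curve and the per-form amounts are summed.
  Forms below their curve's LOD contribute zero and are flagged.

### Complement profiles and band reconciliation

Absolute amounts are expressed per µg of protein extract or per mL of
blood. The "complement" view renormalizes subtypes not flagged below-LOQ
to percent of total (sum exactly 100). For comparison with SDS-PAGE of
acid extracts, subtypes are pooled into bands (default: high =
{H1.3, H1.4, H1.5}, intermediate = {H1.1, H1.2}, low = {H1.0}); subtypes
outside every band (H1X, unresolved electrophoretically) are dropped and
the remainder renormalized before summation. Replicate CV is 100·sd/mean
with the n−1 denominator.

## Peptide selection

Cleavage rules: trypsin cuts C-terminal to K/R, suppressed before proline;
Glu-C cuts after E (ammonium-bicarbonate-type specificity) or after E and
D (phosphate-type); both specificities are runnable because the effective
specificity depends on digestion buffer. With k allowed missed cleavages
every concatenation of up to k+1 adjacent fully cleaved fragments is
emitted. Candidate filters: length ≤ 24 residues ("less than 25"),
neutral unmodified monoisotopic mass ≥ 600 Da. Uniqueness is sequence
identity — a candidate must occur as an exact substring of exactly one
family member's full sequence; I and L are distinct characters (uniqueness
is a database notion, not a mass notion), and an optional background
proteome can veto candidates. Candidate enumeration defaults to zero
missed cleavages; miscleaved quantification forms are declared explicitly
in the assay file rather than auto-selected, because their selection in
practice rests on observability evidence the toolkit only consumes (ESS,
detected-species lists).

Positions are 1-based counting the initiator Met as residue 1. The
packaged H1 panel encodes each peptide's coordinates; the H1.1 panel
peptide (KKPAGPSVSELIVQAASSSK, a doubly miscleaved tryptic species) spans
residues 37–56. `verify_assay_positions` round-trips every panel peptide
against user-supplied family sequences.

Isobaric hazard: the packaged H1.2 and H1.4 peptides (TAPAAPAAAPPAE /
TAPAAPAAPAPAE) have identical composition and therefore identical mass.
Nothing in the toolkit keys peptides by mass; identity is always
(sequence, subtype).

### Mass constants

Residue monoisotopic masses come from pyteomics' standard table; water
18.010565 Da, proton 1.007276 Da. Heavy-label deltas are the exact full
¹³C/¹⁵N substitutions behind the nominal +8/+7/+4 labels: K +8.0142
(6×1.003355 + 2×0.997035), L/I +7.0172, A +4.0071 Da. Protein molar mass
(for fmol→ng conversion) uses average residue masses computed from the
supplied sequence, keeping the toolkit family-agnostic.

## Small-cohort statistics

- **Method comparison**: percentages are logit-transformed (0 and 1
  clamped to ε = 1e-6 with a warning) and compared per (band, cell-line)
  contrast by a two-sample t-test on the method factor, with
  Benjamini–Hochberg correction across contrasts. A joint
  general-linear-hypothesis formulation would need design details that a
  per-contrast test does not; the contrast-level significance decision is
  the surface that matters and is what the tests pin down.
- **ROC**: thresholds at midpoints between adjacent distinct scores; AUC
  by concordance-pair counting with ties at ½ (hence AUC = 1 − U/(n₁n₂),
  property-tested); the operating point maximizes Youden's J with
  deterministic first-best tie-breaking.
- **MCC**: the printed formula, 0 by convention when a marginal is zero,
  making the statistic total; cross-checked in tests against the
  φ-coefficient identity.
- **Rank effect size**: U counts pairs with the second group ranked above
  the first (ties ½); Wendt's r = 1 − 2U/(n₁n₂). The critical r at level
  α is found by *full enumeration* of all C(n₁+n₂, n₂) arrangements —
  feasible for the cohort sizes this toolkit targets — taking the largest
  U with one-sided exact P(U ≤ u) ≤ α. One-sided is the convention
  adopted throughout for these directional small-cohort questions. For
  n₁ = 8, n₂ = 2 this gives r = 0.875 (U = 1, p = 2/45).
- **Clustering / PCA**: subject profiles are clustered on d = 1 − Pearson
  r with average linkage (scipy), deterministic under input order; PCA is
  column-centered, unit-variance-scaled by default, with component signs
  fixed largest-loading-positive so runs are reproducible. Explained
  variance percentages sum to 100.

## Synthetic data: what it emulates, and what it does not

The generators emit the post-integration artifacts the pipeline consumes.
Per-transition response factors are a fixed property of the peptide form
(hash-derived), shared between light and heavy (co-eluting isotopologues)
and between sample and external-curve runs of the same species. Area
noise is multiplicative log-normal with unit mean and stated CV — the
error structure of integrated peak areas — applied independently per
transition. Miscleavage and oxidation divert stated fractions of the
light signal into sibling forms. Cohorts draw total amounts from
group-wise normals (truncated at 0) and subtype percentages from
Dirichlet distributions, which respect the sum-to-100 constraint.

Not emulated: chromatographic interference, retention-time drift,
integration-boundary errors, between-day response drift, matrix effects,
or correlated noise across transitions. Passing recovery tests therefore
demonstrates the *reduction logic* is correct and stable under stated
noise, not that real acquisitions meet these error models.

Default study conditions: triplicate measurement; 10% per-transition noise
CV (recovered-amount replicate CVs then stay below 15% in ≥ 90% of
simulated runs, the reproducibility regime a validated assay reports);
calibration levels 0.05–5 ng bracketing sub-ng LOQs; heavy spike 1 ng; a
default cohort of 6 responders vs 2 non-responders, the unbalanced
shape that motivates the exact rank statistics.

## Problem sizes in the test and acceptance runs

Property suites use 25–100 randomized instances per property, cohorts up
to 12 subjects for exhaustive rank-null and clustering oracles, and 30–40
simulation runs for the CV and null-AUC checks; the full suite and the
acceptance script each complete in seconds on one CPU. These sizes were
chosen so every combinatorial oracle remains exhaustive rather than
sampled.

## Known limitations

- Uniqueness screening is family-internal by default; proteome-wide
  screening requires supplying a background FASTA.
- ESS is consumed, never computed; candidates absent from the annotation
  table simply rank last.
- No weighted calibration, confidence intervals on AUC, multivariable
  risk models, or survival analysis.
- The packaged H1 panel encodes peptide coordinates and label chemistry;
  applying the full selection workflow to the real seven-subtype family
  requires the UniProt sequences as a user-supplied FASTA
  (`prmkit select-peptides`), since sequence data is not bundled.
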