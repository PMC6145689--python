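# Methods

## Problem setting

Urine from prostate cancer (PCa) and benign prostatic hyperplasia (BPH)
patients is compared by TMT10plex quantitative glycoproteomics.  Five case
channels (126–128C) and five control channels (129N–131) carry one patient
each.  Four peptide populations are analyzed separately: intact
N-glycopeptides (peptide with glycan attached), desialo-O-glycopeptides,
de-N-glycosylated peptides (PNGase F leaves +0.984 Da deamidation at the
sequon Asn, marking the glycosylation site) and non-modified peptides
(protein-level proxy).  The goal is a panel of intact N-glycopeptides whose
abundance separates the groups.

## Glycan model

Compositions are multisets over {HexNAc, Hex, Fuc, NeuAc, NeuGc} with
monoisotopic residue masses 203.079373, 162.052824, 146.057909, 291.095417
and 307.090331 Da.  Peptide and elemental masses come from pyteomics;
modification deltas (TMT 229.16293, carbamidomethyl 57.02146, deamidation
0.98402, oxidation 15.99491 Da) are computed from elemental composition and
carried at full precision — three-decimal values in displays are rounding.

Classification is the five-way partition used for class-level abundance
summaries: high-mannose (HexNAc = 2, Hex ≥ 5, no Fuc, no sialic acid) and
complex/hybrid split by terminal fucosylation/sialylation (C/H, C/H+Fuc,
C/H+NeuAc, C/H+Fuc/Sia).  Design choices: paucimannosidic/truncated
compositions fold into C/H (the five-class reporting has no pauci bin);
"sialylated" means NeuAc + NeuGc > 0.

Isobaric collisions are enumerated exhaustively over a capped composition
space (defaults HexNAc ≤ 9, Hex ≤ 10, Fuc ≤ 3, NeuAc ≤ 4, NeuGc ≤ 1) at
10 ppm.  Two identities matter chemically: Fuc + NeuGc vs Hex + NeuAc
(Δ ≈ 1 µDa) and NeuGc vs NeuAc + peptide oxidation (Δ ≈ 0.6 µDa).  NeuGc
evidence is judged from oxonium ions at the theoretical m/z 308.0976 /
290.0870 ([NeuGc+H]+ and its water loss; NeuAc: 292.1027 / 274.0921); by
default either ion within 10 ppm counts as evidence (configurable to require
both).  On conflict (nominal NeuGc, NeuAc-only evidence) the rewrite prefers
Fuc(−1)NeuGc(−1) → Hex(+1)NeuAc(+1), which needs no extra modification
hypothesis, and otherwise NeuGc(−1) → NeuAc(+1) plus one oxidation; every
rewrite is asserted mass-conserving within 1e-3 Da.

## Quantification

PSM-quality gates are strict inequalities: PIF > 0.75 and, for glycopeptide
classes only, PEP-2D < 0.001.  Target-decoy filtering runs at 0% peptide
FDR: targets scoring strictly above the best decoy survive.  Redundant PSMs
(including charge states) are summed into features keyed by
peptide + modifications + composition.  Zeros are missing, never log(0);
features need coverage in ≥ 70% of channels and ≥ 2 samples per group to be
tested; no imputation.  Normalization is log2 + per-channel median centering
(mean centering is available as an option; the two source descriptions of
the normalization differ, and median is the default because it is robust to
the heavy-tailed feature distribution).  PRM-style quantification sums a
glycopeptide's spectra within a closed retention-time window and divides by
whole-run channel totals.

## Outlier-channel detection

One control channel is modeled as aberrant.  PCA (SVD of the
feature-centered channel × feature table) is run on the log2 matrix
*before* per-channel centering: a global channel offset — exactly the
defect simulated — lies in the null space of median centering and would be
invisible afterwards.  A channel is flagged when its PC1–PC2 distance from
the centroid exceeds 3× the median distance.  On the default cohort exactly
channel 131 is flagged, leaving the 5-vs-4 design used everywhere
downstream.

## Differential statistics

The moderated t follows the standard empirical-Bayes hierarchy: s²_g |
σ²_g ~ σ²_g χ²_{d_g}/d_g with a scaled inverse-χ² prior (s₀², d₀).  The
prior is estimated by closed-form moment matching on e_g = log s²_g −
ψ(d_g/2) + log(d_g/2): the excess variance of e over mean ψ′(d_g/2) gives
d₀ = 2ψ′⁻¹(·) (Newton iteration on the trigamma), and s₀² follows from the
mean of e.  Non-positive excess variance yields d₀ = ∞ (variances fully
pooled).  Posterior variance is the df-weighted blend; p-values use
t(d₀ + d_g).  Features with zero residual df are excluded from prior
fitting.  The implementation is checked in the test suite against
Bioconductor limma (agreement ~1e-12) and against its analytic limits
(d₀ = 0: ordinary pooled t; d₀ = ∞: fixed-variance z).  eBayes-style trend
and robust options are not implemented (defaults assumed).  BH q-values use
the step-up minimum; the q ≤ 0.25 gate is inclusive so borderline q = 0.25
entries pass, matching the published table that contains such rows.

## Panel selection

Four independent predicates, order-irrelevant: q ≤ 0.25; linear ratio
strictly > 1.3 or strictly < 0.77; site corroboration; whitelist.
Corroboration requires a de-N peptide of the same protein whose deamidation
site lies on a sequon (N-X-[S/T/C], X ≠ P) aligned with a sequon of the
intact peptide (string equality or containment, covering missed-cleavage
variants).  The packaged whitelist is a synthetic stand-in for a curated
serum-glycoform resource, derived from the compositions in the packaged
56-entry differential table, and is user-replaceable.  Protein-level
cross-reference flags an entry glyco-specific when the mean non-modified
ratio of its protein is flat (within [0.77, 1.3]) or moves oppositely.

## Panel evaluation

Features are ranked by |moderated t| (the published ranking criterion is
unstated; PLS-VIP is the documented alternative).  For each panel size a
2-component PLS regression on the 0/1 class label is fitted under
leave-one-out cross-validation — chosen because n = 9 leaves no room for
held-out splits — and AUC is computed from held-out scores by the
Mann–Whitney rank formula with ties counted ½.  Heat-map clustering uses
Euclidean average linkage (only the metric is prescribed by the source
analysis; linkage is a config switch) on row-standardized log2 values.
PCA is centering-only by default (unit-variance scaling unstated in the
source; available as an option).

## Synthetic cohorts

The generator emulates the study conditions; its defaults are fixed, not
tuning knobs.  Reporter intensity for feature f, channel c:
I = 2^(b_f + log2(r_f)·1[c case]) / n_PSMs × ε, with baseline b_f ~
N(17, 1.5²) (log2 of typical reporter sums), multiplicative log-normal noise
ε at 20% CV, and n_PSMs = 1 + Poisson(2) redundant spectra per feature.
Differential structure comes from the packaged 56-row table: intact
glycoforms at their published PCa/BPH ratios (1,000 additional null intact
features), de-N peptides at the published site ratios, non-modified peptides
at each protein's average ratio.  Ten percent of PSMs are co-isolation
contaminated: PIF ~ U(0.3, 0.75) and intensities blended toward a flat
background proportionally to 1 − PIF (ratio compression); clean PSMs have
PIF ~ U(0.9, 1).  Channel 131 carries a +2 log2 global shift (an
unambiguous PC-space outlier; the real sample's defect is unrecorded).
Missingness is feature-wise at 5% (TMT reporter blocks are complete per
spectrum, so whole features, not single channels, go missing).  Decoys are
10% of PSMs with scores N(100, 10) vs targets N(150, 15).  Optional planted
NeuGc mislabels replace a null feature's Hex+NeuAc composition with its
isobaric Fuc+NeuGc variant.  All randomness derives from one seed; a fixed
seed reproduces every table byte for byte.

What the simulation does not model: isotope-impurity crosstalk between TMT
channels, peptide-level interference structure (contamination is blended
toward a feature-flat background), chromatographic drift, correlated
biological covariation between glycoforms of one protein, and real
inter-patient variance heterogeneity.  Passing tests therefore demonstrate
correctness of the pipeline's statistics and selection logic under the
stated generative model, not performance on real cohorts.

## Parameter recovery definition

Sensitivity is measured over *recoverable* planted features: those present
in the quantified matrix after the identification-quality filters and whose
corroborating de-N feature exists in the data.  Feature-wise missingness can
delete a planted glycoform or its only site evidence outright, and no
correct pipeline can select a feature without observed evidence; counting
such cases as misses would measure the simulator, not the cascade.  At the
default conditions the cascade recovers ≥ 90% (typically 94–100%) of
recoverable features with zero false selections.

## Problem sizes and numerical choices

Default runs use ~1,056 intact features (56 planted + 1,000 null), 150–300
features in the other classes and ~3,300 intact PSMs — small enough that the
full analysis completes in seconds while leaving the moderated-t prior and
BH behavior in their realistic regimes; null calibration tests use 2,000 and
5,000 features.  Ties in AUC count ½; retention-time windows are closed
intervals; the trigamma inverse uses Newton iteration from the asymptotic
start 0.5 + 1/y with analytic handling of extreme arguments; PLS component
count is capped at min(2, features, n − 2) per fold.

## Known limitations

The cohort-level discovery counts of the original study (hundreds of
glycoproteins and sites) depend on raw spectra that were never deposited and
are not reproducible here; the packaged 56-row table is a transcription with
a checksum guard, and its intact carrier peptides are reconstructed from the
de-N peptides of the same sites (the original carriers are not printed).
The whitelist stands in for a curated external resource.  Spectrum
simulation covers diagnostic oxonium ions only, not full glycopeptide
fragmentation.
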