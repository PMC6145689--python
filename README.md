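# glycopanel

Quantitative urinary glycoproteomics for biomarker discovery: a tested
reimplementation of the analysis that turns TMT10-labeled glycopeptide
identification tables into a validated panel of differential intact
N-glycopeptides distinguishing prostate cancer (PCa) from benign prostatic
hyperplasia (BPH).

Serum PSA cannot separate these two conditions, but site-specific protein
glycosylation in urine can: a panel of 56 intact N-glycopeptides (peptide +
attached glycan composition, quantified by TMT reporter ions) perfectly
discriminates PCa from BPH urine.  This package implements every
computational stage of that analysis — the glycan mass chemistry, the
identification-quality filters, the moderated differential statistics and
the multi-criteria panel-selection cascade — and, because no raw data are
publicly deposited, exercises them end to end on synthetic cohorts with
planted ground truth.

Audience: computational proteomics researchers who want a reusable, testable
version of this analysis pattern, and methodologists studying panel
selection in small-n isobaric designs.

## The analysis

**Glycan mass algebra.** Compositions `HexNAc(a)Hex(b)Fuc(c)NeuAc(d)NeuGc(e)`
with monoisotopic residue masses; two near-isobaric identities drive
composition validation: m(NeuGc) − m(NeuAc) = m(Met oxidation) and
m(Fuc) + m(NeuGc) = m(Hex) + m(NeuAc), both within 10⁻⁴ Da.  NeuAc/NeuGc
assignments are checked against diagnostic oxonium ions (m/z 292.103/274.092
vs 308.098/290.087) and conflicting NeuGc assignments are rewritten
mass-conservingly.

**Quantification.** PSMs pass PIF > 0.75 and PEP-2D < 0.001 (strict), then a
0% peptide-level target-decoy FDR filter; redundant PSMs are summed into
features (peptide + modifications + composition), log2 transformed and
median-centered per channel.  An outlier channel is detected by PCA and
removed (5 PCa vs 4 BPH channels remain).

**Differential statistics.** Per feature g with pooled variance s²_g on d_g
df, an empirical-Bayes prior (s₀², d₀) is fitted by digamma/trigamma moment
matching on log s²_g; the moderated statistic

    t̃_g = (x̄₁ − x̄₂) / ( s̃_g √(1/n₁ + 1/n₂) ),   s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)

is referred to t(d₀ + d_g), with Benjamini–Hochberg q-values.  The
implementation agrees with Bioconductor limma to ~1e-12 (tested).

**Panel selection.** Four gates: q ≤ 0.25; ratio > 1.3 or < 0.77;
glycosylation site corroborated by a deamidated sequon in the
de-N-glycosylated fraction; composition in a serum-glycoform whitelist.
Selected glycoforms are cross-referenced against non-modified peptides to
flag glyco-specific regulation.  Panels are evaluated by leave-one-out
2-component PLS-DA with rank-formula AUC.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (seed 1) and write their tables under `results/`:

```
$ python analysis/01_simulate_cohort.py
intact_n  :  3278 PSMs (298 decoys)
...
planted intact glycoforms: 56 (31 up, 25 down)

$ python analysis/02_quantify_normalize.py
intact_n  :  3278 PSMs ->  2664 after filters ->  990 features
...

$ python analysis/03_differential_abundance.py
outlier channels (PCA, 3x median distance): ['131']
intact_n  :  990 tested,  70 at q<=0.25 (prior d0=9.86, s0^2=0.0319)
...

$ python analysis/04_select_panel.py
panel entries: 49 (26 up, 23 down; 20 glyco-specific)
sensitivity on recoverable planted features: 0.942 (49/52)
empirical FDR among selected: 0.000

$ python analysis/05_evaluate_panel.py
2-cluster cut of the panel heat map: block sizes [26, 23] (planted up/down: [26, 23])
panel size 20: LOO PLS-DA AUC = 1.000
panel size 28: LOO PLS-DA AUC = 1.000
panel size 56: LOO PLS-DA AUC = 1.000

$ python analysis/06_validate_neugc.py
conflicts flagged: 12
correctly reassigned: 12/12
```

Reading: the simulator plants the 56 published glycoform fold-changes among
1,000 null intact glycopeptides; the pipeline removes the shifted channel
131, recovers 94% of the recoverable planted features with no false
selections, and the selected panel discriminates the groups perfectly
(AUC = 1.0) under leave-one-out cross-validation — the behavior reported for
the real cohort.  A `glycopanel` CLI exposes the same stages
(`glycopanel simulate|quantify|normalize|diff|panel|roc|validate-spectra|run-all`).

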