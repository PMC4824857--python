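# Methods

This note documents the models, default parameters and numerical choices
behind `srmquant`, and what the synthetic-data tests do and do not establish
about real data.

## Isotope-dilution quantification

The core arithmetic is classical stable-isotope dilution: the light:heavy
peak-area ratio at a chosen spike level, the spiked amount (mol) and the cell
equivalents on column give copies per cell via Avogadro's number
(`quant.peptide_cpc`). Defaults follow the census experiment: 200,000 cells
on column, heavy-standard spikes at low (100–250 amol), medium (1–2 fmol) and
high (10–20 fmol), four biological replicates. The spike level is chosen per
peptide as the one whose median ratio is closest to 1 within the working band
[0.1, 10]; ties prefer the higher spike (better counting statistics), and if
no level is in band the nearest is used with an `out_of_range` flag.

QC: a replicate passes at q ≤ 0.01 and S/N > 5; a peptide needs ≥ 3 of 4
passing replicates. The S/N clause is read strictly — a replicate failing S/N
counts against the quorum even if it passes the FDR cut (`strict_sn=False`
gives the lenient reading in which S/N only vetoes). The summary cpc is the
median over passing replicates, matching the robust-statistics philosophy of
the rCV (100·1.4826·MAD/median). Note the rCV estimator is biased low at
small n: for four values its median is ≈ 0.67× the true CV, which matters
when interpreting replicate-level dispersion (see noise model below).

Type B upper limits: no published formula exists for the "< x cpc" bounds, so
the package derives one from the detection criterion itself — the light peak
must have been below S/N = 5, so a hypothetical light area of 5 × noise
against the observed heavy area bounds the ratio and hence the cpc. The bound
is invariant across spike levels because the heavy area scales with the
spike.

Reconciliation: "median average of the two peptide values" is the arithmetic
mean (the median of two numbers). The 0.54 log₂ discrepancy threshold is the
census dataset's own median sibling discrepancy and is configurable; passing
`discrepancy_threshold_log2=None` to `quantify_proteins` recomputes it from
the dataset at hand. Protein rCV is recomputed over all replicate cpc values
of both peptides only for concordant AA pairs; otherwise the contributing
peptide's rCV is carried.

## Peak-group scoring and FDR

The scorer is a deliberately transparent composite (not a semi-supervised
discriminant): co-elution/pattern Pearson correlation across transitions,
normalised intensity dot product, and log₁₀ mean S/N, each z-scaled on the
decoy population and summed with configurable weights (equal by default).
Sub-scores are ratios, so the composite is invariant to uniform area scaling.
Decoys shift each target's product m/z by +11 Th (incrementing until ≥ 0.5 Th
from every real product) and keep the precursor m/z and RT window, emulating
spike-in style decoys that need no endogenous decoy peptide. q-values come
from plain target–decoy counting, FDR(s) = #{decoys ≥ s}/#{targets ≥ s},
monotonised; an optional +1 pseudo-count gives a conservative 1/#targets
floor. On mixtures with 10% false targets this estimator is conservative
(decoy counts estimate the false-target tail as if all targets were false),
so empirical FDR at q ≤ 0.01 is well below nominal.

## Assay design

Tryptic digestion cleaves after K/R except before P. Missed-cleavage risk is
an explicit additive rule table (proline block = 1.0, acidic D/E neighbour
+0.25, dibasic context +0.30, clamped to [0, 1]) — a deliberately simple,
versioned stand-in for sequence-trained predictors; it is monotone in every
fired rule, which is what selection and ordering need. Quantotypic selection
takes the two best peptides per protein after hard filters (7–25 residues,
unique in the proteome, no Met/Cys unless nothing else exists — then flagged),
ranking by risk then length preference. QconCAT assembly minimises summed
junction risk exactly for ≤ 7 peptides and otherwise takes the best of greedy
chains from every start and the input order (so it is never worse than the
input ordering).

Masses are monoisotopic throughout (proton 1.007276 Da), computed via
pyteomics and cross-checked in the tests against an independent residue-mass
table; y ions retain the water and the C-terminal label, b ions neither. The
default heavy label is [¹³C₆] (+6.020129 Da) on the C-terminal K/R: the
printed light/heavy standard pair (785.8/788.8 at 2+) implies a ≈ +6 Da shift
and the exact label is not recorded, so the shift is configurable
([¹³C₆,¹⁵N₂] and [¹³C₆,¹⁵N₄] constants are provided). Transition selection is
two-stage: six by (y-ions above the precursor first, then intensity), then
three of those six by signal-to-background, with fragment-index tie-breaks.
Scheduling feasibility is pure arithmetic: 12 points over a 15 s peak gives a
1.25 s cycle; at 40 ms minimum dwell at most ⌊1.25/0.040⌋ = 31 transitions
may co-elute within a ±1.5 min window.

## Synthetic-data generator

The generator emulates the statistical structure of the census data, not its
biology:

* log₁₀ protein cpc ~ Normal(2.8, 0.9) — ~5 orders of magnitude, centred so
  that with the detection floor the A/B/C peptide fractions land near the
  observed 44/38/17%.
* Two surrogate peptides per gene; each carries a log-normal light-response
  bias (log₂ sd 0.55) standing in for differential digestion/modification
  losses — the one distribution the source experiment does not constrain.
  It reproduces a median sibling |log₂ X/Y| ≈ 0.54 before censoring; LOD
  truncation pulls the observed pipeline value below that, as it would in
  real data.
* **Noise model:** every measured peak area — light *and* heavy — gets
  independent multiplicative log-normal noise at `replicate_cv` (default
  12%), because each replicate is a separate digest/injection of both
  analyte and standard. The ratio CV is therefore √2 × 12% ≈ 17%, and the
  median of the small-sample rCV estimator over 4 replicates is
  ≈ 0.67 × 17% ≈ 11.4%, i.e. the generator's default conditions reproduce
  the observed repeatability on the estimator actually used. A model with
  noiseless heavy areas cannot do this: it yields measured median rCVs near
  8% for the same per-area CV.
* Censoring: light peak groups below `lod_area` (default 1.7e4 area units,
  with background noise = lod/5 so S/N = 5 exactly at the LOD) are missing →
  Type B; a per-peptide assay-failure probability (default 0.17) yields
  background-level signal for both labels → Type C. The implied Type-B bound
  is ≈ 500 cpc at the default settings. Decoy peak groups are emitted as
  background-only signal for the FDR stage.
* Transcriptome: log₁₀ TE = log₁₀(1035) + Σ γᵢ·fᵢ (centred features)
  + Σ δⱼ·fⱼ·(log₁₀ M − mean) + η, and mRNA cpc = protein cpc / TE, so
  TE ≡ P/M holds exactly per gene. When interaction coefficients are present
  the equation is solved per gene so the linear relation the translation
  model fits holds exactly (feature latents are truncated at ±3.5 sd to keep
  the solve positive). FPKM is mRNA cpc with 5% log-normal noise on an
  arbitrary scale.
* Default feature effects (tAI +0.35, CAF20 RIP −0.22, PARS +0.18, poly-A
  −0.12, PEST +0.20, half-life +0.12; residual η sd 0.59) are sized once so
  the default dataset shows mRNA-only r² ≈ 0.58 and full-model r² ≈ 0.70 on
  log₁₀ protein, the regime reported for matched chemostat data. Because
  log₁₀ protein is the root variable, r²(full) = sd_p²/(sd_p² + sd_η²); the
  `SimConfig.model_recovery` conditions use this identity to hit a target r²
  (0.70 → η = 0.9·√(3/7)).

All randomness flows from the single `seed` through per-stage
`numpy.random.SeedSequence` children; identical configs give byte-identical
outputs.

What the synthetic tests do **not** show: real chromatographic interference,
RT drift, isotope-envelope effects, correlated (batch) replicate error,
non-log-normal abundance tails, or biological coupling between abundance and
detectability beyond the hard LOD. Passing them demonstrates that the
pipeline's rules and arithmetic are implemented correctly and calibrated
under the stated noise model, not that the model captures every property of
instrument data. One visible consequence of the generator's geometry: with
protein as the root variable the OLS log-log slope of protein on mRNA is
attenuated below 1 (≈ 0.6 at defaults), unlike the ≈ 1.08 observed in real
matched data; the slope estimators are therefore validated against
closed-form limits (OLS → ρ and major axis → 1 on equal-variance bivariate
normals) rather than against the generator.

## Translation model selection

Forward selection always includes log₁₀ mRNA; every candidate feature is
tried as a main effect and as an interaction with centred log₁₀ mRNA (the
feature is centred before multiplying). The step winner maximises adjusted
r² and is accepted if its partial F-test p < 0.01; ties break by term name,
near-collinear candidates (|r| > 0.99 with an included term) are skipped with
a note, and genes missing any feature are dropped listwise. Because each step
tests the best of ~2k candidate forms at a nominal α = 0.01, the family-wise
false-inclusion probability per step is ≈ 5–10%; "recovery" of a generative
structure therefore means the true terms are selected, and occasional small
spurious terms are expected behaviour of sequential F-tests, not a defect.

## Model-II regression

Ranged Major Axis: both variables are ranged to [0, 1] by (v − min)/range,
the first principal axis of the ranged cloud gives the slope, which is
back-transformed by range_y/range_x. This makes the estimator scale-invariant
and symmetric (swapping axes inverts the slope), appropriate when both
variables carry error. The plain major-axis slope is also reported; on
equal-variance data it tends to 1 regardless of correlation, the property the
tests exercise.

## Dataset comparison

Abundances are rescaled to ppm assuming 6×10⁷ protein molecules per cell.
Spearman correlations use pairwise-complete positive values (zeros and
missing are excluded, never imputed); pairs below the overlap minimum
(default 50 shared proteins) are reported missing rather than fabricated.
Clustering is agglomerative on 1 − ρ with average linkage (the linkage is not
recorded in the source and is configurable); the dendrogram is written as
Newick with UPGMA-style heights (node height = merge distance / 2). M–A uses
M = log₂ ratio and A = mean log₂ abundance.

## Turnover classes

Half-life bins at 20 and 40 min; the short-half-life bin (0–20 min) is
labelled **fast**, the standard biochemical usage, since published usage is
inconsistent (a figure legend and the accompanying text disagree); the
mapping is a label only and does not affect any computation.

## Problem sizes

Test and benchmark runs use 500–1200 genes, 4 replicates, 3 spike levels, 100
FDR simulations and 50 model-recovery runs — sizes at which the Monte-Carlo
checks are stable while the full suite stays fast; all generators scale to
larger n via `SimConfig`.
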