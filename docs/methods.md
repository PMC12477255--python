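# Methods

This document specifies the generative model, the processing algorithms,
their parameters and defaults, and the numerical choices behind `cytopipe`.
Everything stated here is implemented and tested in the package; nothing
below is an empirical claim about real data.

## 1. Generative model

### 1.1 Intensity model

All biology is defined on the arcsinh scale with cofactor 5, the standard
variance-stabilizing transform for mass cytometry. A cell of population *p*
expresses marker *m* as

```
z ~ Normal(loc(p, m), marker_sd)
x = max(5 · sinh(z), 0)          # raw ion-count-like intensity
```

so that `arcsinh(x/5) ≈ z` except for truncation of the small negative tail.
Defaults (`TruthConfig`):

| Parameter | Default | Rationale |
| --- | --- | --- |
| `positive_level` | 4.0 | bright positive mode, well separated on arcsinh scale |
| `negative_level` | 0.35 | background/spillover-like low mode |
| `marker_sd` | 0.30 | overlap small enough that threshold gating is meaningful |
| `signaling_baseline` | 1.0 | intermediate basal phospho-signal, room to shift both ways |

Each population has a fixed positive-marker set (e.g. B cells: CD45, CD20,
HLA-DR; intermediate monocytes: CD45, CD14, CD16, CD11b, CD11c, HLA-DR);
all other phenotype markers sit at the negative level.

### 1.2 Experiment design

Defaults mirror a three-arm vaccine study: groups `mock`, `mRNA`, `protein`
with 8 animals each; tissues `PBMC` and `LN`; stimulation conditions
`UNSTIM`, `PMAI` (PMA/ionomycin) and `R848`; 13 reported mononuclear
populations (CD4 T, CD8 T, activated HLA-DR+Ki67+ CD8 T, double-negative T,
B, IgM+ B, CD56+ and CD16+ NK, pDC, mDC, classical / intermediate /
non-classical monocytes) plus unlabeled "other" mononuclear cells and a
granulocyte component outside the mononuclear gate
(`granulocyte_fraction = 0.12`).

Mixture weights per (animal, tissue) start from tissue-specific base
frequencies (e.g. PBMC: 30% CD4 T, 10% classical monocytes; LN: 20% B),
multiplied by group-effect factors encoding the seeded group differences
(mock vs vaccinated: ×3.5 activated CD8 T and ×0.33 pDC in PBMC; ×3.0
intermediate monocytes, ×1.4 B and ×1.7 IgM+ B in LN), by a severity
coupling `exp(β · severity)`, and by per-animal lognormal jitter
(`animal_jitter_sd = 0.35`). Named components are renormalized only if they
would exceed the non-granulocyte budget; the remainder is "other".

### 1.3 Severity and outcomes

Each animal carries a latent severity: group means 2.4 (mock), 1.2 (mRNA),
0.8 (protein), sd 0.45, centered at a reference of 1.5 for couplings.
Outcomes are linear in severity with Gaussian noise, clipped to their scale:
viral RNA log10 (range 0–10), pathology score (0–4), radiograph score
(0–3). Severity also couples to designated features — frequencies (PBMC
activated CD8 T +0.35, LN intermediate monocytes +0.35, PBMC pDC −0.30 per
severity unit) and signaling responses (PBMC NK CD56 pCREB under PMAI
+0.30, LN IgM+ B IkBa under PMAI −0.30) — giving outcome correlations a
known answer.

### 1.4 Stimulation responses

Stimulation adds shifts on the arcsinh scale to signaling markers of
specific populations: PMA/ionomycin drives broad pErk1/2, pCREB, pP38,
pMAPKAP2 and pS6 responses (+0.5 to +1.2) with IkBa degradation (−0.5) in B
cells; R848 drives pDC/monocyte/B responses. Per-(animal, population,
marker, stimulation) Gaussian noise (`response_noise_sd = 0.05`) and
per-(animal, tissue, marker) baseline offsets (`baseline_jitter_sd = 0.05`,
common to all aliquots of an animal, so they cancel in responses) make
animals exchangeable but not identical.

### 1.5 Barcodes, beads, drift, doublets

* **Barcodes**: 6 palladium channels, 3-of-6 codes (20 possible, 16 used per
  batch). Positive channels at arcsinh level 5.5, negative at 0.3, sd 0.25.
* **Beads**: 5 disjoint bead channels at level 4.0 (sd 0.2); cell events
  carry low bead-channel background (0.10). Beads are spiked at a
  configurable fraction of events.
* **Drift**: a smooth global sensitivity `m(u) = c0 + c1·u + c2·u²`,
  `u = t / 600 s`, default `(1.0, −0.25, 0.10)`, multiplies every raw
  intensity; per-channel overrides are supported. Acquisition times are
  strictly increasing uniform order statistics over the 600 s window.
* **Doublets**: channel-wise sums of two cell draws from two different
  samples of the pool; their barcode-channel union has > k high channels,
  which is what debarcoding must reject.

### 1.6 CBC

Per-animal complete blood counts: WBC lognormal around 9,500 cells/µL,
neutrophil fraction clipped to [0.1, 0.8], eosinophil fraction to
[0, 0.1], so `WBC − (neutrophils + eosinophils) ≥ 0` holds by construction.

### 1.7 Determinism

All randomness flows through `numpy.random.Generator` objects seeded by a
`SeedSequence` of the experiment seed (masked to < 2³¹) plus CRC32 hashes of
string tokens naming the draw site (e.g. animal id, tissue, stimulation).
Simulating the same sample twice is byte-identical; different draw sites are
statistically independent.

## 2. Processing algorithms

### 2.1 Bead identification

Otsu's threshold on the mean arcsinh bead-channel signal, with a quantile
fallback and an explicit bimodality requirement (the two class means must be
≥ 1.5 arcsinh units apart). Unimodal-high inputs are called all beads;
unimodal-low inputs yield an empty mask with a warning rather than false
positives.

### 2.2 Normalization

Finck-style sliding-window correction: bead events are sorted by time and
grouped into consecutive windows of 500; per channel the local bead median
defines a multiplicative correction `reference / local median` anchored at
the window's median time. Corrections are linearly interpolated between
knots and held flat beyond the outermost knots. The reference defaults to
the file's own overall bead medians; `pooled_bead_reference` across batches
aligns multiple batches to a common scale. Bead channels get their own
per-channel corrections; all other channels receive the geometric mean
across bead channels (the drift is a global sensitivity, and the geometric
mean is the natural average of multiplicative factors). A zero local median
is an error, never silently skipped.

### 2.3 Debarcoding

1. arcsinh-transform barcode channels and rescale each to [0, 1] between
   its 1st and 99th percentiles (clipped).
2. Per event, take the k highest channels as the code; separation = k-th
   highest − (k+1)-th highest rescaled intensity. Events below the
   separation cutoff (default 0.3) are unassigned (`low_separation` —
   doublets land here because their > k high channels leave no gap);
   indicator patterns not in the scheme are `bad_code`.
3. Mahalanobis purity filter per assigned sample: location and covariance
   of the rescaled barcode channels are estimated robustly — a per-channel
   median/MAD pre-screen (diagonal distance, χ²(0.99) cutoff) selects
   inliers, then the classical mean/covariance of the inliers defines the
   final squared Mahalanobis distances. The robust step matters: a few
   percent of foreign-code contaminants would otherwise inflate the
   covariance along their own direction and evade any fixed threshold.
   Events beyond `max_dist` (default 30, squared-distance convention;
   χ²₆ 0.999 ≈ 22.5) are unassigned. Samples with fewer events than
   dimensions + 1 are skipped with a warning; near-singular covariances are
   ridge-regularized (ε = 10⁻⁶ × mean diagonal).

The outputs partition the input: every event is exactly one of assigned,
unassigned, or bead; the pipeline manifest asserts this conservation.

### 2.4 Gating

A validated DAG of threshold gates on the arcsinh scale; each node is a
conjunction of `channel >/< cutoff` rules AND its parent's membership. The
default tree roots at CD45+CD66− (mononuclear) and defines the 13 reported
populations; intermediate monocytes are CD11b+CD16+HLA-DR+. The default
cutoff 2.2 is the midpoint of the generator's negative (0.35) and positive
(4.0) modes. Trees round-trip through YAML for auditability.

### 2.5 Features

* Frequencies: 100 × population count / mononuclear count; zero-denominator
  samples are excluded with a warning.
* Pseudo-absolute counts (PBMC, unstimulated): frequency ×
  (WBC − neutrophils − eosinophils); missing CBC yields a flagged-missing
  row, never an imputed value.
* Nested correction: reported children subtracted from reported parents
  (B ⊃ IgM+ B, CD8 T ⊃ activated CD8 T) for disjoint composition displays.
* Signaling: per-(sample, population, marker) median of arcsinh(x/5);
  populations under `min_cells = 20` events give NaN. Responses are
  stimulated − unstimulated within (animal, tissue, population, marker);
  missingness propagates.

### 2.6 Statistics

* Pairwise group tests: equal-variance Student t (unpaired); stimulation
  responses: one-sample t across animals on the per-animal differences
  (equivalent to a paired t on matched aliquots). Zero-variance inputs are
  flagged degenerate instead of dividing by zero.
* Multi-group: one-way ANOVA (F = t² for two groups, covered by tests).
* Benjamini–Hochberg step-up within declared families (frequency tests per
  tissue; response ANOVAs per tissue × stimulation; outcome correlations
  per tissue × outcome × feature family). NaN p-values are excluded from
  the family size m. The implementation is our own step-up; tests verify it
  against a brute-force oracle and `statsmodels`.
* Volcano classification uses the uncorrected p (< 0.05) and
  |mean arcsinh change| > 0.1, both strict.
* Feature selection: top ⌈0.2·N⌉ per (tissue, stimulation) by combined rank
  (ascending p rank + descending |change| rank), ties broken by larger
  |change| then lexicographic feature id — fully deterministic.
* Heatmap Z-scores: (group mean − grand mean of all animal values) /
  population-convention SD of all animal values.
* Outcome correlations: Pearson r of every frequency feature and every
  signaling response against each outcome, pooled across animals
  (optionally per group); BH within (tissue, outcome, family); `hatch`
  marks adjusted p > 0.05. Correlating all responses (not only the
  heatmap-selected subset) keeps the correlation analysis independent of
  the display selection.

## 3. Numerical choices

* FCS 3.1 files are float32 little-endian list mode; round-trips are exact
  at float32 precision. The TEXT delimiter is ASCII 0x1E (record
  separator) because `/` occurs in marker names (pErk1/2). TEXT and DATA
  offsets are stabilized by fixed-point iteration when writing; truncated
  or malformed files raise `FCSParseError` naming the offending segment or
  keyword.
* Barcode rescaling uses percentile (not min/max) bounds for robustness to
  outliers; the rescaled scale makes the separation cutoff dimensionless.
* The Mahalanobis threshold is on squared distance; the robust estimate is
  a single deterministic reweighting (median/MAD screen → classical
  estimate), never an iterative fit, so results are exactly reproducible.
* BH uses a stable argsort and reverse cumulative minimum; all ranking
  ties break deterministically.
* Sliding-window normalization uses `np.interp` (linear, flat beyond end
  knots). With few beads the knots cover the acquisition sparsely and edge
  extrapolation dominates — bead density, not the algorithm, limits
  accuracy there.

## 4. What the generator does and does not emulate

Emulated: population mixtures with group effects and animal variation,
staining positive/negative modes on the arcsinh scale, stimulation-induced
signaling shifts, severity-linked features and outcomes, palladium
barcoding with doublets, normalization beads, smooth sensitivity drift,
CBC panels.

Not emulated: ion-count (Poisson-like) noise and zero-inflation of real
CyTOF detectors; isotopic impurity/oxide spillover between channels;
cell-size (DNA/event-length) covariates; abrupt sensitivity jumps or
clogs; acquisition rate variation; biological covariance between markers
within a population (markers are conditionally independent given the
population); batch reagent-lot effects beyond global drift.

## 5. Limitations

* Threshold gating assumes the bimodal staining model above; it is not a
  clustering method and would need retuned cutoffs for other intensity
  models.
* The debarcoder assumes exactly one k-of-n scheme per pooled file and
  equal-ish sample sizes when estimating per-sample covariances.
* Statistical conventions (equal-variance t, fixed BH families) are fixed
  choices matching the analysis design, not adaptive procedures.
* Synthetic results quantify the pipeline's self-consistency against its
  own generative model; they are not evidence about any real dataset.
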