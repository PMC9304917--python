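# Methods

`poriascreen` re-implements, as a tested and reusable pipeline, a screening
workflow that discriminates the two medicinal parts of the *Wolfiporia cocos*
sclerotium — the inner white *Poria* and the outer peel *Poriae cutis* — from
FT-NIR fingerprints and HPLC common-peak tables, and screens candidate
triterpenoid biomarkers. This note records the models, the defaults and why,
the numerical choices, and what the synthetic data does and does not show.

## Synthetic data model (`synth`)

Real sample collections of this kind are rarely public, so the package ships
a generator that reproduces the *statistical structure* of the reference
design: 200
samples (2 parts × 10 growing regions, 3 replicate scans each) on a
10,000–4,000 cm⁻¹ grid at 4 cm⁻¹ steps (1,501 points).

**Band model.** A spectrum is a sum of Gaussian bands over a weak concave
polynomial baseline. Band centers sit at the conventional FT-NIR assignments
for this material — C–H overtone/combination bands near 8,300 and
6,850 cm⁻¹, O–H/C–H combination bands near 5,600, 5,200, 4,400 and
4,100 cm⁻¹. No attempt is made to model real triterpenoid band physics; the
bands only carry the right qualitative geometry.

**Class and region structure.** The part effect multiplies band intensities
inside the two discriminating windows (7,200–5,350 and 5,200–4,000 cm⁻¹) by
1 ± part_effect/2 (default part_effect = 0.12). Each region applies a smaller
fixed random rescaling of all bands (region_effect = 0.03, multiplier drawn
once per region from ±region_effect/2). The defaults are calibrated only to
reproduce the qualitative ordering reported for the real data — between-part
differences exceed between-region differences — which the test suite asserts
on noise-free output; neither magnitude is stated in any source.

**Noise model.** Three scales, all configurable:

| knob | default | meaning |
|---|---|---|
| `noise_sd` | 0.002 AU | white detector noise per point |
| `baseline_drift_sd` | 0.01 AU | offset/tilt of the baseline |
| `scatter_sd` | 0.04 | multiplicative scatter factor sd |

Scatter follows the standard multiplicative-plus-offset model that MSC and
SNV are designed to remove. Scatter and drift are *two-level*: the large
components are per sample (how this portion of powder packs, slow instrument
drift), while the three replicate scans — taken back-to-back without
re-preparing the sample — share them almost entirely and differ only by a
20 % jitter plus a **monotone scan-order scatter component** (step =
`scatter_sd` per scan). That ordered component models progressive compaction
of the powder under repeated scanning and is essential to the design: the
replicate series doubles as the perturbation series of the 2D correlation
maps, and a generalized-2DCOS perturbation must vary systematically along its
ordering variable — purely iid replicate noise has no perturbation direction
and yields structureless maps.

**HPLC peak table.** Columns carry chromatogram peak *labels*
(2, 4, 5, 6, 8, 13, 14, 15, 16 — nine common peaks of a longer elution
profile), not positions 1–9. Six labeled peaks {4, 6, 13, 14, 15, 16} are
multiplied by 1.8 in the *Poria* class; lognormal per-sample noise with 10 %
CV is applied and each row is sum-normalized to relative areas. Because of
that closure, the three non-discriminant peaks shift *down* in *Poria* —
they deliberately carry most of the base mass (≈ 75 %) so the closure shift
stays small relative to the planted effects and the VIP > 1 rule isolates
exactly the planted six. The nearly-uniform effect size matters: strongly
uneven effects push the weakest planted peak below the VIP threshold.

**Calibration standards.** Five triterpenoid analytes with typical reported
concentration ranges (e.g. 0.22–6,730 µg·ml⁻¹ for poricoic acid A) and
plausible DAD-scale slopes; levels are geometrically spaced (a serial
dilution) by default, linear spacing available. Area noise is additive with
sd = `noise_sd` × (top-level area) so analytes with slopes spanning decades
are comparably noisy.

All three generators draw from streams keyed by (seed, task-tag), so each
stage is reproducible in isolation and identical seeds give bitwise-identical
output.

## Preprocessing (`preprocess`)

Replicate averaging, Savitzky–Golay second derivative (SD), SNV and MSC. The
SD window/order default to 17 points / cubic — common FT-NIR practice; no
source states values — with the derivative scaled by the true grid spacing
(units AU·(cm⁻¹)⁻²). Edge points where the window does not fit are filled by
evaluating the boundary polynomial fit (no NaNs), flagged in metadata. The
grid is stored descending (10,000 → 4,000 cm⁻¹, the plotting convention);
all math is orientation-agnostic.

## Splitting (`split`)

Kennard–Stone max–min Euclidean selection: seed with the two mutually
farthest records, repeatedly add the record with the largest minimum distance
to the selected set, stop at round-half-up(n · fraction). Half-up rounding
reproduces the conventional 67/33 partition of 100 records at 2/3. Every tie
breaks to the lowest original index, making the split fully deterministic
across platforms; distances are taken on the records as given, with no
internal scaling. The random holdout (10 % external verification set) is
seeded sampling without replacement.

## PCA and PLS-DA (`latent`)

PCA is the SVD of the column-centered matrix; the explained fraction of
component k is σ²ₖ/Σσ². PLS-DA is PLS1 regression on a 0/1 class coding
fitted by NIPALS with deflation (class 1 = discriminating class, prediction
threshold fixed at ŷ = 0.5). Spectra are mean-centered only (no
unit-variance scaling), the usual choice for spectral data where the
variables share units.

Diagnostics follow the SIMCA conventions:

- R²Y = 1 − SSE/SSY on the training fit; RMSEE = √(SSE/(n − a − 1)) with a
  latent variables (RMSEC and RMSEE are treated as synonyms);
- Q² = 1 − PRESS/SSY and RMSECV = √(PRESS/n) from deterministic interleaved
  ("venetian blind", record i → fold i mod 7) cross-validation that refits
  the whole model per fold; 7 folds by default;
- AUC from the Mann–Whitney rank statistic of the continuous prediction;
- per-class %NER and overall %CCR as 100 × correct/total; ratios with a zero
  denominator are reported as undefined, never as 0;
- LV selection (when not fixed): smallest count whose Q² is within 0.01 of
  the maximum over 1..10.

**Permutation test.** 200 label permutations; for each, the model is
refitted with the same LV count and (|corr(y_perm, y)|, R²Y, Q²) recorded.
Lines are fitted through the permuted points plus the unpermuted anchor at
correlation 1. The model is *valid* when every permuted Q² lies below the
original and the Q² line's intercept at correlation 0 is ≤ 0 — the criterion
read off the conventional permutation plot.

## OPLS-DA and VIP (`oplsvip`)

The orthogonal-projection decomposition: the predictive weight is
w ∝ Xᵀy; each orthogonal round extracts the part of the X-loading orthogonal
to w, deflates X, and the predictive component is taken on the filtered
matrix. Peak tables are unit-variance scaled by default (relative areas span
magnitudes); Pareto and no scaling are available. R²X is the cumulative
X-variance of all components; Q² cross-validates the entire procedure,
scaling included. The orthogonal-component count defaults to 1, or can be
chosen by increasing while CV-Q² improves by > 0.01. VIP is computed from
the predictive component only (the "VIP_pred" convention): with a single
predictive component VIP_j = √p · |w_j|/‖w‖, so Σ VIP² = p by construction.
Biomarkers are variables with VIP strictly > 1, reported descending.

## 2D correlation spectroscopy (`twodcos`)

For a perturbation-ordered series W (m traces × p wavenumbers, reference
spectrum — conventionally the series mean — subtracted):

- synchronous Φ = WᵀW/(m − 1): symmetric, positive semi-definite,
  auto-peaks (diagonal) ≥ 0;
- asynchronous Ψ = WᵀNW/(m − 1) with the Hilbert–Noda matrix
  N_jk = 0 if j = k else 1/(π(k − j)): antisymmetric, zero diagonal, and
  identically zero for m = 2 (mean-centered two-point dynamics cancel);
- integrated map = Φ ∘ Ψ element-wise (antisymmetric like Ψ).

The per-sample perturbation series is the sample's replicate scans (m = 3 by
default), so 200 samples yield 200 map triples = 600 maps. The wavenumber
grid is block-averaged to ≤ 64 points before correlation (configurable up to
256) to bound the p × p maps; block averaging keeps band shapes while
suppressing white noise. Maps render to fixed-size images on a symmetric
diverging scale centered at zero (a zero map renders flat mid-scale);
matrix-form Φ and Ψ are verified against explicit double/triple-loop
summation oracles to < 1e-10.

## Residual network (`rescnn`)

A 12-weighted-layer residual classifier written directly on numpy arrays
(im2col-free convolutions as nine shifted tensor contractions; batch
normalization; manual backpropagation verified against central finite
differences in the test suite): one 3×3 stem convolution (stride 2), five
residual blocks of two 3×3 convolutions each with identity or 1×1-projection
shortcuts (widths 16, 16, 32, 32, 64; F(x) = H(x) − x formulation), global
average pooling, and a 2-class linear head — batch-norm layers and
projection shortcuts are not counted, per the usual convention. Global
average pooling makes the parameter count (≈ 102 k) independent of image
size.

Training: softmax cross-entropy, plain SGD with momentum 0.9, learning rate
0.01 and weight decay 1e-4 on convolution/linear weights, batch 32, ≤ 30
epochs at 64×64 input, no augmentation. The learning rate steps down ×0.1
after two thirds of the epoch budget; with a constant 0.01 the late-epoch
weights oscillate visibly (training loss rising an order of magnitude) and
borderline held-out samples flip. Everything is seeded; runs repeat exactly
under single-threaded execution. Defaults (image size, epoch budget, map
grid) are desk-scale choices for a single CPU; 224×224 input is available.

## Quantification (`quant`)

Ordinary least-squares standard curves (area Y on concentration X), R² as
squared Pearson correlation with the conventional > 0.99 linearity flag;
LOD = 3σ/slope and LOQ = 10σ/slope at signal-to-noise 3 and 10, with σ the
caller-supplied sd of blank-region baseline residuals (the package does not
model chromatographic baselines); spike recovery judged against the
pharmacopeia band 85–110 % inclusive; RSD summaries (100·sd/mean) reported
but not gated. Contents are back-calculated as (area − intercept)/slope —
floored at 0 with a flag below the intercept, flagged when outside the
validated range — and the two parts are compared per analyte with Welch's
unequal-variance t-test (no source names a test; Welch is the safe default
for unequal group variances).

## Network-pharmacology filtering (`netfilter`)

Pure table/graph operations on user-supplied exports (no live database
queries): components kept at OB ≥ 30 % and DL ≥ 0.18 (inclusive, as the
thresholds are stated); target–target interaction edges kept at confidence
strictly > 0.9, duplicates collapsed, self-loops and isolated nodes removed;
core targets are nodes with degree ≥ 6 whose betweenness *and* closeness
centralities strictly exceed their network medians ("parameters greater than
the median" is not enumerated anywhere; these two are the standard Cytoscape
Network-Analyzer parameters and the choice is configurable); degree ranking
of the component–target–pathway graph breaks ties alphabetically. A toy
component/edge table ships with the package (synthetic stand-ins shaped like
TCMSP/STRING exports) so everything is testable offline.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* the analysis assumes —
class-dependent band intensities, region effects smaller than part effects,
scatter/drift/noise at plausible scales, a systematic replicate-order
perturbation, planted discriminant peaks, linear calibration — but not real
*W. cocos* chemistry: no water-vapor artifacts, no instrument optics, no
real band assignments of individual triterpenoids, no peak shifts or
nonlinear detector effects. Perfect discrimination on synthetic data
therefore demonstrates that the pipeline's statistics and learning machinery
work as specified, not that real-world accuracy would reach the same values.
Headline values that depend on a particular laboratory's measurements (exact
R²/Q², epoch counts, per-class tables) are not reproduction targets; the
pipeline reports its own computed analogs.

## Known limitations

- The CNN is CPU-bound numpy; desk-scale by design (minutes per training
  run), with no GPU path and no pretrained weights.
- Kennard–Stone is O(n²) in memory for the pairwise distance matrix.
- The OPLS-DA Q² cross-validates the component counts chosen, not the
  choice rule itself.
- LOD/LOQ require the caller to supply the baseline noise estimate.
- The netfilter median rule can be empty by design on symmetric graphs
  (nothing strictly exceeds the median).
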