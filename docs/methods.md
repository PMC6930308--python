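# Methods

## Problem and model

The task is multivariate classification of six plant varieties from NIR leaf
absorbance spectra, A = log₁₀(1/R), recorded over 12000–3800 cm⁻¹ at 4 cm⁻¹
steps (2051 points). Classification is by partial least-squares discriminant
analysis (PLS-DA): the class block Y is one-hot coded (six columns), both
X and Y are column-centred on the calibration set, and a PLS-2 decomposition
extracts latent variables t_a = X w_a with maximal covariance to Y. The
regression matrix in the original variable space is B = W(PᵀW)⁻¹Qᵀ;
predictions are ŷ = X_c B + ȳ and a sample is assigned to the class with the
largest score (ties to the earliest class in the declared order). Per-class
score thresholds that minimise calibration in/out errors are estimated as
diagnostics, but the assignment rule is argmax: the reporting assumes every
sample lands in exactly one class.

### NIPALS details

Components are extracted sequentially with X-deflation only
(X ← X − t pᵀ, p = Xᵀt/tᵀt). The inner loop's fixed point is the dominant
eigenvector of XᵀYYᵀX; we compute it directly from the c × c eigenproblem
(YᵀX)(XᵀY) (c = 6 classes), then run the classical update loop
(budget 500 iterations, relative tolerance 10⁻¹²) from that start. This is
numerically identical to iterated NIPALS but immune to the slow power-method
convergence that occurs on deep components where the residual's top
eigenvalues nearly coincide. Requesting more components than the residual
supports raises a rank error; the full-rank decomposition reproduces
multivariate least squares (verified against a normal-equations oracle), and
the single-response case matches an independent PLS-1 implementation.

### Latent-variable selection

Venetian-blinds cross-validation on the calibration set: samples ordered by
class then original order are dealt into 10 folds in blinds of thickness 1.
Each fold refits the X/Y centering on its training part (no leakage across
the blind boundary). For each candidate count 1..20 the pooled out-of-fold
hard assignments give a per-class error; the smallest count attaining the
minimum mean per-class error is selected. Averaging the error over classes
rather than samples weights all varieties equally (the design is balanced,
so the two coincide here up to fold-boundary effects).

## Preprocessing

The fixed chain is SNV → Savitzky–Golay first derivative → mean centering.

* **SNV** normalises each spectrum to zero mean and unit standard deviation,
  with the sample (n−1) denominator; either denominator convention rescales
  all rows by the same factor and is immaterial downstream. Constant rows
  are rejected explicitly.
* **SG derivative** uses a 15-point window and 2nd-order polynomial. The
  derivative is per index step; since the axis is uniform (4 cm⁻¹) this is a
  constant multiple of d/d(cm⁻¹) and irrelevant after centering. The 7 edge
  points on each side are trimmed rather than extrapolated — the axis
  extremes are uninformative, and extrapolated edges would otherwise attract
  spurious importance. 2051 points become 2037.
* **Mean centering** always uses calibration means; test spectra are never
  centred on themselves.

## Splitting

Kennard–Stone (max–min Euclidean distance, ties to the lowest row index) is
run independently within each class, selecting round(0.7 · n) calibration
samples (half-up rounding; exactly 35 of 50 here). Distances are computed on
SNV+SG-preprocessed, *uncentered* spectra: centering depends on the split
(a circularity), while the SNV+SG space is the geometry the model actually
sees. A seeded uniform-random split is available as an alternative and gives
comparable downstream accuracy on the synthetic data.

## Variable importance and truncation

* **VIP**: VIP_j = √(p Σ_a SSY_a (w_{aj}/‖w_a‖)² / Σ_a SSY_a) with
  SSY_a = (t_aᵀt_a)(q_aᵀq_a), the multi-response generalisation appropriate
  for a six-column dummy block; Σ_j VIP_j² = p by construction, and scores
  near or above 1 are conventionally "relevant".
* **Selectivity ratio**: for each class, the spectra are projected onto the
  normalised regression vector (target projection); SR_j is the ratio of
  explained to residual variance of variable j on that single component.
  Residuals below 10⁻¹² of the column total cap SR at 10¹². Per-class
  vectors are aggregated by the elementwise maximum — a variable important
  for *any* class discrimination should be retained.
* **Regression vector**: |B_{jc}| per class.

Importance is computed from the full six-class model (not per-class
submodels). The truncation cut points are configuration defaults — 
6700 cm⁻¹ (dried) and 7500 cm⁻¹ (fresh), keeping the low-wavenumber side —
not derived automatically from the indicator curves: the choice of a cut is
a judgement over three indicator plots, and automating it would over-claim.
The truncated model is an independent refit: the raw leaf spectra are cut
first and the whole chain (SNV on the cut range, SG, centering, LV
selection) is re-run on the same calibration/test membership.

## Synthetic data generator

No instrument data ship with the package; the generator emulates the study
design so the pipeline is testable end to end.

* **Design**: 6 varieties × 10 trees × 5 leaves × 3 replicate scans per
  sample type; axis 12000→3800 cm⁻¹ descending in 4 cm⁻¹ steps.
* **Bands**: Gaussian in wavenumber. Fresh mode: dominant broad water bands
  at 5000 and 7000 cm⁻¹ (O-H combination / first overtone), a C-H
  combination band at 4300 cm⁻¹, a weak shoulder at 5600 cm⁻¹ and a weak
  8500 cm⁻¹ second-overtone band. Dried mode: narrower bands at 4350, 4750,
  5200, 5800 and 6600 cm⁻¹ (C-H/N-H/O-H combinations and first overtones),
  plus class-independent bands at 7300 and 8500 cm⁻¹. Both modes leave
  7500–10000 cm⁻¹ low in information.
* **Varietal signal**: each class receives a binary contrast pattern over
  the informative bands, multiplying base amplitudes by 1 ± 0.08. Patterns
  are even-weight binary codewords (pairwise Hamming distance ≥ 2) drawn at
  random per seed. Two properties motivated this over i.i.d. draws within
  [0.92, 1.08]: (i) every pair of varieties is guaranteed to differ on at
  least two bands, so no two classes are spectrally identical by chance; and
  (ii) hypercube vertices are never convex combinations of other vertices,
  which excludes the masking failure of linear indicator regression (a class
  lying between two others along a line can never win the argmax regardless
  of sample size). With `class_effect = 0` all multipliers are 1 and the
  pipeline must perform at chance — the suite checks this.
* **Variance hierarchy**: per-tree and per-leaf random band-amplitude shifts
  (SD 0.006 and 0.008 absorbance units), i.i.d. per-point replicate noise
  (SD 0.003), a per-spectrum multiplicative gain (SD 0.03, giving SNV real
  scatter to correct) and a random linear baseline (offset SD 0.05, slope
  SD 0.02). The study reports no within-class variance components, only that
  per-class accuracies land in the 90–100% band; these defaults were chosen
  to put the dried pipeline in that band (dried min per-class test accuracy
  94–100% over 8 seeds) with fresh mode noticeably worse, reproducing the
  qualitative fresh/dried ordering.

**What passing tests do and do not show.** The generator reproduces band
layout, hierarchical variance, scatter and the accuracy regime — not real
leaf chemistry: no water-content or particle-size physics, no wavelength-
dependent scatter, no instrument drift, no correlated (non-Gaussian) noise,
and the class signal is a clean amplitude pattern rather than many small
correlated compositional shifts. End-to-end results on it validate the
pipeline's correctness and its behaviour under a known signal-to-noise
regime; they are not evidence about any particular instrument or crop.

## Numerical choices and degenerate inputs

* Replicates are averaged on absorbance (after log(1/R)), the common
  chemometric convention; averaging before/after the log differs only at
  second order in the replicate spread.
* CSV artifacts are written with 17 significant digits and read with
  round-trip float parsing, so write→read is bit-stable.
* Threshold estimation scans midpoints of adjacent sorted unique scores and
  takes the lowest midpoint among error-minimisers.
* Degenerate inputs raise typed errors naming the offending sample:
  constant rows under SNV, non-positive reflectance under log(1/R),
  rank-exhausted deflation, zero regression vectors under target projection,
  empty truncation windows.
* Default problem sizes throughout (and in `scripts/acceptance.py`) are the
  full emulated design — 300 leaves per sample type; a complete dried run
  takes a few seconds on one CPU.

## Known limitations

* The decision rule is argmax only; the estimated thresholds are reported
  but never used for assignment, so "none of the above" outcomes are
  impossible by design.
* No outlier diagnostics (Q residuals, Hotelling T²) and no alternative
  preprocessing chains (MSC, detrending, second derivative) — the chain is
  fixed to the optimized protocol the pipeline encodes.
* Truncation cut points are fixed configuration values, not data-driven.
* The CV error curve is often flat near its minimum; the smallest-count tie
  rule makes selection deterministic but can sit one or two LVs below the
  error-equivalent alternatives.
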