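# Methods

This note records the models implemented by `histofract`, the numerical
conventions behind them, what the synthetic-data generators do and do not
emulate, and the known limitations of the estimators.

## Preprocessing

Images are one immunostain channel (stain decomposition is upstream and out
of scope). RGB input is reduced by the unweighted channel mean, rounded half
up — the classic ImageJ "8-bit" conversion — and clamped to [0, 255].
Binarization uses the IsoData iterative-intermeans threshold on the 256-bin
histogram: T is the fixed point of T ← ⌊(μ_≤T + μ_>T)/2⌋. Foreground is the
**dark** side (intensity ≤ T), because chromogenic stain absorbs light; a
constant image yields an empty mask. Outlines are foreground pixels with at
least one 4-connected background neighbour, the image border counting as
background, which produces closed 8-connected contours. All grids are
row-major with origin at the top-left; every box grid is anchored there
(single-origin counting; multi-origin averaging is deliberately not used so
that every count is reproducible and checkable against a brute-force loop).

The default physical pixel size is 0.145 µm, matching a ×400 acquisition at
145 nm/pixel; it only affects the µm² area feature.

## Monofractal estimators

**Scale grid.** Powers of two from 2 up to 45% of the shorter image side, at
least 3 scales (so images must be ≥ 18 px in practice). Partial boxes at the
right/bottom edges are included; excluding them biases N(ε) low on
non-dyadic crops. The fit is OLS of log N(ε) on log(1/ε) (natural logs; the
base cancels in the slope). `box_counts_binary` accepts an explicit scale
list: for base-3 constructions such as the Sierpinski carpet, base-3 scales
{3, 9, 27, 81} put box edges on the construction lattice and make the count
series exact, which is what the carpet validation uses.

**DBC.** Differential box counting after Sarkar–Chaudhuri: intensity cell
height h = ε·256/min(rows, cols); each ε×ε box contributes
⌊(max − min)/h⌋ + 1 cells; N(ε) is the sum. A flat surface gives slope 2.

**Lacunarity.** Λ = mean over scales of (σ(ε)/μ(ε))², with the mean and SD of
per-box mass taken over *all* grid boxes, empty ones included (the empty
boxes are exactly the gaps lacunarity is meant to measure). Mass is the
foreground pixel count (binary) or the DBC cell count (grayscale).

**Grayscale outline FD.** The field does not define an outline on grayscale
data; here it is DBC applied to the image with all non-outline pixels set to
0, so only contour relief contributes. This is a package convention, flagged
as such.

## Multifractal estimation

Measures: binary boxes carry their foreground pixel count; grayscale boxes
carry the summed inverted intensity (255 − I), so stain-dark regions are
mass-heavy and the measure is non-negative. Box masses are normalized per
scale over occupied boxes only, which keeps negative moment orders finite;
all moment sums are evaluated in log space (logsumexp) so Q = −10 does not
overflow.

The Chhabra–Jensen direct method is used instead of a Legendre transform of
τ(Q): per Q the weights ν_i(Q) = μ_i^Q/Σμ_j^Q give

* α(Q) = slope of Σ ν_i ln μ_i vs ln ε,
* f(Q) = slope of Σ ν_i ln ν_i vs ln ε,
* τ(Q) = slope of ln Σ μ_i^Q vs ln ε,

with D_Q = τ(Q)/(Q−1) for Q ≠ 1 and D_1 = α(1). Legendre consistency
(f ≈ Qα − τ) is kept as a test property only. The Q grid is the half-open
200-point lattice −10.0, −9.9, …, +9.9; it contains Q = 0 and Q = 1 by
construction.

Thirteen scalars summarize each spectrum: D_Q, α and f(α) pinned at Q = 0
(the package's convention for reducing the three curves to single features),
plus max D_Q, min/max f(α), the α values at those extrema, OLS slopes of
D_Q(Q), α(Q) and f(α)(Q) over the full grid, the D_Q(Q) slope restricted to
Q ∈ [−1, 3] (endpoints inclusive), and Σ f(α(Q)) over the 99 grid points
with Q > 0. Two modalities × 13 multifractal + 3 monofractal features give
the 32 fractal features per image; mean intensity and stained area complete
the 34-column schema.

**Known limitation — negative Q on binary supports.** On binary image
measures, boxes clipping a structure boundary contain a single foreground
pixel at every scale, so the minimum normalized mass barely scales and the
fitted D_Q can dip (rise with Q) for Q < 0. This boundary-box artifact is a
property of moment methods on binary supports, not of this implementation:
on multiplicative cascades — the self-similar class where the estimator is
consistent across the whole Q range — the spectrum matches the closed form
log₂(Σ p_i^Q)/(1−Q) to ~1e-15 and is monotone for every seeded random
weight draw. Monotonicity of D_Q and α should therefore not be assumed for
arbitrary binary masks at strongly negative Q.

**Known limitation — DBC on rough surfaces.** Vanilla DBC underestimates the
dimension of rough fractional-Brownian surfaces at 8-bit, few-hundred-pixel
scale: the per-box relief stays comparable to the intensity cell height, so
the "+1" floor term never vanishes, and box relief does not yet follow its
asymptotic ε^H law. Measured on variogram-verified fBm surfaces (256×256,
mean of 3 seeds): FD ≈ 2.41 for H = 0.2 (theory 2.8), ≈ 2.26 for H = 0.5
(theory 2.5), ≈ 2.09 for H = 0.8 (theory 2.2). The estimate is strictly
monotone in H and well separated between surfaces, which is what the
prognostic use requires, but it is not an unbiased dimension estimate for
rough surfaces; this matches the published record that motivated the many
"improved DBC" variants (none of which are in scope).

## Synthetic data

The generators provide every input with a known answer; all are
bit-reproducible given (spec, seed).

* **Analytic masks**: line (FD 1), filled square (FD 2), Sierpinski triangle
  (log 3/log 2, built by the bit-AND construction so the dyadic count series
  is exact at full depth), Sierpinski carpet (log 8/log 3, size 3^depth),
  Mandelbrot-percolation carpets (expected dimension log₂(4p) for retention
  p, clipped to [0, 2]).
* **fBm surfaces** by spectral synthesis: white complex Gaussian noise
  shaped by |f|^−(H+1), inverse FFT, rescaled to [0, 255]. The field is
  synthesized on a 2× finer grid and subsampled — self-affinity is preserved
  under subsampling, and this restores the small-lag roughness that
  truncated spectral synthesis smooths away (variogram-estimated H:
  0.29/0.52/0.75 for nominal 0.2/0.5/0.8).
* **Blob clusters** mimic stained malignant-cell clusters: a union of
  discs (radius ≈ size/48, ±20% jitter) stamped on a torus, count set by the
  Poisson coverage identity density = 1 − exp(−n·E[πr²]/area), so realized
  coverage concentrates around the target (SD ≈ 0.008 at 256²). Grayscale
  texture is Gaussian-smoothed noise, darker inside blobs (~120 ± 30) on a
  white (255) background, so mean intensity falls as coverage rises. Not
  emulated: scanner noise, chromogen color, nuclei, tissue architecture —
  passing tests show estimator correctness on stain-like geometry, not
  clinical performance.
* **Cohorts** emulate the reference study frame: n = 73, target event rate
  25% (≈ 18 events), uniform censoring over 77–165 months (the observed
  censored-follow-up range). Each patient is latently high- or low-risk
  (50/50); imaging features are drawn per group (mean intensity
  244.5 ± 3.1 high vs 234.4 ± 9.1 low; binary FD 1.640 ± 0.10 vs
  1.722 ± 0.09). Event times are exponential with hazard
  λ₀·exp(Σ β_f z_f) on pooled-standardized features; λ₀ is solved per cohort
  (Brent's method on the exact P(T < C) under uniform censoring) so the
  expected event fraction hits the target. Default planted effects are
  β = +1.1 per SD of mean intensity and −1.1 per SD of binary FD — the
  reference direction (lighter staining, lower FD ⇒ higher risk) at a
  magnitude giving AUCs ≈ 0.25/0.75, i.e. clearly prognostic but far from
  deterministic.

## Prognostic evaluation

* **AUC**: Mann–Whitney estimator (ties ½), p from the tie-corrected normal
  approximation; nonparametric case-resampling bootstrap gives a percentile
  95% CI and the bias-corrected point 2·AUC − mean(boot). Resamples that
  lose an outcome class are redrawn.
* **Cutpoint**: exhaustive scan of all midpoints between consecutive sorted
  distinct values leaving ≥ 10% of patients on each side, maximizing the
  two-group log-rank χ²; ties (within 1e-12) break toward the more balanced
  split. The scan is vectorized over all candidates at once and verified
  against per-candidate lifelines `logrank_test` calls; it is invariant
  under strictly monotone feature transforms. At least 10 distinct values
  are required.
* **Cox**: lifelines `CoxPHFitter` (Efron ties). If all events fall in one
  group the partial likelihood is monotone; the fit is stabilized with a
  small ridge (0.01) and flagged. The bootstrap (default 1,000 resamples,
  stratified by group) yields a bias-corrected percentile CI for the HR.
* **Optimism exposure**: dichotomizing at an outcome-optimized cutpoint
  inflates type-I error, so the per-feature report carries both the naive
  Wald p and a corrected p in which the cutpoint scan is re-run inside every
  bootstrap resample; the observed coefficient is shrunk by the *median*
  resampling optimism (median, because near-separation resamples make the
  coefficient distribution heavy-tailed) and referred to the observed Wald
  SE. On null simulations this roughly halves the excess rejections; it
  does not fully restore nominal level, which is documented behavior of the
  bias, not hidden.
* **PH check**: lifelines `proportional_hazard_test` on scaled Schoenfeld
  residuals (rank time transform); requires ≥ 5 events.
* **Multivariate**: candidates with univariate Wald P < 0.20 enter, backward
  elimination drops the worst covariate until all retained P < 0.05; an
  empty model is a valid outcome. Perfect collinearity (|ρ| > 0.999) is
  pruned up front and flagged.
* Everything stochastic takes an explicit seed, recorded in every report.

## Problem sizes

Validation uses 512² rasters for the analytic anchors, 256² for fBm and blob
batches, depth-6 cascades (64² masses over scales 2–16), and cohorts of
n = 73–200 with hundreds of replicates — sizes at which every check runs in
seconds while the scaling regressions still span ≥ 3–7 scales.
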