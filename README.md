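# histofract

Fractal histomorphology features from single-stain histology images, and
their prognostic evaluation against time-to-event outcomes.

## The problem

In breast-tumor sections immunostained for pan-cytokeratin, the spatial
organization of the stained (epithelial/malignant) compartment carries
prognostic information: how dark the staining is, how much area it covers,
and how its geometry fills space across scales. `histofract` turns a
single-channel 8-bit image into 34 quantitative features —

* **intensity (2):** mean pixel intensity over the whole image, and total
  thresholded stained area (pixels and µm²);
* **monofractal (6):** box-counting fractal dimension FD, outline FD and
  lacunarity Λ, each for the binary mask (regular box counting) and the
  grayscale image (differential box counting, DBC);
* **multifractal (26):** 13 scalars per modality summarizing the
  generalized-dimension spectrum D_Q, the Hölder exponents α(Q) and the
  singularity spectrum f(α) over 200 moment orders Q ∈ [−10, 10).

— and evaluates any feature set against follow-up data (time to metastasis,
event flag) with ROC AUC, outcome-optimized cutpoints, Kaplan–Meier and Cox
proportional-hazards models, Schoenfeld PH checks, Spearman correlations,
and bootstrap internal validation (1,000 resamples by default).

## The core estimators

Binary box counting tiles the image with origin-anchored ε×ε boxes and fits

    log N(ε) = −FD · log ε + c

by OLS over a dyadic scale grid (ε = 2, 4, 8, … up to 45% of the shorter
image side). DBC treats intensity as surface height: each box contributes
⌊(max − min)/h⌋ + 1 intensity cells of height h = ε·256/min(rows, cols).
Lacunarity is the scale-averaged squared coefficient of variation of per-box
mass. Multifractal spectra use the Chhabra–Jensen direct method: per moment
order Q the normalized box masses μ_i are reweighted as
ν_i(Q) = μ_i^Q / Σ_j μ_j^Q, and α(Q), f(Q) and the mass exponent τ(Q) are
OLS slopes over log ε, with D_Q = τ(Q)/(Q−1) and D_1 = α(1).

Because no imaging cohort is distributed with the package, every estimator
is validated against constructions with known answers: lines and filled
squares, Sierpinski sets, Mandelbrot-percolation carpets, fractional
Brownian surfaces, binomial cascades with closed-form spectra, and simulated
survival cohorts with planted hazards (module `histofract.synthgen`).

## Worked example

`python examples/fractal_dimensions.py`:

```
line                 estimated FD = 1.0000   true = 1.0000   fit r2 = 1.0000
filled               estimated FD = 2.0000   true = 2.0000   fit r2 = 1.0000
sierpinski_triangle  estimated FD = 1.5850   true = 1.5850   fit r2 = 1.0000
sierpinski_carpet    estimated FD = 1.8928   true = 1.8928   fit r2 = 1.0000
```

The estimator recovers each construction's analytic dimension (log 3/log 2
for the triangle, log 8/log 3 for the carpet).

`python examples/prognostic_evaluation.py` simulates a 73-patient cohort
(~25% metastasis events) with the planted directions *lighter staining and
lower FD ⇒ higher risk*, and prints:

```
cohort: n = 73, events = 23
                   auc  auc_corrected  cutpoint       hr    hr_p  hr_p_boot  low_risk_direction
mean_intensity  0.7487         0.7493  239.1887  17.2014  0.0054     0.0037                 0.0
bin_fd          0.2948         0.2988    1.7009   0.1399  0.0080     0.0050                 1.0

multivariate model retains: ['mean_intensity']
```

AUC < 0.5 / HR < 1 flags an association with *low* risk, the direction
reported for fractal dimension. `hr_p` is the Wald p at the
outcome-optimized cutpoint (optimistically biased); `hr_p_boot` re-selects
the cutpoint inside every bootstrap resample and discounts that optimism.

The other examples (`extract_features.py`, `multifractal_spectrum.py`) show
the 34-column feature table on synthetic stain images and the spectrum of a
binomial cascade against its closed form (agreement to ~1e-15).

A thin CLI wraps the same functions:

```bash
histofract simulate cohort --seed 2 --out cohort.csv
histofract extract --input imgs/ --out features.csv
histofract prognosis --cohort cohort.csv --features features.csv \
    --boot 1000 --seed 17 --out report/
```

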