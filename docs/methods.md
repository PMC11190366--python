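# Methods

This note records the models implemented in `pfacalc`, the assumptions and
parameter choices behind them, and what the synthetic benchmarks do and do
not demonstrate.

## Threshold regression

The lethal electric-field threshold (EFT, kV/cm) of a biphasic train is
modeled as a power law in pulse count `p#`, phase duration `t_p` (µs) and
pulse repetition frequency `f` (kHz):

    ln EFT = c0 + c1 ln p# + c2 ln t_p + c3 ln f

`LogLogEFTRegressor` fits this by ordinary least squares on the log scale
(residual sum of squares of ln EFT), which is equivalent to assuming
multiplicative log-normal errors — appropriate for a strictly positive
threshold spanning more than a decade. The estimator takes raw positive
parameters and applies the log transform internally, so it composes with
scikit-learn model selection directly on physical inputs. The *frozen*
model carries the published full-precision coefficients; refitting the
packaged 52 condition means reproduces their signs and closely similar
values. No regularization or replicate weighting is applied: only condition
means are available, and the design is a near-balanced factorial where OLS
is well-conditioned. Rank-deficient designs (a feature with a single level)
are rejected with the feature named.

Diagnostics report absolute and relative errors per condition, with the
**predicted** value as the relative-error denominator, and Pearson
correlations of the observed threshold with the raw (unlogged) parameters —
on the packaged data these are −0.69 (phase duration), −0.28 (pulse count)
and +0.25 (PRF), confirming the ordering of effect strengths.

### Cross-validation

`cross_validate` shuffles the records with an explicit integer seed
(default 0), splits them into k = 10 folds differing in size by at most
one, refits on each training set and reports mean ± SD of R² in log space.
Two baselines are deliberately distinguished:

- training R²: the ordinary in-sample coefficient of determination;
- held-out R²: 1 − SS_res/SS_tot with SS_tot taken about the **training
  set's** response mean.

With 52 records a held-out fold has only 5–6 points; a fold-local SS_tot is
then dominated by sampling noise and can make an accurate model look
arbitrarily bad (or good) on individual folds. Using the training mean as
the baseline predictor is the standard remedy and is what the reported
held-out scores mean here. On the packaged means this gives roughly 0.97
(train) and 0.95 (held-out), averaged over shuffle seeds.

### Parameter recovery benchmark

`generate_synthetic_observations` draws thresholds as the model prediction
times exp(ε), ε ~ N(0, noise_cv), on any design. At noise_cv = 0 a refit
returns the generating coefficients to ≤1e-10 (numerical identity); at
noise_cv = 0.1 on the 52-point study design, the mean of 20 seeded refits
stays within 3 empirical SDs of the generating values. The 10% figure
matches the typical relative standard error of the measured thresholds.

## Dosimetry

The dose model is deliberately minimal — adiabatic, with no heat diffusion,
so it bounds the true temperature excursion from above:

    on_time  = 2 · t_p · p#               (both phases conduct; the 1 µs
                                           interphase delay carries none)
    peak SAR = σ E² / ρ                   [W/kg]
    AD       = peak SAR · on_time / 1000  [J/g]
    AH       = AD / c_p                   [°C]

Defaults: ρ = 1000 kg/m³ and c_p = 4.186 J/(g·K) (water/Tyrode), and
σ = 2.31 S/m. The conductivity is an *effective calibrated* value: the bath
conductivity used to produce the packaged heating column is not itself part
of the dataset, so `calibrate_medium` solves AH = σE²·t_on/(1000·ρ·c_p) for
σ on one reference condition (50 pulses, 0.2 µs, 200 kHz). Because
AH ∝ E²·t_p·p# exactly, one calibration row fixes the whole table: the
other conditions' heating values are then reproduced to within ~3%
(sub-percent for most), and the full-table range is 4.5–18.7 °C. Users with
a different medium should override all three constants.

## Electrode field map

The study's electrodes are two parallel steel needles (radius a = 0.35 mm,
center distance D = 1.72 mm) perpendicular to the monolayer; the package
models the in-plane field in 2-D as the classic two-wire problem. Each
conductor at ±V/2 is replaced by its equivalent line charge at (±b, 0),
b = √((D/2)² − a²), giving

    |E|(P) = 2Λb / (r₁r₂),    Λ = V / (2·arccosh(D/(2a))),

exact for infinite cylinders. Iso-magnitude contours are Cassini ovals
r₁r₂ = m² with m² = 2Λb/|E|: a single oval enclosing both electrodes below
the lemniscate level (the field value at the midpoint), two lobes above it.
The single-oval area has the closed form 2m²·E((b/m)⁴) (complete elliptic
integral of the second kind, parameter convention); two-lobe areas are
polygonized by marching squares with shoelace summation, which agrees with
the closed form to better than 0.1% where both apply. Enclosed areas count
the conductor cross-sections; an optional flag subtracts them (2πa² when
both electrodes are inside the contour), mirroring how measured death areas
may or may not include the electrode imprints.

`eft_from_area` inverts the strictly decreasing area(threshold) curve by
Brent's method to an area tolerance of 1e-4 mm²; round-tripping
threshold → area → threshold reproduces the input to 1e-3 kV/cm.

### Why 2-D, and the numeric oracle

The original experiments used a 3-D finite-element simulation whose
geometry (solution depth, electrode insertion) is not published, so the
absolute area↔threshold pairs of the study are not reproducible from first
principles; the 2-D idealization is validated *internally* instead.
`numeric_field` is an independent finite-difference Laplace solver:
Dirichlet ±V/2 on the electrode circles with **Shortley–Weller cut-cell
stencils** (plain staircasing of the circular boundary biases the effective
conductor radius by O(h), a ~4% field error at practical h), direct sparse
solve, field by central differences. On a finite box both natural outer
closures are wrong in opposite directions — an insulating (Neumann) edge
reflects the dipole, a grounded edge absorbs it — each leaving a measured
2.5–6% bias on a 2 mm probe disc at feasible box sizes. The default
`outer_bc="open"` therefore averages the insulating and grounded solves,
cancelling the leading image term; the averaged solve agrees with the
analytic map to within 0.5% everywhere outside a 0.1 mm shell around the
electrodes (defaults: h = 0.05 mm, 14–20 mm box). Halving h reduces the
residual disagreement, consistent with first-order boundary convergence.

## Image quantification

Synthetic scenes emulate the assay's confocal images: a 6×6 mm field of
view at 10 µm/pixel; Calcein-AM renders live background bright (0.85 of
dynamic range) and the death region dark (0.20); propidium iodide inverts
the contrast (0.15/0.75); electrode imprints are dark disks (0.05) in all
channels; a linear illumination ramp and additive Gaussian noise complete
the scene. The death region is the field map's isoline region at a chosen
threshold, and its exact rendered pixel area is returned as ground truth.

The automated measurement applies one saturation-stretch pass (0.35% of
pixels, Calcein only), a global Otsu threshold (dark side for Calcein,
bright for PI), hole filling, opening and closing with a radius-3 disk,
hole filling again, and selection of the connected component at the image
center. Two implementation details matter in practice: (i) on quantized or
rendered images with few gray levels, Otsu is computed on the exact value
histogram so the returned threshold is an actual level and the ≤ split is
unambiguous — the binned variant can misclassify a level that sits at a bin
boundary; (ii) holes are filled *before* opening, because the bright rim
between an imprint and the lesion edge can be thinner than the structuring
element, and opening first would cut the imprint hole open to the
background. When the first Otsu split isolates the small imprint class
instead of the lesion (possible in three-level images), the majority side
is re-thresholded once. A flood-fill "wand" and a manual-polygon path are
available as fallbacks, mirroring how interactive tools are used when
particle analysis fails.

On these synthetics the automated path recovers ground truth essentially
exactly (well within the 2% noiseless / 3% at-10%-noise tolerances), and
Calcein and PI measurements of the same scene agree within 5%. What this
shows is that the *geometry and arithmetic* of the pipeline are correct.
Real images add texture, stitching seams, debris, partial detachment and
out-of-focus light that the generator does not emulate, so the published
thresholds and morphology parameters (saturation fraction 0.0035, disk
radius 3 px) should be treated as calibrated-to-synthetic defaults, not as
validated settings for arbitrary microscopes.

## Calculator

`run_calculator` composes the pieces: clamp each input to the studied range
([50, 400] pulses, [0.2, 10] µs, [2, 200] kHz — the continuous intervals,
since the fit interpolates), warn per clamped parameter, evaluate the
frozen model, attach the ±33% relative-error band (the model's maximum
relative fitting error; the measured-data uncertainty is of the same
order, so the band, not the point estimate, is the actionable output),
compute the dose report at the predicted threshold, and, when a voltage is
given, the lesion area under the analytic study-geometry map. Clamping to
the continuous interval rather than the four tested levels is a deliberate
choice: the regression is explicitly an interpolant over the range.

## Numerical and degenerate-input conventions

- Thresholds, durations and frequencies must be strictly positive;
  non-positive values raise rather than clamp everywhere.
- `eft_from_area` reports the attainable maximum area when asked for more.
- A threshold above the field maximum on the electrode surface yields a
  lesion area of 0.
- The Cassini closed form degenerates to the circle area πm² as b → 0.
- Observation CSV cells accept `mean ± se` strings or split `*_se`
  columns; malformed cells raise with the row and column named.
- All randomness (synthetic observations, synthetic images, CV shuffles)
  flows through explicit integer seeds; fixed seeds give bit-identical
  outputs.

## Problem sizes

The test suite and the acceptance script run the regression on the
52-condition packaged table (CV over 5–10 shuffle seeds, 20-seed
Monte-Carlo recovery), one finite-difference solve at h = 0.05 mm on a
14 mm box plus two coarser convergence solves, and 20-plus rendered
600×600 synthetic images. These sizes were chosen as the smallest at which
each claim is stable under seed changes.

## Known limitations

- The power law is empirical, fitted on one cell type in monolayer format;
  it is not a first-principles electroporation model and must not be
  extrapolated outside the studied range (the calculator enforces this).
- Replicate-level data are unpublished, so all fitting uses condition
  means; replicate-level diagnostics (e.g., the study's maximum absolute
  error) are not reproducible from the packaged table.
- The dose model ignores heat diffusion and electrode electrochemistry;
  reported heating is a worst case.
- The 2-D field model ignores the finite insertion depth and the bath
  above the monolayer; absolute area↔threshold pairs from the 3-D
  experimental analysis are therefore not reproduced, and the field model
  is validated only against its own oracles.
- The imaging pipeline is validated on synthetic scenes only; see above.
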