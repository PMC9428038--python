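# Methods

## The problem and the pipeline

Mid-infrared microspectroscopic imaging of thin tissue sections yields one
absorbance spectrum per pixel; the 1800–648 cm⁻¹ fingerprint window carries
the lipid ester (~1740 cm⁻¹), amide I/II (~1655/1545 cm⁻¹) and nucleic-acid
phosphate (~1240/1080 cm⁻¹) bands whose relative intensities differ between
tumour subtypes. `mirclass` reproduces the full analysis chain on such data:
spectral pretreatment, five supervised pixel classifiers, and two evaluation
regimes (per-pixel confusion statistics and per-patient cut-off voting).
Because measured cohorts of this kind are rarely public, the package also
contains a first-class phantom generator that produces per-patient
hyperspectral cubes with the statistical structure the analysis assumes.

## Phantom model

A patient cube is built as

```
A(i, j, ν) = Σ_b f_b · g_b(ν)            class signature, jittered per patient
           + Σ_p c_{ijp} σ_base · u^p    per-pixel polynomial baseline
           + λ Σ_s a_{ijs} R_s(ν)        atmospheric contamination
           + σ_noise ε_{ijν}             detector noise
```

where `g_b` are Gaussian or Lorentzian bands (both parameterized by center,
FWHM and peak amplitude), `f_b = exp(σ_pat z_b)` is a multiplicative
lognormal amplitude factor drawn **once per patient and band** (absorbance
stays non-negative; within-patient pixels remain exchangeable, which the
patient-vote analysis assumes), `u ∈ [−1, 1]` is the normalized spectral
coordinate, `R_s` are synthesized CO₂/H₂O reference shapes, `a_{ijs} =
|1 + 0.3 N(0,1)|` a per-pixel contamination strength, and `ε` i.i.d.
standard normal.

Parameters, units and defaults:

| parameter | meaning | default |
|---|---|---|
| grid | spectral axis, cm⁻¹ | 4000 → 648, step 8 (420 channels) |
| image_height_px × image_width_px | field geometry | 40 × 96 (3,840 spectra) |
| pixel_size_um | pixel edge, µm | 6.25 (0.15 mm² field) |
| patients_per_class | cohort size per subtype | 10 (30 patients) |
| patient_amplitude_sd | lognormal σ of per-patient band jitter | 0.05 |
| pixel_noise_sd | additive noise σ, absorbance units | 0.02 |
| baseline | polynomial order / coefficient σ | 2 / 0.01 |
| atmospheric_level | contamination scale (0 disables) | 0 |

The default subtype signatures (an editable YAML shipped with the package)
place the same five tissue bands in all three classes and differ only in
amplitude ratios — subtype contrast is compositional, not positional. The
smallest across class pairs of the largest per-band amplitude gap
("band-amplitude contrast") is 0.20 absorbance units, i.e. 10× the default
pixel noise σ. Absorbance is in arbitrary units throughout: published
spectra of this kind show no calibrated scale, so only ratios matter.

Seeding: every patient's stream is `default_rng((cohort_seed,
patient_seed))` with `patient_seed = SHA-256(seed | subtype | index) mod
2³¹`. Adding patients or classes therefore never perturbs existing
patients, and regeneration is bit-identical.

**What the phantom does not emulate:** resonant-Mie/EMSC scattering
distortions, paraffin residues, spatial (tissue-morphology) correlation
between neighbouring pixels, detector drift across the scan, or mixed-
differentiation tumours. Passing tests on phantoms therefore demonstrate
the correctness and statistical behaviour of the pipeline, not clinical
performance on measured FFPE spectra.

## Preprocessing

Order: atmospheric correction → PCA noise reduction → fingerprint slice
(matching the acquisition software convention the pipeline emulates).

*Atmospheric suppression.* Per spectrum `s`, `(offset, β)` minimize
‖s − (offset·1 + Rᵀβ)‖²; the corrected spectrum is `s − Rᵀβ̂` — contaminant
shapes are removed, the fitted constant offset is retained. The reference
set must be full-rank; collinear species are named in the error. This is an
ordinary least-squares replacement for proprietary vendor algorithms, which
is exactly what it claims to be: where tissue bands overlap the H₂O comb,
some tissue signal leaks into β̂ (visible in `examples/02_preprocess.py`).

*Noise reduction.* Spectra are mean-centered over rows and reconstructed
from the top k = 20 singular vectors; the mean is added back. No variance
scaling (spectroscopy convention). Sign indeterminacy is fixed by forcing
each loading's largest-magnitude element positive, so the decomposition is
deterministic. If k ≥ rank, the output equals the input. Unlike smoothing,
the truncated reconstruction does not broaden peaks: a test verifies the
interpolated FWHM of a noise-free band changes by less than one channel.
Denoising is fitted on the whole table (all patients jointly) by default;
whether per-image fitting is preferable is an open question on real data.

*Fingerprint slice.* Channels with 648 ≤ ν ≤ 1800 cm⁻¹, bounds inclusive on
both ends — required to obtain exactly 145 channels on the 8 cm⁻¹ grid.

## Classifiers

Shared conventions: labels sorted lexicographically internally; exact score
ties resolve to the lexicographically smaller label; priors uniform (the
design is balanced 10-10-10); covariance estimators unbiased (n−1, pooled
df); every covariance is augmented by `ridge_eps · mean(diag) · I`
(default `ridge_eps = 1e-6`) before inversion; no feature scaling.

- **linear**: pooled within-class covariance Bayes rule.
- **quadratic**: per-class covariances with the −½ln|Σₖ| term.
- **mahalanobis**: per-class Mahalanobis distance to the centroid, *without*
  determinant or prior terms. This is the classical distance classifier; the
  missing determinant penalty makes it favour the class with the widest
  covariance, which is the known failure mode in which it collapses onto a
  single subtype on heterogeneous real data.
- **C-SVC / ν-SVC**: linear-kernel soft-margin machines fitted per
  one-vs-one pair (dual solved to KKT tolerance 1e-6 via libsvm through
  scikit-learn); the fitted state (per-machine weights, bias, support
  indices, dual coefficients) is held explicitly, and prediction is
  majority vote with ties broken by the larger sum of signed decision
  values, then lexicographically. Defaults C = 1, ν = 0.5 — the software
  this emulates publishes no hyperparameters, so these are the common
  defaults, stated as assumptions. ν is checked against the per-pair
  feasibility bound 2·min(n_a, n_b)/(n_a + n_b) before fitting.

The train/test split takes, within each patient in flatten (row-major)
order, even 0-based positions as training and odd as test — "every second
spectrum", scoped per patient so both halves stay balanced for the vote.

## Evaluation

Pixel-based: K×K confusion matrix in fixed (SQ, LUAD, SCLC) order;
one-vs-rest sensitivity, specificity, PPV, NPV per class; 0/0 ratios are
reported as NaN, never silently 0 or 1.

Patient-based: per patient, the fraction of evaluated spectra predicted as
the true subtype; a patient passes cut-off c iff fraction ≥ c (a patient at
exactly 50% passes). Fractions are computed over **test** spectra only by
default — scoring training spectra would leak fit quality into the headline
accuracy; a `vote_pool="all"` switch restores the all-spectra convention.
Per-subtype accuracies are reported as numerator/denominator pairs (k/10).

## Numerical and design choices

- Cholesky-based solves for all discriminant quadratic forms; a singular
  covariance with `ridge_eps = 0` is an explicit error, not a warning.
- The long-format cube CSV round-trips float64 bit-exactly (shortest
  round-trip decimal text; reading uses the round-trip float parser). The
  ENVI writer stores float32, so its round-trip contract is ≤ 1e-6 relative.
- A single-channel spectral axis (start == end) is tolerated as a degenerate
  grid so scalar-feature toy problems can use the same table type.
- All randomness flows from the one config seed; no stage reads global
  random state, and identical configs produce byte-identical output files.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script experiments run on reduced geometries
chosen as the package's default desk-scale configuration: 10 × 24-pixel
cubes (240 spectra/patient, 30 patients) for full-pipeline runs and
4 × 6-pixel cubes for multi-seed recovery and degradation studies. The
statistical behaviour (full recovery at ≥ 5× contrast-to-noise; collapse to
1/3 sensitivity at ≤ 1/50) is insensitive to the field size, which enters
only through the per-patient vote denominator.

## Known limitations

- Phantom realism as listed above; in particular, pixel exchangeability
  within a patient makes patient votes better behaved than on real tissue,
  where morphological heterogeneity produces spatially clustered errors.
- The atmospheric step is plain OLS on synthetic references, not a
  line-by-line radiative model; it under-corrects when contamination
  overlaps strong tissue bands.
- Whether real acquisitions should be denoised per image or per dataset,
  and whether spectra should be normalized before classification, cannot be
  settled on phantoms; both are exposed as options with the joint/no-
  normalization defaults documented here.
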