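# mirclass

Label-free mid-infrared (FTIR) hyperspectral imaging is a candidate tool for
differential diagnosis of lung-cancer subtypes: a transflection microscope
scans a tissue section and records one absorbance spectrum per 6.25 µm pixel,
and supervised classifiers assign each pixel's fingerprint-region spectrum
(1800–648 cm⁻¹, 145 wavenumbers at 8 cm⁻¹ spacing) to squamous cell carcinoma
(SQ), adenocarcinoma (LUAD) or small-cell carcinoma (SCLC). `mirclass`
implements that whole analysis as a tested, reusable Python pipeline for
spectroscopists and computational pathologists:

- **phantom** — synthetic per-patient hyperspectral cubes (default 40 × 96
  pixels on a 4000–648 cm⁻¹ axis; 3 subtypes × 10 patients) with
  class-specific band signatures, per-patient amplitude jitter, baseline
  drift, optional atmospheric CO₂/H₂O contamination and detector noise, for
  method development when measured cohorts are unavailable;
- **preprocess** — atmospheric suppression by least-squares fitting of
  reference spectra, noise reduction by 20-factor principal-component
  reconstruction, fingerprint-region selection;
- **classify** — the five classical models compared in this setting: Bayes
  discriminants with pooled covariance (linear), per-class covariance
  (quadratic), per-class Mahalanobis distance, and linear soft-margin SVMs in
  the C-SVC and ν-SVC formulations with one-vs-one voting, trained on every
  second spectrum of each image;
- **evaluate** — pixel-based confusion statistics (sensitivity, specificity,
  PPV, NPV per subtype) and patient-based cut-off voting: a patient is
  called correct at cut-off *c* iff the fraction of their spectra predicted
  as the true subtype is ≥ *c*, swept over *c* ∈ {50, 60, 70, 80, 90, 95}%.

## Core model

Each pixel spectrum **x** ∈ ℝ¹⁴⁵ is assigned by one of

- linear discriminant: argmax₍ₖ₎ **x**ᵀΣ⁻¹μₖ − ½μₖᵀΣ⁻¹μₖ + ln πₖ (pooled Σ),
- quadratic discriminant: argmax₍ₖ₎ −½ln|Σₖ| − ½(**x**−μₖ)ᵀΣₖ⁻¹(**x**−μₖ) + ln πₖ,
- Mahalanobis rule: argmin₍ₖ₎ (**x**−μₖ)ᵀΣₖ⁻¹(**x**−μₖ),
- C-SVC / ν-SVC: one-vs-one linear maximum-margin machines, majority vote;

and patient *p* with test spectra 𝒯ₚ is scored by the vote fraction
fₚ = |{x ∈ 𝒯ₚ : ŷ(x) = yₚ}| / |𝒯ₚ|, thresholded at the cut-off.

## Worked example

```
python examples/03_classify_and_evaluate.py
```

generates a reduced phantom cohort (30 patients, 10 × 24 pixel cubes on the
fingerprint axis, pixel noise 0.08 a.u.), runs all five models and prints:

```
patient-based accuracy at the 50% cut-off (n_correct / n_total):
  lda-linear       SQ 10/10, LUAD 10/10, SCLC 10/10
  lda-quadratic    SQ 10/10, LUAD 10/10, SCLC 10/10
  lda-mahalanobis  SQ 10/10, LUAD 10/10, SCLC 10/10
  svm-c            SQ 10/10, LUAD 10/10, SCLC 10/10
  svm-nu           SQ 10/10, LUAD 10/10, SCLC 10/10

pixel-based metrics, linear C-SVC:
      sensitivity  specificity  ppv  npv
SQ            1.0          1.0  1.0  1.0
LUAD          1.0          1.0  1.0  1.0
SCLC          1.0          1.0  1.0  1.0
```

Every patient's vote fraction clears the 50% cut-off and every test pixel is
classified correctly: at this noise level the three synthetic signatures are
fully separable. Raising `pixel_noise_sd` degrades the table toward chance
(1/3 sensitivity); see `docs/methods.md` for what the phantom does and does
not emulate.

There is also a thin CLI covering each stage plus the whole pipeline:

```
mirclass run-all --seed 1 --out out/
mirclass generate --config cfg.yaml --out cubes/
```

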