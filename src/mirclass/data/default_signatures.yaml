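# Default subtype fingerprints: shared tissue bands, class-specific amplitude
# ratios (arbitrary absorbance units). Band positions are the usual mid-IR
# tissue assignments: ~1740 lipid ester C=O, ~1655 amide I, ~1545 amide II,
# ~1240 asymmetric and ~1080 symmetric phosphate / nucleic-acid stretches.
# Classes differ in relative intensities, not positions. Edit freely.
SQ:
  - {center_cm1: 1740, fwhm_cm1: 30, amplitude: 0.30, shape: gaussian}
  - {center_cm1: 1655, fwhm_cm1: 50, amplitude: 1.00, shape: gaussian}
  - {center_cm1: 1545, fwhm_cm1: 45, amplitude: 0.55, shape: gaussian}
  - {center_cm1: 1240, fwhm_cm1: 60, amplitude: 0.25, shape: gaussian}
  - {center_cm1: 1080, fwhm_cm1: 60, amplitude: 0.30, shape: gaussian}
LUAD:
  - {center_cm1: 1740, fwhm_cm1: 30, amplitude: 0.50, shape: gaussian}
  - {center_cm1: 1655, fwhm_cm1: 50, amplitude: 0.85, shape: gaussian}
  - {center_cm1: 1545, fwhm_cm1: 45, amplitude: 0.45, shape: gaussian}
  - {center_cm1: 1240, fwhm_cm1: 60, amplitude: 0.35, shape: gaussian}
  - {center_cm1: 1080, fwhm_cm1: 60, amplitude: 0.45, shape: gaussian}
SCLC:
  - {center_cm1: 1740, fwhm_cm1: 30, amplitude: 0.20, shape: gaussian}
  - {center_cm1: 1655, fwhm_cm1: 50, amplitude: 0.90, shape: gaussian}
  - {center_cm1: 1545, fwhm_cm1: 45, amplitude: 0.50, shape: gaussian}
  - {center_cm1: 1240, fwhm_cm1: 60, amplitude: 0.45, shape: gaussian}
  - {center_cm1: 1080, fwhm_cm1: 60, amplitude: 0.60, shape: gaussian}
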