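# Synthetic atmospheric reference band lists (unit peak scale).
# CO2: antisymmetric stretch doublet near 2360/2340 cm^-1.
# H2O: a coarse rotational-vibrational comb across the 1900-1300 cm^-1
# bending region. Narrow Lorentzians approximate unresolved line groups.
co2:
  - {center_cm1: 2360, fwhm_cm1: 12, amplitude: 1.00, shape: lorentzian}
  - {center_cm1: 2340, fwhm_cm1: 12, amplitude: 0.80, shape: lorentzian}
  - {center_cm1: 668,  fwhm_cm1: 10, amplitude: 0.25, shape: lorentzian}
h2o:
  - {center_cm1: 1870, fwhm_cm1: 10, amplitude: 0.35, shape: lorentzian}
  - {center_cm1: 1820, fwhm_cm1: 10, amplitude: 0.45, shape: lorentzian}
  - {center_cm1: 1772, fwhm_cm1: 10, amplitude: 0.55, shape: lorentzian}
  - {center_cm1: 1717, fwhm_cm1: 10, amplitude: 0.70, shape: lorentzian}
  - {center_cm1: 1670, fwhm_cm1: 10, amplitude: 0.85, shape: lorentzian}
  - {center_cm1: 1617, fwhm_cm1: 10, amplitude: 1.00, shape: lorentzian}
  - {center_cm1: 1560, fwhm_cm1: 10, amplitude: 0.90, shape: lorentzian}
  - {center_cm1: 1508, fwhm_cm1: 10, amplitude: 0.75, shape: lorentzian}
  - {center_cm1: 1457, fwhm_cm1: 10, amplitude: 0.60, shape: lorentzian}
  - {center_cm1: 1403, fwhm_cm1: 10, amplitude: 0.45, shape: lorentzian}
  - {center_cm1: 1340, fwhm_cm1: 10, amplitude: 0.30, shape: lorentzian}
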