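"""Generate a phantom FTIR cohort and look at one patient's cube.

Builds 30 synthetic patients (10 per subtype) with the default class
signatures, prints the cube geometry and writes one cube to CSV.
"""

from pathlib import Path

from mirclass import PhantomConfig, generate_cohort, io, make_grid

# Reduced 10 x 24 pixel field; the full measurement geometry would be
# image_height_px=40, image_width_px=96 (3,840 spectra per patient).
config = PhantomConfig(
    grid=make_grid(4000, 648, 8),
    image_width_px=24,
    image_height_px=10,
    patients_per_class=10,
    seed=1,
)
cohort = generate_cohort(config)

cube = cohort.cubes[0]
print(f"cohort: {len(cohort)} patients "
      f"({config.patients_per_class} per subtype {config.subtypes})")
print(f"cube {cube.patient_id}: {cube.height_px} x {cube.width_px} px "
      f"x {cube.grid.n_channels} channels, {cube.n_spectra} spectra, "
      f"{cube.area_mm2 * (40 * 96) / cube.n_spectra:.2f} mm^2 at full geometry")
print(f"axis: {cube.grid.start_cm1} -> {cube.grid.end_cm1} cm^-1, "
      f"step {cube.grid.step_cm1} cm^-1")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
io.write_cube(cube, out / f"{cube.patient_id}.csv")
print(f"wrote {out / (cube.patient_id + '.csv')}")
# Typical output: 30 patients, each cube 10 x 24 x 420; absorbance values
# are arbitrary units dominated by the amide I band near 1655 cm^-1.
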