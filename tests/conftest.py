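import numpy as np
import pandas as pd
import pytest

from mirclass import BaselineConfig, PhantomConfig, SpectrumTable, make_grid


def table_from_arrays(spectra, grid, patient_ids=None, subtypes=None, roles=None):
    """Build a SpectrumTable from a raw matrix with minimal metadata."""
    spectra = np.asarray(spectra, dtype=float)
    n = spectra.shape[0]
    if patient_ids is None:
        patient_ids = ["P0"] * n
    if subtypes is None:
        subtypes = ["SQ"] * n
    if roles is None:
        roles = ["unassigned"] * n
    meta = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "subtype": subtypes,
            "row": 0,
            "col": np.arange(n),
            "role": roles,
        }
    )
    # keep (patient_id, row, col) unique across patients
    meta["col"] = meta.groupby("patient_id").cumcount()
    return SpectrumTable(spectra=spectra, grid=grid, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid145():
    """The fingerprint axis: 1800 down to 648 cm^-1, 8 cm^-1 step."""
    return make_grid(1800, 648, 8)


@pytest.fixture
def grid10():
    """A tiny 10-channel axis for hand-sized problems."""
    return make_grid(1800, 1728, 8)


@pytest.fixture
def tiny_config():
    """A miniature but fully structured cohort: 3 classes x 2 patients,
    4 x 6 pixel cubes on the fingerprint axis."""
    return PhantomConfig(
        grid=make_grid(1800, 648, 8),
        image_width_px=6,
        image_height_px=4,
        patients_per_class=2,
        seed=7,
    )


@pytest.fixture
def noisefree_config():
    """Same geometry, every stochastic ingredient switched off."""
    return PhantomConfig(
        grid=make_grid(1800, 648, 8),
        image_width_px=6,
        image_height_px=4,
        patients_per_class=2,
        patient_amplitude_sd=0.0,
        pixel_noise_sd=0.0,
        baseline=BaselineConfig(order=2, coeff_sd=0.0),
        atmospheric_level=0.0,
        seed=7,
    )
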