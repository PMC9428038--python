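"""Spectral pretreatment: flattening, atmospheric correction, PCA noise
reduction and fingerprint-region selection.

The pipeline order mirrors the measurement software it emulates:
atmospheric CO2/H2O suppression by least squares first, then a 20-factor
principal-component reconstruction (noise carries little variance, so the
truncated reconstruction is noise-reduced without broadening peaks the way
smoothing would), then restriction to the 1800-648 cm^-1 fingerprint
window (145 channels on the default 8 cm^-1 grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import PatientCohort, WavenumberGrid, atmospheric_spectra

ROLES = ("train", "test", "unassigned")

META_COLUMNS = ["patient_id", "subtype", "row", "col", "role"]


@dataclass
class SpectrumTable:
    """Flattened spectra matrix with per-row provenance metadata.

    ``spectra`` is (n_spectra, n_channels); ``meta`` carries patient_id,
    subtype, pixel row/col and the train/test role, one row per spectrum,
    with (patient_id, row, col) unique.
    """

    spectra: np.ndarray
    grid: WavenumberGrid
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        if self.spectra.shape[1] != self.grid.n_channels:
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} channels, grid has "
                f"{self.grid.n_channels}"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if len(self.meta) != self.spectra.shape[0]:
            raise ValueError("metadata length != number of spectra")
        bad_roles = set(self.meta["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}")
        if self.meta.duplicated(subset=["patient_id", "row", "col"]).any():
            raise ValueError("(patient_id, row, col) must be unique")

    @property
    def n_spectra(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[1]

    def copy(self) -> "SpectrumTable":
        return SpectrumTable(self.spectra.copy(), self.grid, self.meta.copy())

    def subset(self, mask) -> "SpectrumTable":
        mask = np.asarray(mask)
        return SpectrumTable(
            self.spectra[mask], self.grid, self.meta.loc[mask].reset_index(drop=True)
        )


def flatten_cohort(cohort: PatientCohort) -> SpectrumTable:
    """Stack all cubes into one table: pixels in row-major order per patient,
    patients in cohort order, role ``unassigned``."""
    if not cohort.cubes:
        raise ValueError("cohort is empty")
    grid = cohort.cubes[0].grid
    for c in cohort.cubes:
        if c.grid != grid:
            raise ValueError(
                f"cube {c.patient_id} is on a different grid "
                f"({c.grid.start_cm1}-{c.grid.end_cm1}/{c.grid.step_cm1}); "
                "all cubes must share one grid"
            )
    blocks, frames = [], []
    for c in cohort.cubes:
        h, w = c.height_px, c.width_px
        blocks.append(c.absorbance.reshape(h * w, -1))
        rr, cc = np.divmod(np.arange(h * w), w)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": c.patient_id,
                    "subtype": c.subtype,
                    "row": rr,
                    "col": cc,
                    "role": "unassigned",
                }
            )
        )
    return SpectrumTable(
        np.vstack(blocks), grid, pd.concat(frames, ignore_index=True)
    )


# ---------------------------------------------------------------------------
# Atmospheric correction
# ---------------------------------------------------------------------------

@dataclass
class AtmosphericReferenceSet:
    """Unit-scale contaminant spectra (one row per species) on a grid."""

    references: np.ndarray  # (m, n_channels)
    species: list[str]
    grid: WavenumberGrid

    def __post_init__(self) -> None:
        self.references = np.atleast_2d(np.asarray(self.references, dtype=float))
        if self.references.shape[0] != len(self.species):
            raise ValueError("one species name per reference row required")
        if self.references.shape[1] != self.grid.n_channels:
            raise ValueError("reference length != grid channels")
        norms = np.linalg.norm(self.references, axis=1)
        if np.any(norms == 0):
            dead = [s for s, n in zip(self.species, norms) if n == 0]
            raise ValueError(f"all-zero reference rows for species {dead}")

    @classmethod
    def synthetic(cls, grid: WavenumberGrid) -> "AtmosphericReferenceSet":
        refs, names = atmospheric_spectra(grid)
        return cls(references=refs, species=names, grid=grid)


def _collinear_species(design: np.ndarray, species: list[str]) -> list[str]:
    # A species is collinear if it lies (numerically) in the span of the
    # offset column plus the other references.
    n = design.shape[0]
    culprits = []
    for j, name in enumerate(species):
        others = np.delete(design, j + 1, axis=1)  # column 0 is the offset
        target = design[:, j + 1]
        beta, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ beta
        if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(target), 1.0):
            culprits.append(name)
    return culprits or list(species)


def atmospheric_correct(
    table: SpectrumTable, references: AtmosphericReferenceSet
) -> tuple[SpectrumTable, pd.DataFrame]:
    """Least-squares suppression of atmospheric contributions.

    Per spectrum s, (offset, beta) minimize ||s - (offset*1 + R^T beta)||^2;
    the corrected spectrum is s - R^T beta_hat — the fitted constant offset
    is retained, only contaminant shapes are removed. Returns the corrected
    table and the per-spectrum coefficients (offset + one column/species).
    """
    if references.grid != table.grid:
        raise ValueError("references are not on the table's grid")
    R = references.references
    design = np.column_stack([np.ones(table.n_channels), R.T])  # (c, 1+m)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_species(design, references.species)
        raise ValueError(
            f"rank-deficient atmospheric reference set; collinear species: {bad}"
        )
    coef, *_ = np.linalg.lstsq(design, table.spectra.T, rcond=None)  # (1+m, n)
    corrected = table.spectra - coef[1:].T @ R
    coef_df = pd.DataFrame(
        coef.T, columns=["offset"] + list(references.species)
    )
    return SpectrumTable(corrected, table.grid, table.meta.copy()), coef_df


# ---------------------------------------------------------------------------
# PCA noise reduction
# ---------------------------------------------------------------------------

@dataclass
class DenoiseReport:
    """What the truncated reconstruction kept."""

    n_factors: int
    variance_captured: np.ndarray  # fraction of total variance per kept factor
    grand_mean: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.variance_captured, dtype=float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("variance fractions must lie in [0, 1]")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if v.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum to more than 1")
        self.variance_captured = v


def pca_denoise(
    table: SpectrumTable, n_factors: int = 20, per_patient: bool = False
) -> tuple[SpectrumTable, DenoiseReport]:
    """Reconstruct every spectrum from the top ``n_factors`` principal
    components of the row-mean-centered table.

    No variance scaling (spectroscopy convention). Component signs are fixed
    by forcing each loading vector's largest-magnitude element positive, so
    the decomposition — not just the reconstruction — is deterministic.
    If ``n_factors`` >= the rank of the centered matrix the output equals
    the input.

    ``per_patient=True`` fits a separate decomposition per patient's block
    of rows instead of one joint model (off by default: images are treated
    jointly); the returned report then describes the whole reassembled
    table re-decomposed jointly, for comparability.
    """
    if n_factors < 1:
        raise ValueError(f"n_factors must be >= 1, got {n_factors}")
    if table.n_spectra < 2:
        raise ValueError("need at least 2 spectra to denoise")
    if per_patient:
        out = table.copy()
        for _, idx in table.meta.groupby("patient_id", sort=False).indices.items():
            block = SpectrumTable(
                table.spectra[idx], table.grid,
                table.meta.iloc[idx].reset_index(drop=True),
            )
            denoised, _ = pca_denoise(block, n_factors=n_factors)
            out.spectra[idx] = denoised.spectra
        _, joint_report = pca_denoise(out, n_factors=n_factors)
        return out, joint_report
    X = table.spectra
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    k = min(n_factors, len(s))
    recon = (U[:, :k] * s[:k]) @ Vt[:k] + mean
    total = float(np.sum(s**2))
    frac = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    report = DenoiseReport(n_factors=k, variance_captured=frac, grand_mean=mean)
    return SpectrumTable(recon, table.grid, table.meta.copy()), report


# ---------------------------------------------------------------------------
# Fingerprint selection
# ---------------------------------------------------------------------------

def slice_fingerprint(
    table: SpectrumTable, high_cm1: float = 1800.0, low_cm1: float = 648.0
) -> SpectrumTable:
    """Restrict the table to channels with low <= wavenumber <= high
    (bounds inclusive; 1800-648 keeps 145 channels on the default grid)."""
    if low_cm1 > high_cm1:
        raise ValueError("low bound exceeds high bound")
    v = table.grid.values
    mask = (v >= low_cm1 - 1e-9) & (v <= high_cm1 + 1e-9)
    if not mask.any():
        raise ValueError(
            f"no channel inside [{low_cm1}, {high_cm1}] cm^-1 on this grid"
        )
    kept = v[mask]
    new_grid = WavenumberGrid(
        start_cm1=float(kept[0]), end_cm1=float(kept[-1]), step_cm1=table.grid.step_cm1
    )
    return SpectrumTable(table.spectra[:, mask], new_grid, table.meta.copy())
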