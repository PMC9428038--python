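"""Synthetic hyperspectral phantom cohorts.

Generates per-patient mid-infrared absorbance cubes with the statistical
structure a transflection FTIR measurement of FFPE tissue sections would
produce: a class-specific fingerprint built from Gaussian/Lorentzian bands,
multiplicative patient-to-patient amplitude variation, per-pixel polynomial
baseline drift, optional atmospheric CO2/H2O contamination and additive
detector noise.

Geometry defaults follow a 250 um x 600 um field imaged at 6.25 um pixels
(40 x 96 = 3,840 spectra per patient) on a 4000-648 cm^-1 axis sampled
every 8 cm^-1.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

SUBTYPES = ("SQ", "LUAD", "SCLC")
"""Canonical reporting order of the three histological subtypes."""

_BAND_SHAPES = ("gaussian", "lorentzian")


# ---------------------------------------------------------------------------
# Spectral axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberGrid:
    """Descending, uniformly spaced wavenumber axis (cm^-1).

    Channel ``k`` holds ``start_cm1 - k * step_cm1``; the last channel is
    ``end_cm1`` exactly, so the step must divide the span.
    """

    start_cm1: float
    end_cm1: float
    step_cm1: float

    def __post_init__(self) -> None:
        # start == end is tolerated as a degenerate single-channel axis
        # (needed for scalar-feature toys); start < end is always an error.
        if self.start_cm1 < self.end_cm1:
            raise ValueError(
                f"grid start ({self.start_cm1}) must not be below end ({self.end_cm1})"
            )
        if not self.step_cm1 > 0:
            raise ValueError(f"grid step must be positive, got {self.step_cm1}")
        span = self.start_cm1 - self.end_cm1
        ratio = span / self.step_cm1
        if abs(ratio - round(ratio)) > 1e-9:
            remainder = span - np.floor(ratio) * self.step_cm1
            raise ValueError(
                f"step {self.step_cm1} does not divide span {span} exactly "
                f"(remainder {remainder:g})"
            )

    @property
    def n_channels(self) -> int:
        return int(round((self.start_cm1 - self.end_cm1) / self.step_cm1)) + 1

    @property
    def values(self) -> np.ndarray:
        """Channel wavenumbers, descending."""
        return self.start_cm1 - self.step_cm1 * np.arange(self.n_channels)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_channels


def make_grid(start_cm1: float, end_cm1: float, step_cm1: float) -> WavenumberGrid:
    """Build a descending wavenumber axis from ``start_cm1`` down to ``end_cm1``."""
    return WavenumberGrid(start_cm1, end_cm1, step_cm1)


# ---------------------------------------------------------------------------
# Bands and class signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """A single absorbance band.

    ``gaussian``:   a * exp(-4 ln2 ((v - c) / fwhm)^2)
    ``lorentzian``: a * (fwhm/2)^2 / ((v - c)^2 + (fwhm/2)^2)

    Both profiles peak at ``amplitude`` and reach half height at
    ``center_cm1 +/- fwhm_cm1 / 2``.
    """

    center_cm1: float
    fwhm_cm1: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm_cm1 <= 0:
            raise ValueError(f"band fwhm must be positive, got {self.fwhm_cm1}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in _BAND_SHAPES:
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = np.asarray(wavenumbers, dtype=float) - self.center_cm1
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4.0 * np.log(2.0) * (d / self.fwhm_cm1) ** 2)
        half = self.fwhm_cm1 / 2.0
        return self.amplitude * half**2 / (d**2 + half**2)


@dataclass(frozen=True)
class ClassSignature:
    """The noise-free fingerprint of one subtype: a sum of bands."""

    subtype: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"signature for {self.subtype} has no bands")
        object.__setattr__(self, "bands", tuple(self.bands))

    def validate_on(self, grid: WavenumberGrid) -> None:
        for b in self.bands:
            if not (grid.end_cm1 <= b.center_cm1 <= grid.start_cm1):
                raise ValueError(
                    f"band center {b.center_cm1} cm^-1 outside grid span "
                    f"[{grid.end_cm1}, {grid.start_cm1}]"
                )


def evaluate_signature(signature: ClassSignature, grid: WavenumberGrid) -> np.ndarray:
    """Noise-free absorbance spectrum of ``signature`` on ``grid``."""
    signature.validate_on(grid)
    v = grid.values
    out = np.zeros(grid.n_channels)
    for band in signature.bands:
        out += band.profile(v)
    return out


def _signatures_from_mapping(raw: dict) -> tuple[ClassSignature, ...]:
    sigs = []
    for subtype, bands in raw.items():
        sigs.append(
            ClassSignature(
                subtype=subtype,
                bands=tuple(
                    Band(
                        center_cm1=b["center_cm1"],
                        fwhm_cm1=b["fwhm_cm1"],
                        amplitude=b["amplitude"],
                        shape=b.get("shape", "gaussian"),
                    )
                    for b in bands
                ),
            )
        )
    return tuple(sigs)


def load_default_signatures() -> tuple[ClassSignature, ...]:
    """Default SQ/LUAD/SCLC signatures shipped with the package.

    The three classes share the usual tissue bands (lipid ester ~1740,
    amide I ~1655, amide II ~1545, phosphate ~1240/1080 cm^-1) and differ
    only in relative band intensities, mimicking subtype fingerprints that
    are compositional rather than positional.
    """
    text = resources.files("mirclass.data").joinpath("default_signatures.yaml").read_text()
    return _signatures_from_mapping(yaml.safe_load(text))


def load_signatures_yaml(path) -> tuple[ClassSignature, ...]:
    """Read class signatures from a user YAML file (same schema as the default)."""
    with open(path) as fh:
        return _signatures_from_mapping(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineConfig:
    """Per-pixel polynomial baseline drift: random coefficients of a
    degree-``order`` polynomial in the normalized axis coordinate."""

    order: int = 2
    coeff_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("baseline order must be >= 0")
        if self.coeff_sd < 0:
            raise ValueError("baseline coeff_sd must be >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    """Everything needed to generate a cohort deterministically."""

    grid: WavenumberGrid = field(default_factory=lambda: make_grid(4000, 648, 8))
    image_width_px: int = 96
    image_height_px: int = 40
    pixel_size_um: float = 6.25
    patients_per_class: int = 10
    signatures: tuple[ClassSignature, ...] = field(default_factory=load_default_signatures)
    patient_amplitude_sd: float = 0.05
    pixel_noise_sd: float = 0.02
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    atmospheric_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patients_per_class < 1:
            raise ValueError("patients_per_class must be >= 1")
        if self.patient_amplitude_sd < 0 or self.pixel_noise_sd < 0:
            raise ValueError("sd parameters must be >= 0")
        if self.atmospheric_level < 0:
            raise ValueError("atmospheric_level must be >= 0")
        subs = [s.subtype for s in self.signatures]
        if len(self.signatures) != 3 or len(set(subs)) != 3:
            raise ValueError("exactly three signatures with distinct subtypes required")
        for s in self.signatures:
            s.validate_on(self.grid)

    def signature_for(self, subtype: str) -> ClassSignature:
        for s in self.signatures:
            if s.subtype == subtype:
                return s
        raise ValueError(f"no signature for subtype {subtype!r}")

    @property
    def subtypes(self) -> tuple[str, ...]:
        return tuple(s.subtype for s in self.signatures)

    def with_updates(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Cubes and cohorts
# ---------------------------------------------------------------------------

@dataclass
class SpectralCube:
    """One patient's hyperspectral image: rows x cols x channels absorbance."""

    patient_id: str
    subtype: str
    grid: WavenumberGrid
    absorbance: np.ndarray  # (height_px, width_px, n_channels)
    pixel_size_um: float

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 3:
            raise ValueError("absorbance must be height x width x channels")
        if a.shape[2] != self.grid.n_channels:
            raise ValueError(
                f"cube has {a.shape[2]} channels but grid has {self.grid.n_channels}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("cube contains non-finite absorbance values")
        self.absorbance = a

    @property
    def height_px(self) -> int:
        return self.absorbance.shape[0]

    @property
    def width_px(self) -> int:
        return self.absorbance.shape[1]

    @property
    def n_spectra(self) -> int:
        return self.height_px * self.width_px

    @property
    def area_mm2(self) -> float:
        """Imaged field area in mm^2 (0.15 for the default 40x96 @ 6.25 um)."""
        return self.n_spectra * (self.pixel_size_um * 1e-3) ** 2


@dataclass
class PatientCohort:
    """All patients' cubes plus the configuration that produced them."""

    cubes: list[SpectralCube]
    config: PhantomConfig

    def __post_init__(self) -> None:
        ids = [c.patient_id for c in self.cubes]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.cubes)


# ---------------------------------------------------------------------------
# Atmospheric contamination
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def load_atmospheric_bands() -> dict[str, list[Band]]:
    """Band lists for the CO2 doublet and the H2O rotational-vibrational comb."""
    text = resources.files("mirclass.data").joinpath("atmospheric_bands.yaml").read_text()
    raw = yaml.safe_load(text)
    out: dict[str, list[Band]] = {}
    for species, bands in raw.items():
        out[species] = [
            Band(
                center_cm1=b["center_cm1"],
                fwhm_cm1=b["fwhm_cm1"],
                amplitude=b["amplitude"],
                shape=b.get("shape", "lorentzian"),
            )
            for b in bands
        ]
    return out


def atmospheric_spectra(grid: WavenumberGrid) -> tuple[np.ndarray, list[str]]:
    """Synthesized unit-scale atmospheric reference spectra on ``grid``.

    Returns (m x n_channels matrix, species names). Bands falling outside the
    grid span contribute their tails only; a species entirely without signal
    on the grid is dropped.
    """
    v = grid.values
    rows, names = [], []
    for species, bands in load_atmospheric_bands().items():
        spec = np.zeros(grid.n_channels)
        for b in bands:
            spec += b.profile(v)
        if np.max(np.abs(spec)) > 1e-12:
            rows.append(spec)
            names.append(species)
    if not rows:
        raise ValueError("no atmospheric species overlaps the grid span")
    return np.vstack(rows), names


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def stable_patient_seed(seed: int, subtype: str, index: int) -> int:
    """Deterministic per-patient seed from (cohort seed, subtype, index).

    SHA-256 based so that adding patients or classes never perturbs the
    seeds (hence the data) of existing patients.
    """
    digest = hashlib.sha256(f"{seed}|{subtype}|{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def generate_patient_cube(
    config: PhantomConfig, subtype: str, patient_id: str, patient_seed: int
) -> SpectralCube:
    """One patient's cube: jittered class signature + baseline + atmosphere + noise.

    The random stream is ``default_rng((config.seed, patient_seed))``; draw
    order (amplitude jitter, baseline coefficients, atmospheric coefficients,
    pixel noise) is fixed so that generated values are reproducible and vary
    smoothly with the sd parameters.
    """
    signature = config.signature_for(subtype)  # raises for unknown subtype
    rng = np.random.default_rng((int(config.seed), int(patient_seed)))
    h, w, c = config.image_height_px, config.image_width_px, config.grid.n_channels
    v = config.grid.values

    # One multiplicative lognormal factor per band, drawn once per patient:
    # within-patient pixels stay exchangeable, as the patient-vote analysis assumes.
    z = rng.standard_normal(len(signature.bands))
    factors = np.exp(config.patient_amplitude_sd * z)
    base = np.zeros(c)
    for band, f in zip(signature.bands, factors):
        base += f * band.profile(v)

    cube = np.broadcast_to(base, (h, w, c)).copy()

    # Per-pixel polynomial baseline on the normalized axis coordinate u in [-1, 1].
    u = np.linspace(-1.0, 1.0, c)
    powers = np.vstack([u**p for p in range(config.baseline.order + 1)])  # (order+1, c)
    coeffs = rng.standard_normal((h, w, config.baseline.order + 1))
    cube += config.baseline.coeff_sd * np.einsum("ijp,pc->ijc", coeffs, powers)

    # Atmospheric contamination: per-pixel non-negative strength per species.
    refs, _ = atmospheric_spectra(config.grid)
    strength = np.abs(1.0 + 0.3 * rng.standard_normal((h, w, refs.shape[0])))
    cube += config.atmospheric_level * np.einsum("ijm,mc->ijc", strength, refs)

    cube += config.pixel_noise_sd * rng.standard_normal((h, w, c))

    return SpectralCube(
        patient_id=patient_id,
        subtype=subtype,
        grid=config.grid,
        absorbance=cube,
        pixel_size_um=config.pixel_size_um,
    )


def generate_cohort(config: PhantomConfig) -> PatientCohort:
    """Generate ``patients_per_class`` cubes per subtype, deterministically.

    Patient ids are ``{subtype}{index:02d}`` (e.g. ``SQ03``); regeneration
    with an identical config is bit-identical.
    """
    cubes = []
    for signature in config.signatures:
        for i in range(config.patients_per_class):
            pid = f"{signature.subtype}{i:02d}"
            pseed = stable_patient_seed(config.seed, signature.subtype, i)
            cubes.append(generate_patient_cube(config, signature.subtype, pid, pseed))
    return PatientCohort(cubes=cubes, config=config)
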