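"""Readers and writers: cubes (long CSV and ENVI), spectrum tables, model
and configuration serialization, and the run manifest.

The long-format CSV is the canonical interchange (human-inspectable,
diff-able, bit-exact round trip via shortest round-trip decimal text); the
ENVI header + raw float32 pair exists for interoperability with
hyperspectral viewers and round-trips to 32-bit precision (~1e-7 relative).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (
    BinaryMachine,
    DiscriminantModel,
    MarginModel,
)
from .phantom import (
    Band,
    BaselineConfig,
    ClassSignature,
    PhantomConfig,
    SpectralCube,
    WavenumberGrid,
    make_grid,
)
from .preprocess import META_COLUMNS, SpectrumTable

CUBE_CSV_COLUMNS = [
    "patient_id", "subtype", "row", "col", "wavenumber_cm1", "absorbance",
]


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

def grid_from_values(values: np.ndarray) -> WavenumberGrid:
    """Reconstruct a WavenumberGrid from explicit channel values."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two channels to infer a grid")
    steps = -np.diff(values)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise ValueError("channel values are not uniformly descending")
    return WavenumberGrid(float(values[0]), float(values[-1]), float(round(steps[0], 9)))


def grid_hash(grid: WavenumberGrid) -> str:
    """Short stable fingerprint of a spectral axis (for model/channel checks)."""
    key = f"{grid.start_cm1}:{grid.end_cm1}:{grid.step_cm1}"
    return hashlib.sha256(key.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Cube CSV
# ---------------------------------------------------------------------------

def write_cube_csv(cube: SpectralCube, path) -> None:
    """Long-format CSV: one row per (pixel, channel)."""
    h, w, c = cube.absorbance.shape
    rr, cc = np.divmod(np.arange(h * w), w)
    df = pd.DataFrame(
        {
            "patient_id": cube.patient_id,
            "subtype": cube.subtype,
            "row": np.repeat(rr, c),
            "col": np.repeat(cc, c),
            "wavenumber_cm1": np.tile(cube.grid.values, h * w),
            "absorbance": cube.absorbance.reshape(-1),
        }
    )
    df["pixel_size_um"] = cube.pixel_size_um
    df.to_csv(path, index=False)


def read_cube_csv(path) -> SpectralCube:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ValueError(f"cannot parse cube CSV {path}: {exc}") from exc
    missing = [c for c in CUBE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cube CSV {path} missing column(s) {missing}")
    pids = df["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"cube CSV {path} holds {len(pids)} patients, expected 1")
    subtypes = df["subtype"].unique()
    if len(subtypes) != 1:
        raise ValueError(f"cube CSV {path} holds multiple subtypes")
    h = int(df["row"].max()) + 1
    w = int(df["col"].max()) + 1
    first_pixel = df[(df["row"] == 0) & (df["col"] == 0)]
    grid = grid_from_values(first_pixel["wavenumber_cm1"].to_numpy())
    c = grid.n_channels
    if len(df) != h * w * c:
        raise ValueError(
            f"cube CSV {path}: {len(df)} rows, expected {h}x{w}x{c} = {h * w * c}"
        )
    # rows are written pixel-major, channel-minor; re-sort defensively
    df = df.sort_values(["row", "col", "wavenumber_cm1"], ascending=[True, True, False])
    absorbance = df["absorbance"].to_numpy().reshape(h, w, c)
    pixel_size = float(df["pixel_size_um"].iloc[0]) if "pixel_size_um" in df else 6.25
    return SpectralCube(
        patient_id=str(pids[0]),
        subtype=str(subtypes[0]),
        grid=grid,
        absorbance=absorbance,
        pixel_size_um=pixel_size,
    )


# ---------------------------------------------------------------------------
# Cube ENVI (text header + raw float32, BSQ interleave)
# ---------------------------------------------------------------------------

def write_cube_envi(cube: SpectralCube, path) -> None:
    """Write ``path``.hdr (ENVI text header) and ``path``.raw (float32 BSQ)."""
    base = Path(path)
    hdr = base.with_suffix(".hdr")
    raw = base.with_suffix(".raw")
    h, w, c = cube.absorbance.shape
    wl = ", ".join(f"{v:g}" for v in cube.grid.values)
    hdr.write_text(
        "ENVI\n"
        f"description = {{mirclass cube patient_id={cube.patient_id} "
        f"subtype={cube.subtype} pixel_size_um={cube.pixel_size_um}}}\n"
        f"samples = {w}\nlines = {h}\nbands = {c}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\ninterleave = bsq\nbyte order = 0\n"
        "wavelength units = cm-1\n"
        f"wavelength = {{{wl}}}\n"
    )
    # BSQ: band-sequential (bands, lines, samples)
    data = np.ascontiguousarray(
        np.moveaxis(cube.absorbance.astype("<f4"), 2, 0)
    )
    data.tofile(raw)


def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{hdr_path}: not an ENVI header (missing magic)")
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for lineno, line in enumerate(text.splitlines()[1:], start=2):
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            if line.strip():
                raise ValueError(f"{hdr_path}:{lineno}: malformed line {line!r}")
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            buf, in_braces = [val], True
        else:
            fields[key] = val
    return fields


def read_cube_envi(path) -> SpectralCube:
    base = Path(path)
    hdr = base.with_suffix(".hdr")
    raw = base.with_suffix(".raw")
    if not hdr.exists():
        raise ValueError(f"missing ENVI header {hdr}")
    fields = _parse_envi_header(hdr)
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise ValueError(f"{hdr}: missing required field {req!r}")
    if fields["data type"] != "4":
        raise ValueError(f"{hdr}: unsupported data type {fields['data type']}")
    if fields["interleave"].lower() != "bsq":
        raise ValueError(f"{hdr}: unsupported interleave {fields['interleave']}")
    w, h, c = int(fields["samples"]), int(fields["lines"]), int(fields["bands"])
    wl_text = fields.get("wavelength", "")
    wl = [float(t) for t in wl_text.strip("{} ").replace(",", " ").split()]
    if len(wl) != c:
        raise ValueError(f"{hdr}: wavelength list has {len(wl)} entries, bands = {c}")
    grid = grid_from_values(np.array(wl))
    data = np.fromfile(raw, dtype="<f4")
    if data.size != h * w * c:
        raise ValueError(f"{raw}: {data.size} values, expected {h * w * c}")
    cube_arr = np.moveaxis(data.reshape(c, h, w), 0, 2).astype(float)
    desc = fields.get("description", "")
    meta = dict(
        tok.split("=", 1) for tok in desc.strip("{} ").split() if "=" in tok
    )
    return SpectralCube(
        patient_id=meta.get("patient_id", base.stem),
        subtype=meta.get("subtype", "SQ"),
        grid=grid,
        absorbance=cube_arr,
        pixel_size_um=float(meta.get("pixel_size_um", 6.25)),
    )


def write_cube(cube: SpectralCube, path, format: str = "long_csv") -> None:
    if format == "long_csv":
        write_cube_csv(cube, path)
    elif format == "envi":
        write_cube_envi(cube, path)
    else:
        raise ValueError(f"unknown cube format {format!r}")


def read_cube(path, format: str = "long_csv") -> SpectralCube:
    if format == "long_csv":
        return read_cube_csv(path)
    if format == "envi":
        return read_cube_envi(path)
    raise ValueError(f"unknown cube format {format!r}")


# ---------------------------------------------------------------------------
# Spectrum tables (wide CSV: metadata columns + one column per channel)
# ---------------------------------------------------------------------------

def write_table_csv(table: SpectrumTable, path) -> None:
    chan_cols = [f"wn_{v:g}" for v in table.grid.values]
    df = pd.concat(
        [table.meta.reset_index(drop=True), pd.DataFrame(table.spectra, columns=chan_cols)],
        axis=1,
    )
    df.to_csv(path, index=False)


def read_table_csv(path) -> SpectrumTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table CSV {path} missing column(s) {missing}")
    chan_cols = [c for c in df.columns if c.startswith("wn_")]
    if not chan_cols:
        raise ValueError(f"table CSV {path} has no wn_* channel columns")
    values = np.array([float(c[3:]) for c in chan_cols])
    grid = grid_from_values(values)
    return SpectrumTable(
        spectra=df[chan_cols].to_numpy(float),
        grid=grid,
        meta=df[META_COLUMNS].copy(),
    )


# ---------------------------------------------------------------------------
# Config YAML
# ---------------------------------------------------------------------------

def config_to_dict(config: PhantomConfig) -> dict:
    return {
        "grid": {
            "start_cm1": config.grid.start_cm1,
            "end_cm1": config.grid.end_cm1,
            "step_cm1": config.grid.step_cm1,
        },
        "image_width_px": config.image_width_px,
        "image_height_px": config.image_height_px,
        "pixel_size_um": config.pixel_size_um,
        "patients_per_class": config.patients_per_class,
        "signatures": {
            s.subtype: [asdict(b) for b in s.bands] for s in config.signatures
        },
        "patient_amplitude_sd": config.patient_amplitude_sd,
        "pixel_noise_sd": config.pixel_noise_sd,
        "baseline": {"order": config.baseline.order, "coeff_sd": config.baseline.coeff_sd},
        "atmospheric_level": config.atmospheric_level,
        "seed": config.seed,
    }


def config_from_dict(raw: dict) -> PhantomConfig:
    kw = dict(raw)
    if "grid" in kw:
        g = kw["grid"]
        kw["grid"] = make_grid(g["start_cm1"], g["end_cm1"], g["step_cm1"])
    if "signatures" in kw:
        kw["signatures"] = tuple(
            ClassSignature(
                subtype=sub,
                bands=tuple(Band(**b) for b in bands),
            )
            for sub, bands in kw["signatures"].items()
        )
    if "baseline" in kw:
        kw["baseline"] = BaselineConfig(**kw["baseline"])
    return PhantomConfig(**kw)


def write_config_yaml(config: PhantomConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def read_config_yaml(path) -> PhantomConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------

def model_to_dict(model) -> dict:
    if isinstance(model, DiscriminantModel):
        return {
            "kind": "discriminant",
            "variant": model.variant,
            "labels": model.labels,
            "means": model.means.tolist(),
            "covariances": model.covariances.tolist(),
            "priors": model.priors.tolist(),
            "ridge_eps": model.ridge_eps,
            "grid_channels": model.grid_channels.tolist(),
            "grid_hash": grid_hash(grid_from_values(model.grid_channels)),
            "scaler_mean": None if model.scaler_mean is None else model.scaler_mean.tolist(),
            "scaler_sd": None if model.scaler_sd is None else model.scaler_sd.tolist(),
        }
    if isinstance(model, MarginModel):
        return {
            "kind": "margin",
            "formulation": model.formulation,
            "labels": model.labels,
            "hyperparameter": model.hyperparameter,
            "machines": [
                {
                    "label_neg": m.label_neg,
                    "label_pos": m.label_pos,
                    "w": m.w.tolist(),
                    "b": m.b,
                    "support_indices": m.support_indices.tolist(),
                    "dual_coef": m.dual_coef.tolist(),
                }
                for m in model.machines
            ],
            "grid_channels": model.grid_channels.tolist(),
            "grid_hash": grid_hash(grid_from_values(model.grid_channels)),
            "scaler_mean": None if model.scaler_mean is None else model.scaler_mean.tolist(),
            "scaler_sd": None if model.scaler_sd is None else model.scaler_sd.tolist(),
        }
    raise TypeError(f"not a serializable model: {type(model)!r}")


def model_from_dict(raw: dict):
    if raw.get("kind") == "discriminant":
        return DiscriminantModel(
            variant=raw["variant"],
            labels=list(raw["labels"]),
            means=np.array(raw["means"]),
            covariances=np.array(raw["covariances"]),
            priors=np.array(raw["priors"]),
            ridge_eps=float(raw["ridge_eps"]),
            grid_channels=np.array(raw["grid_channels"]),
            scaler_mean=None if raw.get("scaler_mean") is None else np.array(raw["scaler_mean"]),
            scaler_sd=None if raw.get("scaler_sd") is None else np.array(raw["scaler_sd"]),
        )
    if raw.get("kind") == "margin":
        return MarginModel(
            formulation=raw["formulation"],
            labels=list(raw["labels"]),
            hyperparameter=float(raw["hyperparameter"]),
            machines=[
                BinaryMachine(
                    label_neg=m["label_neg"],
                    label_pos=m["label_pos"],
                    w=np.array(m["w"]),
                    b=float(m["b"]),
                    support_indices=np.array(m["support_indices"], dtype=int),
                    dual_coef=np.array(m["dual_coef"]),
                )
                for m in raw["machines"]
            ],
            grid_channels=np.array(raw["grid_channels"]),
            scaler_mean=None if raw.get("scaler_mean") is None else np.array(raw["scaler_mean"]),
            scaler_sd=None if raw.get("scaler_sd") is None else np.array(raw["scaler_sd"]),
        )
    raise ValueError(f"unknown model kind {raw.get('kind')!r}")


def write_model_json(model, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def read_model_json(path):
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def config_hash(config: PhantomConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: config hash, stage timestamps, artifacts."""

    config_hash: str
    version: str
    stages: dict = dataclasses.field(default_factory=dict)   # stage -> timestamp
    artifacts: list = dataclasses.field(default_factory=list)

    def add_artifact(self, path) -> None:
        p = str(path)
        if p in self.artifacts:
            raise ValueError(f"artifact listed twice: {p}")
        self.artifacts.append(p)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
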