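"""Tables, trace containers, and run configuration.

Ion-event lists are small and travel as comma-separated UTF-8 text with 12
significant digits (lossless round-trip of the schema fields); raw traces
are large and go into an HDF5 container as signed 16-bit datasets with a
per-ion scale factor and acquisition/ground-truth attributes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .instrument import AcquisitionConfig, IonGroundTruth, TimeTrace, TrapCalibration
from .populations import PopulationGates
from .rayleigh import RayleighConstants
from .stft import IonMeasurement

__all__ = [
    "SchemaError",
    "ION_TABLE_COLUMNS",
    "read_ion_table",
    "write_ion_table",
    "read_ground_truth_table",
    "write_ground_truth_table",
    "write_traces",
    "read_traces",
    "RunConfig",
    "load_config",
    "config_from_mapping",
]


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


ION_TABLE_COLUMNS = (
    "ion_id",
    "f0_hz",
    "mz_th",
    "charge_e",
    "mass_da",
    "n_segments_used",
    "drift_hz_per_s",
    "flags",
)

_NUMERIC_COLUMNS = {
    "ion_id": int,
    "f0_hz": float,
    "mz_th": float,
    "charge_e": float,
    "mass_da": float,
    "n_segments_used": int,
    "drift_hz_per_s": float,
}


def write_ion_table(measurements, path) -> None:
    """Write measurements as CSV; extra per-ion fields become extra columns."""
    rows = []
    for m in measurements:
        row = {
            "ion_id": m.ion_id,
            "f0_hz": m.f0_hz,
            "mz_th": m.mz_th,
            "charge_e": m.charge_e,
            "mass_da": m.mass_da,
            "n_segments_used": m.n_segments_used,
            "drift_hz_per_s": m.drift_hz_per_s,
            "flags": m.flags_str,
            "amplitude": m.amplitude,
        }
        row.update(m.extra)
        rows.append(row)
    extra_cols = sorted({k for m in measurements for k in m.extra})
    columns = list(ION_TABLE_COLUMNS) + ["amplitude"] + extra_cols
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.12g")


def read_ion_table(path) -> list[IonMeasurement]:
    """Read an ion table; missing schema columns or malformed rows raise
    :class:`SchemaError` naming the column / line."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ION_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"ion table {path} is missing required column {col!r}")
    extras = [c for c in df.columns if c not in ION_TABLE_COLUMNS and c != "amplitude"]
    out = []
    for i, row in df.iterrows():
        parsed = {}
        for col, typ in _NUMERIC_COLUMNS.items():
            try:
                parsed[col] = typ(float(row[col]))
            except ValueError:
                raise SchemaError(
                    f"ion table {path} line {i + 2}: malformed value {row[col]!r} in {col!r}"
                ) from None
        flags = frozenset(f for f in str(row["flags"]).split("|") if f)
        extra = {c: row[c] for c in extras}
        out.append(
            IonMeasurement(
                ion_id=parsed["ion_id"],
                f0_hz=parsed["f0_hz"],
                amplitude=float(row["amplitude"]) if "amplitude" in df.columns else float("nan"),
                mz_th=parsed["mz_th"],
                charge_e=parsed["charge_e"],
                mass_da=parsed["mass_da"],
                n_segments_used=parsed["n_segments_used"],
                drift_hz_per_s=parsed["drift_hz_per_s"],
                flags=flags,
                extra=extra,
            )
        )
    return out


def write_ground_truth_table(ions, path) -> None:
    from .simulate import ensemble_to_dataframe

    ensemble_to_dataframe(ions).to_csv(path, index=False, float_format="%.12g")


def read_ground_truth_table(path) -> list[IonGroundTruth]:
    df = pd.read_csv(path)
    required = ("ion_id", "mass_da", "charge_e", "f0_hz", "population_label")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"ground-truth table {path} is missing column {col!r}")
    return [
        IonGroundTruth(
            mass_da=float(r.mass_da),
            charge_e=float(r.charge_e),
            f0_hz=float(r.f0_hz),
            population_label=str(r.population_label),
            mass_loss_rate_da_per_s=float(getattr(r, "mass_loss_rate_da_per_s", 0.0)),
            ion_id=int(r.ion_id),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# HDF5 trace container


def write_traces(traces, path, acq: AcquisitionConfig | None = None) -> None:
    """Store traces as int16 datasets under /ions/<id> with a per-ion scale
    attribute and ground-truth metadata."""
    import h5py

    with h5py.File(path, "w") as h5:
        grp = h5.create_group("ions")
        if acq is not None:
            for k, v in asdict(acq).items():
                h5.attrs[k] = v
        for tr in traces:
            peak = float(np.max(np.abs(tr.samples))) or 1.0
            scale = peak / 32000.0
            ds = grp.create_dataset(
                str(tr.ion_id), data=np.round(tr.samples / scale).astype(np.int16)
            )
            ds.attrs["scale"] = scale
            ds.attrs["sample_rate_hz"] = tr.sample_rate_hz
            ds.attrs["ion_id"] = tr.ion_id
            if tr.ground_truth is not None:
                for k, v in asdict(tr.ground_truth).items():
                    ds.attrs[f"truth_{k}"] = v
            for k, v in tr.metadata.items():
                ds.attrs[f"meta_{k}"] = v


def read_traces(path) -> list[TimeTrace]:
    import h5py

    out = []
    with h5py.File(path, "r") as h5:
        for name in sorted(h5["ions"], key=lambda s: int(s)):
            ds = h5["ions"][name]
            scale = float(ds.attrs["scale"])
            truth = None
            if "truth_mass_da" in ds.attrs:
                truth = IonGroundTruth(
                    mass_da=float(ds.attrs["truth_mass_da"]),
                    charge_e=float(ds.attrs["truth_charge_e"]),
                    f0_hz=float(ds.attrs["truth_f0_hz"]),
                    population_label=str(ds.attrs["truth_population_label"]),
                    mass_loss_rate_da_per_s=float(ds.attrs["truth_mass_loss_rate_da_per_s"]),
                    ion_id=int(ds.attrs["truth_ion_id"]),
                )
            out.append(
                TimeTrace(
                    samples=ds[...].astype(float) * scale,
                    sample_rate_hz=float(ds.attrs["sample_rate_hz"]),
                    ion_id=int(ds.attrs["ion_id"]),
                    ground_truth=truth,
                )
            )
    return out


# --------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved pipeline configuration (see ``load_config``)."""

    preset: str
    n_ions: int = 500
    seed: int = 1
    overrides: dict | None = None
    calibration: TrapCalibration = TrapCalibration()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    rayleigh: RayleighConstants = RayleighConstants()
    gates: PopulationGates = PopulationGates()
    measurement_mode: str = "stft"  # "stft" (waveform path) or "truth" (emulated)
    fit_axis: str = "charge"
    fit_k: int | str = "auto"
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_ions <= 0:
            raise ValueError("n_ions must be positive")
        if self.measurement_mode not in ("stft", "truth"):
            raise ValueError("measurement_mode must be 'stft' or 'truth'")
        if self.fit_axis not in ("charge", "mass"):
            raise ValueError("fit_axis must be 'charge' or 'mass'")


def _build_section(cls, mapping: dict, name: str):
    valid = {f.name for f in dc_fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {name!r}; "
            f"valid keys: {sorted(valid)}"
        )
    if cls is PopulationGates and "rayleigh_band" in mapping:
        mapping = dict(mapping, rayleigh_band=tuple(mapping["rayleigh_band"]))
    return cls(**mapping)


def config_from_mapping(doc: dict) -> RunConfig:
    """Build a validated RunConfig from a plain mapping; unknown keys are
    rejected with the valid alternatives listed."""
    doc = dict(doc)
    sections = {
        "calibration": TrapCalibration,
        "acquisition": AcquisitionConfig,
        "rayleigh": RayleighConstants,
        "gates": PopulationGates,
    }
    kwargs = {}
    for key, cls in sections.items():
        if key in doc:
            kwargs[key] = _build_section(cls, doc.pop(key) or {}, key)
    top_valid = {f.name for f in dc_fields(RunConfig)}
    unknown = set(doc) - top_valid
    if unknown:
        raise ValueError(
            f"unknown top-level config key(s) {sorted(unknown)}; valid keys: {sorted(top_valid)}"
        )
    kwargs.update(doc)
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration with strict key validation."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping")
    return config_from_mapping(doc)
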