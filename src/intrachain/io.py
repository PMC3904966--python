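"""Schema-validated table I/O and pipeline configuration.

All tables travel as plain CSV with a header row.  Schemas are named
column sets; reading validates the header and basic value sanity, and a
write→read round trip is the identity for the numeric payload.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

SCHEMAS = {
    "curves": ["lag_s", "g", "variance"],
    "raw_curves": ["acquisition", "lag_s", "g"],
    "bursts": ["event_id", "i_donor", "i_acceptor"],
    "tau-table": ["protein_id", "construct", "ph", "tau_r_us", "tau_r_sd_us"],
    "et-table": ["protein_id", "construct", "ph", "eteff", "eteff_sd"],
    "dynamics-table": ["protein_id", "construct", "ph", "tau_r_us", "tau_r_sd_us",
                       "eteff", "eteff_sd", "rms_raw_A", "rms_A", "rg_A", "rg_sd_A",
                       "d_abs_A2_per_us", "d_abs_err", "tau_rec_us", "d_rel",
                       "d_rel_err"],
}


class SchemaError(ValueError):
    pass


def _check_schema(frame: pd.DataFrame, schema: str) -> None:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    missing = [c for c in SCHEMAS[schema] if c not in frame.columns]
    if missing:
        raise SchemaError(f"table does not match schema {schema!r}; "
                          f"missing columns: {missing}")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema."""
    text = Path(path).read_text()
    header = text.splitlines()[0] if text else ""
    if ";" in header or (header.count(",") == 0 and "\t" not in header and header):
        first_data = text.splitlines()[1] if len(text.splitlines()) > 1 else ""
        if ";" in header or ";" in first_data:
            raise SchemaError(
                "file appears to use ';' separators / locale decimal commas; "
                "re-export with '.' decimals and ',' separators")
    frame = pd.read_csv(path)
    for column in frame.columns:
        if frame[column].dtype == object:
            sample = frame[column].astype(str)
            if sample.str.fullmatch(r"-?\d+,\d+").any():
                raise SchemaError(
                    f"column {column!r} contains locale decimal commas; "
                    "re-export with '.' as the decimal separator")
    _check_schema(frame, schema)
    return frame


def write_table(frame: pd.DataFrame, path, schema: str | None = None) -> None:
    if schema is not None:
        _check_schema(frame, schema)
    frame.to_csv(path, index=False)


def _bundled(name: str) -> pd.DataFrame:
    resource = importlib.resources.files("intrachain.data") / name
    with importlib.resources.as_file(resource) as path:
        return pd.read_csv(path)


def load_tau_table() -> pd.DataFrame:
    """Bundled per-construct relaxation times (mean +/- SD, us)."""
    return _bundled("tau_table.csv")


def load_et_table() -> pd.DataFrame:
    """Bundled per-construct mean transfer efficiencies (mean +/- SD)."""
    return _bundled("et_table.csv")


def load_reference_relative_d() -> pd.DataFrame:
    """Published relative diffusion coefficients, transcribed as a
    comparison reference (not an input to any computation)."""
    return _bundled("relative_d_reference.csv")


@dataclass
class PipelineConfig:
    """Every physical constant of the end-to-end pipeline in one place."""

    s: float = 0.175
    beta: float = 0.6
    gamma: float = 1.2
    r0: float = 54.0
    contact_distance: float = 4.0
    sss_constant: float = 3.545
    linker_mode: str = "none"
    linker_delta: float = 0.0
    alpha: float = 0.05
    reference: tuple = ("alphaS", "LF", 7.4)
    seed: int = 0
    tau_table_path: str | None = None
    et_table_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("s", "beta", "gamma", "r0", "contact_distance",
                     "sss_constant", "alpha"):
            if getattr(self, name) < 0 or (name != "beta" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        self.reference = tuple(self.reference)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["reference"] = list(self.reference)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def provenance(self) -> dict:
        block = asdict(self)
        block["reference"] = list(self.reference)
        return block


def write_provenance(config: PipelineConfig, path) -> None:
    Path(path).write_text(json.dumps(config.provenance(), indent=2))
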