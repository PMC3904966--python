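"""End-to-end report: from measured summary tables to relative diffusion
coefficients and property-vs-parameter long tables.

``report`` consumes the per-construct relaxation-time and mean-efficiency
tables (bundled transcriptions of the measured values by default), runs
the Gaussian-chain inversion and the diffusion-coefficient derivation,
and emits:

* a relative-diffusion table (one row per protein/construct/pH),
* a long table pairing each construct's physico-chemical properties with
  tau_R and mean ET_eff, and
* a long table pairing those properties with D_rel, including the extra
  proline-rich C-terminal segment of beta-synuclein (residues 102-126)
  for which only sequence properties are available.

The report is deterministic: it involves no randomness, only fixture
tables and configured constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sequences
from .chain import GaussianChainModel
from .dynamics import DynamicsConfig, build_records
from .io import PipelineConfig, load_et_table, load_tau_table, read_table

log = logging.getLogger("intrachain")


@dataclass
class ReportBundle:
    dynamics: pd.DataFrame          # full per-row derivation incl. d_rel
    properties_vs_measured: pd.DataFrame  # tau_R / ET_eff vs sequence properties
    properties_vs_d_rel: pd.DataFrame     # D_rel vs sequence properties
    provenance: dict


def _chain_model(config: PipelineConfig) -> GaussianChainModel:
    return GaussianChainModel(r0=config.r0, linker_mode=config.linker_mode,
                              linker_delta=config.linker_delta)


def _dynamics_config(config: PipelineConfig) -> DynamicsConfig:
    return DynamicsConfig(contact_distance=config.contact_distance,
                          sss_constant=config.sss_constant,
                          reference=config.reference)


def _property_rows(keys: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for rec in keys.itertuples():
        rows.append(sequences.construct_properties(rec.protein_id, rec.construct,
                                                   ph=rec.ph))
    frame = pd.DataFrame(rows).rename(columns={"construct": "construct_"})
    return frame.rename(columns={"construct_": "construct"})


def report(config: PipelineConfig | None = None) -> ReportBundle:
    """Regenerate the derived tables from the measured summary tables."""
    config = config or PipelineConfig()
    tau = read_table(config.tau_table_path, "tau-table") \
        if config.tau_table_path else load_tau_table()
    et = read_table(config.et_table_path, "et-table") \
        if config.et_table_path else load_et_table()
    if et.empty or tau.empty:
        raise ValueError("tau/et tables must be non-empty")

    log.info("deriving dynamics: R0=%.1f A, a=%.1f A, sss=%.3f, linker=%s",
             config.r0, config.contact_distance, config.sss_constant,
             config.linker_mode)
    records = build_records(tau, et, _chain_model(config), _dynamics_config(config))

    keys = records[["protein_id", "construct", "ph"]]
    props = _property_rows(keys)
    measured = props.merge(
        records[["protein_id", "construct", "ph", "tau_r_us", "tau_r_sd_us",
                 "eteff", "eteff_sd"]],
        on=["protein_id", "construct", "ph"])

    d_rel_long = props.merge(
        records[["protein_id", "construct", "ph", "d_rel", "d_rel_err"]],
        on=["protein_id", "construct", "ph"])
    # the proline-rich betaS 102-126 segment: sequence properties exist, but
    # its measured tau_R/ET_eff summary values were not published, so D_rel
    # is not derivable and stays missing
    if ("betaS", "CT2") in sequences.load_constructs():
        extra = []
        for ph in sorted(d_rel_long["ph"].unique()):
            row = sequences.construct_properties("betaS", "CT2", ph=ph)
            row["d_rel"] = np.nan
            row["d_rel_err"] = np.nan
            extra.append(row)
        d_rel_long = pd.concat([d_rel_long, pd.DataFrame(extra)],
                               ignore_index=True)

    return ReportBundle(dynamics=records, properties_vs_measured=measured,
                        properties_vs_d_rel=d_rel_long,
                        provenance=config.provenance())
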