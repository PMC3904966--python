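"""Intrachain diffusion coefficients and reconfiguration times.

In the Szabo-Schulten-Schulten first-passage picture, the end-to-end
contact time of a Gaussian chain with radius of gyration Rg, contact
distance ``a`` and intrachain diffusion coefficient D satisfies
tau_R ~= a Rg^3 / (3.545 ... D) in the small-``a`` limit, so

    D = 3.545 * Rg^3 / (a * tau_R)

Uncertainty in D follows the printed propagation

    delta_Rg3 = Rg^3 * 3 * (sigma_Rg / Rg)
    delta_D   = (3.545 / a) * (delta_Rg3 / tau_R)

Absolute values of D depend on the unknown contact distance ``a`` and on
the Forster radius behind Rg; both cancel in the relative coefficients
D_rel = D / D(reference), which are the quantities reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import GaussianChainModel, invert_efficiency


class DynamicsError(ValueError):
    pass


@dataclass(frozen=True)
class DynamicsConfig:
    """Constants of the diffusion-coefficient calculation.

    contact_distance : A; dye-stacking contact at which quenching occurs.
    sss_constant : prefactor of the first-passage relation (3.545).
    reference : (protein_id, construct, ph) row that D_rel normalizes to.
    tau_rec_formula : 'msd_over_6d' gives tau_rec = <r^2> / (6 D).
    """

    contact_distance: float = 4.0
    sss_constant: float = 3.545
    reference: tuple = ("alphaS", "LF", 7.4)
    tau_rec_formula: str = "msd_over_6d"

    def __post_init__(self) -> None:
        if self.contact_distance <= 0 or self.sss_constant <= 0:
            raise DynamicsError("contact_distance and sss_constant must be positive")
        if self.tau_rec_formula != "msd_over_6d":
            raise DynamicsError(f"unknown tau_rec formula {self.tau_rec_formula!r}")


def diffusion_coefficient(rg: float, tau_r: float,
                          config: DynamicsConfig = DynamicsConfig()) -> float:
    """Absolute intrachain D = sss * Rg^3 / (a * tau_R).

    Units follow the inputs: Rg in A and tau_R in us gives D in A^2/us.
    """
    if rg <= 0 or tau_r <= 0:
        raise DynamicsError("rg and tau_r must be positive")
    return config.sss_constant * rg ** 3 / (config.contact_distance * tau_r)


def propagate_error(rg: float, rg_sd: float, tau_r: float,
                    config: DynamicsConfig = DynamicsConfig(),
                    tau_r_sd: float = 0.0, mode: str = "printed") -> float:
    """Uncertainty of the absolute D.

    ``mode='printed'`` (default) applies delta_D = (sss/a) * delta_Rg3 / tau_R
    with delta_Rg3 = 3 Rg^2 sigma_Rg, i.e. only the Rg term.  The opt-in
    ``mode='quadrature'`` additionally folds in the tau_R uncertainty.
    """
    if rg <= 0 or tau_r <= 0 or rg_sd < 0 or tau_r_sd < 0:
        raise DynamicsError("inputs must be positive (uncertainties >= 0)")
    delta_rg3 = rg ** 3 * 3.0 * (rg_sd / rg)
    delta = (config.sss_constant / config.contact_distance) * delta_rg3 / tau_r
    if mode == "quadrature":
        d = diffusion_coefficient(rg, tau_r, config)
        delta = d * np.hypot(3.0 * rg_sd / rg, tau_r_sd / tau_r)
    elif mode != "printed":
        raise DynamicsError(f"unknown error mode {mode!r}")
    return delta


def reconfiguration_time(rms: float, d_abs: float,
                         config: DynamicsConfig = DynamicsConfig()) -> float:
    """Chain reconfiguration time tau_rec = <r^2> / (6 D).

    Units follow the inputs: rms in A and D in A^2/us gives tau_rec in us.
    """
    if rms <= 0 or d_abs <= 0:
        raise DynamicsError("rms and D must be positive")
    return rms ** 2 / (6.0 * d_abs)


REQUIRED_TAU_COLUMNS = ["protein_id", "construct", "ph", "tau_r_us", "tau_r_sd_us"]
REQUIRED_ET_COLUMNS = ["protein_id", "construct", "ph", "eteff", "eteff_sd"]


def build_records(tau_table: pd.DataFrame, et_table: pd.DataFrame,
                  chain_model: GaussianChainModel = GaussianChainModel(),
                  config: DynamicsConfig = DynamicsConfig(),
                  error_mode: str = "printed") -> pd.DataFrame:
    """Merge relaxation-time and efficiency tables into dynamics records.

    Rows are keyed by (protein_id, construct, ph).  For each row the mean
    ET_eff is inverted under the Gaussian chain, D and its error are
    computed, D_rel is normalized to the configured reference row, and the
    reconfiguration time is attached.  The default pipeline uses the *raw*
    (linker-uncorrected) rms so that D_rel is independent of R0.
    """
    for cols, table, name in ((REQUIRED_TAU_COLUMNS, tau_table, "tau"),
                              (REQUIRED_ET_COLUMNS, et_table, "et")):
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise DynamicsError(f"{name} table missing columns: {missing}")
    merged = tau_table.merge(et_table, on=["protein_id", "construct", "ph"],
                             how="inner", validate="one_to_one")
    if merged.empty:
        raise DynamicsError("tau and et tables share no (protein, construct, ph) rows")

    rows = []
    for rec in merged.itertuples():
        dims = invert_efficiency(rec.eteff, chain_model, eteff_sd=rec.eteff_sd)
        use_corrected = chain_model.linker_mode != "none"
        rms = dims.rms if use_corrected else dims.rms_raw
        rg = rms / np.sqrt(6.0)
        d_abs = diffusion_coefficient(rg, rec.tau_r_us, config)
        d_err = propagate_error(rg, dims.rg_sd, rec.tau_r_us, config,
                                tau_r_sd=rec.tau_r_sd_us, mode=error_mode)
        rows.append({
            "protein_id": rec.protein_id, "construct": rec.construct, "ph": rec.ph,
            "tau_r_us": rec.tau_r_us, "tau_r_sd_us": rec.tau_r_sd_us,
            "eteff": rec.eteff, "eteff_sd": rec.eteff_sd,
            "rms_raw_A": dims.rms_raw, "rms_A": rms, "rg_A": rg,
            "rg_sd_A": dims.rg_sd, "d_abs_A2_per_us": d_abs,
            "d_abs_err": d_err,
            "tau_rec_us": reconfiguration_time(rms, d_abs, config),
        })
    return relative_diffusion(pd.DataFrame(rows), config)


def relative_diffusion(records: pd.DataFrame,
                       config: DynamicsConfig = DynamicsConfig()) -> pd.DataFrame:
    """Attach D_rel (and its error) normalized to the reference record.

    The reference row gets D_rel = 1 with zero error; other rows scale the
    absolute error by the reference D.  Constants a, sss and (for raw-rms
    pipelines) R0 cancel in the ratio.
    """
    prot, cons, ph = config.reference
    mask = ((records["protein_id"] == prot) & (records["construct"] == cons)
            & (records["ph"] == ph))
    if mask.sum() != 1:
        raise DynamicsError(f"reference record {config.reference} not found exactly once")
    d_ref = float(records.loc[mask, "d_abs_A2_per_us"].iloc[0])
    out = records.copy()
    out["d_rel"] = out["d_abs_A2_per_us"] / d_ref
    out["d_rel_err"] = out["d_abs_err"] / d_ref
    out.loc[mask, "d_rel"] = 1.0
    out.loc[mask, "d_rel_err"] = 0.0
    return out
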