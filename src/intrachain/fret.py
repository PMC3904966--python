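"""Single-molecule FRET burst processing: thresholding, corrected transfer
efficiencies, histograms, and the double-Gaussian peak fit.

Per accepted burst the corrected transfer efficiency is

    ET = (I_A - beta * I_D) / ((I_A - beta * I_D) + gamma * I_D)

where ``beta`` removes donor bleed-through into the acceptor channel and
``gamma`` compensates quantum-yield and detection-efficiency differences
between the channels.  Efficiencies are histogrammed over [-0.2, 1.2] and
fitted with a sum of two area-parameterized Gaussians: a zero peak from
donor-only molecules and a data peak whose center is the mean ET_eff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd


class BurstError(ValueError):
    pass


@dataclass(frozen=True)
class Corrections:
    """Channel correction factors (instrument-calibrated)."""

    beta: float = 0.6
    gamma: float = 1.2

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise BurstError("beta must be >= 0")
        if self.gamma <= 0:
            raise BurstError("gamma must be > 0")


@dataclass
class BurstSet:
    """Per-event donor/acceptor photon counts."""

    i_donor: np.ndarray
    i_acceptor: np.ndarray
    bin_duration_s: float | None = None

    def __post_init__(self) -> None:
        self.i_donor = np.asarray(self.i_donor, dtype=float)
        self.i_acceptor = np.asarray(self.i_acceptor, dtype=float)
        if self.i_donor.shape != self.i_acceptor.shape or self.i_donor.ndim != 1:
            raise BurstError("donor/acceptor counts must be equal-length 1-D arrays")
        if np.any(self.i_donor < 0) or np.any(self.i_acceptor < 0):
            raise BurstError("counts must be >= 0")

    def __len__(self) -> int:
        return self.i_donor.size

    @property
    def total(self) -> np.ndarray:
        return self.i_donor + self.i_acceptor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"event_id": np.arange(len(self)),
                             "i_donor": self.i_donor, "i_acceptor": self.i_acceptor})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BurstSet":
        return cls(frame["i_donor"].to_numpy(), frame["i_acceptor"].to_numpy())


def select_threshold(buffer_mean: float, buffer_sd: float, k: float = 5.0) -> float:
    """Burst-acceptance threshold from buffer-only statistics: mean + k * SD."""
    if k <= 0:
        raise BurstError("k must be > 0")
    if buffer_sd < 0:
        raise BurstError("buffer SD must be >= 0")
    return buffer_mean + k * buffer_sd


def apply_threshold(bursts: BurstSet, threshold: float,
                    mode: str = "sum") -> BurstSet:
    """Keep events whose signal exceeds the threshold.

    ``mode='sum'`` (default) thresholds the summed channel I_D + I_A;
    ``mode='per_channel'`` requires each channel to exceed it.
    """
    if mode == "sum":
        keep = bursts.total > threshold
    elif mode == "per_channel":
        keep = (bursts.i_donor > threshold) & (bursts.i_acceptor > threshold)
    else:
        raise BurstError(f"unknown threshold mode {mode!r}")
    return BurstSet(bursts.i_donor[keep], bursts.i_acceptor[keep],
                    bursts.bin_duration_s)


def compute_eteff(bursts: BurstSet, corrections: Corrections = Corrections()
                  ) -> tuple[np.ndarray, int]:
    """Corrected efficiency per event.

    Returns ``(efficiencies, n_excluded)``: events whose corrected
    denominator is non-positive are excluded (QC count), all others are
    retained even when noise pushes them slightly outside [0, 1].
    """
    corrected_a = bursts.i_acceptor - corrections.beta * bursts.i_donor
    denom = corrected_a + corrections.gamma * bursts.i_donor
    valid = denom > 0
    eff = corrected_a[valid] / denom[valid]
    return eff, int(np.count_nonzero(~valid))


HIST_RANGE = (-0.2, 1.2)
HIST_BINS = 70


@dataclass
class EfficiencyHistogram:
    """Binned corrected efficiencies over [-0.2, 1.2]."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.edges.size != self.counts.size + 1:
            raise BurstError("need len(edges) == len(counts) + 1")
        if np.any(self.counts < 0):
            raise BurstError("counts must be >= 0")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_efficiencies(cls, efficiencies: np.ndarray, bins: int = HIST_BINS,
                          hist_range: tuple[float, float] = HIST_RANGE
                          ) -> "EfficiencyHistogram":
        counts, edges = np.histogram(np.clip(efficiencies, *hist_range),
                                     bins=bins, range=hist_range)
        return cls(edges, counts)


def area_gaussian(x: np.ndarray, area: float, width: float, center: float) -> np.ndarray:
    """Area-parameterized Gaussian y = (A / (w sqrt(pi/2))) exp(-2 (x-xc)^2 / w^2)."""
    return (area / (width * np.sqrt(np.pi / 2.0))) * np.exp(-2.0 * (x - center) ** 2 / width ** 2)


@dataclass
class GaussianPeak:
    area: float
    width: float
    center: float


@dataclass
class DoubleGaussianFit:
    """Zero (donor-only) and data peaks fitted to an efficiency histogram.

    ``mean_et`` is the center of the data peak, identified as the Gaussian
    with the larger center.
    """

    zero_peak: GaussianPeak
    data_peak: GaussianPeak
    mean_et_stderr: float
    r_squared: float
    converged: bool
    flagged: bool = False
    flag_reason: str = ""

    @property
    def mean_et(self) -> float:
        return self.data_peak.center

    def summary(self) -> str:
        return "\n".join([
            "Double-Gaussian efficiency-histogram fit",
            "-" * 46,
            f"converged: {self.converged}   flagged: {self.flagged} {self.flag_reason}",
            f"R^2 = {self.r_squared:.5f}",
            f"zero peak: center {self.zero_peak.center:+.3f}, width {self.zero_peak.width:.3f}, "
            f"area {self.zero_peak.area:.3g}",
            f"data peak: center {self.data_peak.center:+.3f}, width {self.data_peak.width:.3f}, "
            f"area {self.data_peak.area:.3g}",
            f"mean ET_eff = {self.mean_et:.3f} +/- {self.mean_et_stderr:.3f}",
        ])


class DoubleGaussianModel:
    """Least-squares double-Gaussian model for an efficiency histogram."""

    def __init__(self, histogram: EfficiencyHistogram):
        self.histogram = histogram

    def default_initial_guess(self) -> dict:
        h = self.histogram
        centers, counts = h.centers, h.counts
        near_zero = np.abs(centers) < 0.1
        data_region = centers >= 0.12
        if np.any(data_region) and counts[data_region].max() > 0:
            data_center = float(centers[data_region][np.argmax(counts[data_region])])
        else:
            data_center = 0.5
        zero_area = float(counts[near_zero].sum() * h.bin_width)
        data_area = max(float(counts.sum() * h.bin_width - zero_area), h.bin_width)
        return {"a0": max(zero_area, h.bin_width * 0.5), "w0": 0.08, "c0": 0.0,
                "a1": data_area, "w1": 0.12, "c1": data_center}

    def fit(self, initial_guess: dict | None = None) -> DoubleGaussianFit:
        guess = self.default_initial_guess()
        if initial_guess:
            guess.update(initial_guess)
        h = self.histogram
        pars = lmfit.Parameters()
        pars.add("a0", value=guess["a0"], min=0.0)
        pars.add("w0", value=guess["w0"], min=1e-4)
        # the zero peak models donor-only molecules: its center is physically
        # pinned near zero once beta is correct
        pars.add("c0", value=guess["c0"], min=-0.15, max=0.15)
        pars.add("a1", value=guess["a1"], min=0.0)
        pars.add("w1", value=guess["w1"], min=1e-4)
        pars.add("c1", value=guess["c1"], min=-0.25, max=1.25)

        x, y = h.centers, h.counts

        def residual(p):
            model = area_gaussian(x, p["a0"].value, p["w0"].value, p["c0"].value) + \
                    area_gaussian(x, p["a1"].value, p["w1"].value, p["c1"].value)
            return model - y

        out = lmfit.Minimizer(residual, pars).minimize(method="leastsq")
        peaks = [GaussianPeak(out.params[f"a{i}"].value, out.params[f"w{i}"].value,
                              out.params[f"c{i}"].value) for i in (0, 1)]
        # deterministic assignment: the data peak is the one with larger center
        peaks.sort(key=lambda p: p.center)
        zero_peak, data_peak = peaks
        data_is_c1 = data_peak.center == out.params["c1"].value
        stderr = out.params["c1" if data_is_c1 else "c0"].stderr
        fitted = area_gaussian(x, zero_peak.area, zero_peak.width, zero_peak.center) + \
            area_gaussian(x, data_peak.area, data_peak.width, data_peak.center)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
        flagged, reason = False, ""
        if not out.success:
            flagged, reason = True, "optimizer did not converge"
        elif (abs(data_peak.center - zero_peak.center) < h.bin_width
              and min(zero_peak.area, data_peak.area) > h.bin_width):
            flagged, reason = True, "peaks collapsed within one bin"
        return DoubleGaussianFit(zero_peak=zero_peak, data_peak=data_peak,
                                 mean_et_stderr=float(stderr) if stderr else float("nan"),
                                 r_squared=r2, converged=bool(out.success),
                                 flagged=flagged, flag_reason=reason)


def fit_double_gaussian(histogram: EfficiencyHistogram,
                        initial_guess: dict | None = None) -> DoubleGaussianFit:
    return DoubleGaussianModel(histogram).fit(initial_guess)


def mean_eteff_over_repeats(fits: Sequence[DoubleGaussianFit | float]
                            ) -> tuple[float, float]:
    """Mean and SD of data-peak centers over repeat histograms.

    Accepts fit objects or bare center values.  Fewer than three repeats is
    allowed but warned about, mirroring the minimum-replication convention.
    """
    centers = np.array([f.mean_et if isinstance(f, DoubleGaussianFit) else float(f)
                        for f in fits])
    if centers.size == 0:
        raise BurstError("no fits supplied")
    if centers.size < 3:
        warnings.warn("fewer than 3 repeat histograms; mean ET_eff is weakly "
                      "constrained", stacklevel=2)
    sd = float(centers.std(ddof=1)) if centers.size > 1 else 0.0
    return float(centers.mean()), sd
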