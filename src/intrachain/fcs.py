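"""Fluorescence autocorrelation curves and diffusion × quenching-kinetics fits.

The fitted model for a freely diffusing species carrying a self-quenching
dye pair is

    G(tau) = (1/N) * prod_i [1 + A_i * exp(-tau / tau_R_i)]
                  * (1 + tau/tau_D)^-1 * (1 + s^2 tau/tau_D)^-1/2

with N the mean number of molecules in the confocal observation volume,
``s`` the radial/axial ratio of the volume, ``tau_D`` the translational
diffusion time, and 0–2 kinetic terms each with amplitude ``A_i`` and
relaxation time ``tau_R_i``.  The amplitude maps to the mean quenched
(dark) fraction F through A = F / (1 - F).

``FCSModel`` wraps an averaged :class:`CorrelationCurve` and its fit is
weighted by the inverse per-lag variance across replicate acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd


class FCSParameterError(ValueError):
    """Non-physical model parameters."""


class CalibrationError(RuntimeError):
    """Observation-volume calibration failed."""


@dataclass
class CorrelationCurve:
    """One averaged autocorrelation curve with per-lag variance.

    Parameters
    ----------
    lags : array of float
        Lag times in seconds, strictly increasing and positive.
    g : array of float
        Correlation amplitude at each lag.
    variance : array of float
        Per-lag sample variance across replicate acquisitions (>= 0).
    n_acquisitions : int
        Number of replicate acquisitions averaged into this curve.
    """

    lags: np.ndarray
    g: np.ndarray
    variance: np.ndarray
    n_acquisitions: int = 1

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if not (self.lags.shape == self.g.shape == self.variance.shape):
            raise ValueError("lags, g, variance must have equal length")
        if self.lags.ndim != 1 or self.lags.size == 0:
            raise ValueError("curve must be a non-empty 1-D series")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if np.any(self.variance < 0):
            raise ValueError("variance entries must be >= 0")

    def __len__(self) -> int:
        return self.lags.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "g": self.g, "variance": self.variance})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_acquisitions: int = 1) -> "CorrelationCurve":
        return cls(frame["lag_s"].to_numpy(), frame["g"].to_numpy(),
                   frame["variance"].to_numpy(), n_acquisitions)


@dataclass
class FCSModelParams:
    """Parameters of the diffusion × kinetics correlation model."""

    N: float
    tau_d: float
    s: float = 0.175
    kinetic_terms: Sequence[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.N <= 0 or self.tau_d <= 0:
            raise FCSParameterError("N and tau_d must be positive")
        if not (0.0 < self.s <= 1.0):
            raise FCSParameterError("s must lie in (0, 1]")
        for amp, tau_r in self.kinetic_terms:
            if amp < 0 or tau_r <= 0:
                raise FCSParameterError("kinetic terms need A >= 0 and tau_R > 0")
            if tau_r >= self.tau_d:
                warnings.warn("kinetic tau_R >= tau_D: fit is unlikely to be physical",
                              stacklevel=2)

    @property
    def quenched_fractions(self) -> list[float]:
        """Dark-state fractions F_i = A_i / (1 + A_i) implied by the amplitudes."""
        return [amp / (1.0 + amp) for amp, _ in self.kinetic_terms]


def model_g(params: FCSModelParams, lag) -> np.ndarray | float:
    """Evaluate the correlation model at one or many lag times (seconds)."""
    tau = np.asarray(lag, dtype=float)
    if np.any(tau < 0):
        raise FCSParameterError("lag must be >= 0")
    out = np.ones_like(tau)
    for amp, tau_r in params.kinetic_terms:
        out = out * (1.0 + amp * np.exp(-tau / tau_r))
    diffusion = (1.0 + tau / params.tau_d) ** -1 * \
                (1.0 + params.s ** 2 * tau / params.tau_d) ** -0.5
    result = out * diffusion / params.N
    return float(result) if result.ndim == 0 else result


def average_curves(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of replicate curves; variance is the sample variance."""
    if len(curves) < 2:
        raise ValueError("need at least two curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if len(c) != len(curves[0]) or not np.allclose(c.lags, lags, rtol=0, atol=0):
            raise ValueError("curves must share an identical lag grid")
    stack = np.vstack([c.g for c in curves])
    return CorrelationCurve(lags, stack.mean(axis=0), stack.var(axis=0, ddof=1),
                            n_acquisitions=len(curves))


@dataclass
class FCSFitResult:
    """Result of an autocorrelation fit.

    Attributes
    ----------
    params : FCSModelParams
        Best-fit parameter values.
    uncertainties : dict
        1-sigma uncertainties keyed by parameter name (NaN when not estimable).
    r_squared, reduced_chi_squared : float
        Unweighted R^2 and weighted reduced chi^2 diagnostics.
    residuals : array
        (g_model - g) at each lag.
    converged : bool
        False when the optimizer did not report success.
    """

    params: FCSModelParams
    uncertainties: dict
    r_squared: float
    reduced_chi_squared: float
    residuals: np.ndarray
    converged: bool
    n_points: int = 0

    def summary(self) -> str:
        lines = ["FCS correlation fit",
                 "-" * 46,
                 f"points: {self.n_points}   converged: {self.converged}",
                 f"R^2 = {self.r_squared:.6f}   reduced chi^2 = {self.reduced_chi_squared:.4g}",
                 f"N      = {self.params.N:.4g} +/- {self.uncertainties.get('N', float('nan')):.2g}",
                 f"tau_D  = {self.params.tau_d:.4g} s +/- {self.uncertainties.get('tau_d', float('nan')):.2g}",
                 f"s      = {self.params.s:.4g}"]
        for i, (amp, tau_r) in enumerate(self.params.kinetic_terms, start=1):
            lines.append(f"A_{i}    = {amp:.4g} +/- {self.uncertainties.get(f'a{i}', float('nan')):.2g}"
                         f"   (quenched fraction {amp / (1 + amp):.3f})")
            lines.append(f"tau_R{i} = {tau_r:.4g} s +/- {self.uncertainties.get(f'tau_r{i}', float('nan')):.2g}")
        return "\n".join(lines)

    @property
    def tau_r(self) -> float:
        """Relaxation time of the dominant (largest-amplitude) kinetic term."""
        if not self.params.kinetic_terms:
            raise FCSParameterError("fit has no kinetic component")
        return max(self.params.kinetic_terms, key=lambda t: t[0])[1]


VARIANCE_FLOOR_FRACTION = 1e-3  # of the median positive variance


def _weights(curve: CorrelationCurve) -> np.ndarray:
    positive = curve.variance[curve.variance > 0]
    if positive.size == 0:
        warnings.warn("all variances are zero; using unit weights", stacklevel=3)
        return np.ones_like(curve.variance)
    floor = VARIANCE_FLOOR_FRACTION * np.median(positive)
    return 1.0 / np.sqrt(np.maximum(curve.variance, floor))


class FCSModel:
    """Weighted least-squares model for one averaged correlation curve.

    Parameters
    ----------
    curve : CorrelationCurve
        Averaged curve with per-lag variances used as inverse weights.
    n_kinetic_components : int
        0 (pure diffusion, e.g. single-labeled controls), 1 or 2.
    s : float
        Observation-volume ratio; fixed during sample fits (calibrated
        separately with :func:`calibrate_s`).
    fix_s : bool
        Release ``s`` as a free parameter when False (calibration fits).
    """

    def __init__(self, curve: CorrelationCurve, n_kinetic_components: int = 1,
                 s: float = 0.175, fix_s: bool = True):
        if n_kinetic_components not in (0, 1, 2):
            raise FCSParameterError("n_kinetic_components must be 0, 1 or 2")
        n_free = 2 + 2 * n_kinetic_components + (0 if fix_s else 1)
        if len(curve) <= n_free:
            raise FCSParameterError("curve has too few points for the free parameters")
        self.curve = curve
        self.n_kinetic = n_kinetic_components
        self.s = s
        self.fix_s = fix_s

    def default_initial_guess(self) -> dict:
        g0 = max(self.curve.g[0], 1e-12)
        half = g0 / 2.0
        below = np.nonzero(self.curve.g <= half)[0]
        tau_d0 = self.curve.lags[below[0]] if below.size else self.curve.lags[-1] / 2
        guess = {"N": 1.0 / g0, "tau_d": tau_d0}
        for i in range(1, self.n_kinetic + 1):
            guess[f"a{i}"] = 0.3
            guess[f"tau_r{i}"] = 1e-6 * (3.0 ** (i - 1))
        return guess

    def _build_params(self, initial_guess: dict | None) -> lmfit.Parameters:
        guess = self.default_initial_guess()
        if initial_guess:
            guess.update(initial_guess)
        pars = lmfit.Parameters()
        pars.add("N", value=guess["N"], min=1e-9)
        pars.add("tau_d", value=guess["tau_d"], min=1e-12)
        pars.add("s", value=guess.get("s", self.s), min=1e-6, max=1.0,
                 vary=not self.fix_s)
        for i in range(1, self.n_kinetic + 1):
            pars.add(f"a{i}", value=guess[f"a{i}"], min=0.0)
            pars.add(f"tau_r{i}", value=guess[f"tau_r{i}"], min=1e-12)
        return pars

    def _params_from(self, pars) -> FCSModelParams:
        terms = [(pars[f"a{i}"].value, pars[f"tau_r{i}"].value)
                 for i in range(1, self.n_kinetic + 1)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tau_R/tau_D physicality warned by caller
            return FCSModelParams(pars["N"].value, pars["tau_d"].value,
                                  pars["s"].value, terms)

    def fit(self, initial_guess: dict | None = None) -> FCSFitResult:
        weights = _weights(self.curve)
        lags, g = self.curve.lags, self.curve.g

        def residual(pars):
            return (model_g(self._params_from(pars), lags) - g) * weights

        minimizer = lmfit.Minimizer(residual, self._build_params(initial_guess))
        out = minimizer.minimize(method="leastsq")
        params = self._params_from(out.params)
        fitted = model_g(params, lags)
        ss_res = float(np.sum((g - fitted) ** 2))
        ss_tot = float(np.sum((g - g.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        uncertainties = {name: (p.stderr if p.stderr is not None else float("nan"))
                         for name, p in out.params.items() if p.vary}
        return FCSFitResult(params=params, uncertainties=uncertainties,
                            r_squared=r2, reduced_chi_squared=float(out.redchi),
                            residuals=fitted - g, converged=bool(out.success),
                            n_points=len(self.curve))


def fit_curve(curve: CorrelationCurve, n_kinetic_components: int = 1,
              s_fixed: float = 0.175, initial_guess: dict | None = None) -> FCSFitResult:
    """Convenience wrapper: build an :class:`FCSModel` and fit it."""
    return FCSModel(curve, n_kinetic_components, s=s_fixed).fit(initial_guess)


CALIBRATION_REDCHI_THRESHOLD = 10.0


def calibrate_s(free_dye_curve: CorrelationCurve,
                initial_guess: dict | None = None) -> tuple[float, FCSFitResult]:
    """Determine the observation-volume ratio ``s`` from a free-dye curve.

    Fits a pure-diffusion model (no kinetic terms) with ``s`` floating, as
    done with a fast-diffusing reference dye.  Returns ``(s, fit_result)``;
    the value is meant to be reused as ``s_fixed`` in sample fits.
    """
    result = FCSModel(free_dye_curve, n_kinetic_components=0, fix_s=False).fit(initial_guess)
    s = result.params.s
    if not (0.0 < s <= 1.0) or not result.converged:
        raise CalibrationError(f"calibration failed (s = {s:.3g})")
    if result.reduced_chi_squared > CALIBRATION_REDCHI_THRESHOLD:
        warnings.warn("calibration fit is poor (reduced chi^2 "
                      f"{result.reduced_chi_squared:.3g}); input may contain "
                      "more than one diffusing species", stacklevel=2)
    return s, result
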