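"""Synthetic FCS and smFRET data with the statistical structure the
analysis pipeline assumes.

Two FCS paths are provided:

* a *fast path* (:func:`simulate_fcs_curve`) that evaluates the fitted
  correlation model on a quasi-logarithmic lag ladder and adds seeded
  Gaussian noise — cheap input for fit-recovery tests; and
* a *mechanistic path* (:func:`simulate_photon_trace` +
  :func:`multi_tau_correlate`) in which molecules diffuse through a
  periodic box, are detected through a 3D-Gaussian observation volume,
  and carry an independent two-state bright/dark telegraph process whose
  relaxation time 1/(k_dark + k_bright) maps to tau_R and whose
  equilibrium dark fraction F maps to the amplitude A = F/(1-F).  Photon
  counts are Poisson and split binomially between two detector channels,
  so their cross-correlation is free of shot noise — the digital
  pseudo-crosscorrelation arrangement.

FRET burst streams are generated per event with Poisson total photons,
binomial donor/acceptor partitioning that folds the beta/gamma channel
asymmetries in *forward* direction (so the corrected efficiency estimator
recovers the true efficiency in expectation), a donor-only subpopulation,
and Poisson background per channel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .fcs import CorrelationCurve, FCSModelParams, model_g
from .fret import BurstSet

# internal length scale of the observation volume; every observable of the
# trace simulation depends only on tau_D and s, not on the waist itself
PSF_WAIST_XY_UM = 0.3
BOX_WAIST_FACTOR = 10.0
PSF_CUTOFF = 1e-4  # neglected detection weight < 0.2% of the total


def multi_tau_lag_grid(base: float = 2e-7, points_per_level: int = 16,
                       n_levels: int = 14) -> np.ndarray:
    """Quasi-logarithmic lag ladder of a digital multi-tau correlator."""
    lags = [base * k for k in range(1, points_per_level + 1)]
    spacing = base
    for _ in range(1, n_levels):
        spacing *= 2.0
        start = lags[-1] + spacing
        lags.extend(start + spacing * k for k in range(points_per_level // 2))
    return np.asarray(lags)


def simulate_fcs_curve(model_params: FCSModelParams, noise_level: float = 0.02,
                       n_replicates: int = 12, seed: int = 0,
                       duration_s: float = 30.0,
                       lags: np.ndarray | None = None) -> list[CorrelationCurve]:
    """Seeded noisy replicates of a model correlation curve (fast path).

    Per-lag noise is Gaussian with SD = noise_level * (g + 1/sqrt(n_eff)),
    n_eff = duration / lag being the number of independent stretches of
    that length in one acquisition — long lags are noisier, as in measured
    curves.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if lags is None:
        lags = multi_tau_lag_grid()
    g_true = model_g(model_params, lags)
    n_eff = np.maximum(duration_s / lags, 1.0)
    sigma = noise_level * (g_true + 1.0 / np.sqrt(n_eff))
    curves = []
    for _ in range(n_replicates):
        noisy = g_true + rng.normal(0.0, 1.0, size=lags.size) * sigma
        curves.append(CorrelationCurve(lags, noisy, np.zeros_like(lags),
                                       n_acquisitions=1))
    return curves


@dataclass(frozen=True)
class FCSSimParams:
    """Study conditions of the mechanistic photon-trace simulation.

    Defaults describe a dilute labeled protein: about one molecule in the
    observation volume, a 400 us transit time, a dark-state relaxation of
    4 us with 30% equilibrium dark fraction, and an emitter brightness of
    3e5 counts/s at the center of the volume.
    """

    n_mean: float = 1.0
    tau_d: float = 400e-6
    s: float = 0.175
    k_to_dark: float = 0.75e5
    k_to_bright: float = 1.75e5
    brightness: float = 3e5
    background: float = 2e3
    duration_s: float = 4.0
    bin_width_s: float = 4e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_to_dark < 0 or self.k_to_bright < 0:
            raise ValueError("rates must be >= 0")
        if min(self.tau_d, self.bin_width_s, self.duration_s) <= 0:
            raise ValueError("times must be positive")

    @property
    def dark_fraction(self) -> float:
        total = self.k_to_dark + self.k_to_bright
        return self.k_to_dark / total if total > 0 else 0.0

    @property
    def relaxation_time(self) -> float:
        """1/(k_dark + k_bright), the tau_R the correlation should show."""
        total = self.k_to_dark + self.k_to_bright
        return 1.0 / total if total > 0 else math.inf

    @property
    def kinetic_amplitude(self) -> float:
        """F / (1 - F), the amplitude the correlation fit should recover."""
        f = self.dark_fraction
        return f / (1.0 - f)


def _telegraph_switch_times(rng: np.random.Generator, duration: float,
                            k_leave_bright: float, k_leave_dark: float,
                            start_bright: bool) -> np.ndarray:
    """Transition instants of an alternating two-state renewal process."""
    if k_leave_bright == 0 and start_bright:
        return np.empty(0)
    mean_cycle = (1.0 / k_leave_bright if k_leave_bright > 0 else duration) + \
                 (1.0 / k_leave_dark if k_leave_dark > 0 else duration)
    times = []
    t, bright = 0.0, start_bright
    block = max(int(2.5 * duration / mean_cycle) + 16, 16)
    block += block % 2  # even block keeps the alternation phase across blocks
    # draw waiting times in blocks until the trace is covered
    while t < duration:
        rates = np.empty(block)
        rates[0::2] = k_leave_bright if bright else k_leave_dark
        rates[1::2] = k_leave_dark if bright else k_leave_bright
        waits = rng.exponential(1.0, size=block) / rates
        cum = t + np.cumsum(waits)
        times.append(cum)
        t = cum[-1]
    all_times = np.concatenate(times)
    return all_times[all_times < duration]


def simulate_photon_trace(params: FCSSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Binned photon counts in two detector channels.

    Molecules take discrete Brownian steps in a periodic box of 10 PSF
    waists per axis; their detection weight is the 3D-Gaussian PSF
    exp(-2(x^2+y^2)/w^2 - 2 z^2/w_z^2); each molecule carries an
    independent bright/dark telegraph state.  Counts per bin are Poisson
    with rate brightness * PSF * bright + background and are split
    binomially (p = 0.5) between the channels.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    relax = p.relaxation_time
    if math.isfinite(relax) and p.bin_width_s > relax / 4:
        warnings.warn("bin width is not small against the telegraph relaxation "
                      "time; the fast correlation component will be distorted",
                      stacklevel=2)

    w_xy = PSF_WAIST_XY_UM
    w_z = w_xy / p.s
    box = np.array([BOX_WAIST_FACTOR * w_xy, BOX_WAIST_FACTOR * w_xy,
                    BOX_WAIST_FACTOR * w_z])
    v_eff = np.pi ** 1.5 * w_xy ** 2 * w_z
    n_mol = max(int(round(p.n_mean * box.prod() / v_eff)), 1)
    diffusion = w_xy ** 2 / (4.0 * p.tau_d)

    n_bins = int(round(p.duration_s / p.bin_width_s))
    # positions are updated on a coarser grid: transit is slow against the bin
    pos_every = max(int(p.tau_d / (40.0 * p.bin_width_s)), 1)
    n_coarse = -(-n_bins // pos_every)
    step_sd = math.sqrt(2.0 * diffusion * pos_every * p.bin_width_s)

    if p.brightness > 0:
        f_dark = p.dark_fraction
        start_bright = rng.random(n_mol) >= f_dark
        switch = [_telegraph_switch_times(rng, p.duration_s, p.k_to_dark,
                                          p.k_to_bright, bool(sb))
                  for sb in start_bright]
    positions = rng.uniform(0.0, 1.0, size=(n_mol, 3)) * box

    counts = np.empty(n_bins, dtype=np.int64)
    chunk_coarse = max(int(2.5e5 / pos_every), 1)
    fine_offsets = np.arange(pos_every)

    for c0 in range(0, n_coarse, chunk_coarse):
        c1 = min(c0 + chunk_coarse, n_coarse)
        nc = c1 - c0
        steps = rng.normal(0.0, step_sd, size=(n_mol, nc, 3))
        pos = positions[:, None, :] + np.cumsum(steps, axis=1)
        positions = np.mod(pos[:, -1, :], box)
        pos = np.mod(pos, box)
        centered = pos - box / 2.0
        psf = np.exp(-2.0 * (centered[..., 0] ** 2 + centered[..., 1] ** 2) / w_xy ** 2
                     - 2.0 * centered[..., 2] ** 2 / w_z ** 2)

        b0, b1 = c0 * pos_every, min(c1 * pos_every, n_bins)
        rate = np.zeros((nc, pos_every))
        if p.brightness > 0:
            for m in range(n_mol):
                sel = np.nonzero(psf[m] > PSF_CUTOFF)[0]
                if sel.size == 0:
                    continue
                bins = (c0 + sel[:, None]) * pos_every + fine_offsets[None, :]
                t_mid = (bins + 0.5) * p.bin_width_s
                bright = (np.searchsorted(switch[m], t_mid) % 2 == 0) \
                    == start_bright[m]
                rate[sel] += psf[m, sel][:, None] * bright
        lam = (p.brightness * rate + p.background) * p.bin_width_s
        counts[b0:b1] = rng.poisson(lam.ravel()[:b1 - b0])

    ch1 = rng.binomial(counts, 0.5)
    return ch1, counts - ch1


def multi_tau_correlate(channel_1: np.ndarray, channel_2: np.ndarray,
                        bin_width_s: float, points_per_level: int = 16,
                        n_levels: int = 12) -> CorrelationCurve:
    """Normalized cross-correlation on a multi-tau lag ladder.

    g(tau) = <dI1(t) dI2(t+tau)> / (<I1><I2>), with the means taken over
    the overlapping stretch at each lag.  Level 0 evaluates integer lags
    1..points_per_level on the raw traces; each further level halves the
    time resolution by block-averaging and evaluates the upper half of the
    lag window, the standard digital-correlator ladder.
    """
    a = np.asarray(channel_1, dtype=float)
    b = np.asarray(channel_2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("channels must be equal-length 1-D arrays")
    lags, g = [], []
    spacing = bin_width_s
    for level in range(n_levels):
        if len(a) < 2 * points_per_level:
            warnings.warn(f"trace too short for {n_levels} correlator levels; "
                          f"ladder truncated at level {level}", stacklevel=2)
            break
        ks = range(1, points_per_level + 1) if level == 0 \
            else range(points_per_level // 2 + 1, points_per_level + 1)
        for k in ks:
            x, y = a[:-k], b[k:]
            mx, my = x.mean(), y.mean()
            lags.append(k * spacing)
            g.append(float(np.dot(x, y) / x.size / (mx * my) - 1.0)
                     if mx > 0 and my > 0 else 0.0)
        n_pairs = len(a) // 2
        a = (a[:2 * n_pairs:2] + a[1:2 * n_pairs:2]) / 2.0
        b = (b[:2 * n_pairs:2] + b[1:2 * n_pairs:2]) / 2.0
        spacing *= 2.0
    lags = np.asarray(lags)
    g = np.asarray(g)
    return CorrelationCurve(lags, g, np.zeros_like(g), n_acquisitions=1)


@dataclass(frozen=True)
class BurstSimParams:
    """Study conditions of the FRET burst-stream generator.

    Defaults reflect the bright, threshold-selected subset of a
    diffusing-molecule burst experiment: thousands of events, a couple of
    hundred detected photons per accepted burst, and a donor-only
    subpopulation from incomplete acceptor labeling.
    """

    true_eteff: float = 0.84
    n_events: int = 3000
    mean_total_photons: float = 250.0
    donor_only_fraction: float = 0.25
    background_per_channel: float = 0.5
    beta: float = 0.6
    gamma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_eteff <= 1.0):
            raise ValueError("true_eteff must lie in [0, 1]")
        if not (0.0 <= self.donor_only_fraction <= 1.0):
            raise ValueError("donor_only_fraction must lie in [0, 1]")


def acceptor_fraction(true_eteff: float, beta: float, gamma: float) -> float:
    """Acceptor-channel photon fraction that the corrected-ratio estimator
    maps back to ``true_eteff``.

    Solving ET = (p - beta (1-p)) / ((p - beta (1-p)) + gamma (1-p)) for
    the acceptor fraction p gives the forward (generating) model of the
    channel asymmetries.
    """
    donor_frac = (1.0 - true_eteff) / ((1.0 + beta) * (1.0 - true_eteff)
                                       + gamma * true_eteff)
    return 1.0 - donor_frac


def simulate_bursts(params: BurstSimParams) -> BurstSet:
    """Seeded synthetic burst stream with a donor-only subpopulation."""
    p = params
    rng = np.random.default_rng(p.seed)
    donor_only = rng.random(p.n_events) < p.donor_only_fraction
    eff = np.where(donor_only, 0.0, p.true_eteff)
    p_acc = np.array([acceptor_fraction(e, p.beta, p.gamma) for e in (0.0, p.true_eteff)])
    prob = p_acc[(~donor_only).astype(int)]
    total = rng.poisson(p.mean_total_photons, size=p.n_events)
    i_acceptor = rng.binomial(total, prob)
    i_donor = total - i_acceptor
    if p.background_per_channel > 0:
        i_donor = i_donor + rng.poisson(p.background_per_channel, size=p.n_events)
        i_acceptor = i_acceptor + rng.poisson(p.background_per_channel, size=p.n_events)
    del eff
    return BurstSet(i_donor.astype(float), i_acceptor.astype(float))


def simulate_buffer_events(n_events: int, rate_per_channel: float = 1.0,
                           seed: int = 0) -> BurstSet:
    """Background-only event stream (Poisson counts in both channels)."""
    rng = np.random.default_rng(seed)
    return BurstSet(rng.poisson(rate_per_channel, size=n_events).astype(float),
                    rng.poisson(rate_per_channel, size=n_events).astype(float))
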