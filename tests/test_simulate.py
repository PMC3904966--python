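"""Synthetic-data generators and the multi-tau correlator."""

import math

import numpy as np
import pytest

from intrachain.fcs import FCSModelParams, average_curves, model_g
from intrachain.simulate import (BurstSimParams, FCSSimParams, acceptor_fraction,
                                 multi_tau_correlate, multi_tau_lag_grid,
                                 simulate_bursts, simulate_fcs_curve,
                                 simulate_photon_trace)

MODEL = FCSModelParams(2.0, 4e-4, 0.175, [(0.3, 1.2e-6)])


def brute_force_g(a, b, k):
    """Direct O(N) evaluation at one integer lag with fsum accumulation."""
    x, y = a[:len(a) - k], b[k:]
    mx = math.fsum(x) / len(x)
    my = math.fsum(y) / len(y)
    return math.fsum(float(p) * float(q) for p, q in zip(x, y)) / len(x) / (mx * my) - 1.0


class TestFastPath:
    def test_zero_noise_reproduces_model(self):
        curve = simulate_fcs_curve(MODEL, noise_level=0.0, n_replicates=1, seed=0)[0]
        assert np.allclose(curve.g, model_g(MODEL, curve.lags), atol=1e-15)

    def test_seed_determinism(self):
        a = simulate_fcs_curve(MODEL, seed=42)[0]
        b = simulate_fcs_curve(MODEL, seed=42)[0]
        assert np.array_equal(a.g, b.g)
        assert not np.array_equal(a.g, simulate_fcs_curve(MODEL, seed=43)[0].g)

    def test_replicate_variance_positive_everywhere(self):
        avg = average_curves(simulate_fcs_curve(MODEL, n_replicates=12, seed=1))
        assert np.all(avg.variance > 0)

    def test_lag_grid_is_increasing_quasi_log(self):
        lags = multi_tau_lag_grid()
        assert np.all(np.diff(lags) > 0)
        # spacing grows by octaves after the linear head
        assert lags[-1] / lags[0] > 1e4


class TestCorrelator:
    def test_constant_traces_have_zero_correlation(self):
        trace = np.full(4096, 7.0)
        curve = multi_tau_correlate(trace, trace, 1e-6, n_levels=4)
        assert np.allclose(curve.g, 0.0, atol=1e-14)

    def test_independent_white_noise_uncorrelated(self, rng):
        a = rng.poisson(5.0, size=20000).astype(float)
        b = rng.poisson(5.0, size=20000).astype(float)
        curve = multi_tau_correlate(a, b, 1e-6, n_levels=4)
        assert np.max(np.abs(curve.g)) < 0.02

    def test_matches_brute_force_at_shared_lags(self, rng):
        n = 10_000
        a = rng.poisson(3.0, size=n).astype(float)
        b = 0.5 * a + rng.poisson(2.0, size=n)  # correlated channels
        curve = multi_tau_correlate(a, b, 1e-6, points_per_level=16, n_levels=6)
        for i, k in enumerate(range(1, 17)):  # level-0 lags are shared
            assert curve.g[i] == pytest.approx(brute_force_g(a, b, k), abs=1e-10)

    def test_coarse_levels_match_block_averaged_oracle(self, rng):
        n = 8192
        a = rng.poisson(4.0, size=n).astype(float)
        b = rng.poisson(4.0, size=n).astype(float) + 0.3 * a
        curve = multi_tau_correlate(a, b, 1e-6, points_per_level=8, n_levels=3)
        # level 2: average blocks of 4, lags 5..8 coarse units
        a2 = a.reshape(-1, 4).mean(axis=1)
        b2 = b.reshape(-1, 4).mean(axis=1)
        lag_index = {round(l / 1e-6): g for l, g in zip(curve.lags, curve.g)}
        for k in (5, 6, 7, 8):
            assert lag_index[4 * k] == pytest.approx(brute_force_g(a2, b2, k),
                                                     abs=1e-10)

    def test_short_trace_truncates_ladder_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            curve = multi_tau_correlate(np.ones(64), np.ones(64), 1e-6,
                                        points_per_level=16, n_levels=8)
        assert len(curve) < 8 * 16


class TestPhotonTrace:
    def test_seed_determinism(self):
        p = FCSSimParams(duration_s=0.05, seed=7)
        assert np.array_equal(simulate_photon_trace(p)[0],
                              simulate_photon_trace(p)[0])

    def test_zero_brightness_is_background_poisson(self):
        p = FCSSimParams(brightness=0.0, background=5e4, duration_s=0.2, seed=1)
        ch1, ch2 = simulate_photon_trace(p)
        total = ch1 + ch2
        expected = p.background * p.bin_width_s
        assert total.mean() == pytest.approx(expected, rel=0.05)
        # Poisson: variance equals mean
        assert total.var() == pytest.approx(total.mean(), rel=0.1)

    def test_mean_count_rate_matches_closed_form(self):
        # <rate> = N * brightness * (1 - F) / 2^{3/2} + background;
        # fast diffusion keeps the 20 ms blocks of the SE estimate independent
        p = FCSSimParams(tau_d=50e-6, brightness=1e5, duration_s=0.5, seed=3)
        ch1, ch2 = simulate_photon_trace(p)
        total = (ch1 + ch2).astype(float)
        expected = (p.n_mean * p.brightness * (1 - p.dark_fraction) / 2 ** 1.5
                    + p.background)
        block_means = total.reshape(25, -1).mean(axis=1) / p.bin_width_s
        se = block_means.std(ddof=1) / np.sqrt(block_means.size)
        assert abs(block_means.mean() - expected) < 3 * se

    def test_no_dark_state_means_no_fast_component(self):
        p = FCSSimParams(k_to_dark=0.0, duration_s=0.3, seed=5)
        assert p.dark_fraction == 0.0
        assert p.kinetic_amplitude == 0.0
        ch1, ch2 = simulate_photon_trace(p)
        curve = multi_tau_correlate(ch1, ch2, p.bin_width_s, n_levels=12)
        # microsecond lags show no extra amplitude over the diffusion plateau
        fast = curve.g[curve.lags < 4e-6].mean()
        plateau = curve.g[(curve.lags > 2e-5) & (curve.lags < 8e-5)].mean()
        assert fast == pytest.approx(plateau, abs=0.15 * abs(plateau))

    def test_coarse_bin_width_warns(self):
        with pytest.warns(UserWarning, match="bin width"):
            simulate_photon_trace(FCSSimParams(bin_width_s=4e-6, duration_s=0.01))


class TestBursts:
    def test_acceptor_fraction_inverts_corrections_exactly(self):
        from intrachain.fret import BurstSet, Corrections, compute_eteff
        for e_true in (0.1, 0.5, 0.9):
            p = acceptor_fraction(e_true, 0.6, 1.2)
            eff, _ = compute_eteff(BurstSet([(1 - p) * 1000], [p * 1000]),
                                   Corrections(0.6, 1.2))
            assert eff[0] == pytest.approx(e_true, abs=1e-12)

    def test_seed_determinism(self):
        a = simulate_bursts(BurstSimParams(seed=9))
        b = simulate_bursts(BurstSimParams(seed=9))
        assert np.array_equal(a.i_donor, b.i_donor)
        assert np.array_equal(a.i_acceptor, b.i_acceptor)

    def test_donor_only_fraction_one_gives_single_zero_population(self):
        from intrachain.fret import EfficiencyHistogram, compute_eteff
        bursts = simulate_bursts(BurstSimParams(donor_only_fraction=1.0, seed=2))
        eff, _ = compute_eteff(bursts)
        hist = EfficiencyHistogram.from_efficiencies(eff)
        high = hist.counts[hist.centers > 0.4].sum()
        assert high < 0.005 * hist.n_events

    def test_event_count_and_nonnegativity(self):
        bursts = simulate_bursts(BurstSimParams(n_events=1234, seed=0))
        assert len(bursts) == 1234
        assert (bursts.total >= 0).all()
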