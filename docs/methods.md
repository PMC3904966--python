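# Methods

This note documents the models implemented in `intrachain`, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Correlation model and FCS fitting

The fitted autocorrelation is the product of a 3D diffusion factor and
zero to two multiplicative kinetic factors:

    G(τ) = (1/N) · Π_i (1 + A_i e^(−τ/τ_R,i)) · (1+τ/τ_D)^(−1) · (1+s²τ/τ_D)^(−1/2)

Conventions and choices:

* **Kinetic factor form.** The literature writes the reaction factor
  either as (1 + A e^(−τ/τ_R)) or as (1 − F + F e^(−τ/τ_R))/(1 − F);
  these are the same curve under A = F/(1−F). We parameterize by the
  amplitude A (with A ≥ 0 enforced) and expose the quenched-state
  fraction F = A/(1+A) as a derived quantity. This is exactly the
  correlation of a two-state telegraph emitter with equilibrium dark
  fraction F, which is how the generator produces its ground truth.
* **Weights.** Averaged curves carry the per-lag sample variance across
  replicate acquisitions; fits minimize residuals weighted by
  1/√variance. Zero variances at sparse lags are an artifact of small
  replicate counts, so weights are floored at 10⁻³ of the median
  positive variance; a curve with no positive variances falls back to
  unit weights with a warning.
* **Initial guesses.** N from 1/G(first lag); τ_D from the lag where G
  falls to half its initial value; A = 0.3 and τ_R = 1 µs for the first
  kinetic term. All overridable.
* **s is calibrated, not fitted per sample.** `calibrate_s` fits a
  pure-diffusion model with s floating to a free-dye curve (a single
  fast-diffusing species) and the result (0.175 for the reference
  instrument geometry) is then fixed in all sample fits. A calibration
  fit with reduced χ² above 10 warns that the input probably contains
  more than one species.
* **Model comparison.** One vs two kinetic components is reported via
  R² and reduced χ² only; no automatic F-test. No triplet term is
  included: the kinetic component in these samples is quenching, not
  photophysics, and a triplet factor would be degenerate with it.
* **Diagnostics.** R² is computed unweighted on G; non-convergence is
  flagged on the result, not raised.

## FRET burst processing

* **Threshold.** Accepted events must exceed buffer_mean + k·buffer_SD
  (default k = 5) on the summed channel I_D + I_A. Whether the original
  measurements thresholded per channel or on the sum is not recoverable;
  the sum is the conventional choice and per-channel mode is available.
* **Corrected efficiency.** ET = (I_A − βI_D)/((I_A − βI_D) + γI_D)
  with β = 0.6, γ = 1.2 as instrument defaults. Events whose corrected
  denominator is non-positive are excluded and counted; efficiencies
  slightly outside [0, 1] are retained for histogramming.
* **Histogram.** 70 bins over [−0.2, 1.2]; at thousands of events this
  resolves both the donor-only zero peak and the data peak.
* **Double-Gaussian fit.** y = Σ_i (A_i/(w_i√(π/2)))·exp(−2(x−x_c,i)²/w_i²).
  The peak with the larger center is the data peak (deterministic
  assignment); its center is the mean ET_eff. The zero peak models
  donor-only molecules, so its center is bounded to |x_c| ≤ 0.15 — with
  a correct β it sits at zero, and the bound prevents the zero peak
  from absorbing a low-efficiency data peak. Peak collapse within one
  bin width and optimizer failure are flagged, not raised.
* **Replication.** Mean ET_eff over repeat histograms is the arithmetic
  mean ± SD of data-peak centers; fewer than three repeats warns.

## Gaussian-chain inversion

The mean efficiency of a Gaussian chain is
⟨E⟩ = ∫ P(r)/(1+(r/R0)⁶) dr with
P(r) = 4πr²(3/(2π⟨r²⟩))^{3/2} e^(−3r²/(2⟨r²⟩)). Because ⟨E⟩ depends
only on x = rms/R0, the integral is evaluated in the dimensionless
variable u = r/rms (adaptive quadrature, absolute tolerance 10⁻⁹, upper
limit 10 rms — the neglected tail mass is < 10⁻¹⁵) and inverted by
bracketing + Brent's method on x (tolerance 10⁻⁹).

* **R0 = 54 Å** is a literature value for the Alexa 488/594 pair, used
  only to express rms in Å. Every relative quantity downstream is built
  from rms *ratios*, in which R0 cancels; tests assert this to 10⁻¹⁰.
* **Dye-linker correction.** The published chain dimensions were
  linker-corrected by an unstated amount. The default pipeline applies
  no correction (and therefore stays R0-invariant); a
  `subtract_fixed` mode subtracts a configurable Δ from the raw rms,
  floored at 1 Å, for sensitivity analysis.
* **Ideal-coil yardstick.** rms = b√(C·n) with b = 3.8 Å and C = 2.8 —
  a calibration chosen to give ≈32 Å for a 25-residue coil, the
  textbook comparison point; not a fitted quantity.

## Diffusion coefficients and reconfiguration times

D = 3.545·R_g³/(a·τ_R) with contact distance a = 4 Å (a TMR-stacking
scale; the value is irrelevant to every reported quantity because it
cancels in D_rel). The error is propagated exactly as the printed
formula: δ_Rg3 = 3R_g²σ_Rg, δ_D = (3.545/a)·δ_Rg3/τ_R — i.e. only the
R_g term; an opt-in quadrature mode folds in σ_τR as well. D_rel
normalizes to αS LF at pH 7.4, which is defined to be 1 with zero
error. Reconfiguration time defaults to τ_rec = ⟨r²⟩/(6D); the formula
is pluggable because more elaborate mode-expansion definitions exist,
and τ_rec values are reported as order-of-magnitude context only.

σ_Rg comes from the mean-ET_eff standard deviation through the local
derivative of the inversion (central difference, step ≤ 10⁻⁴).

## Group comparison

Two-tailed Mann–Whitney U. For n₁+n₂ ≤ 16 the p-value is exact: all
C(n₁+n₂, n₁) labelings are enumerated and labelings with |U − n₁n₂/2|
at least the observed deviation are counted; ties use mid-ranks. Larger
samples use the normal approximation with tie correction. The exact
branch is validated against an independent pairwise-counting
enumeration oracle; on continuous null data its empirical type-I error
at α = 0.05 is at or below α (the discrete U makes it conservative).
Summary tables flag between-protein differences (vs αS, star) and
between-pH differences (pH 3.5 vs 7.4, plus) at α = 0.05, with no
multiple-testing correction (none was applied in the original design).

## Synthetic-data generator

The generator produces data under the *assumptions of the fitted
models*, which is what makes it a useful oracle and also bounds what
passing tests mean.

**Fast path.** `simulate_fcs_curve` evaluates the correlation model on
a multi-tau-style lag ladder and adds independent Gaussian noise with
SD = noise_level·(g + 1/√n_eff), n_eff = duration/lag — long lags are
noisier, mimicking averaged-curve statistics. Defaults: noise_level
0.02, 30 s acquisitions, 12 replicates.

**Mechanistic path.** `simulate_photon_trace` moves molecules by
discrete Brownian steps through a periodic box of 10 PSF waists per
axis, detects them through exp(−2(x²+y²)/w² − 2z²/w_z²), switches each
molecule between bright and dark states with an alternating-exponential
telegraph process, draws Poisson counts per bin, and splits them
binomially between two channels (pseudo-crosscorrelation geometry, so
shot noise cancels in the cross-correlation). `multi_tau_correlate`
implements the standard digital-correlator ladder (16 linear lags, then
octave coarsening with 8 lags per level) with overlap-normalized
g(τ) = ⟨I₁I₂⟩/(⟨I₁⟩⟨I₂⟩) − 1; its level-0 values are bit-comparable to
a direct brute-force correlation.

Scaled-down study conditions, chosen once by power analysis of the
estimator noise (not tuned to any particular seed): telegraph
relaxation 4 µs with 30% dark fraction, 0.4 µs bins (10 per relaxation
time), 4 s traces, brightness 3·10⁵ counts/s per molecule, occupancy
N = 1, τ_D = 400 µs, background 2·10³ counts/s. A full-length
experiment (minutes of trace at ~1 µs relaxation) would be needlessly
slow to simulate; the shorter, brighter configuration reaches the same
estimator regime. Two implementation approximations are documented
here: positions update every τ_D/40 (diffusion is static over a few
bins — displacement ≪ waist), and molecules with PSF weight < 10⁻⁴ in
the current window are skipped (< 0.2% of the detected intensity).

**What the trace simulator does not model:** the coupling between
contact formation and chain configuration (quenching is an independent
telegraph process, not a distance-gated reaction), detector afterpulsing
and dead time, triplet photophysics, and hydrodynamic interactions.
Passing the recovery tests therefore demonstrates that the estimator
chain (correlator → weighted fit) is unbiased *under the fitted model's
own assumptions*, not that the model captures all features of real
traces.

**Bursts.** `simulate_bursts` draws per-event totals ~ Poisson(mean),
splits them binomially with an acceptor probability that folds β and γ
in the forward direction (so the corrected-ratio estimator is centered
on the true efficiency), adds a donor-only subpopulation (fraction
0.25) and Poisson background (0.5 counts/channel/event). The default
250 detected photons per event describes the bright, threshold-selected
subset of a burst stream; at lower photon counts the zero and data
peaks broaden (σ_E ∝ 1/√photons) and begin to overlap for low-ET
constructs, which biases the double-Gaussian centers — the generator
default keeps the peaks in the separable regime the fit assumes, and
the overlap behavior itself is observable by lowering
`mean_total_photons`.

## Degenerate inputs and tie-breaks

* Curves: non-increasing lag grids, negative variances and mismatched
  grids are rejected at construction.
* All-zero variances → unit weights + warning; all-tied group
  comparison → p = 1 + warning; < 3 FRET repeats → warning.
* Double-Gaussian peak assignment: larger center wins, always.
* Efficiency inversion rejects ET outside (0, 1); linker subtraction
  floors rms at 1 Å.
* CSV readers reject semicolon separators and locale decimal commas
  with an actionable message.

## Problem sizes used in tests

Unit and property tests run in milliseconds. The stochastic end-to-end
checks use: 12 replicate curves (fast path), three 4 s photon traces
(~10⁷ bins each), 3000-event burst streams at ET ∈ {0.2, 0.5, 0.84},
500 null replications for the type-I error check, and exhaustive
Mann–Whitney enumeration up to n₁ = n₂ = 7. The full suite and the
acceptance script each finish in about a minute and a half on one CPU.

## Known limitations

* The measured summary tables (τ_R, mean ET_eff per construct) are
  transcribed inputs; replicate-level measurements were never published,
  so the significance annotations of the original tables cannot be
  recomputed and the Mann–Whitney module is validated on synthetic
  replicates instead.
* The published relative diffusion coefficients carry an unpublished
  dye-linker correction; the reproduction criterion is therefore
  agreement within twice the published standard errors (achieved for
  all 24 entries), not equality.
* The net-charge-per-residue convention behind the published value for
  the proline-rich βS segment (0.372) is not recoverable; with standard
  side-chain pKa values the pipeline computes 0.400, and the pKa set,
  terminus handling and divisor are configurable rather than asserted.
* Percent identity is ungapped position-wise comparison of homologous
  equal-length ranges; it reproduces the published AH values but is not
  an alignment, and no gapped aligner is included.
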