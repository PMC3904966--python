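# intrachain

Intrachain dynamics and solution conformations of disordered protein
segments, measured by fluorescence correlation spectroscopy (FCS) with
dye self-quenching and by single-molecule FRET — packaged as a reusable
analysis pipeline for the three human synucleins (α, β, γ).

## The problem

Intrinsically disordered proteins such as the synucleins have no stable
tertiary structure; what distinguishes one region from another is how
*fast* it reconfigures and how *compact* its conformational ensemble is.
Two single-molecule observables capture this:

1. **End-to-end contact kinetics.** A segment labeled at both ends with
   tetramethylrhodamine (TMR) self-quenches whenever chain motion brings
   the dyes into contact. The fluorescence autocorrelation of such a
   sample decays with two characteristic times — the translational
   transit τ_D through the confocal volume and a fast relaxation τ_R
   from the quenching reaction:

   G(τ) = (1/N) · Π_i (1 + A_i·e^(−τ/τ_R,i)) · (1+τ/τ_D)^(−1) · (1+s²τ/τ_D)^(−1/2)

   with N the mean occupancy, s the radial/axial ratio of the
   observation volume, and A the amplitude of the kinetic component
   (A = F/(1−F) for quenched-state fraction F).

2. **Ensemble dimensions.** The same segment labeled with a FRET pair
   yields per-burst corrected transfer efficiencies

   ET = (I_A − β·I_D) / ((I_A − β·I_D) + γ·I_D)

   (β donor bleed-through, γ detection/quantum-yield factor), which are
   histogrammed and fit with two area-parameterized Gaussians — a
   donor-only zero peak and a data peak whose center is the mean ET_eff.
   Under a Gaussian-chain model, mean ET_eff inverts to the RMS
   end-to-end distance ⟨r²⟩^1/2 and radius of gyration R_g = ⟨r²⟩^1/2/√6.

Combining the two, the Szabo–Schulten–Schulten first-passage relation
gives an intrachain diffusion coefficient

   D = 3.545 · R_g³ / (a · τ_R),     δ_D = (3.545/a) · (3·R_g²·σ_Rg) / τ_R

with a the dye contact distance. Absolute D depends on unknowable
constants (a, the Förster radius R0 behind R_g), so the pipeline reports
**relative** coefficients D_rel normalized to a reference construct
(αS LF at pH 7.4) — a ratio in which a, the 3.545 prefactor, and R0 all
cancel exactly. Reconfiguration times follow as τ_rec = ⟨r²⟩/(6D).

The package also profiles the segments themselves (ungapped percent
identity, Zimmerman bulkiness normalized to glycine, Kyte–Doolittle
hydropathy, Henderson–Hasselbalch net charge per residue) and compares
replicate groups with an exact two-tailed Mann–Whitney U test — and it
ships a synthetic-data generator (Brownian motion through a 3D-Gaussian
observation volume with two-state bright/dark telegraph kinetics, a
multi-tau digital correlator, and a FRET burst-stream generator) that
validates every estimator against known ground truth.

## Worked example

Regenerate the derived tables from the bundled measured summary tables
(per-construct τ_R and mean ET_eff):

```python
from intrachain import report
bundle = report()
cols = ["protein_id", "construct", "ph", "tau_r_us", "eteff",
        "rms_raw_A", "rg_A", "d_rel", "d_rel_err", "tau_rec_us"]
print(bundle.dynamics[cols].head(8).round(3).to_string(index=False))
```

```
protein_id construct  ph  tau_r_us  eteff  rms_raw_A   rg_A  d_rel  d_rel_err  tau_rec_us
    alphaS        AH 7.4      2.08   0.84     37.755 15.413  0.680      0.000       0.152
    alphaS        AH 3.5      2.35   0.88     34.714 14.172  0.468      0.032       0.187
    alphaS        LF 7.4      1.10   0.88     34.714 14.172  1.000      0.000       0.088
    alphaS        LF 3.5      1.20   0.88     34.714 14.172  0.917      0.127       0.096
    alphaS       NAC 7.4      1.23   0.82     39.184 15.997  1.286      0.000       0.087
    alphaS       NAC 3.5      1.48   0.89     33.897 13.838  0.692      0.051       0.121
    alphaS        CT 7.4      1.37   0.84     37.755 15.413  1.033      0.060       0.100
    alphaS        CT 3.5      2.44   0.91     32.162 13.130  0.359      0.030       0.210
```

Reading the αS rows at pH 7.4: a mean ET_eff of 0.84 inverts to an RMS
donor–acceptor distance of ≈38 Å (R_g ≈ 15 Å) — close to the ≈32 Å of an
ideal 25-residue random coil, i.e. a compact but genuinely disordered
ensemble. The NAC segment diffuses ≈29% faster than the LF reference
(D_rel 1.29) while the amphipathic-helix region AH is the slowest
(D_rel 0.68); dropping to pH 3.5 slows every αS segment, most
dramatically the C-terminus (D_rel 0.36). Reconfiguration times land at
0.09–0.21 µs, the same order as the measured relaxation times.

Sequence profiling from the shell:

```
$ intrachain seq-props --construct betaS:NAC --ph 7.4
protein_id,construct,ph,n_residues,net_charge_per_residue,abs_charge_per_residue,bulkiness_per_residue,hydrophobicity_per_residue
betaS,NAC,7.4,25,0.0015,0.0015,3.674,0.292
```

The βS hydrophobic-core segment has a glycine-normalized bulkiness of
3.7 per residue — noticeably leaner than the αS and γS counterparts
(both ≈4.4), which matches its roughly 50–100% faster end-to-end
contact dynamics.

Other CLI verbs: `simulate-fcs`, `fit-fcs`, `simulate-bursts`,
`fit-fret`, `chain-dims`, `derive-dynamics`, `compare`, `report`.

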