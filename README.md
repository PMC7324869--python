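# s100kit

Analysis toolkit for the Ca²⁺-dependent activation of the S100A1 protein
and its competition with actin for the elastic PEVK region of titin.

S100A1 is an EF-hand Ca²⁺ sensor: a high-affinity canonical hand (cEF,
K_d ≈ 27–50 µM) and a low-affinity pseudo hand (pEF, K_d ≈ 250–16,700 µM)
gate the opening of a hydrophobic target-binding cleft between helices H3
and H4. Because cytosolic Ca²⁺ sits far below the pEF affinity, wild-type
S100A1 is rarely fully activated — but redox modification of C85
(glutathionylation) can shift the balance. This package provides, for
people analysing simulations and binding assays of such systems:

* **structure/trajectory metrics** — the H3/H4 opening angle
  (Cα(A53)–hinge-centroid–Cα(C85)), backbone RMSF, residue contact maps
  (7 Å, |i−j| ≥ 6), DSSP-style α-helix probability (Kabsch–Sander
  H-bonds), Shrake–Rupley SASA, H-bond counts, per-residue MM-GBSA
  interaction differences ΔG = ⟨G_dimer⟩ − ⟨G_monomer⟩, and hierarchical
  clustering of frames on pairwise RMSD;
* **umbrella-sampling reconstruction** — 1-D WHAM
  (G(z) = −RT ln ρ(z) from windows biased by ½K(z−z_i)²), Monte-Carlo
  bootstrap errors, block-averaging + mean-force error propagation, and
  binding-ΔG extraction from the profile;
* **a competition model** — apo / Ca·S100A1 / 2Ca·S100A1 binding a PEVK
  peptide (K_d1, K_d2, K_d2′) against actin (A + P ⇌ AP), solved by
  mass action with clamped or depletable Ca²⁺, fitted to dose–response
  data, and calibrated to experiment through
  λ = e^{(ΔG_expt − ΔG_calc)/RT}, including post-translational-
  modification predictions K_d,mod = λ·K_d·e^{(ΔG_mod − ΔG_WT)/RT};
* **synthetic-data generators** with known ground truth for every input
  (biased Metropolis samples of a known potential, ideal backbones at
  chosen (φ,ψ), noisy binding curves, energy tables).

## Worked example

```python
import numpy as np
import s100kit as sk

# calibration of computed vs experimental dissociation constants
cal = sk.calibrate_lambda(-6.5, -9.5)            # RT = 0.593 kcal/mol
factor = sk.ptm_scale_factor(-12.9, -7.6, cal)   # C85 glutathionylation
print(f"lambda = {cal.lam:.3f}")
print(f"PTM Kd scale factor = {factor:.3f}  (~{1/factor:.0f}-fold tighter)")

# reconstruct a PMF from synthetic umbrella windows (49 windows, K = 18)
pot = sk.default_double_well()                   # bound well 9.5 kcal/mol deep
windows = sk.sample_umbrella_windows(pot, sk.SamplerParams(seed=1,
                                                           n_samples=10_000))
profile = sk.bootstrap_error(windows, n_trials=30, seed=2)
dg, err = sk.binding_dg(profile, bound_region=(12, 16),
                        unbound_region=(28, 33.5))
print(f"binding dG = {dg:.2f} +/- {err:.2f} kcal/mol")

# Ca2+-dependent displacement of actin-bound PEVK by S100A1
grid = np.array([0.0, 1.0, 10.0])
for pca in (7.0, 4.0):
    curve = sk.dose_response(grid, actin_uM=5.0, pevk_uM=1.0, pca=pca)
    print(f"pCa {pca}: f_AP at [S]=0,1,10 uM ->",
          np.round(curve['f_AP'].to_numpy(), 3))
```

prints

```
lambda = 157.436
PTM Kd scale factor = 0.021  (~48-fold tighter)
binding dG = -9.47 +/- 0.10 kcal/mol
pCa 7.0: f_AP at [S]=0,1,10 uM -> [0.892 0.761 0.327]
pCa 4.0: f_AP at [S]=0,1,10 uM -> [0.892 0.516 0.077]
```

λ = 157.436 is the multiplicative map from PMF-computed to experimental
dissociation constants; the 0.021 factor is the predicted K_d reduction of
Ca²⁺-loaded S100A1 after C85 glutathionylation (a ~48-fold affinity gain).
The reconstructed binding ΔG recovers the synthetic well depth
(−9.5 kcal/mol) within its bootstrap error, and the dose–response shows
S100A1 displacing actin-bound PEVK more effectively at elevated Ca²⁺
(pCa 4) than at resting levels (pCa 7).

## Layout

```
src/s100kit/
  structure.py    PDB/trajectory containers, selection, window-series I/O
  metrics.py      opening angle, superposition/RMSD, RMSF, contacts,
                  H-bonds, frame clustering
  dssp.py         Kabsch–Sander α-helix assignment
  sasa.py         Shrake–Rupley surface areas
  energetics.py   per-residue interaction-energy bookkeeping
  wham.py         WHAM, bootstrap + block-averaging errors, binding ΔG
  competition.py  Ca²⁺-state competition model, λ calibration, fitting
  synthetic.py    seeded generators with ground-truth sidecars
  cli.py          `s100` command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
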