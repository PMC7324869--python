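# Methods

## Scope and model system

`s100kit` analyses the Ca²⁺-dependent activation of the S100A1 homodimer
and its competition with actin for the titin PEVK segment. It covers three
layers:

1. **structural gating metrics** computed on structures/trajectories
   (H3/H4 opening angle, backbone RMSF, residue contact maps, DSSP-style
   α-helix probability, Shrake–Rupley SASA, hydrogen-bond counts,
   per-residue interaction-energy differences, hierarchical frame
   clustering);
2. **free-energy reconstruction** of 1-D umbrella-sampling data by WHAM,
   with Monte-Carlo bootstrap and block-averaging/mean-force error
   estimates and binding-ΔG extraction;
3. an **equilibrium competition model** of apo / half-saturated /
   fully-saturated S100A1 binding a PEVK peptide against actin, with a
   calibration (λ) that maps computed dissociation constants onto the
   experimental scale and predicts the effect of C85 glutathionylation.

Simulation engines (MD, GB solvation) are out of scope; the package
consumes their outputs (PDB models, per-window reaction-coordinate series,
per-residue energy tables).

## Structural metrics

**Opening angle.** The target-binding cleft between helices 3 and 4 opens
upon Ca²⁺ binding. The metric is the angle at the hinge vertex — the
geometric centroid of the Cα atoms of residues 61–62 and 72–73 — between
rays to the Cα of A53 (H3) and C85 (H4). A Cα-only centroid is used for
the vertex because the ray endpoints are Cα atoms; mass weighting over
these four nearly identical atoms is numerically indistinguishable. The
angle is invariant under rigid motion by construction.

**RMSF.** Frames are superposed (Kabsch, proper rotations only) onto the
mean structure, with frame 1 as the initial reference and one
mean-refinement iteration. The per-residue value pools the squared
deviations of the residue's backbone atoms (N, Cα, C, O) before the root
is taken. The alignment selection can differ from the reported selection.

**Contacts.** Two residues are in contact when the minimum distance over
their heavy-atom pairs is ≤ 7 Å (closed boundary: exactly 7 Å counts).
Same-chain pairs closer than 6 positions in sequence are excluded;
inter-chain pairs are always eligible. The min-heavy-atom rule is the
common trajectory-analysis default; the source analyses do not state an
atom rule.

**Helicity.** Only the α-helix (H) state is assigned. A backbone H-bond is
scored with the Kabsch–Sander electrostatic energy
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, accepted at
E < −0.5 kcal/mol; distances below 0.5 Å clamp to a strong bond. A residue
is helical when it lies in a run started by two consecutive i→i+4 bonds
(the minimal-helix rule). Missing amide hydrogens are rebuilt 1.01 Å from
N opposite the bisector of N–C(prev) and N–Cα; the N-terminal amide is
skipped as a donor. The assignment is cross-checked against mdtraj's DSSP
in the test suite.

**SASA.** Shrake–Rupley with a deterministic golden-spiral mesh
(960 points/atom by default), probe 1.4 Å, standard van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å, ...). Unknown elements fall
back to 1.70 Å with a warning. A mesh point exactly on a neighbour's
surface counts as occluded only if strictly inside (`<` test), so two
exactly coincident spheres each retain their full mesh — a documented
convention, exercised in the tests.

**Interaction energies.** Per-residue tables of E_EEL, E_vdW and E_solv
(bonded terms excluded upstream) for the dimer and each monomer are
combined as ΔG(residue) = ⟨ΣE⟩_dimer − ⟨ΣE⟩_monomer. The reported spread
is the quadrature sum of the two ensembles' frame-wise standard
deviations (the ensembles are sampled independently, so paired
differences are not available in general). The residue sum equals the
total ensemble difference exactly.

**Clustering.** Average-linkage agglomerative clustering on the pairwise
best-fit RMSD matrix; representatives are medoids (minimum summed RMSD,
ties to the lower frame index); clusters are ordered by decreasing
population, and a helper returns the k least-populated representatives —
the protocol used to seed successive production cycles.

## WHAM reconstruction

Windows carry harmonic biases `U_i(z) = ½K(z−z_i)²` (the NAMD colvars
convention; `bias_convention="full"` switches to `K(z−z_i)²`), with
K = 18 kcal/mol/Å² and centres 9.5–33.5 Å every 0.5 Å (49 windows) as the
reference layout. Samples are histogrammed at 0.1 Å (default); RT is
0.596 kcal/mol (300 K).

The window free energies f_i satisfy the self-consistent WHAM equations.
Because those equations are the stationarity conditions of a convex
likelihood, the solver first minimises that likelihood (L-BFGS followed by
exact-Newton polishing on the tiny n_windows×n_windows Hessian) and then
runs the direct fixed-point iteration until max|Δf_i| < 1e−10 — the warm
start makes the iteration terminate essentially immediately while keeping
the documented convergence contract. Bins never visited are dropped;
interior gaps raise a warning. G(z) = −RT ln ρ(z) is anchored at zero
minimum.

**Bootstrap error.** Each of 30 trials (default) resamples every window's
samples with replacement, re-runs WHAM on the shared bin grid, re-anchors
(minimum by default; unbound-tail anchoring behind a flag) and the per-bin
standard deviation over trials is ε(z). Stored samples from the synthetic
sampler are thinned to near-independence (below), so resampling with
replacement is a valid bootstrap for them.

**Block-averaging / mean-force error.** The variance of each window's mean
RC is estimated by block averaging (block size 200, trailing partial block
dropped; variance of block means over the number of blocks). In the
stiff-spring view the free-energy increment across window i is the
restraint force times the centre spacing d_i, so its variance is
(K·d_i)²·σ²(x̄_i); increments accumulate in quadrature from the reference
end, giving a monotone ε(z). The two estimators agree within a factor of
~1.1 on the synthetic study (tested within the looser factor-3 band).

**Binding ΔG.** ΔG = min G over the bound region − mean G over the unbound
plateau; errors at the two locations combine in quadrature. No
standard-state volume correction is applied (none is applied in the
source analysis either).

## Competition model

Three Ca²⁺ states of S100A1 (apo, half-saturated: cEF occupied,
fully-saturated: cEF+pEF) bind PEVK (P) with Kd1, Kd2, Kd2′; actin
competes via A + P ⇌ AP (K_AP). Default constants: Kd1 = 0.52,
Kd2 = 0.13, Kd2′ = 0.03 µM (the fitted values), Kd_cEF = 27 µM,
Kd_pEF = 250 µM (the tight ends of the reported ranges — the values at
which the states are most populated at physiological Ca²⁺). Only
independent constants are parameterised; Ca²⁺ affinities of peptide-bound
states follow from closing the thermodynamic cycles (Wegscheider), so
detailed balance holds by construction. Per-state enable flags implement
the model variant in which the half-saturated state does not bind.

The solver runs damped Newton on the log free concentrations of the
conserved components; log coordinates keep all species positive and the
conservation system has a unique root there. Conservation and every Kd
relation hold to better than 1e−9 relative (verified per call).

**Ca²⁺ handling.** By default free Ca²⁺ is clamped at 10^(6−pCa) µM
(buffered assay). A depletion mode treats that amount as *total* Ca²⁺ and
solves the free level via its own conservation residual (monotone in free
Ca²⁺, bracketed on [0, Ca_T]) around the inner solve. Depletion matters
when the protein is dosed to concentrations comparable to the Ca²⁺ pool,
which is exactly the regime of the emulated competition assay (S100A1 up
to 100 µM against a 0.1 mM Ca²⁺ pool).

**Stoichiometry.** Concentrations are per binding site (one PEVK site per
S100A1 subunit); "total S100A1" therefore means subunit concentration.
K_AP = 0.5 µM, actin 5 µM and PEVK 1 µM are package defaults for the
emulated assay; the underlying report does not print them.

**Calibration and PTM prediction.** ΔG = RT ln(Kd/c°) with RT = 0.593
kcal/mol (≈298 K — the only value that reproduces the printed calibration
numbers exactly; the WHAM module independently uses 300 K) and c° = 1 M.
λ = exp((ΔG_expt − ΔG_calc)/RT) maps computed onto experimental Kd scales
(157.436 for −6.5 vs −9.5 kcal/mol). A PTM rescales the Ca²⁺-loaded
constants by λ·exp((ΔG_mod − ΔG_WT)/RT); for glutathionylation
(ΔG_glu = −12.9, the mean of the two variant values; ΔG_WT = −7.6) this is
0.021, i.e. a ~48-fold affinity gain.

**Fitting.** Nonlinear least squares on log₁₀ Kd (bounds 10⁻⁴–10³ µM),
jointly across curves at different Ca²⁺ conditions; replicate doses share
one equilibrium solve. Parameters whose decade-scale perturbation leaves
the residual sum essentially unchanged are flagged unidentifiable.
Optional residual-bootstrap confidence intervals are seeded.

### Identifiability and the synthetic fit study

With clamped Ca²⁺ the observable depends on the three Kds only through one
effective combination per pCa (the bound-S100A1 term reduces to
S_T·p·β/(1+p·β) with β a single pCa-dependent scalar), so data at m
distinct clamped Ca²⁺ levels determine at most m parameter combinations —
two curves cannot determine three constants, whatever the estimator. The
synthetic dose–response study is therefore designed, via an a-priori
Cramér–Rao analysis at the generating parameters, to be well-posed:

* three Ca²⁺ conditions, pCa {7, 5, 4} — the same three levels as the
  package's prediction curves;
* Ca²⁺ depletion on (total Ca²⁺ = 10^(6−pCa) µM), reflecting that the
  emulated assay doses S100A1 to levels comparable to its Ca²⁺ pool;
* triplicate measurements per dose (standard assay practice), 12 doses
  from 0 to 100 µM, Gaussian noise of sd 0.02 on f_AP (clipped to [0,1]).

Under this design the Cramér–Rao standard deviations at 2% noise are
≈3%, 8% and 9% for Kd1, Kd2 and Kd2′, so ±15% recovery is an informative
test of the estimator rather than a coin flip. What passing shows: the
solver + fitter pipeline is consistent and close to the information bound
on data of the assumed error model. What it does not show: that real
cosedimentation data (correlated errors, baseline drift, uncertain
totals) would constrain the constants equally well.

## Synthetic data

* **Umbrella sampler** — vectorised Metropolis chains (Gaussian proposals,
  sd 0.25 Å; burn-in 2000; thinning 10) targeting exp(−(U+bias)/RT) in all
  windows simultaneously; bit-identical under a fixed seed. Thinning is
  chosen so stored samples are near-independent, which makes the plain
  bootstrap and the block-averaging error model consistent with each
  other. The default double-well surface has its bound well 9.5 kcal/mol
  below the plateau at z = 14 Å (matching the scale of the computed
  binding free energy and the observed well position) plus a shallow
  2 kcal/mol shoulder at 18.5 Å — a scale choice, not a reconstruction of
  any measured profile.
* **Backbone builder** — internal-coordinate (NeRF) placement of N, Cα, C,
  O (+ amide H) with standard bond lengths/angles, ω = 180°; (φ,ψ) =
  (−57°, −47°) gives an ideal α-helix (rise ≈ 1.5 Å/residue), (180°, 180°)
  a fully extended chain.
* **Binding curves / energy tables** — forward model plus seeded Gaussian
  noise, each emitting a ground-truth record consumed by the recovery
  tests.

## Numerical conventions and degenerate inputs

* WHAM tolerance 1e−10 (units of RT) on the window free energies; bin
  width 0.1 Å; unbiased windows (K = 0) are legal and reduce WHAM to
  plain histogramming.
* Equilibrium solver tolerance 1e−12 relative on conservation; zero
  totals eliminate the corresponding component analytically.
* Clustering ties (medoid, ordering) break toward the lower frame index.
* PDB altlocs keep the highest-occupancy copy (first on tie); NMR
  multi-model files default to model 1, with the model index exposed.
* Angles are clipped into [−1, 1] before arccos; coincident ray atoms
  raise.

## Problem sizes

The bundled studies are sized for a laptop: the WHAM study uses 49
windows × 10⁴ stored samples (≈10⁶ Metropolis steps after thinning) and
30 bootstrap trials; the fit study uses 108 observations and a 3-parameter
optimisation. These sizes put the statistical errors of the synthetic
studies well inside the tested tolerances.

## Known limitations

* The DSSP reduction assigns only H vs not-H; 3₁₀/π helices and sheets are
  out of scope.
* The competition scheme is an equilibrium reconstruction; the governing
  equations of the original supplementary material were not available, so
  the "S100A1 binds AP and displaces actin" wording is implemented as
  competition for free PEVK, which is thermodynamically equivalent for the
  observable f_AP.
* Kinetics, sarcomere mechanics and titin-isoform effects are not
  modelled.
* The trajectory reader supports multi-model PDB; binary trajectory
  formats are intentionally not required by the analysis contracts.
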