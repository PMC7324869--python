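"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the data the analysis modules consume:

* harmonically restrained Metropolis samples from a known 1-D potential
  (umbrella windows for WHAM), laid out like the TRTK12 unbinding study:
  centres 9.5–33.5 Å every 0.5 Å (49 windows), K = 18 kcal/mol/Å²;
* ideal polyalanine backbones at chosen (φ, ψ) dihedrals (DSSP harness);
* mass-action dose–response binding curves with Gaussian noise
  (competition-model harness), and per-residue energy tables with planted
  interaction offsets (MM-GBSA bookkeeping harness).

Every generator is a pure function of its seed and can emit a ground-truth
sidecar for the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .competition import CaBindingParams, PeptideAffinities, dose_response
from .energetics import ENERGY_TERMS, EnergyTable
from .structure import Atom, Structure
from .wham import RT_300K, UmbrellaWindow, default_window_centers

__all__ = [
    "PotentialSpec",
    "SamplerParams",
    "BindingCurveSpec",
    "default_double_well",
    "sample_umbrella_windows",
    "build_helix_coords",
    "build_chain",
    "generate_binding_curves",
    "generate_energy_tables",
]


@dataclass(frozen=True)
class PotentialSpec:
    """A 1-D potential U(z) in kcal/mol over the sampling interval."""

    kind: str                       # 'harmonic' | 'double_well' | 'tabulated'
    params: dict = field(default_factory=dict)
    rt: float = RT_300K

    def u(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.kind == "harmonic":
            return 0.5 * p["k"] * (z - p["center"]) ** 2
        if self.kind == "double_well":
            out = np.zeros_like(z)
            for c, depth, width in p["wells"]:
                out -= depth * np.exp(-((z - c) ** 2) / (2.0 * width ** 2))
            return out
        if self.kind == "tabulated":
            return np.interp(z, p["z"], p["u"])
        raise ValueError(f"unknown potential kind {self.kind!r}")


def default_double_well() -> PotentialSpec:
    """Bound well 9.5 kcal/mol deep at 14 Å, shoulder well, flat plateau.

    The depth matches the scale of the computed TRTK12 binding free energy
    (ΔG_calc = −9.5 kcal/mol); the shape is a generic two-well test surface,
    not a reconstruction of any measured profile.
    """
    return PotentialSpec("double_well",
                         {"wells": [(14.0, 9.5, 1.2), (18.5, 2.0, 1.0)]})


@dataclass(frozen=True)
class SamplerParams:
    """Metropolis sampler settings; the seed is mandatory."""

    seed: int
    n_samples: int = 10_000
    step: float = 0.25              # Å, Gaussian proposal sd
    burn_in: int = 2_000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.step <= 0 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid sampler parameters")


def sample_umbrella_windows(potential: PotentialSpec,
                            sampler: SamplerParams,
                            centers: np.ndarray | None = None,
                            force_constant: float = 18.0,
                            bias_convention: str = "half"
                            ) -> list[UmbrellaWindow]:
    """Biased Boltzmann samples for every umbrella window.

    All windows are advanced in lock-step by a vectorised Metropolis chain
    targeting exp(−(U(z) + bias_i(z))/RT); after burn-in, one sample per
    window is stored every ``thin`` steps.  Bit-identical under a fixed
    seed.
    """
    centers = default_window_centers() if centers is None else np.asarray(centers, float)
    windows = [UmbrellaWindow(c, np.zeros(1), force_constant, f"w{i:02d}")
               for i, c in enumerate(centers)]

    probe = np.linspace(centers.min() - 2, centers.max() + 2, 512)
    if not np.all(np.isfinite(potential.u(probe))):
        raise ValueError("potential is unbounded on the sampling interval")

    rng = np.random.default_rng(sampler.seed)
    rt = potential.rt
    z = centers.copy()
    conv = {"half": 0.5, "full": 1.0}[bias_convention]

    def total_u(zv: np.ndarray) -> np.ndarray:
        return potential.u(zv) + conv * force_constant * (zv - centers) ** 2

    u_cur = total_u(z)
    n_keep = sampler.n_samples
    samples = np.empty((n_keep, centers.size))
    kept = 0
    total_steps = sampler.burn_in + n_keep * sampler.thin
    for step_no in range(total_steps):
        prop = z + rng.normal(0.0, sampler.step, size=z.shape)
        u_prop = total_u(prop)
        accept = rng.random(z.shape) < np.exp(np.minimum(0.0, -(u_prop - u_cur) / rt))
        z = np.where(accept, prop, z)
        u_cur = np.where(accept, u_prop, u_cur)
        if step_no >= sampler.burn_in and (step_no - sampler.burn_in) % sampler.thin == sampler.thin - 1:
            samples[kept] = z
            kept += 1
    for i, w in enumerate(windows):
        w.samples = samples[:, i].copy()
    return windows


# ---------------------------------------------------------------------------
# ideal backbone builder (NeRF internal-coordinate placement)

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "N-H": 1.01}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}
_ELEMENT_MASS = {"N": 14.007, "C": 12.011, "O": 15.999, "H": 1.008}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom D given A-B-C, |CD|, ∠BCD and dihedral A-B-C-D."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(dihedral),
                        bond * np.sin(angle) * np.sin(dihedral)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(dihedrals: list[tuple[float, float]], chain_id: str = "A",
                with_hydrogens: bool = True) -> Structure:
    """Polyalanine backbone from per-residue (φ, ψ); ω fixed at 180°."""
    n_res = len(dihedrals)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    for phi, psi in dihedrals:
        if not (np.isfinite(phi) and np.isfinite(psi)):
            raise ValueError("dihedrals must be finite")

    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    ang = np.radians(_ANGLE["N-CA-C"])
    c_pos = [ca_pos[0] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        psi_prev = dihedrals[i - 1][1]
        n_i = _place(n_pos[-1], ca_pos[-1], c_pos[-1],
                     _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        ca_i = _place(ca_pos[-1], c_pos[-1], n_i,
                      _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        c_i = _place(c_pos[-1], n_i, ca_i,
                     _BOND["CA-C"], _ANGLE["N-CA-C"], dihedrals[i][0])
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)
    o_pos = []
    for i in range(n_res):
        if i < n_res - 1:
            o_i = _place(n_pos[i + 1], ca_pos[i], c_pos[i],
                         _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
        else:
            o_i = _place(n_pos[i], ca_pos[i], c_pos[i],
                         _BOND["C-O"], _ANGLE["CA-C-O"], dihedrals[i][1] + 180.0)
        o_pos.append(o_i)

    atoms: list[Atom] = []
    for i in range(n_res):
        resnum = i + 1
        entries = [("N", "N", n_pos[i]), ("CA", "C", ca_pos[i]),
                   ("C", "C", c_pos[i]), ("O", "O", o_pos[i])]
        if with_hydrogens and i > 0:
            u = c_pos[i - 1] - n_pos[i]
            v = ca_pos[i] - n_pos[i]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            h = n_pos[i] - _BOND["N-H"] * (u + v) / np.linalg.norm(u + v)
            entries.append(("H", "H", h))
        for name, element, pos in entries:
            atoms.append(Atom(name, element, resnum, "ALA", chain_id, pos,
                              _ELEMENT_MASS[element]))
    return Structure(atoms)


def build_helix_coords(n_residues: int, phi: float = -57.0,
                       psi: float = -47.0, chain_id: str = "A",
                       with_hydrogens: bool = True) -> Structure:
    """Ideal uniform-dihedral backbone; defaults give an α-helix."""
    if not (2 <= n_residues <= 1000):
        raise ValueError("n_residues must be in [2, 1000]")
    return build_chain([(phi, psi)] * n_residues, chain_id, with_hydrogens)


# ---------------------------------------------------------------------------
# binding curves and energy tables

@dataclass(frozen=True)
class BindingCurveSpec:
    """Ground-truth parameters for synthetic dose–response tables."""

    affinities: PeptideAffinities = field(default_factory=PeptideAffinities)
    ca_params: CaBindingParams = field(default_factory=CaBindingParams)
    actin_uM: float = 5.0
    pevk_uM: float = 1.0
    k_ap_uM: float = 0.5
    # the three Ca²⁺ conditions of the prediction figure (pCa 7, 5, 4);
    # fewer distinct Ca²⁺ levels leave the per-state constants on a ridge
    pca_list: tuple[float, ...] = (7.0, 5.0, 4.0)
    # the emulated assay doses S100A1 up to levels comparable to its total
    # Ca²⁺ pool, so Ca²⁺ depletion along the dose axis is part of the signal
    ca_depleted: bool = True
    n_replicates: int = 3      # standard triplicate measurements per dose
    s100_grid_uM: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0,
                                       5.0, 10.0, 20.0, 50.0, 100.0)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def generate_binding_curves(spec: BindingCurveSpec
                            ) -> tuple[pd.DataFrame, dict]:
    """Noisy f_AP dose–response table plus the generating ground truth.

    Gaussian noise of sd ``spec.noise_sd`` is added to the solved f_AP and
    clipped to [0, 1].  The ground-truth record carries every generating
    parameter for downstream recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for pca in spec.pca_list:
        clean = dose_response(np.array(spec.s100_grid_uM), spec.actin_uM,
                              spec.pevk_uM, pca, spec.ca_params,
                              spec.affinities, spec.k_ap_uM,
                              ca_depleted=spec.ca_depleted)
        for rep in range(spec.n_replicates):
            noisy = clean.copy()
            noisy["replicate"] = rep
            noisy["f_AP_true"] = clean["f_AP"]
            noisy["f_AP"] = np.clip(
                clean["f_AP"] + rng.normal(0.0, spec.noise_sd, len(clean)),
                0.0, 1.0)
            frames.append(noisy[["s100_total_uM", "pCa", "replicate",
                                 "f_AP", "f_AP_true"]])
    table = pd.concat(frames, ignore_index=True)
    truth = {
        "kd1_uM": spec.affinities.kd1_uM,
        "kd2_uM": spec.affinities.kd2_uM,
        "kd2p_uM": spec.affinities.kd2p_uM,
        "kd_cef_uM": spec.ca_params.kd_cef_uM,
        "kd_pef_uM": spec.ca_params.kd_pef_uM,
        "actin_uM": spec.actin_uM,
        "pevk_uM": spec.pevk_uM,
        "k_ap_uM": spec.k_ap_uM,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return table, truth


def generate_energy_tables(n_frames: int, residues: list[tuple[str, int]],
                           offsets: dict[tuple[str, int], float],
                           noise: float = 0.0, seed: int = 0
                           ) -> tuple[EnergyTable, list[EnergyTable], dict]:
    """Dimer + monomer energy tables with planted interaction offsets.

    The dimer's per-residue mean total exceeds the matching monomer's by the
    planted offset (kcal/mol); iid Gaussian noise of sd ``noise`` is added
    per frame and term.  Residues are assigned to monomers by chain.
    Returns (dimer, [monomers...], ground truth).
    """
    rng = np.random.default_rng(seed)
    chains = sorted({ch for ch, _ in residues})
    base = {r: rng.uniform(-20.0, 0.0, size=3) for r in residues}

    def make_rows(residue_list, with_offsets):
        rows = []
        for frame in range(n_frames):
            for r in residue_list:
                e = base[r] + rng.normal(0.0, noise, size=3)
                if with_offsets:
                    e = e + np.array([offsets.get(r, 0.0), 0.0, 0.0])
                rows.append({"frame": frame, "chain": r[0], "residue": r[1],
                             **dict(zip(ENERGY_TERMS, e))})
        return pd.DataFrame(rows)

    dimer = EnergyTable(make_rows(residues, True), "dimer")
    monomers = [EnergyTable(make_rows([r for r in residues if r[0] == ch], False),
                            f"monomer{ch}") for ch in chains]
    truth = {"offsets": {f"{ch}:{rn}": offsets.get((ch, rn), 0.0)
                         for ch, rn in residues},
             "noise": noise, "seed": seed, "n_frames": n_frames}
    return dimer, monomers, truth
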