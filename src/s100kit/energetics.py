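"""Per-residue interaction energy bookkeeping for end-point (MM-GBSA style)
dimerisation energies.

The solvation-model evaluation itself happens upstream (e.g. MMPBSA.py);
this module consumes per-frame, per-residue tables of the three retained
terms — electrostatics (E_EEL), van der Waals (E_vdW) and solvation
(E_solv); bonded terms are excluded upstream — and forms the ensemble
difference

    ΔG(residue) = ⟨E_EEL + E_vdW + E_solv⟩_dimer − ⟨same⟩_monomer

whose sum over residues is the total ⟨G_dimer⟩ − ⟨G_monomers⟩.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EnergyTable", "per_residue_interaction_delta"]

ENERGY_TERMS = ["E_EEL", "E_vdW", "E_solv"]
_KEY = ["chain", "residue"]


@dataclass
class EnergyTable:
    """Per-frame, per-residue energy terms (kcal/mol) for one system.

    ``data`` columns: frame, chain, residue, E_EEL, E_vdW, E_solv.
    ``system`` labels the ensemble (e.g. "dimer", "monomerA", "monomerB").
    """

    data: pd.DataFrame
    system: str

    def __post_init__(self) -> None:
        missing = [c for c in ["frame", *_KEY, *ENERGY_TERMS]
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"EnergyTable missing columns: {missing}")
        per_res = self.data.groupby(_KEY)["frame"].count()
        if per_res.nunique() > 1:
            raise ValueError("inconsistent frame counts across residues")

    @classmethod
    def from_csv(cls, path: str | Path, system: str) -> "EnergyTable":
        return cls(pd.read_csv(path), system)

    def residues(self) -> list[tuple[str, int]]:
        return list(self.data.groupby(_KEY, sort=False).groups)

    def total_per_frame(self) -> pd.Series:
        """Summed energy over residues, per frame (houses ⟨G⟩)."""
        tot = self.data.assign(total=self.data[ENERGY_TERMS].sum(axis=1))
        return tot.groupby("frame")["total"].sum()

    def mean_total(self) -> float:
        return float(self.total_per_frame().mean())


def per_residue_interaction_delta(dimer: EnergyTable,
                                  monomers: list[EnergyTable]) -> pd.DataFrame:
    """Per-residue ΔG contribution of dimerisation, with spread.

    The monomers' residue sets must partition the dimer's.  Returns a tidy
    frame (chain, residue, delta, sd): ``delta`` is the difference of the
    frame-averaged per-residue totals and ``sd`` the frame-wise standard
    deviations of the two ensembles combined in quadrature.
    """
    dimer_res = set(dimer.residues())
    mono_res: set[tuple[str, int]] = set()
    for m in monomers:
        r = set(m.residues())
        if r & mono_res:
            raise ValueError("monomer residue sets overlap")
        mono_res |= r
    if mono_res != dimer_res:
        raise ValueError("monomer residues do not partition the dimer's residues")

    def stats(table: EnergyTable) -> pd.DataFrame:
        d = table.data.assign(total=table.data[ENERGY_TERMS].sum(axis=1))
        g = d.groupby(_KEY)["total"]
        return pd.DataFrame({"mean": g.mean(), "var": g.var(ddof=0)})

    dim = stats(dimer)
    mono = pd.concat([stats(m) for m in monomers])
    out = dim.join(mono, lsuffix="_dim", rsuffix="_mono")
    result = pd.DataFrame({
        "delta": out["mean_dim"] - out["mean_mono"],
        "sd": np.sqrt(out["var_dim"] + out["var_mono"]),
    }).reset_index()
    return result.sort_values(_KEY, ignore_index=True)
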