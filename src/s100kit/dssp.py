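"""α-helix assignment via the Kabsch–Sander hydrogen-bond criterion.

Only the H (α-helix) state is needed here: the observable is the per-residue
probability over a trajectory that a residue belongs to an α-helix, applied
in this package to the C-terminal stretch of helix 4 (C85–S93), whose
folding tracks Ca²⁺ activation of S100A1.

A backbone hydrogen bond between the C=O of residue *i* and the N–H of
residue *j* is scored with the Kabsch–Sander electrostatic model

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   [kcal/mol]

and accepted when E < −0.5 kcal/mol.  A 4-turn exists at *i* when
CO(i)→NH(i+4) is bonded; residues i..i+3 are α-helical when 4-turns exist at
both i−1 and i (two consecutive i→i+4 bonds — the standard minimal-helix
rule).  Missing amide hydrogens are reconstructed 1.01 Å from N opposite the
bisector of the N–C(prev) and N–Cα bonds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structure import Structure, Trajectory

__all__ = ["assign_helix", "helicity", "kabsch_sander_energy"]

_Q_FACTOR = 0.084 * 332.0          # kcal/mol·Å, Kabsch–Sander coupling
_HBOND_CUTOFF = -0.5               # kcal/mol
_MIN_DIST = 0.5                    # Å; closer contacts clamp to a strong bond


def kabsch_sander_energy(c: np.ndarray, o: np.ndarray,
                         n: np.ndarray, h: np.ndarray) -> float:
    """Kabsch–Sander H-bond energy (kcal/mol) for acceptor C=O, donor N–H."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return -9.9
    return _Q_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _chain_backbone(structure: Structure, chain_id: str):
    """Per-residue backbone atom positions (N, CA, C, O, H-or-None)."""
    residues: dict[int, dict[str, np.ndarray]] = {}
    order: list[int] = []
    for a in structure.atoms:
        if a.chain_id != chain_id:
            continue
        if a.residue_number not in residues:
            residues[a.residue_number] = {}
            order.append(a.residue_number)
        if a.name in ("N", "CA", "C", "O", "H", "HN"):
            key = "H" if a.name == "HN" else a.name
            residues[a.residue_number].setdefault(key, a.position)
    out = []
    for rn in order:
        r = residues[rn]
        if not all(k in r for k in ("N", "CA", "C", "O")):
            raise ValueError(f"chain {chain_id} residue {rn}: missing backbone atoms")
        out.append((rn, r))
    return out


def _amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    u = c_prev - n
    v = ca - n
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    bisector = u + v
    norm = np.linalg.norm(bisector)
    if norm < 1e-8:                 # degenerate (collinear) geometry
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        bisector, norm = perp, np.linalg.norm(perp)
    return n - 1.01 * bisector / norm


def assign_helix(structure: Structure, chain_id: str | None = None) -> dict[tuple[str, int], bool]:
    """Map (chain, residue_number) -> is α-helix for one frame."""
    chains = [chain_id] if chain_id else structure.chain_ids
    result: dict[tuple[str, int], bool] = {}
    for ch in chains:
        bb = _chain_backbone(structure, ch)
        n_res = len(bb)
        hpos: list[np.ndarray | None] = []
        for k, (rn, r) in enumerate(bb):
            if "H" in r:
                hpos.append(r["H"])
            elif k > 0:
                hpos.append(_amide_h(r["N"], r["CA"], bb[k - 1][1]["C"]))
            else:
                hpos.append(None)   # N-terminal amide: no donor
        turn4 = np.zeros(n_res, dtype=bool)
        for i in range(n_res - 4):
            j = i + 4
            if hpos[j] is None:
                continue
            e = kabsch_sander_energy(bb[i][1]["C"], bb[i][1]["O"],
                                     bb[j][1]["N"], hpos[j])
            turn4[i] = e < _HBOND_CUTOFF
        is_h = np.zeros(n_res, dtype=bool)
        for i in range(1, n_res):
            if turn4[i - 1] and turn4[i]:
                is_h[i:i + 4] = True
        for k, (rn, _) in enumerate(bb):
            result[(ch, rn)] = bool(is_h[k])
    return result


def helicity(trajectory: Trajectory, residue_range: tuple[int, int] = (85, 93),
             chain_id: str | None = None) -> pd.DataFrame:
    """Per-residue α-helix probability over a trajectory.

    Returns a tidy frame (chain, residue, helicity) restricted to
    ``residue_range`` (inclusive; default C85–S93, the H4 C-terminus).
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    lo, hi = residue_range
    acc: dict[tuple[str, int], int] = {}
    for frame in trajectory.frames:
        s = trajectory.topology.with_coords(frame)
        for key, flag in assign_helix(s, chain_id).items():
            if lo <= key[1] <= hi:
                acc[key] = acc.get(key, 0) + int(flag)
    rows = [{"chain": ch, "residue": rn, "helicity": cnt / len(trajectory)}
            for (ch, rn), cnt in sorted(acc.items())]
    return pd.DataFrame(rows)
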