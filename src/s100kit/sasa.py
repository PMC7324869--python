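"""Shrake–Rupley solvent-accessible surface area.

Each atom is inflated by the probe radius (water, 1.4 Å) and covered with a
deterministic quasi-uniform point mesh (golden-spiral lattice); the
accessible fraction is the share of mesh points outside every neighbouring
inflated sphere.  Points on the surface of one sphere that fall exactly on
another sphere's surface count as occluded (strict interior test with a
small tolerance is avoided by using <).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .structure import Structure

__all__ = ["sasa", "atom_sasa", "VDW_RADII"]

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "CA": 2.31, "MG": 1.73, "ZN": 1.39, "NA": 2.27, "K": 2.75, "FE": 1.94,
}
DEFAULT_RADIUS = 1.70


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral lattice of n quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def _radii(structure: Structure, radii: dict[str, float] | None,
           default_radius: float) -> np.ndarray:
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    out = np.empty(len(structure))
    for i, a in enumerate(structure.atoms):
        el = a.element.upper()
        if el not in table:
            warnings.warn(f"unknown element {el!r}; using default radius "
                          f"{default_radius} Å", stacklevel=2)
        out[i] = table.get(el, default_radius)
    return out


def atom_sasa(structure: Structure, probe: float = 1.4, n_points: int = 960,
              radii: dict[str, float] | None = None,
              default_radius: float = DEFAULT_RADIUS) -> np.ndarray:
    """Per-atom SASA in Å²."""
    coords = structure.coords
    r = _radii(structure, radii, default_radius) + probe
    mesh = _sphere_points(n_points)
    n = len(coords)
    areas = np.empty(n)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    for i in range(n):
        neighbours = np.where((d[i] < r[i] + r) & (np.arange(n) != i))[0]
        pts = coords[i] + r[i] * mesh
        if neighbours.size:
            dd = np.linalg.norm(pts[:, None, :] - coords[neighbours][None, :, :], axis=2)
            free = np.all(dd >= r[neighbours][None, :], axis=1)
        else:
            free = np.ones(n_points, dtype=bool)
        areas[i] = 4.0 * np.pi * r[i] ** 2 * free.mean()
    return areas


def sasa(structure: Structure, probe: float = 1.4, n_points: int = 960,
         radii: dict[str, float] | None = None,
         default_radius: float = DEFAULT_RADIUS) -> pd.DataFrame:
    """Per-residue SASA (Å²) as a tidy frame (chain, residue, sasa)."""
    per_atom = atom_sasa(structure, probe, n_points, radii, default_radius)
    acc: dict[tuple[str, int], float] = {}
    for a, area in zip(structure.atoms, per_atom):
        key = (a.chain_id, a.residue_number)
        acc[key] = acc.get(key, 0.0) + area
    rows = [{"chain": ch, "residue": rn, "sasa": v}
            for (ch, rn), v in acc.items()]
    return pd.DataFrame(rows)
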