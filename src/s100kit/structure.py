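"""Molecular structure containers and PDB / time-series I/O.

Lightweight, order-stable containers for NMR-style multi-model PDB
structures (the S100A1 reference structures 2L0P, 2LP3, 2KBM, ... are
multi-model NMR ensembles) plus atom selection.  Parsing is delegated to
Biopython; the containers here are plain arrays so every downstream metric
can operate on them without carrying a Bio.PDB hierarchy around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "read_pdb",
    "read_trajectory_pdb",
    "write_pdb",
    "count_models",
    "select",
    "read_window_series",
]

# Fallback masses (amu) for elements Biopython cannot resolve.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CA": 40.078, "ZN": 65.38, "MG": 24.305, "FE": 55.845,
    "NA": 22.990, "K": 39.098, "CL": 35.45,
}
_DEFAULT_MASS = 12.011


@dataclass(frozen=True)
class Atom:
    """A single atom with PDB author numbering.

    ``residue_number`` is the author residue number (1-based), matching the
    residue labels used for S100A1 (K30, T39, E73, A84, C85, A53 ...).
    """

    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")


@dataclass
class Structure:
    """An ordered list of atoms from one model of a PDB file."""

    atoms: list[Atom]
    model_index: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_number, residue_name) triples."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_number, a.residue_name), None)
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.name, a.element, a.residue_number, a.residue_name,
                 a.chain_id, coords[i], a.mass)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, self.model_index)


@dataclass
class Trajectory:
    """A frame sequence sharing one topology.

    Every frame is an (n_atoms, 3) array in Å with the same atom order as
    ``topology``.
    """

    topology: Structure
    frames: list[np.ndarray]
    frame_stride: float | None = None

    def __post_init__(self) -> None:
        n = len(self.topology)
        clean = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {i}: expected shape ({n}, 3), got {f.shape}")
            clean.append(f)
        self.frames = clean

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def xyz(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack(self.frames)


@dataclass(frozen=True)
class Selection:
    """Declarative atom filter.

    All criteria are combined with AND; a ``None`` field matches everything.
    ``residue_range`` is inclusive on both ends and uses author numbering.
    """

    chain_id: str | None = None
    residue_range: tuple[int, int] | None = None
    residue_numbers: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None

    @staticmethod
    def of(chain_id: str | None = None,
           residue_range: tuple[int, int] | None = None,
           residue_numbers: Iterable[int] | None = None,
           atom_names: Iterable[str] | str | None = None) -> "Selection":
        if isinstance(atom_names, str):
            atom_names = [atom_names]
        return Selection(
            chain_id=chain_id,
            residue_range=tuple(residue_range) if residue_range else None,
            residue_numbers=frozenset(residue_numbers) if residue_numbers else None,
            atom_names=frozenset(atom_names) if atom_names else None,
        )

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_number <= hi):
                return False
        if self.residue_numbers is not None and atom.residue_number not in self.residue_numbers:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True


def select(structure: Structure, selection: Selection) -> list[int]:
    """Resolve a selection to atom indices in topology order.

    Idempotent and order-stable; an empty result is legal.
    """
    return [i for i, a in enumerate(structure.atoms) if selection.matches(a)]


def _atom_mass(bio_atom) -> float:
    m = getattr(bio_atom, "mass", None)
    if m is not None and np.isfinite(m) and m > 0:
        return float(m)
    elem = (bio_atom.element or "").upper()
    return _MASSES.get(elem, _DEFAULT_MASS)


def _parse(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    return parser.get_structure(path.stem, str(path))


def _model_to_structure(model, model_ordinal: int) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                # disordered atoms: Biopython's selected child is the
                # highest-occupancy altloc (first on tie)
                if atom.is_disordered():
                    atom = atom.selected_child
                atoms.append(Atom(
                    name=atom.get_name(),
                    element=(atom.element or "").strip() or atom.get_name()[0],
                    residue_number=residue.id[1],
                    residue_name=residue.get_resname().strip(),
                    chain_id=chain.id,
                    position=np.asarray(atom.get_coord(), dtype=float),
                    mass=_atom_mass(atom),
                ))
    if not atoms:
        raise ValueError("model contains no atoms")
    return Structure(atoms, model_index=model_ordinal)


def count_models(path: str | Path) -> int:
    """Number of models in a (possibly multi-model) PDB file."""
    return len(list(_parse(path)))


def read_pdb(path: str | Path, model: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``model`` is the 1-based ordinal of the MODEL block (NMR ensembles store
    one conformer per block; single-model files have exactly one).
    """
    bio = _parse(path)
    models = list(bio)
    if not models:
        raise ValueError(f"{path}: no models found")
    if not (1 <= model <= len(models)):
        raise IndexError(f"{path}: model {model} out of range (1..{len(models)})")
    return _model_to_structure(models[model - 1], model)


def read_trajectory_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB as a trajectory (model 1 is the topology)."""
    bio = _parse(path)
    models = list(bio)
    if not models:
        raise ValueError(f"{path}: no models found")
    top = _model_to_structure(models[0], 1)
    frames = [top.coords]
    for k, m in enumerate(models[1:], start=2):
        s = _model_to_structure(m, k)
        if len(s) != len(top):
            raise ValueError(f"{path}: model {k} atom count differs from model 1")
        frames.append(s.coords)
    return Trajectory(top, frames)


def write_pdb(structure_or_trajectory, path: str | Path) -> None:
    """Write a Structure (single MODEL) or Trajectory (one MODEL per frame)."""
    path = Path(path)
    if isinstance(structure_or_trajectory, Trajectory):
        traj = structure_or_trajectory
        models = [(i + 1, traj.topology.with_coords(f)) for i, f in enumerate(traj.frames)]
    else:
        models = [(1, structure_or_trajectory)]
    lines: list[str] = []
    for model_no, s in models:
        lines.append(f"MODEL     {model_no:4d}")
        for serial, a in enumerate(s.atoms, start=1):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {a.residue_name:>3s} {a.chain_id:1s}"
                f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_window_series(path: str | Path, time_column: bool = False) -> np.ndarray:
    """Read one umbrella window's reaction-coordinate samples (Å).

    One numeric value per row; with ``time_column=True`` rows hold
    ``time value`` pairs (whitespace or comma separated) and only the second
    column is kept.  Raises ``ValueError`` naming the offending line for any
    non-numeric row, and for an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            token = fields[1] if time_column and len(fields) > 1 else fields[0]
            try:
                values.append(float(token))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {token!r}") from None
    if not values:
        raise ValueError(f"{path}: no samples found")
    return np.asarray(values, dtype=float)
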