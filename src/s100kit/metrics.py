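"""Structural metrics on structures and trajectories.

The opening of the S100A1 target-binding cleft is tracked by the H3/H4
inter-helix angle: the angle at the hinge centroid (Cα of L61–D62 and
Q72–E73) between rays to the Cα atoms of A53 (helix 3) and C85 (helix 4).
The other operators here — Kabsch superposition RMSD, backbone RMSF,
residue contact maps, hydrogen-bond counting and hierarchical clustering of
frames — are the standard post-processing toolkit for the gating
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .structure import Selection, Structure, Trajectory, select

__all__ = [
    "AngleDefinition",
    "ContactMap",
    "ClusterResult",
    "helix_angle",
    "superpose",
    "superpose_rmsd",
    "rmsf",
    "contact_map",
    "hbond_count",
    "cluster_frames",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class AngleDefinition:
    """H3/H4 opening angle: two Cα rays about a hinge-centroid vertex.

    Defaults follow the S100A1 definition: rays to Cα of A53 and C85, vertex
    at the centroid of the Cα atoms of residues 61–62 and 72–73.
    """

    ray1_atom: Selection = field(
        default_factory=lambda: Selection.of(residue_numbers=[53], atom_names="CA"))
    ray2_atom: Selection = field(
        default_factory=lambda: Selection.of(residue_numbers=[85], atom_names="CA"))
    vertex_residues: Selection = field(
        default_factory=lambda: Selection.of(residue_numbers=[61, 62, 72, 73],
                                             atom_names="CA"))

    def restricted_to_chain(self, chain_id: str) -> "AngleDefinition":
        def on_chain(sel: Selection) -> Selection:
            return Selection(chain_id=chain_id, residue_range=sel.residue_range,
                             residue_numbers=sel.residue_numbers,
                             atom_names=sel.atom_names)
        return AngleDefinition(on_chain(self.ray1_atom), on_chain(self.ray2_atom),
                               on_chain(self.vertex_residues))


def helix_angle(structure: Structure, definition: AngleDefinition | None = None,
                chain_id: str | None = None) -> float:
    """Inter-helix opening angle in degrees, in [0, 180].

    The vertex is the geometric centroid of the hinge Cα atoms; the angle is
    measured between the vertex→ray1 and vertex→ray2 directions.
    """
    definition = definition or AngleDefinition()
    if chain_id is not None:
        definition = definition.restricted_to_chain(chain_id)
    coords = structure.coords

    def one_atom(sel: Selection, label: str) -> np.ndarray:
        idx = select(structure, sel)
        if len(idx) != 1:
            raise ValueError(f"{label} selection resolves to {len(idx)} atoms, need exactly 1")
        return coords[idx[0]]

    vertex_idx = select(structure, definition.vertex_residues)
    if not vertex_idx:
        raise ValueError("vertex selection resolves to no atoms")
    vertex = coords[vertex_idx].mean(axis=0)
    v1 = one_atom(definition.ray1_atom, "ray1") - vertex
    v2 = one_atom(definition.ray2_atom, "ray2") - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("ray atom coincides with vertex")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kabsch optimal superposition of ``mobile`` onto ``reference``.

    Returns (rotation R, translation t) with fit = mobile @ R.T + t, plus the
    transformed coordinates.  Proper rotation enforced (det +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have equal shapes")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t, mobile @ R.T + t


def superpose_rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
                   indices: list[int] | None = None
                   ) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares RMSD of frame_a vs frame_b after optimal superposition.

    ``indices`` restricts both the fit and the RMSD to a subset of atoms.
    Returns (rmsd Å, rotation, translation).
    """
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if indices is not None:
        a, b = a[indices], b[indices]
    if a.shape != b.shape:
        raise ValueError("selected atom counts differ")
    if len(a) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    R, t, fit = superpose(a, b)
    rmsd = float(np.sqrt(np.mean(np.sum((fit - b) ** 2, axis=1))))
    return rmsd, R, t


def _aligned_frames(xyz: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Align frames onto their mean structure (one mean-refinement pass)."""
    ref = xyz[0]
    aligned = np.empty_like(xyz)
    for pass_no in range(2):
        for i, f in enumerate(xyz):
            R, t, _ = superpose(f[fit_idx], ref[fit_idx])
            aligned[i] = f @ R.T + t
        ref = aligned.mean(axis=0)
        xyz = aligned.copy()
    return aligned


def rmsf(trajectory: Trajectory, selection: Selection | None = None,
         align_selection: Selection | None = None) -> pd.DataFrame:
    """Per-residue RMSF (Å) of backbone atoms after superposition.

    Frames are superposed onto the mean structure (initial reference: frame
    1, with one mean-refinement iteration).  The fluctuation of each residue
    is the root of the mean squared deviation pooled over its selected
    atoms.  ``align_selection`` defaults to ``selection`` (default:
    backbone N/CA/C/O everywhere).
    """
    if len(trajectory) < 2:
        raise ValueError("RMSF requires at least 2 frames")
    top = trajectory.topology
    selection = selection or Selection.of(atom_names=BACKBONE_ATOMS)
    idx = np.asarray(select(top, selection), dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    fit_idx = idx if align_selection is None else np.asarray(
        select(top, align_selection), dtype=int)
    aligned = _aligned_frames(trajectory.xyz, fit_idx)
    mean = aligned.mean(axis=0)
    msf_atom = np.mean(np.sum((aligned[:, idx] - mean[idx]) ** 2, axis=2), axis=0)

    rows = []
    keys = [(top.atoms[i].chain_id, top.atoms[i].residue_number) for i in idx]
    frame = pd.DataFrame({"chain": [k[0] for k in keys],
                          "residue": [k[1] for k in keys],
                          "msf": msf_atom})
    for (chain, res), grp in frame.groupby(["chain", "residue"], sort=False):
        rows.append({"chain": chain, "residue": res,
                     "rmsf": float(np.sqrt(grp["msf"].mean()))})
    return pd.DataFrame(rows)


@dataclass
class ContactMap:
    """Residue–residue contact frequencies over a trajectory."""

    residues: list[tuple[str, int, str]]
    frequency: np.ndarray          # symmetric, [0, 1]
    cutoff: float = 7.0
    min_separation: int = 6

    @property
    def n_residues(self) -> int:
        return len(self.residues)


def contact_map(trajectory: Trajectory, cutoff: float = 7.0,
                min_separation: int = 6, heavy_only: bool = True) -> ContactMap:
    """Fraction of frames in which residue pairs are in contact.

    Two residues are in contact when their minimum inter-atomic distance
    (heavy atoms by default) is ≤ ``cutoff`` (closed boundary).  Pairs closer
    than ``min_separation`` in sequence on the same chain are excluded;
    inter-chain pairs are always eligible.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    top = trajectory.topology
    residues = top.residues()
    res_index = {r: k for k, r in enumerate(residues)}
    atom_res = np.array([res_index[(a.chain_id, a.residue_number, a.residue_name)]
                         for a in top.atoms])
    keep = np.ones(len(top.atoms), dtype=bool)
    if heavy_only:
        keep = np.array([a.element.upper() != "H" for a in top.atoms])

    n = len(residues)
    # eligibility mask: same-chain pairs need |i-j| >= min_separation in
    # sequence position within that chain; different chains always eligible
    chain_of = np.array([hash(r[0]) for r in residues])
    seq_pos = np.zeros(n, dtype=int)
    counter: dict[str, int] = {}
    for k, r in enumerate(residues):
        counter[r[0]] = counter.get(r[0], -1) + 1
        seq_pos[k] = counter[r[0]]
    same_chain = chain_of[:, None] == chain_of[None, :]
    sep = np.abs(seq_pos[:, None] - seq_pos[None, :])
    eligible = (~same_chain) | (sep >= min_separation)
    np.fill_diagonal(eligible, False)

    counts = np.zeros((n, n))
    atom_idx = np.where(keep)[0]
    groups = [atom_idx[atom_res[atom_idx] == k] for k in range(n)]
    for frame in trajectory.frames:
        d = cdist(frame[atom_idx], frame[atom_idx])
        res_of = atom_res[atom_idx]
        mind = np.full((n, n), np.inf)
        # reduce atom-pair distances to residue-pair minima
        for i in range(n):
            sel_i = res_of == i
            if not sel_i.any():
                continue
            di = d[sel_i]
            for j in range(i + 1, n):
                sel_j = res_of == j
                if not sel_j.any():
                    continue
                mind[i, j] = mind[j, i] = di[:, sel_j].min()
        counts += (mind <= cutoff) & eligible
    freq = counts / len(trajectory)
    return ContactMap(residues, freq, cutoff, min_separation)


def hbond_count(structure: Structure, donors: list[tuple[int, int]] | None = None,
                acceptors: list[int] | None = None, d_cut: float = 3.5,
                angle_cut: float = 135.0) -> int:
    """Count hydrogen bonds by geometric criteria.

    ``donors`` are (heavy-atom index, hydrogen index) pairs and ``acceptors``
    are heavy-atom indices; when omitted they are detected as N/O atoms with
    a covalently attached hydrogen (< 1.25 Å) and as N/O atoms respectively.
    A bond requires donor–acceptor distance ≤ ``d_cut`` and D–H···A angle
    ≥ ``angle_cut`` (degrees).
    """
    coords = structure.coords
    elements = [a.element.upper() for a in structure.atoms]
    if donors is None or acceptors is None:
        heavy = [i for i, e in enumerate(elements) if e in ("N", "O")]
        hydro = [i for i, e in enumerate(elements) if e == "H"]
        if donors is None:
            donors = []
            for d in heavy:
                for h in hydro:
                    if np.linalg.norm(coords[d] - coords[h]) < 1.25:
                        donors.append((d, h))
        if acceptors is None:
            acceptors = list(heavy)
    count = 0
    for d, h in donors:
        for a in acceptors:
            if a == d:
                continue
            r_da = np.linalg.norm(coords[d] - coords[a])
            if r_da > d_cut:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            ang = np.degrees(np.arccos(np.clip(np.dot(v1, v2) / denom, -1, 1)))
            if ang >= angle_cut:
                count += 1
    return count


@dataclass
class ClusterResult:
    """Hierarchical clustering of trajectory frames.

    Clusters are ordered by decreasing population; ``labels[f]`` is the
    ordered cluster id of frame ``f`` and ``representatives[c]`` the medoid
    frame (minimum summed RMSD to its cluster, ties to the lower index).
    """

    labels: np.ndarray
    sizes: np.ndarray
    representatives: np.ndarray
    rmsd_matrix: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def least_populated(self, k: int) -> np.ndarray:
        """Representative frames of the k least-populated clusters."""
        smallest = sorted(range(self.n_clusters), key=lambda c: (self.sizes[c], -c))[:k]
        return self.representatives[smallest]


def cluster_frames(trajectory: Trajectory, n_clusters: int,
                   selection: Selection | None = None) -> ClusterResult:
    """Agglomerative (average-linkage) clustering on pairwise best-fit RMSD."""
    n = len(trajectory)
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds frame count {n}")
    top = trajectory.topology
    idx = None
    if selection is not None:
        idx = select(top, selection)
        if len(idx) < 3:
            raise ValueError("selection too small for superposition")
    xyz = trajectory.xyz
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = superpose_rmsd(xyz[i], xyz[j], idx)[0]
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    raw_ids = sorted(set(raw), key=lambda c: (-np.sum(raw == c), np.argmax(raw == c)))
    remap = {c: k for k, c in enumerate(raw_ids)}
    labels = np.array([remap[c] for c in raw])
    sizes = np.array([np.sum(labels == k) for k in range(len(raw_ids))])
    reps = np.empty(len(raw_ids), dtype=int)
    for k in range(len(raw_ids)):
        members = np.where(labels == k)[0]
        within = D[np.ix_(members, members)].sum(axis=1)
        reps[k] = members[np.argmin(within)]   # argmin takes the lowest index on ties
    return ClusterResult(labels, sizes, reps, D)
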