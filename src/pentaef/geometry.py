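"""Geometric primitives: helix-axis fitting, inter-helix angles, rigid
superposition, per-region RMSD, distances and hydrogen-bond detection.

The helix axis is the first principal component of the Cα point cloud, with
the sign fixed so it points from the N- to the C-terminal end of the helix.
On regular α-helices this agrees with PyMOL-style axis fits to within a
degree or two, which is why angle comparisons downstream carry a ±3°
tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import AtomRecord, Residue, ResidueSelector, Structure

__all__ = [
    "HelixAxis",
    "SuperpositionResult",
    "HydrogenBond",
    "fit_helix_axis",
    "interhelix_angle",
    "kabsch_superpose",
    "region_rmsd",
    "atom_distance",
    "find_hbonds",
]


@dataclass
class HelixAxis:
    """Fitted helix direction (unit vector, N→C) with centroid and fit quality."""

    direction: np.ndarray
    centroid: np.ndarray
    fit_rms: float
    n_atoms: int

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        self.centroid = np.asarray(self.centroid, float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"helix direction not unit length (|d| = {norm})")
        if self.n_atoms < 4:
            raise ValueError("helix axis must be fitted on at least 4 atoms")


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit: x_target ≈ rotation @ x_mobile + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class HydrogenBond:
    donor_residue: Residue
    donor_atom: AtomRecord
    acceptor_residue: Residue
    acceptor_atom: AtomRecord
    distance: float

    def label(self) -> str:
        return (
            f"{self.donor_atom.atom_name} {self.donor_residue.label()}"
            f" - {self.acceptor_atom.atom_name} {self.acceptor_residue.label()}"
        )


def fit_helix_axis(ca_coords: np.ndarray | Sequence[Sequence[float]]) -> HelixAxis:
    """Fit the principal axis of an ordered Cα trace.

    The direction is the leading right-singular vector of the centred
    coordinates; its sign is chosen so the axis points from the first to the
    last residue.  ``fit_rms`` is the RMS perpendicular distance of the
    points from the fitted line.
    """
    coords = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    if len(coords) < 4:
        raise ValueError(f"need at least 4 Cα positions to fit a helix axis, got {len(coords)}")
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    # orient N-terminus -> C-terminus
    if np.dot(coords[-1] - coords[0], direction) < 0:
        direction = -direction
    residual = centred - np.outer(centred @ direction, direction)
    fit_rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return HelixAxis(direction=direction, centroid=centroid, fit_rms=fit_rms, n_atoms=len(coords))


def interhelix_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Angle in degrees [0, 180] between two directed helix axes."""
    cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns the proper rotation and translation mapping *mobile* onto
    *target*, and the RMSD after the transform.
    """
    mob = np.asarray(mobile, float).reshape(-1, 3)
    tgt = np.asarray(target, float).reshape(-1, 3)
    if mob.shape != tgt.shape:
        raise ValueError(f"point sets differ in size: {mob.shape[0]} vs {tgt.shape[0]}")
    if len(mob) < 3:
        raise ValueError("need at least 3 paired points")
    mob_c, tgt_c = mob.mean(axis=0), tgt.mean(axis=0)
    mob0, tgt0 = mob - mob_c, tgt - tgt_c
    if np.linalg.matrix_rank(np.vstack([mob0, tgt0]), tol=1e-8) < 2:
        raise ValueError("degenerate geometry: points are collinear or coincident")
    rot, _ = Rotation.align_vectors(tgt0, mob0)
    R = rot.as_matrix()
    translation = tgt_c - R @ mob_c
    diff = mob0 @ R.T - tgt0
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=translation, rmsd=rmsd, n_pairs=len(mob))


def _paired_ca(
    mobile: Structure, target: Structure, sel: ResidueSelector
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Cα pairs for author residue numbers resolved in both structures."""

    def ca_map(s: Structure) -> dict[int, np.ndarray]:
        out = {}
        for res in s.chain(sel.chain_id):
            if sel.contains(res) and res.has_atom("CA") and not res.insertion_code:
                out[res.auth_seq_id] = res.atom("CA").coords
        return out

    mob_map, tgt_map = ca_map(mobile), ca_map(target)
    common = sorted(set(mob_map) & set(tgt_map))
    if not common:
        raise ValueError(f"no common Cα residues in range {sel}")
    mob = np.array([mob_map[i] for i in common])
    tgt = np.array([tgt_map[i] for i in common])
    return mob, tgt, common


def region_rmsd(
    mobile: Structure,
    target: Structure,
    align_on: ResidueSelector,
    report_on: Sequence[ResidueSelector],
) -> dict[str, float]:
    """Superpose on one region and report Cα RMSD per region without re-fitting.

    The returned dict maps ``str(selector)`` to RMSD; the alignment region
    itself is reported under ``"align"``.
    """
    mob, tgt, _ = _paired_ca(mobile, target, align_on)
    sup = kabsch_superpose(mob, tgt)
    out = {"align": sup.rmsd}
    for sel in report_on:
        m, t, _ = _paired_ca(mobile, target, sel)
        diff = sup.apply(m) - t
        out[str(sel)] = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return out


def atom_distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance in Å."""
    return float(np.linalg.norm(a.coords - b.coords))


_POLAR_ELEMENTS = {"N", "O"}


def _polar_atoms(
    s: Structure, selection: Optional[ResidueSelector]
) -> list[tuple[Residue, AtomRecord]]:
    out = []
    for res in s.residues():
        if res.is_water:
            continue
        if selection is not None and not selection.contains(res):
            continue
        for atom in res.atoms:
            if atom.element in _POLAR_ELEMENTS:
                out.append((res, atom))
    return out


def find_hbonds(
    s: Structure,
    donors: Optional[ResidueSelector] = None,
    acceptors: Optional[ResidueSelector] = None,
    cutoff: float = 3.5,
) -> list[HydrogenBond]:
    """Distance-criterion hydrogen bonds between N/O atoms of distinct residues.

    Hydrogens are absent from typical X-ray models at these resolutions, so
    the criterion is heavy-atom donor–acceptor distance ≤ ``cutoff`` (default
    3.5 Å) with no angular term.  Results are sorted by distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    don = _polar_atoms(s, donors)
    acc = _polar_atoms(s, acceptors)
    if not don or not acc:
        return []
    tree = cKDTree(np.array([a.coords for _, a in acc]))
    bonds: list[HydrogenBond] = []
    seen: set[tuple[int, int]] = set()
    for di, (dres, datom) in enumerate(don):
        for ai in tree.query_ball_point(datom.coords, cutoff):
            ares, aatom = acc[ai]
            if ares.key == dres.key:
                continue
            pair_id = (id(datom), id(aatom))
            if pair_id in seen:
                continue
            seen.add(pair_id)
            d = atom_distance(datom, aatom)
            bonds.append(HydrogenBond(dres, datom, ares, aatom, d))
    bonds.sort(key=lambda hb: hb.distance)
    return bonds
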