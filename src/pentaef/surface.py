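"""Solvent-accessible surface areas and derived analyses.

SASA is computed with the Shrake–Rupley rolling-probe algorithm: each atom
is covered by an even (Fibonacci-spiral) point mesh on its probe-expanded
sphere, and the accessible fraction is the fraction of points not occluded
by any neighbouring expanded sphere.  Waters and monoatomic ions are
excluded from both the surface and the occluders by default, following the
convention of protein-surface programs.

On top of per-residue SASA the module provides:

* apo→holo relative-change filtering — the residues whose exposed surface
  grows by more than a percentage threshold upon calcium binding;
* hydrophobic patch clustering — single-linkage clusters of solvent-exposed
  hydrophobic residues, ranked by exposed area (a simplified, Hotpatch-like
  analysis: the statistical model of the original server is not reproduced);
* peptide/protein interface burial — per-residue ΔSASA on complex
  separation, ePISA-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure import Residue, Structure, THREE_TO_ONE

__all__ = [
    "SasaProfile",
    "DeltaSasaReport",
    "Patch",
    "InterfaceReport",
    "VDW_RADII",
    "MAX_SASA",
    "compute_sasa",
    "delta_sasa",
    "hydrophobic_patches",
    "interface_burial",
    "atom_radii",
]

# Single-atom van der Waals radii (Å), Bondi-style; used for every atom of
# the element regardless of chemical context.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70

# Theoretical maximum per-residue SASA (Å²) in a Gly-X-Gly tripeptide
# (Tien et al. 2013, theoretical column); reference for relative exposure.
MAX_SASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

HYDROPHOBIC = set("AVLIMFWYP")


@dataclass
class SasaProfile:
    """Per-residue solvent-accessible areas with the sampling parameters used."""

    residue_sasa: dict[tuple[str, int], float]
    probe_radius: float
    n_points: int
    radii_set: str = "single-atom vdW"
    atom_sasa: Optional[dict[tuple[str, int, str], float]] = None

    def total(self) -> float:
        return float(sum(self.residue_sasa.values()))

    def get(self, chain: str, seq_id: int) -> Optional[float]:
        return self.residue_sasa.get((chain, seq_id))


@dataclass
class DeltaSasaReport:
    rows: list[dict]
    flagged: list[tuple[str, int]]
    threshold_pct: float
    min_abs_increase: float

    def to_dict(self) -> dict:
        return {
            "threshold_pct": self.threshold_pct,
            "min_abs_increase": self.min_abs_increase,
            "flagged": [f"{c}:{i}" for c, i in self.flagged],
            "rows": self.rows,
        }


@dataclass
class Patch:
    residues: list[tuple[str, int, str]]  # (chain, seq_id, res_name)
    total_exposed_area: float
    hydrophobic_fraction: float
    rank: int = 0

    def residue_keys(self) -> set[tuple[str, int]]:
        return {(c, i) for c, i, _ in self.residues}


@dataclass
class InterfaceReport:
    buried_a: dict[tuple[str, int], float]
    buried_b: dict[tuple[str, int], float]
    total_buried_area: float

    def buried_keys(self) -> set[tuple[str, int]]:
        return set(self.buried_a) | set(self.buried_b)

    def to_dict(self) -> dict:
        return {
            "total_buried_area": self.total_buried_area,
            "partner_a": {f"{c}:{i}": v for (c, i), v in sorted(self.buried_a.items())},
            "partner_b": {f"{c}:{i}": v for (c, i), v in sorted(self.buried_b.items())},
        }


def atom_radii(elements: Iterable[str]) -> np.ndarray:
    return np.array([VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in elements])


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly distributed points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _surface_atoms(s: Structure, include_hetero: bool) -> list[tuple[Residue, int]]:
    """(residue, atom index) pairs considered part of the molecular surface."""
    out = []
    for res in s.residues():
        if res.is_water:
            continue
        if res.is_hetero and not include_hetero:
            # monoatomic ions and other hetero groups are excluded by default
            continue
        for idx, atom in enumerate(res.atoms):
            if atom.element == "H":
                continue
            out.append((res, idx))
    return out


def sasa_points(
    coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int
) -> np.ndarray:
    """Shrake–Rupley per-atom SASA for explicit coordinates and radii."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    expanded = radii + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.sum() / n_points
    return areas


def compute_sasa(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    include_hetero: bool = False,
) -> SasaProfile:
    """Per-residue SASA of a structure (waters and hetero groups excluded by default)."""
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100 for usable accuracy")
    pairs = _surface_atoms(s, include_hetero)
    if not pairs:
        raise ValueError("structure holds no surface atoms")
    coords = np.array([res.atoms[idx].coords for res, idx in pairs])
    radii = atom_radii([res.atoms[idx].element for res, idx in pairs])
    areas = sasa_points(coords, radii, probe, n_points)
    residue_sasa: dict[tuple[str, int], float] = {}
    atom_sasa: dict[tuple[str, int, str], float] = {}
    for (res, idx), area in zip(pairs, areas):
        key = (res.chain_id, res.auth_seq_id)
        residue_sasa[key] = residue_sasa.get(key, 0.0) + float(area)
        atom_sasa[(res.chain_id, res.auth_seq_id, res.atoms[idx].atom_name)] = float(area)
    return SasaProfile(
        residue_sasa=residue_sasa, probe_radius=probe, n_points=n_points, atom_sasa=atom_sasa
    )


def delta_sasa(
    apo: SasaProfile,
    holo: SasaProfile,
    threshold_pct: float = 30.0,
    min_abs_increase: float = 5.0,
) -> DeltaSasaReport:
    """Apo→holo relative SASA change per residue, with exposure-gain flagging.

    relative_change = 100 · (SASA_holo − SASA_apo) / max(SASA_apo, 1 Å²)

    A residue is flagged when its relative change exceeds ``threshold_pct``
    AND its absolute increase is at least ``min_abs_increase`` Å² — the
    absolute guard keeps near-buried residues with tiny denominators from
    dominating the list.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    common = sorted(set(apo.residue_sasa) & set(holo.residue_sasa))
    if not common:
        raise ValueError("profiles share no residues")
    rows, flagged = [], []
    for key in common:
        a, h = apo.residue_sasa[key], holo.residue_sasa[key]
        rel = 100.0 * (h - a) / max(a, 1.0)
        is_flagged = rel > threshold_pct and (h - a) >= min_abs_increase
        rows.append(
            {
                "chain": key[0],
                "auth_seq_id": key[1],
                "sasa_apo": a,
                "sasa_holo": h,
                "relative_change_pct": rel,
                "flagged": is_flagged,
            }
        )
        if is_flagged:
            flagged.append(key)
    return DeltaSasaReport(rows=rows, flagged=flagged, threshold_pct=threshold_pct,
                           min_abs_increase=min_abs_increase)


def _sidechain_centroid(res: Residue) -> Optional[np.ndarray]:
    backbone = {"N", "CA", "C", "O", "OXT"}
    side = [a.coords for a in res.atoms if a.atom_name not in backbone and a.element != "H"]
    if side:
        return np.mean(side, axis=0)
    if res.has_atom("CA"):
        return res.atom("CA").coords
    return None


def hydrophobic_patches(
    s: Structure,
    sasa: SasaProfile,
    linkage: float = 6.5,
    exposure_fraction: float = 0.20,
) -> list[Patch]:
    """Ranked single-linkage clusters of solvent-exposed hydrophobic residues.

    A residue qualifies when it is hydrophobic (A,V,L,I,M,F,W,Y,P) and its
    SASA is at least ``exposure_fraction`` of its Gly-X-Gly reference
    maximum.  Qualifying residues whose side-chain centroids lie within
    ``linkage`` Å are merged; singleton clusters are dropped.  Patches are
    ranked by total exposed area (rank 1 = largest).
    """
    if linkage <= 0:
        raise ValueError("linkage distance must be positive")
    members = []
    for res in s.residues():
        if res.is_water or res.is_hetero:
            continue
        one = res.one_letter
        if one not in HYDROPHOBIC:
            continue
        area = sasa.get(res.chain_id, res.auth_seq_id)
        if area is None:
            continue
        ref = MAX_SASA.get(one)
        if ref is None or area < exposure_fraction * ref:
            continue
        centroid = _sidechain_centroid(res)
        if centroid is not None:
            members.append((res, centroid, area))
    if not members:
        return []
    centroids = np.array([m[1] for m in members])
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(linkage)
    n = len(members)
    if pairs:
        rows, cols = zip(*pairs)
        adj = csr_matrix((np.ones(len(pairs)), (rows, cols)), shape=(n, n))
    else:
        adj = csr_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    patches = []
    for comp in range(n_comp):
        idx = np.where(labels == comp)[0]
        if len(idx) < 2:
            continue
        residues = [(members[i][0].chain_id, members[i][0].auth_seq_id,
                     members[i][0].res_name) for i in idx]
        total = float(sum(members[i][2] for i in idx))
        patches.append(Patch(residues=sorted(residues), total_exposed_area=total,
                             hydrophobic_fraction=1.0))
    patches.sort(key=lambda p: -p.total_exposed_area)
    for rank, p in enumerate(patches, start=1):
        p.rank = rank
    return patches


def _subset_chains(s: Structure, chain_ids: set[str]) -> Structure:
    chains = {cid: res for cid, res in s.chains.items() if cid in chain_ids}
    if not chains:
        raise ValueError(f"no such chains: {sorted(chain_ids)}")
    return Structure(entry_id=s.entry_id, model_number=s.model_number,
                     chains=chains, source_format=s.source_format)


def interface_burial(
    complex_structure: Structure,
    partner_a: set[str] | Sequence[str],
    partner_b: set[str] | Sequence[str],
    min_burial: float = 1.0,
    probe: float = 1.4,
    n_points: int = 960,
) -> InterfaceReport:
    """Residues buried at a two-partner interface, by ΔSASA on separation.

    SASA is computed for the complex and for each partner in isolation; a
    residue is buried when its isolated-minus-complex SASA is at least
    ``min_burial`` Å².  The total buried area is the sum over both partners.
    """
    partner_a, partner_b = set(partner_a), set(partner_b)
    if partner_a & partner_b:
        raise ValueError(f"partners overlap: {sorted(partner_a & partner_b)}")
    both = _subset_chains(complex_structure, partner_a | partner_b)
    complex_sasa = compute_sasa(both, probe=probe, n_points=n_points)
    buried: dict[str, dict[tuple[str, int], float]] = {}
    for name, chains in (("a", partner_a), ("b", partner_b)):
        isolated = compute_sasa(_subset_chains(complex_structure, chains),
                                probe=probe, n_points=n_points)
        out = {}
        for key, iso_area in isolated.residue_sasa.items():
            delta = iso_area - complex_sasa.residue_sasa.get(key, 0.0)
            if delta >= min_burial:
                out[key] = float(delta)
        buried[name] = out
    total = sum(buried["a"].values()) + sum(buried["b"].values())
    return InterfaceReport(buried_a=buried["a"], buried_b=buried["b"],
                           total_buried_area=float(total))
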