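"""Metal-ion coordination spheres and geometry classification.

EF-hand Ca²⁺ is canonically hepta-coordinated in a pentagonal bipyramid:
five equatorial ligands ~72° apart and two axial ligands ~180° apart.  The
classifier scores a site against the ideal template by exhaustive search
over candidate axial pairs, so the result is exact, order-independent and
invariant under rigid motion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import atom_distance
from .structure import AtomRecord, Residue, ResidueSelector, Structure

__all__ = ["MetalSite", "Ligand", "find_metal_sites", "classify_geometry"]

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_METAL_ELEMENTS = {"CA", "MG", "ZN", "MN", "FE", "NA", "K", "CU", "NI", "CO", "CD", "SR", "BA"}

PBP_THRESHOLD = 20.0  # deg; mean angular deviation below which a class is assigned


@dataclass
class Ligand:
    residue: Residue
    atom: AtomRecord
    distance: float
    source: str  # protein side-chain | protein backbone | water | other

    def label(self) -> str:
        return f"{self.atom.atom_name} {self.residue.label()} ({self.distance:.2f} A)"


@dataclass
class MetalSite:
    metal_residue: Residue
    metal: AtomRecord
    ligands: list[Ligand]
    geometry_class: str = "unclassified"
    geometry_deviation: Optional[float] = None
    ef_hand: Optional[str] = None

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    def ligand_vectors(self) -> np.ndarray:
        """Unit vectors metal → ligand."""
        v = np.array([lig.atom.coords - self.metal.coords for lig in self.ligands])
        return v / np.linalg.norm(v, axis=1, keepdims=True)


def _ligand_source(res: Residue, atom: AtomRecord) -> str:
    if res.is_water:
        return "water"
    if not res.is_hetero:
        return "protein backbone" if atom.atom_name in _BACKBONE_ATOMS else "protein side-chain"
    return "other"


def find_metal_sites(
    s: Structure,
    element: str = "CA",
    cutoff: float = 2.9,
    ef_loops: Optional[dict[str, ResidueSelector]] = None,
) -> list[MetalSite]:
    """One :class:`MetalSite` per hetero metal atom of the given element.

    Ligands are O and N atoms (of protein, water or other hetero groups,
    never of other metals) within ``cutoff`` of the ion; the default 2.9 Å
    covers the canonical 2.3–2.6 Å Ca–O range plus bidentate carboxylates.
    When ``ef_loops`` maps EF-hand names to loop ranges, each site is
    annotated with the loop that contains (or lies closest to) its
    protein ligands.
    """
    if not 0 < cutoff <= 4.0:
        raise ValueError("cutoff must lie in (0, 4] Å")
    element = element.upper()
    metals: list[tuple[Residue, AtomRecord]] = [
        (res, atom)
        for res, atom in s.atoms()
        if atom.is_hetero and atom.element == element and not res.is_water
    ]
    candidates: list[tuple[Residue, AtomRecord]] = [
        (res, atom)
        for res, atom in s.atoms()
        if atom.element in ("O", "N") and atom.element not in _METAL_ELEMENTS
    ]
    sites = []
    for mres, matom in metals:
        ligands = []
        for res, atom in candidates:
            d = atom_distance(matom, atom)
            if d <= cutoff:
                ligands.append(Ligand(res, atom, d, _ligand_source(res, atom)))
        ligands.sort(key=lambda L: L.distance)
        site = MetalSite(metal_residue=mres, metal=matom, ligands=ligands)
        site.geometry_class, site.geometry_deviation = classify_geometry(site)
        if ef_loops:
            site.ef_hand = _assign_ef_hand(site, ef_loops)
        sites.append(site)
    return sites


def _assign_ef_hand(site: MetalSite, ef_loops: dict[str, ResidueSelector]) -> Optional[str]:
    protein_ligs = [L for L in site.ligands if L.source.startswith("protein")]
    best, best_count = None, 0
    for name, sel in ef_loops.items():
        count = sum(1 for L in protein_ligs if sel.contains(L.residue))
        if count > best_count:
            best, best_count = name, count
    return best


# ---------------------------------------------------------------------------
# Geometry classification


def _pairwise_angles(vecs: np.ndarray) -> np.ndarray:
    cos = np.clip(vecs @ vecs.T, -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def _pbp_deviation(vecs: np.ndarray) -> float:
    """Best mean |angular residual| vs the pentagonal-bipyramidal template (n=7).

    Exhaustive over the C(7,2)=21 candidate axial pairs.  For each candidate:
    axial–axial vs 180°, axial–equatorial vs 90° (10 terms), and adjacent
    equatorial neighbours (ordered by azimuth about the axial axis) vs 72°
    (5 terms).
    """
    n = len(vecs)
    angles = _pairwise_angles(vecs)
    best = np.inf
    for i, j in itertools.combinations(range(n), 2):
        axis = vecs[i] - vecs[j]
        axis /= np.linalg.norm(axis)
        eq = [k for k in range(n) if k not in (i, j)]
        residuals = [abs(angles[i, j] - 180.0)]
        residuals += [abs(angles[a, k] - 90.0) for a in (i, j) for k in eq]
        # order equatorial ligands by azimuth about the axial direction
        ref = vecs[eq[0]] - np.dot(vecs[eq[0]], axis) * axis
        ref /= np.linalg.norm(ref)
        ref2 = np.cross(axis, ref)
        azim = sorted(
            eq,
            key=lambda k: np.arctan2(np.dot(vecs[k], ref2), np.dot(vecs[k], ref)),
        )
        for a, b in zip(azim, azim[1:] + azim[:1]):
            residuals.append(abs(angles[a, b] - 72.0))
        dev = float(np.mean(residuals))
        best = min(best, dev)
    return best


def _octahedral_deviation(vecs: np.ndarray) -> float:
    """Best mean |angular residual| vs the octahedral template (n=6).

    Exhaustive over the 15 perfect matchings of 6 ligands into 3 trans
    pairs: trans pairs vs 180°, all cis pairs vs 90°.
    """
    angles = _pairwise_angles(vecs)

    def matchings(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for k, other in enumerate(rest):
            for m in matchings(rest[:k] + rest[k + 1:]):
                yield [(first, other)] + m

    best = np.inf
    for pairs in matchings(list(range(6))):
        residuals = [abs(angles[a, b] - 180.0) for a, b in pairs]
        trans = {frozenset(p) for p in pairs}
        for a, b in itertools.combinations(range(6), 2):
            if frozenset((a, b)) not in trans:
                residuals.append(abs(angles[a, b] - 90.0))
        best = min(best, float(np.mean(residuals)))
    return best


def classify_geometry(site: MetalSite, threshold: float = PBP_THRESHOLD) -> tuple[str, Optional[float]]:
    """Classify a coordination sphere and report its mean angular deviation.

    n=7 sites are tested against the pentagonal bipyramid, n=6 against the
    octahedron; the class is assigned when the deviation is below
    ``threshold`` (degrees), otherwise ``other``.  Fewer than 4 ligands
    cannot be classified.
    """
    n = site.coordination_number
    if n < 4:
        return "other", None
    vecs = site.ligand_vectors()
    if n == 7:
        dev = _pbp_deviation(vecs)
        return ("pentagonal_bipyramidal" if dev < threshold else "other"), dev
    if n == 6:
        dev = _octahedral_deviation(vecs)
        return ("octahedral" if dev < threshold else "other"), dev
    return "other", None


def site_report_rows(sites: Sequence[MetalSite]) -> list[dict]:
    rows = []
    for site in sites:
        rows.append(
            {
                "metal": f"{site.metal_residue.chain_id}:{site.metal_residue.auth_seq_id}",
                "element": site.metal.element,
                "ef_hand": site.ef_hand,
                "n_ligands": site.coordination_number,
                "geometry": site.geometry_class,
                "deviation_deg": site.geometry_deviation,
                "ligands": "; ".join(L.label() for L in site.ligands),
            }
        )
    return rows
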