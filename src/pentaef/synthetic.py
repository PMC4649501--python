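"""Synthetic structure, peptide and coordination-site generators.

Every downstream stage of the package can be exercised without any
downloaded data: ideal α-helices at prescribed mutual angles stand in for
the EF-hand helices, ideal pentagonal-bipyramidal sites for the Ca²⁺
coordination spheres, and motif-planted peptide sets for phage-display
selection output.  All generators are deterministic under their seed, and
fixtures are plain :class:`~pentaef.structure.Structure` objects that
round-trip through the standard PDB writer, so synthetic and real data flow
through identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import fit_helix_axis
from .structure import AtomRecord, Residue, Structure

__all__ = [
    "HelixSpec",
    "PolyhedronSpec",
    "PeptideGenSpec",
    "build_helix",
    "build_coil",
    "build_efhand_pair",
    "build_metal_site",
    "generate_peptides",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass
class HelixSpec:
    """Ideal α-helix Cα geometry.

    Defaults (rise 1.5 Å, twist 100°, radius 2.3 Å) generate the canonical
    α-helical wheel with consecutive Cα–Cα distances of ≈3.8 Å.
    """

    n_residues: int = 12
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("a helix needs at least 4 residues")
        self.axis_direction = np.asarray(self.axis_direction, float)
        norm = np.linalg.norm(self.axis_direction)
        if norm == 0:
            raise ValueError("axis_direction must be non-zero")
        self.axis_direction = self.axis_direction / norm
        self.origin = np.asarray(self.origin, float)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def helix_ca_coords(spec: HelixSpec) -> np.ndarray:
    """Cα coordinates of the ideal helix, principal axis exactly on ``axis_direction``.

    The raw helical wheel is generated along z and then rotated so that its
    *fitted* principal axis (which differs from z by a small fraction of a
    degree for partial turns) coincides exactly with the requested direction:
    the generated geometry then has a known-exact axis, which is what a
    fixture must provide.
    """
    i = np.arange(spec.n_residues)
    t = np.radians(spec.twist_per_residue * i + spec.phase)
    raw = np.column_stack(
        [spec.radius * np.cos(t), spec.radius * np.sin(t), spec.rise_per_residue * i]
    )
    fitted = fit_helix_axis(raw).direction
    align = _rotation_between(fitted, np.array([0.0, 0.0, 1.0]))
    raw = raw @ align.T
    orient = _rotation_between(np.array([0.0, 0.0, 1.0]), spec.axis_direction)
    coords = raw @ orient.T
    return coords - coords[0] + spec.origin


def _ca_chain(coords: np.ndarray, chain_id: str = "A", start: int = 1,
              res_names: Optional[Sequence[str]] = None) -> list[Residue]:
    residues = []
    for k, xyz in enumerate(coords):
        name = res_names[k] if res_names else "ALA"
        res = Residue(chain_id=chain_id, auth_seq_id=start + k, res_name=name)
        res.add_atom(AtomRecord("CA", "C", np.asarray(xyz, float)))
        residues.append(res)
    return residues


def build_helix(spec: HelixSpec, chain_id: str = "A", start_res: int = 1,
                entry_id: str = "HLX1") -> Structure:
    """Poly-alanine Cα trace of one ideal helix."""
    coords = helix_ca_coords(spec)
    return Structure(entry_id=entry_id, chains={chain_id: _ca_chain(coords, chain_id, start_res)})


def coil_ca_coords(n_residues: int, origin: np.ndarray | Sequence[float] = (0, 0, 0),
                   direction: np.ndarray | Sequence[float] = (1, 0, 0)) -> np.ndarray:
    """Extended (β-strand-like) Cα zigzag: ~3.8 Å steps, non-helical by construction."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    i = np.arange(n_residues)
    coords = (
        np.asarray(origin, float)
        + np.outer(i * 3.3, direction)
        + np.outer(np.where(i % 2 == 0, 0.95, -0.95), perp)
    )
    return coords


def build_coil(n_residues: int, chain_id: str = "A", start_res: int = 1) -> Structure:
    return Structure(entry_id="COIL", chains={chain_id: _ca_chain(coil_ca_coords(n_residues), chain_id, start_res)})


def _two_helix_structure(theta_deg: float, entry_id: str, n_helix: int = 12,
                         n_loop: int = 4) -> Structure:
    """One chain: helix 1 along +z, loop, helix 2 at the prescribed directed angle."""
    spec1 = HelixSpec(n_residues=n_helix)
    coords1 = helix_ca_coords(spec1)
    theta = np.radians(theta_deg)
    dir2 = np.array([0.0, np.sin(theta), np.cos(theta)])
    # start helix 2 well clear of helix 1 so the loop is unambiguous
    origin2 = coords1[-1] + np.array([6.0, 2.0, 3.0])
    spec2 = HelixSpec(n_residues=n_helix, axis_direction=dir2, origin=origin2)
    coords2 = helix_ca_coords(spec2)
    loop = np.array(
        [coords1[-1] + (coords2[0] - coords1[-1]) * (k + 1) / (n_loop + 1) for k in range(n_loop)]
    )
    all_coords = np.vstack([coords1, loop, coords2])
    return Structure(entry_id=entry_id, chains={"A": _ca_chain(all_coords, "A", 1)})


def build_efhand_pair(theta_apo: float, theta_holo: float, n_helix: int = 12,
                      n_loop: int = 4):
    """Apo/holo pair of two-helix EF-hand models opened at the given angles.

    Both structures share the entering-helix geometry; the exiting helix sits
    at ``theta_apo`` (apo) and ``theta_holo`` (holo) to the entering helix.
    Returns ``(apo, holo, annotations, ef_defs)`` ready for the EF-hand angle
    pipeline, with helices labelled A (residues 1..n) and B.
    """
    from .efhands import EFHandDef, HelixAnnotation
    from .structure import ResidueSelector

    if not (0.0 < theta_apo < 180.0 and 0.0 < theta_holo < 180.0):
        raise ValueError("EF-hand opening angles must lie in (0, 180) degrees")
    apo = _two_helix_structure(theta_apo, "APO1", n_helix, n_loop)
    holo = _two_helix_structure(theta_holo, "HOLO", n_helix, n_loop)
    b_start = n_helix + n_loop + 1
    annotations = [
        HelixAnnotation("A", ResidueSelector("A", 1, n_helix)),
        HelixAnnotation("B", ResidueSelector("A", b_start, b_start + n_helix - 1)),
    ]
    ef_defs = [EFHandDef("EF1", "A", "B",
                         loop=ResidueSelector("A", n_helix + 1, n_helix + n_loop))]
    return apo, holo, annotations, ef_defs


# ---------------------------------------------------------------------------
# Coordination polyhedra


@dataclass
class PolyhedronSpec:
    """Ideal metal coordination polyhedron with optional angular jitter."""

    geometry: str = "pentagonal_bipyramidal"
    bond_length: float = 2.4
    angular_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.geometry not in ("pentagonal_bipyramidal", "octahedral"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def polyhedron_directions(geometry: str) -> np.ndarray:
    if geometry == "pentagonal_bipyramidal":
        phi = np.radians(72.0 * np.arange(5))
        equatorial = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(5)])
        axial = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        return np.vstack([axial, equatorial])
    if geometry == "octahedral":
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
        )
    raise ValueError(f"unknown geometry {geometry!r}")


def _jitter_directions(dirs: np.ndarray, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    if sd_deg <= 0:
        return dirs
    out = []
    for d in dirs:
        # random tangent-plane perturbation with the given angular sd
        t = rng.normal(0.0, np.radians(sd_deg), size=2)
        perp1 = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp1) < 1e-6:
            perp1 = np.cross(d, [1.0, 0.0, 0.0])
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(d, perp1)
        v = d + t[0] * perp1 + t[1] * perp2
        out.append(v / np.linalg.norm(v))
    return np.array(out)


def build_metal_site(spec: PolyhedronSpec, center: Sequence[float] = (0.0, 0.0, 0.0),
                     entry_id: str = "SITE") -> Structure:
    """One Ca²⁺ ion plus oxygen pseudo-ligands at the ideal polyhedron vertices.

    The ion is an isolated hetero residue named CA; ligands are water oxygens
    so that real and synthetic coordination spheres share atom chemistry.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(center, float)
    dirs = _jitter_directions(polyhedron_directions(spec.geometry), spec.angular_jitter_sd, rng)
    metal = Residue(chain_id="M", auth_seq_id=1, res_name="CA")
    metal.add_atom(AtomRecord("CA", "CA", center, is_hetero=True))
    residues = [metal]
    for k, d in enumerate(dirs):
        w = Residue(chain_id="M", auth_seq_id=100 + k, res_name="HOH")
        w.add_atom(AtomRecord("O", "O", center + spec.bond_length * d, is_hetero=True))
        residues.append(w)
    return Structure(entry_id=entry_id, chains={"M": residues})


# ---------------------------------------------------------------------------
# Peptide sets


@dataclass
class PeptideGenSpec:
    """Motif-planted random peptide set emulating phage-display output.

    Sixteen-residue peptides mirror the p8-display library; a ``prevalence``
    fraction of sequences carries one planted motif instance at a uniform
    random offset, everything else is drawn from ``background``.
    """

    n: int = 50
    length: int = 16
    pattern: object = None  # MotifPattern
    prevalence: float = 1.0
    background: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.background is None:
            self.background = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")
        if any(aa not in AMINO_ACIDS for aa in self.background):
            raise ValueError("background contains a non-standard residue code")


def generate_peptides(spec: PeptideGenSpec):
    """Generate a :class:`~pentaef.motifs.PeptideSet` with a planted motif."""
    from .motifs import PeptideSet

    if spec.pattern is not None and len(spec.pattern.positions) > spec.length:
        raise ValueError("pattern longer than peptide length")
    rng = np.random.default_rng(spec.seed)
    letters = list(spec.background)
    probs = np.array([spec.background[aa] for aa in letters])
    probs = probs / probs.sum()
    seqs = []
    for _ in range(spec.n):
        seq = list(rng.choice(letters, size=spec.length, p=probs))
        if spec.pattern is not None and rng.random() < spec.prevalence:
            plen = len(spec.pattern.positions)
            offset = int(rng.integers(0, spec.length - plen + 1))
            for j, allowed in enumerate(spec.pattern.positions):
                if len(allowed) == len(AMINO_ACIDS):
                    continue  # wildcard position: keep the background draw
                seq[offset + j] = str(rng.choice(sorted(allowed)))
        seqs.append("".join(seq))
    return PeptideSet(sequences=seqs, condition_label=f"synthetic-seed{spec.seed}")
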