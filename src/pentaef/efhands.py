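"""EF-hand conformational analysis for penta-EF-hand (PEF) proteins.

A PEF monomer carries eight α-helices (A–H) arranged in five EF-hands:
EF1 = [A–B], EF2 = [C–D], EF3 = [D–E], EF4 = [F–G], EF5 = [G–H].  The
opening angle θ of each EF-hand — the angle between the directed axes of
its entering and exiting helices — reports the apo→holo conformational
state, and the angle between the long D- and G-helices reports the movement
of the EF1–EF3 sub-domain relative to the EF4–EF5 dimerization sub-domain.
Calcium binding opens EF1 and EF3 of Sorcin by roughly +18° and +15°, and
tilts the D-helix by about +21° relative to the G-helix.

Helix boundaries can come from three sources: a Cα-geometry assigner
(``auto``), a shipped per-protein registry (``registry``), or a user file
(``file``).  For apo/holo Δθ tables the same residue ranges must be used for
both forms, so that a Δθ measures conformational change, never boundary
re-assignment.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .geometry import HelixAxis, fit_helix_axis, interhelix_angle
from .structure import ResidueSelector, Structure, ca_coords

__all__ = [
    "HelixAnnotation",
    "EFHandDef",
    "AngleReport",
    "DeltaReport",
    "DEFAULT_EF_DEFS",
    "assign_helices",
    "efhand_angles",
    "delta_table",
    "compare_family",
    "registry_annotations",
    "read_annotation_file",
    "write_annotation_file",
]

HELIX_NAMES = "ABCDEFGH"


@dataclass(frozen=True)
class HelixAnnotation:
    helix_name: str
    selector: ResidueSelector


@dataclass(frozen=True)
class EFHandDef:
    """EF-hand topology: entering helix, exiting helix, optional loop range."""

    name: str
    entering_helix: str
    exiting_helix: str
    loop: Optional[ResidueSelector] = None

    def __post_init__(self) -> None:
        if self.entering_helix == self.exiting_helix:
            raise ValueError(f"{self.name}: entering and exiting helix must differ")


def default_ef_defs() -> list[EFHandDef]:
    """The canonical PEF EF-hand ↔ helix-pair mapping."""
    pairs = [("EF1", "A", "B"), ("EF2", "C", "D"), ("EF3", "D", "E"),
             ("EF4", "F", "G"), ("EF5", "G", "H")]
    return [EFHandDef(n, e, x) for n, e, x in pairs]


DEFAULT_EF_DEFS = default_ef_defs()


@dataclass
class AngleReport:
    """Per-EF-hand opening angles θ plus the hD–hG sub-domain angle (degrees)."""

    label: str
    ef_angles: dict[str, Optional[float]]
    hd_hg_angle: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            **{name: self.ef_angles.get(name) for name in sorted(self.ef_angles)},
            "hD_hG": self.hd_hg_angle,
        }


@dataclass
class DeltaReport:
    """Signed apo→holo angle changes: Δθ = θ(holo) − θ(apo)."""

    apo_label: str
    holo_label: str
    ef_deltas: dict[str, Optional[float]]
    hd_hg_delta: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "apo": self.apo_label,
            "holo": self.holo_label,
            **{f"d{name}": self.ef_deltas.get(name) for name in sorted(self.ef_deltas)},
            "dhD_hG": self.hd_hg_delta,
        }


# ---------------------------------------------------------------------------
# Helix assignment

# Cα-only secondary-structure criteria (P-SEA style): short-range Cα
# distances and the pseudo-dihedral of four consecutive Cα atoms.  Ideal
# α-helix values: d(i,i+3) ≈ 5.0–5.3 Å, d(i,i+4) ≈ 6.2 Å, dihedral ≈ +50°.
_D3_RANGE = (4.2, 5.9)
_D4_RANGE = (4.9, 7.0)
_DIHEDRAL_RANGE = (20.0, 80.0)


def _ca_dihedral(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(y, np.dot(n1, n2))))


def _helical_mask(coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    mask = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        d3 = np.linalg.norm(coords[i + 3] - coords[i])
        d4 = np.linalg.norm(coords[i + 4] - coords[i])
        dih = _ca_dihedral(coords[i], coords[i + 1], coords[i + 2], coords[i + 3])
        if (_D3_RANGE[0] <= d3 <= _D3_RANGE[1]
                and _D4_RANGE[0] <= d4 <= _D4_RANGE[1]
                and _DIHEDRAL_RANGE[0] <= dih <= _DIHEDRAL_RANGE[1]):
            mask[i:i + 5] = True
    return mask


def _segments(mask: np.ndarray, min_len: int = 5) -> list[tuple[int, int]]:
    segs, start = [], None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                segs.append((start, i - 1))
            start = None
    if start is not None and len(mask) - start >= min_len:
        segs.append((start, len(mask) - 1))
    return segs


def assign_helices(
    s: Structure,
    chain: str,
    method: str = "auto",
    registry: Optional[str] = None,
    annotation_path: Optional[str] = None,
    n_expected: Optional[int] = None,
) -> list[HelixAnnotation]:
    """Locate the α-helices of one chain and label them A, B, C, ... in order.

    ``auto``
        Cα-geometry assignment; merged helical segments of ≥5 residues.  When
        ``n_expected`` is given (8 for a PEF monomer) the longest
        ``n_expected`` segments are labelled in sequence order; fewer found
        is an error suggesting registry/file mode.
    ``registry``
        Shipped residue-range tables (see :func:`registry_annotations`).
    ``file``
        User-provided TSV: ``helix_name  chain  start  end``.
    """
    if method == "registry":
        if registry is None:
            raise ValueError("registry mode needs a registry name")
        return registry_annotations(registry, chain)
    if method == "file":
        if annotation_path is None:
            raise ValueError("file mode needs an annotation path")
        return [a for a in read_annotation_file(annotation_path) if a.selector.chain_id == chain]
    if method != "auto":
        raise ValueError(f"unknown helix-assignment method {method!r}")

    residues = [r for r in s.chain(chain) if r.has_atom("CA") and not r.is_water]
    coords = np.array([r.atom("CA").coords for r in residues])
    if len(coords) < 5:
        raise ValueError(f"chain {chain}: too few Cα atoms ({len(coords)}) for assignment")
    segs = _segments(_helical_mask(coords))
    if not segs:
        raise ValueError(
            f"chain {chain}: no helical segments found; supply a registry or annotation file"
        )
    if n_expected is not None:
        if len(segs) < n_expected:
            raise ValueError(
                f"chain {chain}: found {len(segs)} helices, expected {n_expected}; "
                "supply a registry or annotation file"
            )
        segs = sorted(sorted(segs, key=lambda t: t[0] - t[1])[:n_expected])
    if len(segs) > len(HELIX_NAMES):
        segs = sorted(sorted(segs, key=lambda t: t[0] - t[1])[:len(HELIX_NAMES)])
    return [
        HelixAnnotation(
            HELIX_NAMES[k],
            ResidueSelector(chain, residues[i].auth_seq_id, residues[j].auth_seq_id),
        )
        for k, (i, j) in enumerate(segs)
    ]


# ---------------------------------------------------------------------------
# Registry
#
# The shipped ranges are approximate, literature-informed helix boundaries in
# author numbering; they are editable data, not measured constants, and every
# report records which registry produced its angles.

_REGISTRY: dict[str, dict[str, tuple[int, int]]] = {
    "sorcin": {
        "A": (36, 46), "B": (52, 62), "C": (71, 81), "D": (92, 114),
        "E": (121, 131), "F": (137, 147), "G": (155, 175), "H": (181, 192),
    },
    "pdcd6": {
        "A": (24, 34), "B": (40, 50), "C": (59, 69), "D": (80, 102),
        "E": (109, 119), "F": (125, 135), "G": (143, 163), "H": (169, 180),
    },
    "calpain-dvi": {
        "A": (95, 105), "B": (111, 121), "C": (130, 140), "D": (151, 173),
        "E": (180, 190), "F": (196, 206), "G": (214, 234), "H": (240, 251),
    },
}


def registry_names() -> list[str]:
    return sorted(_REGISTRY)


def registry_annotations(name: str, chain: str) -> list[HelixAnnotation]:
    try:
        table = _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(f"unknown registry {name!r}; available: {', '.join(registry_names())}") from None
    return [
        HelixAnnotation(h, ResidueSelector(chain, start, end))
        for h, (start, end) in table.items()
    ]


def read_annotation_file(path: str | os.PathLike) -> list[HelixAnnotation]:
    out = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "helix_name":
                continue
            name, chain, start, end = row[:4]
            out.append(HelixAnnotation(name, ResidueSelector(chain, int(start), int(end))))
    return out


def write_annotation_file(annotations: Sequence[HelixAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("helix_name\tchain\tstart\tend\n")
        for a in annotations:
            fh.write(f"{a.helix_name}\t{a.selector.chain_id}\t{a.selector.start}\t{a.selector.end}\n")


# ---------------------------------------------------------------------------
# Angle computation


def helix_axes(
    s: Structure, annotations: Sequence[HelixAnnotation]
) -> dict[str, Optional[HelixAxis]]:
    axes: dict[str, Optional[HelixAxis]] = {}
    for ann in annotations:
        coords = ca_coords(s, ann.selector)
        axes[ann.helix_name] = fit_helix_axis(coords) if len(coords) >= 4 else None
    return axes


def efhand_angles(
    s: Structure,
    chain: str,
    annotations: Sequence[HelixAnnotation],
    ef_defs: Sequence[EFHandDef] = DEFAULT_EF_DEFS,
    label: Optional[str] = None,
) -> AngleReport:
    """θ for each EF-hand plus the hD–hG angle, from fitted helix axes.

    A missing or unresolved helix yields a missing value for the affected
    EF-hand, not a global failure.
    """
    axes = helix_axes(s, annotations)
    ef_angles: dict[str, Optional[float]] = {}
    for ef in ef_defs:
        a, b = axes.get(ef.entering_helix), axes.get(ef.exiting_helix)
        ef_angles[ef.name] = interhelix_angle(a, b) if a is not None and b is not None else None
    hd, hg = axes.get("D"), axes.get("G")
    hd_hg = interhelix_angle(hd, hg) if hd is not None and hg is not None else None
    prov = {str(a.helix_name): str(a.selector) for a in annotations}
    return AngleReport(label=label or s.entry_id, ef_angles=ef_angles,
                       hd_hg_angle=hd_hg, provenance=prov)


def delta_table(apo: AngleReport, holo: AngleReport) -> DeltaReport:
    """Signed differences θ(holo) − θ(apo) per EF-hand and for hD–hG."""
    if set(apo.ef_angles) != set(holo.ef_angles):
        raise ValueError(
            f"EF-hand sets differ: {sorted(apo.ef_angles)} vs {sorted(holo.ef_angles)}"
        )
    deltas = {
        name: (holo.ef_angles[name] - apo.ef_angles[name]
               if apo.ef_angles[name] is not None and holo.ef_angles[name] is not None
               else None)
        for name in apo.ef_angles
    }
    hd_hg = (holo.hd_hg_angle - apo.hd_hg_angle
             if apo.hd_hg_angle is not None and holo.hd_hg_angle is not None else None)
    return DeltaReport(apo_label=apo.label, holo_label=holo.label,
                       ef_deltas=deltas, hd_hg_delta=hd_hg)


def compare_family(
    entries: Sequence[tuple],
    apo_holo_pairs: Sequence[tuple[str, str]] = (),
    ef_defs: Sequence[EFHandDef] = DEFAULT_EF_DEFS,
) -> dict:
    """Angle table for a family of structures, plus Δ rows for apo/holo pairs.

    ``entries`` holds ``(label, structure, chain, annotations)`` tuples;
    ``apo_holo_pairs`` holds ``(apo_label, holo_label)`` tuples.  Returns a
    dict with ``rows`` (AngleReport dicts) and ``deltas`` (DeltaReport
    dicts), in the shape the report writer expects.
    """
    if not entries:
        raise ValueError("need at least one entry")
    labels = [e[0] for e in entries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate entry labels")
    reports: dict[str, AngleReport] = {}
    for label, structure, chain, annotations in entries:
        reports[label] = efhand_angles(structure, chain, annotations, ef_defs, label=label)
    deltas = []
    for apo_label, holo_label in apo_holo_pairs:
        if apo_label not in reports or holo_label not in reports:
            raise KeyError(f"pair ({apo_label}, {holo_label}) references an unknown entry")
        deltas.append(delta_table(reports[apo_label], reports[holo_label]))
    return {
        "rows": [reports[lab].to_dict() for lab in labels],
        "deltas": [d.to_dict() for d in deltas],
    }
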