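"""Coordinate-file I/O and a uniform hierarchical structure model.

Structures are read from PDB or mmCIF files (via :mod:`gemmi`) into a plain
chain -> residue -> atom model keyed by *author* residue numbering, which is
the numbering used throughout the penta-EF-hand literature (Tyr67, Glu97,
Trp105, ...).  Hetero records -- metal ions, bound peptides, waters -- are
retained and flagged, because calcium coordination spheres and interface
analyses need them.

Alternate conformations are collapsed to a single conformer per atom name:
the highest-occupancy altloc wins, ties broken by altloc identifier order.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "ResidueSelector",
    "read_structure",
    "write_structure",
    "select_atoms",
    "write_report",
    "parse_selector",
]

# 3-letter -> 1-letter amino-acid code (standard residues only)
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class AtomRecord:
    """A single atom: name, element, coordinates and crystallographic metadata."""

    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue with author numbering preserved exactly as in the source file."""

    chain_id: str
    auth_seq_id: int
    res_name: str
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_hetero(self) -> bool:
        return all(a.is_hetero for a in self.atoms) if self.atoms else False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {self.res_name}{self.auth_seq_id}")

    def has_atom(self, name: str) -> bool:
        return any(a.atom_name == name for a in self.atoms)

    def add_atom(self, atom: AtomRecord) -> None:
        if self.has_atom(atom.atom_name):
            raise ValueError(
                f"duplicate atom name {atom.atom_name!r} in {self.res_name}{self.auth_seq_id}"
            )
        self.atoms.append(atom)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq_id, self.insertion_code)

    def label(self) -> str:
        code = THREE_TO_ONE.get(self.res_name)
        name = (code and self.res_name.capitalize()) or self.res_name
        return f"{name}{self.auth_seq_id}{self.insertion_code}"


@dataclass
class Structure:
    """An ordered collection of chains of residues (one coordinate model)."""

    entry_id: str = ""
    model_number: int = 1
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_format: str = "PDB"

    def __post_init__(self) -> None:
        for chain_id, residues in self.chains.items():
            for r in residues:
                if r.chain_id != chain_id:
                    raise ValueError(f"residue {r.key} filed under chain {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not found; available chains: {', '.join(self.chains) or '(none)'}"
            ) from None

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[tuple[Residue, AtomRecord]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def protein_chain_ids(self) -> list[str]:
        """Chains holding at least one standard amino-acid residue with a CA atom."""
        out = []
        for cid, residues in self.chains.items():
            if any(r.res_name in THREE_TO_ONE and r.has_atom("CA") for r in residues):
                out.append(cid)
        return out

    def find_residue(self, chain_id: str, auth_seq_id: int, icode: str = "") -> Residue:
        for r in self.chain(chain_id):
            if r.auth_seq_id == auth_seq_id and r.insertion_code == icode:
                return r
        raise KeyError(f"residue {chain_id}:{auth_seq_id}{icode} not found")

    def remove_waters(self) -> "Structure":
        chains = {
            cid: [r for r in residues if not r.is_water]
            for cid, residues in self.chains.items()
        }
        chains = {cid: res for cid, res in chains.items() if res}
        return Structure(self.entry_id, self.model_number, chains, self.source_format)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


@dataclass(frozen=True)
class ResidueSelector:
    """Inclusive author-numbering residue range on one chain."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"selector start {self.start} > end {self.end}")

    def contains(self, res: Residue) -> bool:
        return res.chain_id == self.chain_id and self.start <= res.auth_seq_id <= self.end

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.start}-{self.end}"


def parse_selector(text: str) -> ResidueSelector:
    """Parse a ``CHAIN:START-END`` selection string."""
    try:
        chain, rng = text.split(":")
        start, end = rng.split("-")
        return ResidueSelector(chain, int(start), int(end))
    except ValueError as exc:
        raise ValueError(f"cannot parse selection {text!r}; expected CHAIN:START-END") from exc


# ---------------------------------------------------------------------------
# Reading


def _detect_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".cif", ".mmcif", ".cif.gz")):
        return "mmCIF"
    return "PDB"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def read_structure(
    path: str | os.PathLike,
    format_hint: Optional[str] = None,
    model_number: Optional[int] = None,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    The first model is returned unless ``model_number`` selects another.
    Hetero records (ions, peptides, waters) are retained with
    ``is_hetero=True`` on their atoms.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format_hint or _detect_format(path)
    try:
        if fmt.upper() in ("MMCIF", "CIF"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(path).sole_block())
            fmt = "mmCIF"
        else:
            st = gemmi.read_pdb(path)
            fmt = "PDB"
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()

    if len(st) == 0:
        raise ValueError(f"{path}: file contains no coordinate model")
    if model_number is None:
        model = st[0]
    else:
        matches = [m for m in st if m.num == model_number]
        if not matches:
            raise ValueError(f"{path}: no model numbered {model_number}")
        model = matches[0]

    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            is_het = res.het_flag == "H"
            record = Residue(
                chain_id=ch.name,
                auth_seq_id=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=res.name,
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, alts in by_name.items():
                a = _pick_altloc(alts)
                record.add_atom(
                    AtomRecord(
                        atom_name=name,
                        element=a.element.name.upper(),
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=min(max(a.occ, 0.0), 1.0),
                        b_factor=a.b_iso,
                        is_hetero=is_het,
                    )
                )
            if record.atoms:
                residues.append(record)
        if residues:
            residues.sort(key=lambda r: (r.auth_seq_id, r.insertion_code))
            chains.setdefault(ch.name, []).extend(residues)

    if not chains:
        raise ValueError(f"{path}: model {model.num} contains no atoms")
    entry_id = st.name or os.path.splitext(os.path.basename(path))[0]
    return Structure(entry_id=entry_id, model_number=model.num, chains=chains, source_format=fmt)


# ---------------------------------------------------------------------------
# Writing


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.entry_id or "XXXX"
    model = gemmi.Model(s.model_number)
    for chain_id, residues in s.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.auth_seq_id, res.insertion_code or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.atom_name
                ga.element = gemmi.Element(atom.element or "X")
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | os.PathLike, format: Optional[str] = None) -> None:
    """Write a structure as PDB (default) or mmCIF, chosen by extension or ``format``."""
    path = os.fspath(path)
    fmt = (format or _detect_format(path)).upper()
    st = _to_gemmi(s)
    if fmt in ("MMCIF", "CIF"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


# ---------------------------------------------------------------------------
# Selection


def select_atoms(
    s: Structure,
    sel: ResidueSelector,
    atom_names: Optional[set[str]] = None,
) -> list[tuple[Residue, AtomRecord]]:
    """Atoms of the selected residues in file order; empty list if nothing matches."""
    out: list[tuple[Residue, AtomRecord]] = []
    for res in s.chain(sel.chain_id):
        if sel.contains(res):
            for atom in res.atoms:
                if atom_names is None or atom.atom_name in atom_names:
                    out.append((res, atom))
    return out


def ca_coords(s: Structure, sel: ResidueSelector) -> np.ndarray:
    """Cα coordinates of the selected range, ordered by residue number (n, 3)."""
    pairs = select_atoms(s, sel, atom_names={"CA"})
    pairs = [(r, a) for r, a in pairs if r.res_name in THREE_TO_ONE or not r.is_hetero]
    return np.array([a.coords for _, a in pairs], dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Report serialization


def _round_floats(obj: Any, ndigits: int = 4) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits) if math.isfinite(obj) else None
    if isinstance(obj, np.floating):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def to_plain(obj: Any) -> Any:
    """Convert a report dataclass (or container of them) to plain JSON-able data."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return to_plain(obj.to_dict())
        return {f.name: to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if hasattr(obj, "to_dict") and not isinstance(obj, (dict, list, tuple)):
        return to_plain(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(obj: Any, path: str | os.PathLike, format: str = "JSON") -> None:
    """Serialize a report object as JSON or TSV with fixed 4-decimal float precision.

    TSV expects the object (after conversion) to be a list of flat records or a
    dict with a ``rows`` entry holding one.
    """
    path = os.fspath(path)
    data = _round_floats(to_plain(obj))
    fmt = format.upper()
    if fmt == "JSON":
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif fmt == "TSV":
        rows = data.get("rows") if isinstance(data, dict) else data
        if not isinstance(rows, list) or not rows or not isinstance(rows[0], dict):
            raise ValueError("TSV output needs a list of flat records (or a dict with 'rows')")
        cols = list(rows[0])
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join("" if row.get(c) is None else str(row.get(c)) for c in cols) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}; use TSV or JSON")


def read_report(path: str | os.PathLike) -> Any:
    with open(path) as fh:
        return json.load(fh)
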