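"""Degenerate peptide-motif analysis for phage-display selection output.

The Sorcin-binding consensus from phage display is the relaxed
Φ/Gly/Met-Φ/Gly/Met-x-P pattern: two positions drawn from
{Trp, Tyr, Phe, Gly, Met} (Φ = aromatic), any residue, then a proline.
An alternative acidic-Φ pattern ({Asp, Glu} followed by an aromatic) marks a
second, calcium-favoured ligand class.  Patterns are ordered lists of
allowed-residue sets; scanning, position-frequency matrices and
per-condition enrichment all operate on those sets directly — no
statistical motif discovery is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideSet",
    "MotifPattern",
    "MotifHit",
    "PositionFrequencyMatrix",
    "builtin_patterns",
    "scan_motif",
    "build_pfm",
    "condition_enrichment",
    "read_peptides",
    "strip_linkers",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AROMATIC = frozenset("WYF")
ACIDIC = frozenset("DE")

# phage-vector linkers flanking the displayed 16-mer; vector-derived,
# stripped before analysis
N_LINKER = "SSSG"
C_LINKER = "GGGSGG"


@dataclass
class PeptideSet:
    sequences: list[str]
    condition_label: str = ""
    unique: bool = False

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("peptide set is empty")
        for i, seq in enumerate(self.sequences):
            bad = [c for c in seq if c not in ALPHABET]
            if not seq:
                raise ValueError(f"sequence {i} is empty")
            if bad:
                raise ValueError(f"sequence {i} holds invalid residue code(s) {bad}")

    def effective_sequences(self) -> list[str]:
        """Sequences as analysed: deduplicated (order-preserving) when unique=True."""
        if not self.unique:
            return list(self.sequences)
        seen: dict[str, None] = {}
        for s in self.sequences:
            seen.setdefault(s)
        return list(seen)

    def __len__(self) -> int:
        return len(self.effective_sequences())


@dataclass(frozen=True)
class MotifPattern:
    """Ordered allowed-residue sets; a wildcard position is the full alphabet."""

    positions: tuple[frozenset[str], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("pattern has no positions")
        for k, allowed in enumerate(self.positions):
            if not allowed or not set(allowed) <= set(ALPHABET):
                raise ValueError(f"pattern position {k + 1}: invalid allowed set {sorted(allowed)}")

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, seq: str, start: int) -> bool:
        """0-based window match test."""
        if start < 0 or start + len(self) > len(seq):
            return False
        return all(seq[start + k] in allowed for k, allowed in enumerate(self.positions))

    def describe(self) -> str:
        full = frozenset(ALPHABET)
        parts = []
        for allowed in self.positions:
            if allowed == full:
                parts.append("x")
            elif len(allowed) == 1:
                parts.append(next(iter(allowed)))
            else:
                parts.append("[" + "".join(sorted(allowed)) + "]")
        return "-".join(parts)


@dataclass(frozen=True)
class MotifHit:
    sequence_index: int
    position: int  # 1-based start of the match
    matched: str


def builtin_patterns(phi: frozenset[str] = AROMATIC) -> dict[str, MotifPattern]:
    """The two phage-display consensus patterns.

    ``phi_gm_x_p``: [ΦGM]-[ΦGM]-x-P with Φ/Gly/Met = {W,Y,F,G,M};
    ``acidic_phi``: [DE]-[Φ] with Φ = aromatic (configurable via ``phi``).
    """
    phi_gm = frozenset(phi | {"G", "M"})
    wildcard = frozenset(ALPHABET)
    return {
        "phi_gm_x_p": MotifPattern(
            positions=(phi_gm, phi_gm, wildcard, frozenset("P")), name="phi_gm_x_p"
        ),
        "acidic_phi": MotifPattern(positions=(ACIDIC, frozenset(phi)), name="acidic_phi"),
    }


def scan_motif(seq: str, pattern: MotifPattern, sequence_index: int = 0) -> list[MotifHit]:
    """All (overlapping) window matches of ``pattern`` in ``seq``, left to right."""
    for pos, c in enumerate(seq):
        if c not in ALPHABET:
            raise ValueError(f"invalid residue code {c!r} at position {pos + 1}")
    hits = []
    for start in range(len(seq) - len(pattern) + 1):
        if pattern.matches_at(seq, start):
            hits.append(
                MotifHit(sequence_index, start + 1, seq[start:start + len(pattern)])
            )
    return hits


@dataclass
class PositionFrequencyMatrix:
    counts: np.ndarray  # (length, 20)
    pseudocount: float = 0.0
    n_sequences: int = 0

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        padded = self.counts + self.pseudocount
        return padded / padded.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.counts.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position information in bits (WebLogo convention, uniform background)."""
        freq = self.frequencies()
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=1)
        return np.log2(len(ALPHABET)) - ent

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=list(ALPHABET))


def build_pfm(
    peps: PeptideSet,
    anchor: Optional[MotifPattern] = None,
    pseudocount: float = 0.0,
    window: Optional[tuple[int, int]] = None,
) -> PositionFrequencyMatrix:
    """Position-wise residue counts, optionally anchored on a motif.

    Without an anchor, all sequences must share one length and are counted
    column-wise.  With an anchor pattern, each sequence is aligned on its
    *first* motif hit before counting; sequences without a hit are dropped
    (their count is recoverable from ``n_sequences`` vs ``len(peps)``).
    ``window`` = (n_before, n_after) widens the counted region around the
    anchored motif; positions outside a given sequence contribute nothing.
    """
    seqs = peps.effective_sequences()
    if anchor is None:
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths {sorted(lengths)}; use an anchor pattern")
        length = lengths.pop()
        counts = np.zeros((length, len(ALPHABET)))
        for seq in seqs:
            for pos, c in enumerate(seq):
                counts[pos, ALPHABET.index(c)] += 1
        return PositionFrequencyMatrix(counts, pseudocount, n_sequences=len(seqs))

    before, after = window or (0, 0)
    length = before + len(anchor) + after
    counts = np.zeros((length, len(ALPHABET)))
    n_used = 0
    for idx, seq in enumerate(seqs):
        hits = scan_motif(seq, anchor, idx)
        if not hits:
            continue
        n_used += 1
        start = hits[0].position - 1 - before
        for col in range(length):
            pos = start + col
            if 0 <= pos < len(seq):
                counts[col, ALPHABET.index(seq[pos])] += 1
    if n_used == 0:
        raise ValueError("no sequence contains the anchor motif")
    return PositionFrequencyMatrix(counts, pseudocount, n_sequences=n_used)


def condition_enrichment(
    a: PeptideSet, b: PeptideSet, pattern: MotifPattern
) -> pd.DataFrame:
    """Per-condition fraction of sequences carrying ≥1 motif hit."""
    rows = []
    for peps in (a, b):
        seqs = peps.effective_sequences()
        n_hit = sum(1 for s in seqs if scan_motif(s, pattern))
        rows.append(
            {
                "condition": peps.condition_label,
                "n_sequences": len(seqs),
                "n_with_motif": n_hit,
                "fraction": n_hit / len(seqs),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Input handling


def strip_linkers(seq: str, n_linker: str = N_LINKER, c_linker: str = C_LINKER) -> str:
    """Remove phage-vector flanking linkers if present."""
    if n_linker and seq.startswith(n_linker):
        seq = seq[len(n_linker):]
    if c_linker and seq.endswith(c_linker):
        seq = seq[: -len(c_linker)]
    return seq


def read_peptides(path: str, condition_label: str = "", unique: bool = True,
                  remove_linkers: bool = True) -> PeptideSet:
    """Read peptides from FASTA or one-sequence-per-line text."""
    seqs: list[str] = []
    with open(path) as fh:
        current: list[str] = []
        is_fasta = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                is_fasta = True
                if current:
                    seqs.append("".join(current))
                    current = []
            elif is_fasta:
                current.append(line.upper())
            else:
                seqs.append(line.upper())
        if current:
            seqs.append("".join(current))
    if remove_linkers:
        seqs = [strip_linkers(s) for s in seqs]
    return PeptideSet(sequences=seqs, condition_label=condition_label, unique=unique)


def plot_logo(pfm: PositionFrequencyMatrix, path: str) -> None:
    """Information-content-scaled sequence logo (simple matplotlib rendering)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freq = pfm.frequencies()
    info = pfm.information_content()
    fig, ax = plt.subplots(figsize=(max(3, pfm.length * 0.6), 3))
    for pos in range(pfm.length):
        order = np.argsort(freq[pos])
        bottom = 0.0
        for j in order:
            h = freq[pos, j] * info[pos]
            if h < 1e-3:
                continue
            ax.text(pos + 1, bottom + h / 2, ALPHABET[j],
                    ha="center", va="center", fontsize=8 + 14 * freq[pos, j],
                    family="monospace")
            bottom += h
    ax.set_xlim(0.5, pfm.length + 0.5)
    ax.set_ylim(0, max(1e-6, info.max()) * 1.1)
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
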