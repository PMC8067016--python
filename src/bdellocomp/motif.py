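"""Wildcard protein-motif scanning.

The default pattern is the conserved chitinase catalytic motif DXXDXDXE,
where X matches any of the 20 standard amino acids. Literal positions match
only themselves; non-standard residues (B, Z, U, *, ...) match neither a
literal nor X, so ambiguous translations never produce a hit. All matches,
including overlapping ones, are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .synthetic_data import AMINO_ACIDS

DEFAULT_MOTIF = "DXXDXDXE"

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    start: int  # 0-based
    matched: str

    @property
    def end(self) -> int:
        """Half-open end offset."""
        return self.start + len(self.matched)


def _validate_pattern(pattern: str) -> str:
    if not pattern:
        raise ValueError("empty motif pattern")
    pattern = pattern.upper()
    bad = set(pattern) - _AA_SET - {"X"}
    if bad:
        raise ValueError(f"pattern contains invalid symbols: {sorted(bad)}")
    return pattern


def _matches_at(seq: str, pos: int, pattern: str) -> bool:
    for j, ch in enumerate(pattern):
        residue = seq[pos + j]
        if ch == "X":
            if residue not in _AA_SET:
                return False
        elif residue != ch:
            return False
    return True


def scan_motif(
    proteins: Iterable[tuple[str, str]], pattern: str = DEFAULT_MOTIF
) -> list[MotifMatch]:
    """All (overlapping) motif matches, sorted by (protein_id, start)."""
    pattern = _validate_pattern(pattern)
    plen = len(pattern)
    out: list[MotifMatch] = []
    for pid, seq in proteins:
        seq = seq.upper()
        for pos in range(len(seq) - plen + 1):
            if _matches_at(seq, pos, pattern):
                out.append(MotifMatch(pid, pos, seq[pos : pos + plen]))
    out.sort(key=lambda m: (m.protein_id, m.start))
    return out
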