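"""Small shared helpers: exact percentage rounding and sequence encoding.

Printed percentages throughout the package use half-away-from-zero rounding
(77.78 from 7/9, 21.05 from 4/19, ...), computed from the integer counts so
no binary floating-point artefact can flip a boundary case.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

GROUPS: tuple[str, ...] = (
    "Oligoflexia",
    "Bdello-group1",
    "Bdello-group2",
    "Bacteriovoracia",
)

MARINE = "marine"
NONMARINE_SOURCES: tuple[str, ...] = (
    "subsurface sediment",
    "bioreactor sludge",
    "waste water",
    "ground water",
    "other",
)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_BASE = np.array(list("ACGTN"), dtype="U1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def pct_exact(count: int, total: int, decimals: int = 2) -> float:
    """Percentage 100*count/total rounded half-away-from-zero.

    Computed over exact rationals: pct_exact(7, 9) == 77.78 and
    pct_exact(17, 19) == 89.47 with no float round-trip in between.
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    scale = 10**decimals
    scaled = Fraction(100 * scale * count, total)
    rounded = math.floor(scaled + Fraction(1, 2))
    return rounded / scale


def round_half_away(x: float, decimals: int = 2) -> float:
    """Half-away-from-zero rounding of a float (sign-symmetric)."""
    scale = 10**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def encode_dna(seq: str) -> np.ndarray:
    """Map a DNA string over {A,C,G,T,N} to a uint8 code array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = chr(int(arr[out == 255][0]))
        raise ValueError(f"invalid DNA character {bad!r}")
    return out


def decode_dna(codes: np.ndarray) -> str:
    return "".join(_CODE_BASE[codes])


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
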