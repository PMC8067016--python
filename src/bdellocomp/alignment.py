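"""Seed-and-extend semi-global alignment for short 16S reads.

The read is aligned end-to-end against a window of the reference (reference
overhangs are free), with affine gap costs under the Gotoh three-state
recurrence. Shared k-mer seeds pick the reference windows; the dynamic
program then runs over a diagonal band wide enough that, at the divergence
this pipeline filters for (>97% identity), the banded score equals the
unrestricted optimum.

Scoring convention: match +2, mismatch -3; a gap of length L costs
``gap_open + L * gap_extend`` (defaults -5 - 2L). ``N`` never matches.
Identity = match columns / aligned columns, gap columns included in the
denominator (BLAST convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def _gotoh_semiglobal(
    r: np.ndarray,
    g: np.ndarray,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
):
    """Semi-global Gotoh DP: read ``r`` fully aligned, ref ``g`` overhangs free.

    Returns (score, matches, aligned_columns). States: M (substitution),
    Ix (read char vs gap), Iy (ref char vs gap). Alignments may not end in
    Iy (trailing read-gap columns are just free reference suffix).
    """
    m = r.size
    n = g.size
    M = np.empty((m + 1, n + 1), np.int32)
    Ix = np.empty((m + 1, n + 1), np.int32)
    Iy = np.empty((m + 1, n + 1), np.int32)
    PM = np.zeros((m + 1, n + 1), np.uint8)  # predecessor state of M
    PX = np.zeros((m + 1, n + 1), np.uint8)  # 0: opened from M, 1: extended
    PY = np.zeros((m + 1, n + 1), np.uint8)

    for j in range(n + 1):
        M[0, j] = 0
        Ix[0, j] = NEG
        Iy[0, j] = NEG
    for i in range(1, m + 1):
        M[i, 0] = NEG
        Iy[i, 0] = NEG
        Ix[i, 0] = gap_open + gap_extend * i
        PX[i, 0] = 0 if i == 1 else 1

    for i in range(1, m + 1):
        ri = r[i - 1]
        for j in range(1, n + 1):
            s = match if (ri == g[j - 1] and ri < 4) else mismatch
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            PM[i, j] = p

            a = M[i - 1, j] + gap_open + gap_extend
            b = Ix[i - 1, j] + gap_extend
            if a >= b:
                Ix[i, j] = a
                PX[i, j] = 0
            else:
                Ix[i, j] = b
                PX[i, j] = 1

            a = M[i, j - 1] + gap_open + gap_extend
            b = Iy[i, j - 1] + gap_extend
            if a >= b:
                Iy[i, j] = a
                PY[i, j] = 0
            else:
                Iy[i, j] = b
                PY[i, j] = 1

    best_score = NEG
    best_j = 0
    best_state = 0
    for j in range(n + 1):
        if M[m, j] > best_score:
            best_score = M[m, j]
            best_j = j
            best_state = 0
        if Ix[m, j] > best_score:
            best_score = Ix[m, j]
            best_j = j
            best_state = 1

    # traceback for identity bookkeeping
    i = m
    j = best_j
    state = best_state
    matches = 0
    cols = 0
    while i > 0:
        if state == 0:
            cols += 1
            if r[i - 1] == g[j - 1] and r[i - 1] < 4:
                matches += 1
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            cols += 1
            came = PX[i, j]
            i -= 1
            state = 0 if came == 0 else 1
        else:
            cols += 1
            came = PY[i, j]
            j -= 1
            state = 0 if came == 0 else 2
    return best_score, matches, cols


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    matches: int
    aln_len: int
    orientation: str  # "+" or "-"

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len if self.aln_len else 0.0


def seed_diagonals(read: str, ref: str, k: int) -> list[int]:
    """Diagonals (ref_pos - read_pos) of shared exact k-mers."""
    if len(read) < k or len(ref) < k:
        return []
    ref_pos: dict[str, list[int]] = {}
    for j in range(len(ref) - k + 1):
        ref_pos.setdefault(ref[j : j + k], []).append(j)
    diags: set[int] = set()
    for i in range(len(read) - k + 1):
        hits = ref_pos.get(read[i : i + k])
        if hits:
            for j in hits:
                diags.add(j - i)
    return sorted(diags)


def cluster_windows(
    diags: list[int], read_len: int, ref_len: int, pad: int
) -> list[tuple[int, int]]:
    """Merge nearby seed diagonals into reference windows [start, end)."""
    windows: list[tuple[int, int]] = []
    if not diags:
        return windows
    run = [diags[0]]
    for d in diags[1:]:
        if d - run[-1] <= 2 * pad:
            run.append(d)
        else:
            windows.append(run_window(run, read_len, ref_len, pad))
            run = [d]
    windows.append(run_window(run, read_len, ref_len, pad))
    return windows


def run_window(
    run: list[int], read_len: int, ref_len: int, pad: int
) -> tuple[int, int]:
    start = max(0, run[0] - pad)
    end = min(ref_len, run[-1] + read_len + pad)
    return start, end


def align_coded(
    read_codes: np.ndarray,
    ref_codes: np.ndarray,
    windows: list[tuple[int, int]],
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
) -> tuple[int, int, int] | None:
    """Best (score, matches, cols) over the seeded windows, or None."""
    best: tuple[int, int, int] | None = None
    for start, end in windows:
        res = _gotoh_semiglobal(
            read_codes, ref_codes[start:end], match, mismatch, gap_open, gap_extend
        )
        if best is None or res[0] > best[0]:
            best = (int(res[0]), int(res[1]), int(res[2]))
    return best
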