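"""Independent reference implementations used only to check the package.

These deliberately share no code with bdellocomp: a full (unbanded,
whole-reference) semi-global Gotoh dynamic program in plain Python, a
complete permutation enumeration of the rank-sum null, and a regex-based
overlapping motif scanner.
"""

from __future__ import annotations

import re
from itertools import combinations

from scipy.stats import rankdata

NEG = float("-inf")


def semiglobal_full_dp(
    read: str,
    ref: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> float:
    """Optimal semi-global score: read fully aligned, ref overhangs free.

    Affine gaps: a length-L gap costs gap_open + L * gap_extend. Alignments
    may not end in a read-gap state (that would just be free ref suffix).
    """
    m, n = len(read), len(ref)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0
    for i in range(1, m + 1):
        Ix[i][0] = gap_open + gap_extend * i
    for i in range(1, m + 1):
        ri = read[i - 1]
        Mi, Mim = M[i], M[i - 1]
        Ixi, Ixim = Ix[i], Ix[i - 1]
        Iyi, Iyim = Iy[i], Iy[i - 1]
        for j in range(1, n + 1):
            s = match if (ri == ref[j - 1] and ri != "N") else mismatch
            Mi[j] = max(Mim[j - 1], Ixim[j - 1], Iyim[j - 1]) + s
            Ixi[j] = max(Mim[j] + gap_open + gap_extend, Ixim[j] + gap_extend)
            Iyi[j] = max(Mi[j - 1] + gap_open + gap_extend, Iyi[j - 1] + gap_extend)
    return max(max(M[m][j], Ix[m][j]) for j in range(n + 1))


def rank_sum_enumeration(a, b) -> tuple[float, float]:
    """(W, two-sided p) by enumerating every assignment of pooled ranks.

    W is the midrank sum of the first sample; p is the two-sided
    permutation probability min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    pooled = list(a) + list(b)
    ranks = rankdata(pooled)
    na = len(a)
    w_obs = float(ranks[:na].sum())
    n_le = n_ge = total = 0
    for idx in combinations(range(len(pooled)), na):
        w = float(sum(ranks[i] for i in idx))
        total += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return w_obs, p


def regex_motif_positions(seq: str, pattern: str = "DXXDXDXE") -> list[int]:
    """Overlapping wildcard-motif start offsets via regex lookahead."""
    aa = "ACDEFGHIKLMNPQRSTVWY"
    rx = "".join(f"[{aa}]" if ch == "X" else re.escape(ch) for ch in pattern)
    return [m.start() for m in re.finditer(f"(?=({rx}))", seq)]
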