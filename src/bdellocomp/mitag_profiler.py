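"""16S miTag read classification and depth-stratified abundance profiling.

Reads are matched against a labeled 16S reference set by seeded semi-global
alignment; only reads longer than 100 bp with identity strictly above 97%
to their best reference are assigned, mirroring the published filters. A
raw alignment-score floor stands in for the original search's E-value
cutoff (at >97% identity over >100 bp, any reported hit clears a 1e-5
E-value by orders of magnitude, so the decision boundary is unchanged).

Per-sample relative abundance of a group is the percentage of that sample's
total 16S miTags assigned to the group. Samples are stratified into ocean
layers (epipelagic [0,200) m, mesopelagic [200,1000) m, deep >=1000 m) and
between-layer differences are tested with Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import (
    AlignmentResult,
    align_coded,
    cluster_windows,
    seed_diagonals,
)
from .util import GROUPS, encode_dna, revcomp

LAYERS = ("epipelagic", "mesopelagic", "deep")


@dataclass(frozen=True)
class Reference16S:
    ref_id: str
    group: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.ref_id}: empty sequence")


@dataclass(frozen=True)
class MatchConfig:
    min_read_len: int = 100  # strict >
    min_identity: float = 0.97  # strict >
    k_seed: int = 12
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 60
    band_pad: int = 8


@dataclass(frozen=True)
class HitRecord:
    read_id: str
    ref_id: str
    identity: float
    aln_len: int
    score: int
    group: str


@dataclass
class MiTagSample:
    sample_id: str
    depth_m: float
    reads: list[tuple[str, str]]
    total_mitags: int | None = None

    def __post_init__(self) -> None:
        if self.total_mitags is None:
            self.total_mitags = len(self.reads)


@dataclass
class AbundanceProfile:
    sample_id: str
    layer: str
    abundance_pct: dict[str, float]


class ReferenceDB:
    """Labeled references with a k-mer seed index (forward strand)."""

    def __init__(self, refs: Sequence[Reference16S], k_seed: int = 12) -> None:
        if not refs:
            raise ValueError("reference set is empty")
        self.refs = list(refs)
        self.k = k_seed
        self.codes = [encode_dna(r.sequence) for r in self.refs]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for idx, ref in enumerate(self.refs):
            seq = ref.sequence
            for j in range(len(seq) - self.k + 1):
                self.index.setdefault(seq[j : j + self.k], []).append((idx, j))

    def candidate_diagonals(self, read: str) -> dict[int, list[int]]:
        """ref index -> sorted seed diagonals shared with ``read``."""
        per_ref: dict[int, set[int]] = {}
        k = self.k
        for i in range(len(read) - k + 1):
            hits = self.index.get(read[i : i + k])
            if hits:
                for idx, j in hits:
                    per_ref.setdefault(idx, set()).add(j - i)
        return {idx: sorted(d) for idx, d in per_ref.items()}


def align_read(
    read: str, ref: str | Reference16S, cfg: MatchConfig | None = None
) -> AlignmentResult | None:
    """Best seeded semi-global alignment of ``read`` (either strand) to ``ref``.

    Returns None when no k-mer seed is shared or the best score falls below
    the score floor. Ties between strands go to the forward read.
    """
    cfg = cfg or MatchConfig()
    if not read:
        raise ValueError("empty read")
    ref_seq = ref.sequence if isinstance(ref, Reference16S) else ref
    ref_codes = encode_dna(ref_seq)
    best: AlignmentResult | None = None
    for orient, oriented in (("+", read), ("-", revcomp(read))):
        diags = seed_diagonals(oriented, ref_seq, cfg.k_seed)
        windows = cluster_windows(diags, len(oriented), len(ref_seq), cfg.band_pad)
        if not windows:
            continue
        res = align_coded(
            encode_dna(oriented), ref_codes, windows,
            cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend,
        )
        if res is None:
            continue
        cand = AlignmentResult(res[0], res[1], res[2], orient)
        if best is None or cand.score > best.score:
            best = cand
    if best is None or best.score < cfg.min_score:
        return None
    return best


def _best_hit(
    read_id: str, read: str, refdb: ReferenceDB, cfg: MatchConfig
) -> HitRecord | None:
    """Best-scoring hit across the reference set, both strands."""
    candidates: list[HitRecord] = []
    for orient, oriented in (("+", read), ("-", revcomp(read))):
        per_ref = refdb.candidate_diagonals(oriented)
        if not per_ref:
            continue
        codes = encode_dna(oriented)
        for idx, diags in per_ref.items():
            ref = refdb.refs[idx]
            windows = cluster_windows(
                diags, len(oriented), len(ref.sequence), cfg.band_pad
            )
            res = align_coded(
                codes, refdb.codes[idx], windows,
                cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend,
            )
            if res is None or res[0] < cfg.min_score:
                continue
            score, matches, cols = res
            candidates.append(
                HitRecord(
                    read_id, ref.ref_id, matches / cols if cols else 0.0,
                    cols, score, ref.group,
                )
            )
    if not candidates:
        return None
    # best score; ties: higher identity, longer alignment, smallest ref id
    return min(
        candidates,
        key=lambda h: (-h.score, -h.identity, -h.aln_len, h.ref_id),
    )


def classify_read(
    read: str, refdb: ReferenceDB, cfg: MatchConfig | None = None,
    read_id: str = "read",
) -> str:
    """Group label for a read, or ``"unassigned"``.

    Reads of length <= 100 bp are dropped before alignment; assignment
    additionally requires identity strictly above 0.97 to the best hit.
    """
    cfg = cfg or MatchConfig()
    if len(read) <= cfg.min_read_len:
        return "unassigned"
    hit = _best_hit(read_id, read, refdb, cfg)
    if hit is None or not hit.identity > cfg.min_identity:
        return "unassigned"
    return hit.group


def assign_layer(depth_m: float) -> str:
    """Ocean layer from depth: [0,200) epi-, [200,1000) meso-, >=1000 deep."""
    if depth_m < 0:
        raise ValueError(f"negative depth: {depth_m}")
    if depth_m < 200:
        return "epipelagic"
    if depth_m < 1000:
        return "mesopelagic"
    return "deep"


def profile_sample_hits(
    sample: MiTagSample, refdb: ReferenceDB, cfg: MatchConfig | None = None
) -> tuple[AbundanceProfile, list[HitRecord]]:
    """Profile a sample and keep the best hit of every assigned read."""
    cfg = cfg or MatchConfig()
    if not sample.total_mitags or sample.total_mitags <= 0:
        raise ValueError(f"sample {sample.sample_id}: total_mitags must be > 0")
    counts = {g: 0 for g in GROUPS}
    hits: list[HitRecord] = []
    for read_id, seq in sample.reads:
        if len(seq) <= cfg.min_read_len:
            continue
        hit = _best_hit(read_id, seq, refdb, cfg)
        if hit is not None and hit.identity > cfg.min_identity:
            counts[hit.group] += 1
            hits.append(hit)
    abund = {g: 100.0 * counts[g] / sample.total_mitags for g in GROUPS}
    profile = AbundanceProfile(
        sample.sample_id, assign_layer(sample.depth_m), abund
    )
    return profile, hits


def profile_sample(
    sample: MiTagSample, refdb: ReferenceDB, cfg: MatchConfig | None = None
) -> AbundanceProfile:
    """Per-group relative abundance: 100 x assigned reads / total miTags."""
    profile, _ = profile_sample_hits(sample, refdb, cfg)
    return profile


def profiles_frame(profiles: Iterable[AbundanceProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "layer": p.layer}
        row.update({g: p.abundance_pct[g] for g in GROUPS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "layer", *GROUPS])


def compare_layers(
    profiles: Sequence[AbundanceProfile],
    group: str,
    layer_a: str,
    layer_b: str,
) -> tuple[float, float]:
    """Welch's two-sided t-test on per-sample abundances of ``group``.

    Returns (t statistic, p value); each layer needs at least two samples.
    Identical inputs give t = 0, p = 1.
    """
    a = [p.abundance_pct[group] for p in profiles if p.layer == layer_a]
    b = [p.abundance_pct[group] for p in profiles if p.layer == layer_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >=2 samples per layer, got {len(a)} ({layer_a}) "
            f"and {len(b)} ({layer_b})"
        )
    if np.allclose(a, np.mean(a + b)) and np.allclose(b, np.mean(a + b)):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def significance_label(p: float) -> str:
    """Figure-style annotation: **** below 1e-4, * below 0.05, else ns."""
    if p < 1e-4:
        return "****"
    if p < 0.05:
        return "*"
    return "ns"
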