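"""Presence/absence and copy-number analytics over annotated genomes.

The core objects are a boolean genes x genomes presence matrix and its
copy-number twin, built from long-form annotation tables (genome, namespace,
gene, copies). On top of them:

* group-level presence — a group "has" a gene when at least 50% of its
  genomes carry it (inclusive);
* group-specific genes — present in strictly more than 50% of genomes of
  exactly one group and in at most 50% of every other (the two thresholds
  are deliberately different: "at least" vs "more than");
* marine enrichment — per-gene presence percentages among a group's marine
  vs non-marine genomes, rounded half-away-from-zero to two decimals;
* peptidase Venn partition over the four groups' MEROPS family sets;
* CAZy class profiles (mean per-genome copies per class);
* Wilcoxon rank-sum tests on copy-number vectors (exact null for small
  tie-free samples, normal approximation with continuity and tie
  correction otherwise), reported raw and Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .util import GROUPS, MARINE, pct_exact

NAMESPACES = ("KEGG", "COG", "MEROPS", "CAZy")
CAZY_CLASSES = ("GH", "PL", "GT", "CE", "CBM", "AA")


@dataclass
class PresenceMatrix:
    """Genes x genomes boolean presence plus integer copy numbers."""

    presence: pd.DataFrame  # bool, index=gene_id, columns=genome_id
    copies: pd.DataFrame  # int, same shape
    namespace: pd.Series  # per gene_id

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-form (genome_id, namespace, gene_id, copies) for present genes."""
        stacked = self.copies.stack()
        stacked = stacked[stacked > 0]
        out = stacked.rename("copies").reset_index()
        out.columns = ["gene_id", "genome_id", "copies"]
        out["namespace"] = out["gene_id"].map(self.namespace)
        out = out[["genome_id", "namespace", "gene_id", "copies"]]
        return out.sort_values(
            ["genome_id", "namespace", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)


def build_presence_matrix(
    annotations: pd.DataFrame, genomes: Sequence[str] | None = None
) -> PresenceMatrix:
    """Pivot a long-form annotation table; copies summed over duplicate rows.

    ``genomes`` lists every genome that should appear as a column (genomes
    with no annotations get all-zero columns); by default only annotated
    genomes appear.
    """
    ann = annotations
    if (ann["copies"] < 0).any():
        bad = ann.loc[ann["copies"] < 0].iloc[0]
        raise ValueError(
            f"negative copy number for {bad['genome_id']}/{bad['gene_id']}"
        )
    ns = ann.drop_duplicates("gene_id").set_index("gene_id")["namespace"]
    conflicts = ann.groupby("gene_id")["namespace"].nunique()
    if (conflicts > 1).any():
        raise ValueError(
            f"gene(s) in multiple namespaces: {list(conflicts[conflicts > 1].index)}"
        )
    copies = (
        ann.groupby(["gene_id", "genome_id"])["copies"].sum().unstack(fill_value=0)
    )
    if genomes is not None:
        copies = copies.reindex(columns=list(genomes), fill_value=0)
        unknown = set(ann["genome_id"]) - set(genomes)
        if unknown:
            raise ValueError(f"annotations reference unknown genomes: {sorted(unknown)}")
    copies = copies.sort_index().astype(int)
    copies = copies[sorted(copies.columns)] if genomes is None else copies
    return PresenceMatrix(presence=copies > 0, copies=copies,
                          namespace=ns.sort_index())


def _group_members(meta: pd.DataFrame, group: str) -> list[str]:
    return list(meta.loc[meta["group"] == group, "genome_id"])


def group_presence(
    pm: PresenceMatrix, meta: pd.DataFrame, groups: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per (gene, group) presence fraction and the >=50% group-level flag."""
    groups = list(groups) if groups is not None else [
        g for g in GROUPS if (meta["group"] == g).any()
    ]
    rows = []
    for group in groups:
        members = [g for g in _group_members(meta, group) if g in pm.presence.columns]
        if not members:
            raise ValueError(f"group {group!r} has no genomes")
        sub = pm.presence[members]
        n = len(members)
        n_present = sub.sum(axis=1)
        for gene in pm.genes:
            k = int(n_present[gene])
            rows.append(
                {
                    "gene_id": gene,
                    "group": group,
                    "n_group": n,
                    "n_present": k,
                    "fraction": k / n,
                    "present": k / n >= 0.5,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "group", "n_group", "n_present",
                       "fraction", "present"]
    )


def call_group_specific(gp: pd.DataFrame, gene: str) -> str | None:
    """The unique group with fraction strictly > 0.5 for ``gene``, if all
    other groups sit at <= 0.5; otherwise None."""
    sub = gp[gp["gene_id"] == gene]
    over = sub.loc[sub["fraction"] > 0.5, "group"].tolist()
    return over[0] if len(over) == 1 else None


def count_group_specific(
    pm: PresenceMatrix, meta: pd.DataFrame, namespace: str
) -> dict[str, int]:
    """Number of ``namespace`` genes specific to each group."""
    if namespace not in ("KEGG", "COG"):
        raise ValueError(f"namespace must be KEGG or COG, got {namespace!r}")
    genes = [g for g in pm.genes if pm.namespace.get(g) == namespace]
    gp = group_presence(pm, meta)
    counts = {g: 0 for g in GROUPS if (meta["group"] == g).any()}
    for gene in genes:
        label = call_group_specific(gp, gene)
        if label is not None:
            counts[label] += 1
    return counts


def enrichment_table(
    pm: PresenceMatrix, meta: pd.DataFrame, group: str
) -> pd.DataFrame:
    """Marine vs non-marine presence percentages for one group's genes.

    Rows cover every gene carried by at least one genome of the group, sorted
    by marine percentage (descending, then gene id). Percentages carry exact
    two-decimal and whole-percent (display) roundings; a side with zero
    genomes yields NaN percentages.
    """
    members = meta[meta["group"] == group]
    if members.empty:
        raise ValueError(f"unknown or empty group {group!r}")
    marine_ids = [
        g for g in members.loc[members["environment"] == MARINE, "genome_id"]
        if g in pm.presence.columns
    ]
    nonmar_ids = [
        g for g in members.loc[members["environment"] != MARINE, "genome_id"]
        if g in pm.presence.columns
    ]
    n_mar, n_non = len(marine_ids), len(nonmar_ids)
    rows = []
    in_group = pm.presence[marine_ids + nonmar_ids].any(axis=1)
    for gene in pm.presence.index[in_group]:
        c_mar = int(pm.presence.loc[gene, marine_ids].sum()) if n_mar else 0
        c_non = int(pm.presence.loc[gene, nonmar_ids].sum()) if n_non else 0
        rows.append(
            {
                "gene_id": gene,
                "group": group,
                "marine_n": n_mar,
                "nonmarine_n": n_non,
                "marine_present": c_mar,
                "nonmarine_present": c_non,
                "marine_pct": pct_exact(c_mar, n_mar) if n_mar else np.nan,
                "nonmarine_pct": pct_exact(c_non, n_non) if n_non else np.nan,
                "marine_pct_display": pct_exact(c_mar, n_mar, 0) if n_mar else np.nan,
                "nonmarine_pct_display": pct_exact(c_non, n_non, 0) if n_non else np.nan,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "group", "marine_n", "nonmarine_n",
            "marine_present", "nonmarine_present",
            "marine_pct", "nonmarine_pct",
            "marine_pct_display", "nonmarine_pct_display",
        ],
    )
    return out.sort_values(
        ["marine_pct", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def wilcoxon_copy_test(
    copies_a: Sequence[float], copies_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum on copy-number vectors.

    Returns (W, p) where W is the rank-sum of the first sample with midrank
    ties. The null is exact when min(nA, nB) <= 8 and there are no ties,
    otherwise a normal approximation with continuity and tie correction.
    """
    a = np.asarray(copies_a, dtype=float)
    b = np.asarray(copies_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty copy-number vector")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank-sum W
    return w, float(res.pvalue)


def wilcoxon_table(
    pm: PresenceMatrix,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Per-gene copy-number Wilcoxon tests between two groups, with BH FDR."""
    ids_a = [g for g in _group_members(meta, group_a) if g in pm.copies.columns]
    ids_b = [g for g in _group_members(meta, group_b) if g in pm.copies.columns]
    if not ids_a or not ids_b:
        raise ValueError("both groups need at least one genome")
    genes = [
        g for g in pm.genes
        if namespace is None or pm.namespace.get(g) == namespace
    ]
    rows = []
    for gene in genes:
        w, p = wilcoxon_copy_test(
            pm.copies.loc[gene, ids_a].to_numpy(),
            pm.copies.loc[gene, ids_b].to_numpy(),
        )
        rows.append({"gene_id": gene, "W": w, "p": p})
    out = pd.DataFrame(rows, columns=["gene_id", "W", "p"])
    if len(out):
        out["p_bh"] = stats.false_discovery_control(out["p"], method="bh")
    else:
        out["p_bh"] = []
    return out


@dataclass
class VennPartition:
    """Counts and members of the 15 non-empty group-combination regions."""

    regions: dict[frozenset, list[str]]

    def count(self, groups: Sequence[str]) -> int:
        return len(self.regions.get(frozenset(groups), []))

    def members(self, groups: Sequence[str]) -> list[str]:
        return list(self.regions.get(frozenset(groups), []))

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "groups": "|".join(sorted(key)),
                "n_families": len(fams),
                "families": ",".join(fams),
            }
            for key, fams in sorted(
                self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["groups", "n_families", "families"])


def peptidase_venn(pm: PresenceMatrix, meta: pd.DataFrame) -> VennPartition:
    """Partition MEROPS families by which groups carry them (>=50% rule)."""
    merops = [g for g in pm.genes if pm.namespace.get(g) == "MEROPS"]
    if not merops:
        return VennPartition(regions={})
    gp = group_presence(pm, meta)
    gp = gp[gp["gene_id"].isin(merops) & gp["present"]]
    regions: dict[frozenset, list[str]] = {}
    for gene, sub in gp.groupby("gene_id"):
        signature = frozenset(sub["group"])
        regions.setdefault(signature, []).append(gene)
    return VennPartition(
        regions={k: sorted(v) for k, v in regions.items()}
    )


def cazy_class(gene_id: str) -> str | None:
    """Leading alphabetic prefix if it is a CAZy class, else None."""
    prefix = ""
    for ch in gene_id:
        if ch.isalpha():
            prefix += ch
        else:
            break
    return prefix if prefix in CAZY_CLASSES else None


def cazy_class_counts(pm: PresenceMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean of per-genome summed copy numbers for each CAZy class."""
    cazy_genes = [g for g in pm.genes if pm.namespace.get(g) == "CAZy"]
    classed: dict[str, list[str]] = {c: [] for c in CAZY_CLASSES}
    for gene in cazy_genes:
        cls = cazy_class(gene)
        if cls is None:
            warnings.warn(f"unrecognized CAZy class prefix for {gene!r}; excluded")
            continue
        classed[cls].append(gene)
    groups = [g for g in GROUPS if (meta["group"] == g).any()]
    rows = []
    for group in groups:
        members = [g for g in _group_members(meta, group) if g in pm.copies.columns]
        row = {"group": group}
        for cls in CAZY_CLASSES:
            if classed[cls] and members:
                per_genome = pm.copies.loc[classed[cls], members].sum(axis=0)
                row[cls] = float(per_genome.mean())
            else:
                row[cls] = 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["group", *CAZY_CLASSES])


def source_tally(meta: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each environment source within each group (2 decimals)."""
    if meta["environment"].isna().any():
        bad = meta.loc[meta["environment"].isna(), "genome_id"].tolist()
        raise ValueError(f"genomes without environment label: {bad}")
    rows = []
    for group, sub in meta.groupby("group", sort=True):
        n = len(sub)
        for env, cnt in sub["environment"].value_counts().sort_index().items():
            rows.append(
                {
                    "group": group,
                    "environment": env,
                    "n": int(cnt),
                    "n_group": n,
                    "pct": pct_exact(int(cnt), n),
                }
            )
    return pd.DataFrame(rows, columns=["group", "environment", "n", "n_group", "pct"])
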