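"""Synthetic genomes, annotations, miTag read sets, and motif-bearing proteins.

Two kinds of inputs live here:

* Deterministic *worked-example fixtures* (``make_fixture``): small genome
  collections whose per-group presence counts are the smallest integers that
  reproduce, under half-away-from-zero rounding, the marine-enrichment,
  source-tally, cheB-presence, and shared-peptidase figures this pipeline is
  built to compute. They let every downstream stage run with no downloads.
* Seeded *simulators* for annotation tables, layered 16S miTag read sets,
  mutated genome pairs, and proteins with planted motifs, each returning its
  generating truth so estimators can be checked against known parameters.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
seed reproduces byte-identical serializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ANNOTATION_COLUMNS, METADATA_COLUMNS, write_tsv
from .util import GROUPS, MARINE, NONMARINE_SOURCES, decode_dna, encode_dna

FIXTURE_NAMES = ("W1_enrichment", "W2_sources", "W3_cheB", "W4_peptidases")

#: Reserved gene-id prefix for background (non-focal) genes in simulations,
#: so truth tables are unambiguous.
BACKGROUND_PREFIX = "BGK"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureBundle:
    """A named genome collection: metadata plus long-form annotations."""

    name: str
    metadata: pd.DataFrame
    annotations: pd.DataFrame
    notes: str = ""

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta_path = outdir / f"{self.name}.metadata.tsv"
        ann_path = outdir / f"{self.name}.annotations.tsv"
        write_tsv(self.metadata, meta_path)
        write_tsv(self.annotations, ann_path)
        return {"metadata": meta_path, "annotations": ann_path}


@dataclass
class MiTagConfig:
    """Layered miTag simulation: read counts, lengths, error and divergence."""

    n_reads: int = 10_000
    read_len: tuple[int, int] = (120, 180)
    error_rate: float = 0.005
    ref_length: int = 1500
    ref_divergence: float = 0.10
    decoy_divergence: float = 0.25
    n_decoys: int = 2
    n_samples_per_layer: int = 10
    #: per-layer group abundance vectors; remaining mass is decoy background
    layer_abundance: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class SimConfig:
    """Parameters for the annotation-table simulator."""

    seed: int = 0
    #: group -> (n_marine, n_nonmarine)
    group_sizes: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: (gene_id, group, environment-kind "marine"/"non-marine") -> presence prob
    gene_probs: dict[tuple[str, str, str], float] = field(default_factory=dict)
    copy_mean: float = 1.0
    background_rate: float = 0.0
    n_background_genes: int = 0
    namespace: str = "KEGG"
    mitag: MiTagConfig = field(default_factory=MiTagConfig)

    def validate(self) -> None:
        for key, p in self.gene_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability out of [0,1] for {key}: {p}")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate out of [0,1]")
        for layer, vec in self.mitag.layer_abundance.items():
            if any(v < 0 for v in vec.values()):
                raise ValueError(f"negative abundance in layer {layer}")
            if sum(vec.values()) > 1.0 + 1e-12:
                raise ValueError(f"layer {layer} abundances sum over 1")


def _meta_rows(
    group: str,
    n_marine: int,
    n_nonmarine: int,
    prefix: str,
    nonmarine_sources: Sequence[str] = ("ground water",),
) -> list[dict]:
    """QC-passing metadata rows; non-marine sources cycle deterministically."""
    rows = []
    for i in range(n_marine):
        rows.append(
            {
                "genome_id": f"{prefix}M{i + 1:02d}",
                "group": group,
                "environment": MARINE,
                "completeness": 95.0,
                "contamination": 1.0,
                "n_conserved": 40,
                "gc": 45.0,
                "size_bp": 3_000_000,
            }
        )
    for i in range(n_nonmarine):
        rows.append(
            {
                "genome_id": f"{prefix}N{i + 1:02d}",
                "group": group,
                "environment": nonmarine_sources[i % len(nonmarine_sources)],
                "completeness": 95.0,
                "contamination": 1.0,
                "n_conserved": 40,
                "gc": 45.0,
                "size_bp": 3_000_000,
            }
        )
    return rows


# Marine-enrichment fixture: group -> (n_marine, n_nonmarine,
# {gene -> (marine carriers, non-marine carriers)}). The counts are the
# smallest integers whose rounded percentages reproduce the published
# marine/non-marine presence figures (e.g. 7/9 -> 77.78%, 17/19 -> 89.47%).
_W1_LAYOUT: dict[str, tuple[int, int, dict[str, tuple[int, int]]]] = {
    "Bacteriovoracia": (
        9,
        19,
        {"K02168": (7, 4), "K04063": (7, 2), "K19271": (5, 1), "K03781": (5, 0)},
    ),
    "Bdello-group2": (
        19,
        18,
        {
            "K03442": (17, 2),
            "K08304": (11, 1),
            "K03571": (11, 3),
            "K02168": (11, 0),
            "K00147": (10, 2),
            "K07393": (10, 0),
            "K09001": (10, 2),
        },
    ),
    "Bdello-group1": (
        2,
        6,
        {
            "K08641": (2, 0),
            "K01273": (2, 0),
            "K05995": (2, 0),
            "K15773": (2, 0),
            "K03442": (2, 0),
            "K02168": (2, 0),
            "K06218": (2, 0),
            "K07339": (2, 1),
            "K18843": (2, 0),
            "K19092": (2, 0),
        },
    ),
    "Oligoflexia": (
        1,
        13,
        {
            "K01177": (1, 0),
            "K10111": (1, 0),
            "K10112": (1, 0),
            "K07272": (1, 0),
            "K05841": (1, 0),
            "K03313": (1, 0),
            "K19294": (1, 0),
            "K00499": (1, 0),
        },
    ),
}

# cheB fixture: group -> (n_genomes, n_with_cheB); 41/46 -> 89.13%.
_W3_LAYOUT = {
    "Oligoflexia": (14, 10),
    "Bacteriovoracia": (28, 28),
    "Bdello-group1": (7, 4),
    "Bdello-group2": (46, 41),
}

# Peptidase fixture: six MEROPS families carried by >=50% of genomes in all
# four groups, one family unique to each group, one pair-shared family, and
# one below-threshold family that must not enter the Venn partition.
_W4_SHARED = ("C26", "M16", "M23", "M48", "S01", "S08")
_W4_UNIQUE = {
    "Oligoflexia": "S33",
    "Bdello-group1": "A24",
    "Bdello-group2": "M14",
    "Bacteriovoracia": "C56",
}
_W4_PAIR = ("M01", ("Oligoflexia", "Bacteriovoracia"))
_W4_NOISE = "M99"


def _group_prefix(group: str) -> str:
    return {
        "Oligoflexia": "OF",
        "Bdello-group1": "B1",
        "Bdello-group2": "B2",
        "Bacteriovoracia": "BV",
    }[group]


def make_fixture(name: str) -> FixtureBundle:
    """Build one of the deterministic worked-example fixtures.

    ``W1_enrichment``: marine/non-marine carrier counts per group for the
    osmoprotectant / detox / cell-wall gene set. ``W2_sources``: group sizes
    with 23/53 and 22/47 marine genomes. ``W3_cheB``: cheB carrier counts per
    group. ``W4_peptidases``: MEROPS family layout with a six-family
    four-group core.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")

    meta_rows: list[dict] = []
    ann_rows: list[dict] = []

    if name == "W1_enrichment":
        for group in GROUPS:
            n_mar, n_non, genes = _W1_LAYOUT[group]
            prefix = _group_prefix(group)
            meta_rows.extend(_meta_rows(group, n_mar, n_non, prefix))
            for gene in sorted(genes):
                c_mar, c_non = genes[gene]
                for i in range(c_mar):
                    ann_rows.append(
                        {"genome_id": f"{prefix}M{i + 1:02d}", "namespace": "KEGG",
                         "gene_id": gene, "copies": 1}
                    )
                for i in range(c_non):
                    ann_rows.append(
                        {"genome_id": f"{prefix}N{i + 1:02d}", "namespace": "KEGG",
                         "gene_id": gene, "copies": 1}
                    )
        notes = ("Marine/non-marine carrier counts chosen so presence "
                 "percentages round to the published enrichment values "
                 "(e.g. 7/9=77.78%, 4/19=21.05%, 17/19=89.47%).")
    elif name == "W2_sources":
        meta_rows.extend(_meta_rows("Bacteriovoracia", 23, 30, "BV", NONMARINE_SOURCES))
        meta_rows.extend(_meta_rows("Bdello-group2", 22, 25, "B2", NONMARINE_SOURCES))
        # token annotation so the bundle is complete; not used by the tally
        ann_rows.append({"genome_id": "BVM01", "namespace": "KEGG",
                         "gene_id": "K00001", "copies": 1})
        notes = ("23/53 Bacteriovoracia and 22/47 Bdello-group2 genomes are "
                 "marine: 43.40% and 46.81% after rounding.")
    elif name == "W3_cheB":
        for group in GROUPS:
            n_total, n_with = _W3_LAYOUT[group]
            prefix = _group_prefix(group)
            meta_rows.extend(_meta_rows(group, 0, n_total, prefix))
            for i in range(n_with):
                ann_rows.append(
                    {"genome_id": f"{prefix}N{i + 1:02d}", "namespace": "KEGG",
                     "gene_id": "cheB", "copies": 1}
                )
        notes = ("cheB carriers per group: 10/14, 28/28, 4/7, 41/46; the "
                 "Bdello-group2 fraction rounds to 89.13%.")
    else:  # W4_peptidases
        n_per_group = 4
        for group in GROUPS:
            prefix = _group_prefix(group)
            meta_rows.extend(_meta_rows(group, 0, n_per_group, prefix))
            genomes = [f"{prefix}N{i + 1:02d}" for i in range(n_per_group)]
            families = list(_W4_SHARED) + [_W4_UNIQUE[group]]
            if group in _W4_PAIR[1]:
                families.append(_W4_PAIR[0])
            for fam in sorted(families):
                for g in genomes[:3]:  # 3/4 = 75% >= 50%
                    ann_rows.append(
                        {"genome_id": g, "namespace": "MEROPS",
                         "gene_id": fam, "copies": 1}
                    )
            if group in ("Oligoflexia", "Bdello-group2"):
                # below the 50% group-presence rule: must stay out of the Venn
                ann_rows.append(
                    {"genome_id": genomes[0], "namespace": "MEROPS",
                     "gene_id": _W4_NOISE, "copies": 1}
                )
        notes = ("Six MEROPS families carried by 75% of genomes in every "
                 "group form the four-group Venn core; each group adds one "
                 "unique family.")

    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    annotations = annotations.sort_values(
        ["genome_id", "namespace", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    return FixtureBundle(name=name, metadata=metadata, annotations=annotations,
                         notes=notes)


def simulate_annotations(cfg: SimConfig) -> tuple[FixtureBundle, pd.DataFrame]:
    """Draw an annotation table from per-(gene, group, environment) Bernoulli
    presence probabilities; returns the bundle plus the generating truth table.

    Present genes get copy number ``1 + Poisson(copy_mean - 1)``. Background
    genes use the reserved :data:`BACKGROUND_PREFIX` namespace ids.
    """
    cfg.validate()
    if not cfg.group_sizes:
        raise ValueError("group_sizes is empty")
    rng = np.random.default_rng(cfg.seed)

    meta_rows: list[dict] = []
    for group in sorted(cfg.group_sizes):
        n_mar, n_non = cfg.group_sizes[group]
        prefix = _group_prefix(group) if group in GROUPS else group[:4]
        meta_rows.extend(_meta_rows(group, n_mar, n_non, prefix))
    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)

    focal_genes = sorted({g for g, _, _ in cfg.gene_probs})
    bg_genes = [f"{BACKGROUND_PREFIX}{i:04d}" for i in range(cfg.n_background_genes)]
    extra = max(cfg.copy_mean - 1.0, 0.0)

    ann_rows: list[dict] = []
    truth_rows: list[dict] = []
    for row in meta_rows:
        env_kind = MARINE if row["environment"] == MARINE else "non-marine"
        for gene in focal_genes:
            p = cfg.gene_probs.get((gene, row["group"], env_kind), 0.0)
            if rng.random() < p:
                copies = 1 + (rng.poisson(extra) if extra > 0 else 0)
                ann_rows.append(
                    {"genome_id": row["genome_id"], "namespace": cfg.namespace,
                     "gene_id": gene, "copies": int(copies)}
                )
        for gene in bg_genes:
            if rng.random() < cfg.background_rate:
                ann_rows.append(
                    {"genome_id": row["genome_id"], "namespace": cfg.namespace,
                     "gene_id": gene, "copies": 1}
                )
    for group in sorted(cfg.group_sizes):
        for env_kind in (MARINE, "non-marine"):
            for gene in focal_genes:
                truth_rows.append(
                    {"gene_id": gene, "group": group, "environment": env_kind,
                     "p": cfg.gene_probs.get((gene, group, env_kind), 0.0)}
                )
    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "group", "environment", "p"])
    bundle = FixtureBundle(name=f"sim{cfg.seed}", metadata=metadata,
                           annotations=annotations,
                           notes="simulated from SimConfig")
    return bundle, truth


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases i.i.d. at ``rate``; substitutions always change the base."""
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        # shift by 1..3 within the 4-letter alphabet: never the original base
        out[hit] = (out[hit] + rng.integers(1, 4, hit.size)) % 4
    return out


def simulate_reference_db(
    cfg: MiTagConfig, seed: int
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Generate one 16S reference per group plus decoy references.

    Group references diverge from a common ancestor at ``ref_divergence``;
    decoys are regenerated until they sit at >=15% divergence from every
    group reference so background reads cannot pass a 97% identity filter.
    """
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, cfg.ref_length).astype(np.uint8)
    refs = []
    group_codes = []
    for i, group in enumerate(GROUPS):
        codes = _mutate(base, cfg.ref_divergence, rng)
        group_codes.append(codes)
        refs.append((f"ref_{_group_prefix(group)}", group, decode_dna(codes)))
    decoys = []
    while len(decoys) < cfg.n_decoys:
        codes = _mutate(base, cfg.decoy_divergence, rng)
        if all(np.mean(codes != gc) >= 0.15 for gc in group_codes):
            decoys.append(decode_dna(codes))
    return refs, decoys


def simulate_mitags(
    cfg: SimConfig,
    refs: list[tuple[str, str, str]],
    decoys: list[str],
) -> tuple[list[dict], pd.DataFrame]:
    """Simulate layered miTag samples with known per-group abundances.

    Each read is a substring of a reference of its truth group with i.i.d.
    substitutions at the error rate; the abundance mass not assigned to the
    four groups is filled with decoy-derived background reads. Returns
    samples (dicts with sample_id, depth_m, layer, reads) and a truth table
    (sample_id, read_id, source).
    """
    mt = cfg.mitag
    if not 0.0 <= mt.error_rate < 0.5:
        raise ValueError(f"error rate out of [0, 0.5): {mt.error_rate}")
    cfg.validate()
    lo, hi = mt.read_len
    ref_codes = {group: encode_dna(seq) for _, group, seq in refs}
    for _, group, seq in refs:
        if len(seq) < hi:
            raise ValueError(f"reference for {group} shorter than max read length")
    decoy_codes = [encode_dna(s) for s in decoys]
    layer_depths = {"epipelagic": (5.0, 150.0), "mesopelagic": (250.0, 900.0),
                    "deep": (1000.0, 6000.0)}

    rng = np.random.default_rng(cfg.seed)
    samples: list[dict] = []
    truth_rows: list[dict] = []
    for layer in sorted(mt.layer_abundance):
        abund = mt.layer_abundance[layer]
        groups = sorted(abund)
        probs = np.array([abund[g] for g in groups], dtype=float)
        p_bg = 1.0 - probs.sum()
        labels = groups + ["background"]
        p_all = np.append(probs, p_bg)
        dlo, dhi = layer_depths.get(layer, (0.0, 100.0))
        for s in range(mt.n_samples_per_layer):
            sample_id = f"{layer[:3]}_{s + 1:02d}"
            depth = float(np.round(rng.uniform(dlo, dhi), 1))
            choice = rng.choice(len(labels), size=mt.n_reads, p=p_all)
            lengths = rng.integers(lo, hi + 1, size=mt.n_reads)
            reads = []
            for i in range(mt.n_reads):
                label = labels[choice[i]]
                if label == "background":
                    src = decoy_codes[rng.integers(len(decoy_codes))]
                else:
                    src = ref_codes[label]
                L = int(lengths[i])
                start = int(rng.integers(0, len(src) - L + 1))
                codes = _mutate(src[start : start + L], mt.error_rate, rng)
                read_id = f"{sample_id}_r{i:05d}"
                reads.append((read_id, decode_dna(codes)))
                truth_rows.append(
                    {"sample_id": sample_id, "read_id": read_id, "source": label}
                )
            samples.append(
                {"sample_id": sample_id, "depth_m": depth, "layer": layer,
                 "reads": reads, "total_mitags": mt.n_reads}
            )
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "read_id", "source"])
    return samples, truth


def simulate_genome_pair(
    length: int, p: float, seed: int, k: int = 16
) -> tuple[str, str]:
    """A random genome and a copy mutated by i.i.d. substitutions at rate p."""
    if not 0.0 <= p < 0.3:
        raise ValueError(f"mutation rate out of [0, 0.3): {p}")
    if length < k:
        raise ValueError(f"length {length} shorter than k-mer size {k}")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, length).astype(np.uint8)
    b = _mutate(a, p, rng)
    return decode_dna(a), decode_dna(b)


def simulate_proteins(
    n: int,
    motif_rate: float,
    seed: int,
    length: int = 300,
    motif: str = "DXXDXDXE",
) -> tuple[list[tuple[str, str]], list[tuple[str, int]]]:
    """Random proteins with the motif planted at ``motif_rate`` per sequence.

    Background residues are uniform over the 20 standard amino acids, so
    spurious background matches are possible; the returned truth lists only
    planted (protein_id, 0-based start) positions.
    """
    if not 0.0 <= motif_rate <= 1.0:
        raise ValueError("motif_rate out of [0,1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    records: list[tuple[str, str]] = []
    truth: list[tuple[str, int]] = []
    for i in range(n):
        pid = f"prot{i:04d}"
        seq = list(aa[rng.integers(0, len(aa), length)])
        if rng.random() < motif_rate:
            start = int(rng.integers(0, length - len(motif) + 1))
            for j, ch in enumerate(motif):
                seq[start + j] = ch if ch != "X" else str(aa[rng.integers(len(aa))])
            truth.append((pid, start))
        records.append((pid, "".join(seq)))
    return records, truth
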