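"""Pipeline orchestration: QC -> dereplication -> compare -> profile -> scan.

A flat YAML config names the inputs, thresholds and enabled stages. Every
run writes its tables plus a MANIFEST.tsv (input checksums, thresholds,
package version) under one output directory; a rerun with identical config
and inputs is byte-identical. A failing stage leaves its partial outputs
behind alongside a FAILED marker file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .genome_qc import QcThresholds, dedup, pairwise_ani, qc_filter
from .io import (
    read_annotations,
    read_fasta,
    read_labeled_fasta,
    read_metadata,
    read_tsv,
    write_tsv,
)
from .mitag_profiler import (
    LAYERS,
    MatchConfig,
    MiTagSample,
    Reference16S,
    ReferenceDB,
    compare_layers,
    profile_sample_hits,
    profiles_frame,
    significance_label,
)
from .motif import DEFAULT_MOTIF, scan_motif
from .pangenome import (
    build_presence_matrix,
    cazy_class_counts,
    enrichment_table,
    group_presence,
    peptidase_venn,
    source_tally,
)
from .util import GROUPS

STAGES = ("qc", "compare", "profile", "scan")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    metadata: str | None = None
    annotations: str | None = None
    fasta_dir: str | None = None
    refdb: str | None = None
    samples: str | None = None
    proteins: str | None = None
    motif: str = DEFAULT_MOTIF
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    match_config: MatchConfig = field(default_factory=MatchConfig)
    ani_k: int = 16

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        qc = QcThresholds(**raw.pop("qc_thresholds", {}))
        match = MatchConfig(**raw.pop("match_config", {}))
        return cls(qc_thresholds=qc, match_config=match, **raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        needed: list[tuple[str, str | None]] = []
        if "qc" in self.stages:
            needed.append(("metadata", self.metadata))
        if "compare" in self.stages:
            needed.append(("metadata", self.metadata))
            needed.append(("annotations", self.annotations))
        if "profile" in self.stages:
            needed.append(("refdb", self.refdb))
            needed.append(("samples", self.samples))
        if "scan" in self.stages:
            needed.append(("proteins", self.proteins))
        for name, value in needed:
            if value is None:
                raise ValueError(f"config missing required path: {name}")
            if not Path(value).exists():
                raise ValueError(f"{name} path does not exist: {value}")
        if self.fasta_dir is not None and not Path(self.fasta_dir).is_dir():
            raise ValueError(f"fasta_dir is not a directory: {self.fasta_dir}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_qc(cfg: RunConfig, outdir: Path, report: dict) -> None:
    meta = read_metadata(cfg.metadata)
    passing = qc_filter(meta, cfg.qc_thresholds)
    verdicts = meta[["genome_id", "completeness", "contamination", "n_conserved"]].copy()
    verdicts["pass"] = verdicts["genome_id"].isin(passing)
    write_tsv(verdicts, outdir / "qc_verdicts.tsv")
    report["qc"] = {"n_genomes": int(len(meta)), "n_pass": len(passing)}

    if cfg.fasta_dir:
        sequences = {}
        for fa in sorted(Path(cfg.fasta_dir).glob("*.fa")) + sorted(
            Path(cfg.fasta_dir).glob("*.fasta")
        ):
            for name, seq in read_fasta(fa):
                sequences[name] = seq
        kept = meta[meta["genome_id"].isin(passing)]
        ani = pairwise_ani(
            {g: sequences[g] for g in kept["genome_id"] if g in sequences},
            k=cfg.ani_k,
        )
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "genome_a": r.genome_a,
                        "genome_b": r.genome_b,
                        "jaccard": r.jaccard,
                        "ani": "" if r.ani is None else r.ani,
                        "k": r.k,
                    }
                    for r in ani
                ],
                columns=["genome_a", "genome_b", "jaccard", "ani", "k"],
            ),
            outdir / "ani_pairs.tsv",
        )
        reps, cluster_map = dedup(kept, sequences, cfg.qc_thresholds, k=cfg.ani_k)
        write_tsv(
            pd.DataFrame(
                sorted(cluster_map.items()), columns=["genome_id", "representative"]
            ),
            outdir / "ani_clusters.tsv",
        )
        report["qc"]["n_representatives"] = len(reps)


def _stage_compare(cfg: RunConfig, outdir: Path, report: dict) -> None:
    meta = read_metadata(cfg.metadata)
    ann = read_annotations(cfg.annotations)
    pm = build_presence_matrix(ann, genomes=list(meta["genome_id"]))
    report["compare"] = {"n_genes": len(pm.genes), "n_genomes": len(pm.genomes)}
    presence_out = pm.presence.astype(int)
    presence_out.insert(0, "gene_id", presence_out.index)
    write_tsv(presence_out.reset_index(drop=True), outdir / "presence_matrix.tsv")
    if not pm.genes:
        return
    gp = group_presence(pm, meta)
    write_tsv(gp, outdir / "group_presence.tsv")
    enrichment_frames = []
    for group in GROUPS:
        sub = meta[meta["group"] == group]
        if sub.empty or (sub["environment"] == "marine").sum() == 0:
            continue
        frame = enrichment_table(pm, meta, group)
        if not frame.empty:
            enrichment_frames.append(frame)
    if enrichment_frames:
        write_tsv(
            pd.concat(enrichment_frames, ignore_index=True),
            outdir / "enrichment.tsv",
        )
    venn = peptidase_venn(pm, meta)
    write_tsv(venn.to_frame(), outdir / "peptidase_venn.tsv")
    write_tsv(cazy_class_counts(pm, meta), outdir / "cazy_classes.tsv")
    write_tsv(source_tally(meta), outdir / "source_tally.tsv")


def _stage_profile(cfg: RunConfig, outdir: Path, report: dict) -> None:
    refs = [
        Reference16S(rid, group, seq)
        for rid, group, seq in read_labeled_fasta(cfg.refdb)
    ]
    refdb = ReferenceDB(refs, k_seed=cfg.match_config.k_seed)
    samples_df = read_tsv(
        cfg.samples, required=["sample_id", "depth_m", "total_mitags", "fasta_path"]
    )
    base = Path(cfg.samples).parent
    profiles = []
    hit_rows = []
    for row in samples_df.itertuples(index=False):
        fasta = Path(row.fasta_path)
        if not fasta.is_absolute():
            fasta = base / fasta
        reads = list(read_fasta(fasta))
        sample = MiTagSample(
            row.sample_id, float(row.depth_m), reads, int(row.total_mitags)
        )
        profile, hits = profile_sample_hits(sample, refdb, cfg.match_config)
        profiles.append(profile)
        hit_rows.extend(
            {
                "sample_id": row.sample_id,
                "read_id": h.read_id,
                "ref_id": h.ref_id,
                "identity": round(h.identity, 6),
                "aln_len": h.aln_len,
                "score": h.score,
                "group": h.group,
            }
            for h in hits
        )
    write_tsv(
        pd.DataFrame(
            hit_rows,
            columns=["sample_id", "read_id", "ref_id", "identity",
                     "aln_len", "score", "group"],
        ),
        outdir / "hits.tsv",
    )
    write_tsv(profiles_frame(profiles), outdir / "abundance.tsv")

    test_rows = []
    for group in GROUPS:
        for la, lb in (("epipelagic", "mesopelagic"), ("epipelagic", "deep"),
                       ("mesopelagic", "deep")):
            n_a = sum(p.layer == la for p in profiles)
            n_b = sum(p.layer == lb for p in profiles)
            if n_a < 2 or n_b < 2:
                continue
            t, p = compare_layers(profiles, group, la, lb)
            test_rows.append(
                {
                    "group": group, "layer_a": la, "layer_b": lb,
                    "t": round(t, 6), "p": p,
                    "significance": significance_label(p),
                }
            )
    write_tsv(
        pd.DataFrame(
            test_rows,
            columns=["group", "layer_a", "layer_b", "t", "p", "significance"],
        ),
        outdir / "layer_tests.tsv",
    )
    report["profile"] = {"n_samples": int(len(samples_df)),
                         "n_hits": len(hit_rows)}


def _stage_scan(cfg: RunConfig, outdir: Path, report: dict) -> None:
    proteins = list(read_fasta(cfg.proteins))
    matches = scan_motif(proteins, cfg.motif)
    write_tsv(
        pd.DataFrame(
            [
                {"protein_id": m.protein_id, "start": m.start,
                 "end": m.end, "matched": m.matched}
                for m in matches
            ],
            columns=["protein_id", "start", "end", "matched"],
        ),
        outdir / "motif_matches.tsv",
    )
    report["scan"] = {
        "n_proteins": len(proteins),
        "n_matches": len(matches),
        "n_proteins_with_match": len({m.protein_id for m in matches}),
    }


_STAGE_FUNCS = {
    "qc": _stage_qc,
    "compare": _stage_compare,
    "profile": _stage_profile,
    "scan": _stage_scan,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [s for s in STAGES if s in cfg.stages],
    }
    manifest_rows: list[dict] = [
        {"kind": "version", "name": "bdellocomp", "value": __version__},
        {"kind": "param", "name": "seed", "value": cfg.seed},
        {"kind": "param", "name": "motif", "value": cfg.motif},
    ]
    for name, value in asdict(cfg.qc_thresholds).items():
        manifest_rows.append({"kind": "threshold", "name": f"qc.{name}", "value": value})
    for name, value in asdict(cfg.match_config).items():
        manifest_rows.append(
            {"kind": "threshold", "name": f"match.{name}", "value": value}
        )
    for name in ("metadata", "annotations", "refdb", "samples", "proteins"):
        path = getattr(cfg, name)
        if path is not None and Path(path).is_file():
            manifest_rows.append(
                {"kind": "input", "name": name, "value": _sha256(path)}
            )

    for stage in report["stages"]:
        try:
            _STAGE_FUNCS[stage](cfg, outdir, report)
        except Exception as exc:
            failed_marker.write_text(f"stage {stage} failed: {exc}\n", encoding="utf-8")
            raise

    write_tsv(pd.DataFrame(manifest_rows, columns=["kind", "name", "value"]),
              outdir / "MANIFEST.tsv")
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def render_tables(outdir: str | Path) -> str:
    """Human-readable summary of a run's enrichment tables.

    Each group gets a block shaped like the published marine-enrichment
    table (KEGG id, non-marine %, marine %), showing the whole-percent
    display value next to the exact two-decimal one.
    """
    outdir = Path(outdir)
    path = outdir / "enrichment.tsv"
    lines: list[str] = []
    if not path.exists():
        return "no enrichment rows\n"
    enr = pd.read_csv(path, sep="\t")
    if enr.empty:
        return "no enrichment rows\n"
    for group, sub in enr.groupby("group", sort=True):
        lines.append(f"== Genes enriched in marine genomes: {group} ==")
        lines.append(f"{'KEGG':<10}{'Non-Marine':>16}{'Marine':>16}")
        for row in sub.itertuples(index=False):
            non = (
                "undef"
                if pd.isna(row.nonmarine_pct)
                else f"{int(row.nonmarine_pct_display)}% ({row.nonmarine_pct:.2f})"
            )
            mar = (
                "undef"
                if pd.isna(row.marine_pct)
                else f"{int(row.marine_pct_display)}% ({row.marine_pct:.2f})"
            )
            lines.append(f"{row.gene_id:<10}{non:>16}{mar:>16}")
        lines.append("")
    return "\n".join(lines) + "\n"
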