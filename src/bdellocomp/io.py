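"""Reading and writing the pipeline's file formats.

Everything on disk is plain text: TSV with a header line (UTF-8) and FASTA
wrapped at 80 columns. 16S reference FASTA headers carry the group label as
``>ref_id group=<label>``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

METADATA_COLUMNS = [
    "genome_id",
    "group",
    "environment",
    "completeness",
    "contamination",
    "n_conserved",
    "gc",
    "size_bp",
]
ANNOTATION_COLUMNS = ["genome_id", "namespace", "gene_id", "copies"]


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs; sequences uppercased."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def read_labeled_fasta(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (ref_id, group, sequence) from ``>id group=<label>`` headers."""
    for rec in SeqIO.parse(str(path), "fasta"):
        group = None
        for token in rec.description.split()[1:]:
            if token.startswith("group="):
                group = token[len("group="):]
        if group is None:
            raise ValueError(f"reference {rec.id} lacks a group=<label> tag")
        yield rec.id, group, str(rec.seq).upper()


def write_fasta(
    records: Iterable[tuple[str, str]] | Iterable[tuple[str, str, str]],
    path: str | Path,
    wrap: int = 80,
) -> None:
    """Write (id, seq) or (id, description, seq) records, wrapped at 80."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if len(rec) == 2:
                name, seq = rec
                fh.write(f">{name}\n")
            else:
                name, desc, seq = rec
                fh.write(f">{name} {desc}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_tsv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "gene_id": str})
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, required=["genome_id", "group", "environment"])


def read_annotations(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, required=ANNOTATION_COLUMNS)
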