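"""FASTA/FASTQ/TSV input and output for library, reads and tables."""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq_seqs",
    "write_feature_table",
    "read_feature_table",
]


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write ``(identifier, sequence)`` pairs as FASTA."""
    seqs = (SeqRecord(Seq(s), id=str(i), description="") for i, s in records)
    SeqIO.write(seqs, os.fspath(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping (order preserved)."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(os.fspath(path), "fasta")}


def write_fastq(
    reads: Sequence[str],
    path: str | os.PathLike,
    quality: int = 30,
    name_prefix: str = "read",
) -> None:
    """Write reads as Sanger Phred+33 FASTQ with a constant quality score."""
    if not 0 <= quality <= 41:
        raise ValueError("quality must be a Phred score in [0, 41]")
    q = chr(quality + 33)
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{name_prefix}{i}\n{seq}\n+\n{q * len(seq)}\n")


def read_fastq_seqs(path: str | os.PathLike) -> list[str]:
    """Read only the sequences from a FASTQ file."""
    out: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                out.append(line.strip().upper())
    return out


FEATURE_COLUMNS = ["clone_id", "length_aa", "gc_insert", "gc_orf", "peu", "ids"]


def write_feature_table(features: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the per-clone feature table as TSV; missing values are empty."""
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    extra = [c for c in features.columns if c not in cols]
    features[cols + extra].to_csv(path, sep="\t", index=False, na_rep="")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-clone feature TSV; empty fields become NaN."""
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    return df
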