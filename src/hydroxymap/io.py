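"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: FASTA (genomes incl. spike-in contigs), refFlat gene models,
BED3/BED6 interval tracks, Bismark-style CX cytosine reports (7 columns,
1-based positions, one row per strand-cytosine), FASTQ junction reads and
simple TSV tables.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CX_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_unconverted",
    "count_converted",
    "context",
    "trinucleotide",
]

REFFLAT_COLUMNS = [
    "gene",
    "transcript",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "cds_start",
    "cds_end",
    "exon_count",
    "exon_starts",
    "exon_ends",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into a plain ``{name: sequence}`` dict.

    Uses pyfaidx when an index is useful; for the toy genomes handled here a
    single pass is simpler and avoids stale ``.fai`` files.
    """
    genome: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line.upper())
    if name is not None:
        genome[name] = "".join(parts)
    return genome


# ---------------------------------------------------------------------------
# Gene models (refFlat)


def write_refflat(genes: pd.DataFrame, path: str) -> None:
    df = genes.copy()
    df["exon_starts"] = df["exon_starts"].apply(
        lambda xs: ",".join(str(int(x)) for x in xs) + ","
    )
    df["exon_ends"] = df["exon_ends"].apply(
        lambda xs: ",".join(str(int(x)) for x in xs) + ","
    )
    df[REFFLAT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_refflat(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=REFFLAT_COLUMNS)
    for col in ("exon_starts", "exon_ends"):
        df[col] = df[col].apply(
            lambda s: [int(x) for x in str(s).rstrip(",").split(",")]
        )
    return df


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    cols = ["chrom", "start", "end"]
    extra = [c for c in ("name", "score", "strand") if c in intervals.columns]
    intervals[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


# ---------------------------------------------------------------------------
# CX cytosine reports


def write_cx_report(calls: pd.DataFrame, path: str) -> None:
    """Write a 7-column Bismark-dialect CX report (1-based positions)."""
    calls[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str, columns: list[str] | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0 if columns is None else None,
                       names=columns)


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq(reads: Iterable[str], path: str, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str) -> list[str]:
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                reads.append(line.strip().upper())
    return reads


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
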