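"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ go through Bio.SeqIO, Newick through scikit-bio's TreeNode,
tables through pandas. BED6 is the ground-truth interval dialect
(0-based half-open, name = variant label, score = 0, strand = '+').
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from skbio import TreeNode

VALID_ALPHABET = set("ACGTN")


@dataclass
class SeqRecord:
    """A named nucleotide sequence (uppercase, alphabet ACGTN)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        extra = set(self.sequence) - VALID_ALPHABET
        if extra:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(extra)}")


@dataclass
class IntervalRecord:
    """A BED6 interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[SeqRecord]:
    records = [
        SeqRecord(id=r.id, sequence=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path, width: int = 80) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class FastqRead:
    id: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.quality:
            self.quality = "I" * len(self.sequence)
        if len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    for r in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in r.letter_annotations["phred_quality"]
        )
        reads.append(FastqRead(id=r.id, sequence=str(r.seq).upper(), quality=qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_bed(path: str | Path) -> list[IntervalRecord]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = int(fields[4]) if len(fields) > 4 else 0
            strand = fields[5] if len(fields) > 5 else "+"
            intervals.append(
                IntervalRecord(chrom, start, end, name=name, score=score, strand=strand)
            )
    return intervals


def write_bed(intervals: Iterable[IntervalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n"
            )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV count table (header row; all non-key columns must be
    non-negative numbers)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty counts table {path}")
    numeric = df.select_dtypes("number")
    if (numeric.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick_file(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick_file(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_config(path: str | Path) -> dict:
    """Read a TOML configuration file into a plain dict."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def setup_run_logging(outdir: str | Path, level: str = "INFO") -> logging.Logger:
    """Log to stderr and to <outdir>/run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("cenbarcode")
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    return logger
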