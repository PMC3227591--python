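"""Thin format helpers: FASTA/FASTQ reading and writing.

Genome FASTA access goes through pyfaidx for indexed retrieval; FASTQ records
go through Biopython's SeqIO.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pyfaidx
from Bio import SeqIO

from .align import ReadRecord
from .errors import InputError


def open_genome(path: str | Path) -> pyfaidx.Fasta:
    try:
        return pyfaidx.Fasta(str(path), sequence_always_upper=True)
    except (OSError, pyfaidx.FastaIndexingError) as exc:
        raise InputError(f"cannot open genome FASTA {path}: {exc}") from exc


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path, mate: int | None = None) -> list[ReadRecord]:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(ReadRecord(rec.id, str(rec.seq).upper(), mate, qual))
    except ValueError as exc:
        raise InputError(f"cannot parse FASTQ {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
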