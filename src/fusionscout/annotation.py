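"""Gene models, annotation loading and junction sequence libraries.

A :class:`GeneModel` stores one transcript's exon structure in *transcript
order* (5'->3'), with genomic coordinates kept 0-based half-open internally.
Splice-junction and fusion-junction libraries are built by joining ``x-5``
bases (or the full exon, if shorter) from each flanking exon, so that any
read of length ``x`` fully contained in a junction sequence overlaps each
exon side by at least 5 bases.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

from .errors import ConfigError, InputError

log = logging.getLogger(__name__)

GenomeLike = Mapping[str, object]  # dict of str or pyfaidx.Fasta


def fetch_sequence(genome: GenomeLike, chromosome: str, start: int, end: int) -> str:
    """Return the forward-strand genomic sequence [start, end), uppercased.

    Works with a plain ``dict`` of strings and with ``pyfaidx.Fasta``.
    """
    if chromosome not in genome:
        raise InputError(f"chromosome {chromosome!r} not present in genome")
    return str(genome[chromosome][start:end]).upper()


def genome_contig_names(genome: GenomeLike) -> list[str]:
    return list(genome.keys())


@dataclass
class GeneModel:
    """One transcript: exons (and optionally a CDS span) on a strand.

    ``exons`` are (start, end) genomic intervals, 0-based half-open, stored
    in transcript order: ascending genomic start on '+', descending on '-'.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise InputError(f"{self.gene_id}: gene model with zero exons")
        for s, e in self.exons:
            if e - s < 1:
                raise InputError(f"{self.gene_id}: exon ({s},{e}) has length < 1")
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 < e1:
                raise InputError(f"{self.gene_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})")
        expected = by_start if self.strand == "+" else by_start[::-1]
        if self.exons != expected:
            raise InputError(f"{self.gene_id}: exons not in transcript order for strand {self.strand}")
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (self._covered(cs) and self._covered(ce - 1)):
                raise InputError(f"{self.gene_id}: cds_span {self.cds_span} not within exon union")

    def _covered(self, gpos: int) -> bool:
        return any(s <= gpos < e for s, e in self.exons)

    # --- geometry -----------------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths())

    def exon_boundaries(self) -> list[int]:
        """Transcript coordinates of exon starts/ends: [0, l1, l1+l2, ...]."""
        bounds = [0]
        for length in self.exon_lengths():
            bounds.append(bounds[-1] + length)
        return bounds

    def exon_index_at(self, tpos: int) -> int:
        """1-based exon ordinal containing transcript position ``tpos``."""
        if not (0 <= tpos < self.transcript_length):
            raise InputError(f"{self.gene_id}: transcript position {tpos} out of range")
        bounds = self.exon_boundaries()
        for i in range(self.n_exons):
            if bounds[i] <= tpos < bounds[i + 1]:
                return i + 1
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic position (0-based) inside an exon to a transcript position."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return offset + (gpos - s if self.strand == "+" else e - gpos - 1)
            offset += e - s
        raise InputError(f"{self.gene_id}: genomic position {gpos} not exonic")

    def cds_transcript_span(self) -> tuple[int, int] | None:
        """CDS as a half-open interval in transcript coordinates, or None."""
        if self.cds_span is None:
            return None
        cs, ce = self.cds_span
        if self.strand == "+":
            return self.genomic_to_transcript(cs), self.genomic_to_transcript(ce - 1) + 1
        return self.genomic_to_transcript(ce - 1), self.genomic_to_transcript(cs) + 1

    # --- sequences ----------------------------------------------------------

    def exon_sequence(self, genome: GenomeLike, index: int) -> str:
        """Transcript-orientation sequence of the 1-based ``index``-th exon."""
        if not (1 <= index <= self.n_exons):
            raise InputError(f"{self.gene_id}: exon index {index} out of range 1..{self.n_exons}")
        s, e = self.exons[index - 1]
        seq = fetch_sequence(genome, self.chromosome, s, e)
        return seq if self.strand == "+" else reverse_complement(seq)

    def transcript_sequence(self, genome: GenomeLike) -> str:
        return "".join(self.exon_sequence(genome, i) for i in range(1, self.n_exons + 1))


def distance_to_exon_boundary(position: int, gene: GeneModel) -> int:
    """Distance (bp) from a transcript-relative position to the nearest exon boundary.

    Boundaries include transcript start/end and every internal splice point.
    """
    if not (0 <= position <= gene.transcript_length):
        raise InputError(
            f"{gene.gene_id}: position {position} outside transcript of length "
            f"{gene.transcript_length}"
        )
    return min(abs(position - b) for b in gene.exon_boundaries())


# --- junction libraries ------------------------------------------------------


@dataclass
class JunctionRecord:
    """A synthesized exon-exon junction sequence with provenance.

    The left arm is the 3' end of the upstream exon, the right arm the 5'
    start of the downstream exon, each ``min(x-5, exon length)`` bases long.
    """

    left_gene_id: str
    right_gene_id: str
    left_exon_index: int  # 1-based
    right_exon_index: int  # 1-based
    junction_seq: str
    left_arm_len: int
    right_arm_len: int
    read_length_x: int

    @property
    def name(self) -> str:
        return (f"{self.left_gene_id}|{self.left_exon_index}|"
                f"{self.right_gene_id}|{self.right_exon_index}|{self.read_length_x}")


def _make_junction(left_gene: GeneModel, left_idx: int, right_gene: GeneModel,
                   right_idx: int, x: int, genome: GenomeLike) -> JunctionRecord:
    arm = x - 5
    left_seq = left_gene.exon_sequence(genome, left_idx)
    right_seq = right_gene.exon_sequence(genome, right_idx)
    left_arm = min(arm, len(left_seq))
    right_arm = min(arm, len(right_seq))
    return JunctionRecord(
        left_gene_id=left_gene.gene_id,
        right_gene_id=right_gene.gene_id,
        left_exon_index=left_idx,
        right_exon_index=right_idx,
        junction_seq=left_seq[len(left_seq) - left_arm:] + right_seq[:right_arm],
        left_arm_len=left_arm,
        right_arm_len=right_arm,
        read_length_x=x,
    )


def build_splice_junction_library(genes: Iterable[GeneModel], x: int,
                                  genome: GenomeLike) -> list[JunctionRecord]:
    """Within-gene splice junction library: one record per adjacent exon pair.

    Single-exon genes contribute no records.
    """
    if x < 10:
        raise ConfigError(f"read length x must be >= 10 (so x-5 >= 5), got {x}")
    records = []
    for gene in genes:
        for i in range(1, gene.n_exons):
            records.append(_make_junction(gene, i, gene, i + 1, x, genome))
    return records


def build_fusion_junction_library(gene5: GeneModel, gene3: GeneModel, x: int,
                                  genome: GenomeLike) -> list[JunctionRecord]:
    """All exon(i of gene5) x exon(j of gene3) junctions, gene5 upstream."""
    if x < 10:
        raise ConfigError(f"read length x must be >= 10 (so x-5 >= 5), got {x}")
    if gene5.gene_id == gene3.gene_id and gene5.transcript_id == gene3.transcript_id:
        raise InputError("fusion junction library requires two distinct genes")
    return [
        _make_junction(gene5, i, gene3, j, x, genome)
        for i in range(1, gene5.n_exons + 1)
        for j in range(1, gene3.n_exons + 1)
    ]


def junction_library_to_fasta(records: Sequence[JunctionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.junction_seq}\n")


# --- annotation loading ------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: Path) -> dict[str, dict]:
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GTF columns, got {len(parts)}")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature not in ("exon", "CDS"):
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                raise InputError(f"{path}:{lineno}: missing transcript_id attribute")
            gid = attr.get("gene_id", tid)
            rec = transcripts.setdefault(
                tid, {"gene_id": gid, "chromosome": chrom, "strand": strand,
                      "exons": [], "cds": []})
            interval = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            if rec["chromosome"] != chrom:
                raise InputError(f"{path}:{lineno}: transcript {tid} spans two chromosomes")
            (rec["exons"] if feature == "exon" else rec["cds"]).append(interval)
    return transcripts


def _parse_bed12(path: Path) -> dict[str, dict]:
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise InputError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(parts)}")
            chrom, start, _end, name, _, strand = parts[:6]
            thick_start, thick_end = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(v) for v in parts[10].rstrip(",").split(",") if v]
            starts = [int(v) for v in parts[11].rstrip(",").split(",") if v]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise InputError(f"{path}:{lineno}: block counts disagree with blockCount")
            chrom_start = int(start)
            exons = [(chrom_start + off, chrom_start + off + size)
                     for off, size in zip(starts, sizes)]
            cds = [] if thick_start >= thick_end else [(thick_start, thick_end)]
            # name is "gene_id|transcript_id" or a bare id used for both
            gid, _, tid = name.partition("|")
            transcripts[tid or gid] = {
                "gene_id": gid, "chromosome": chrom, "strand": strand,
                "exons": exons, "cds": cds}
    return transcripts


def load_annotation(path: str | Path, genome: GenomeLike,
                    dialect: str | None = None) -> list[GeneModel]:
    """Load gene models from GTF or BED12 (one :class:`GeneModel` per transcript).

    Minus-strand exon lists are reversed into transcript order; exon/CDS
    sequences are reverse-complemented on access. A record on a chromosome
    absent from the genome is fatal; a zero-exon record is skipped with a
    warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "bed12" if path.suffix.lower() in (".bed", ".bed12") else "gtf"
    if dialect == "gtf":
        transcripts = _parse_gtf(path)
    elif dialect == "bed12":
        transcripts = _parse_bed12(path)
    else:
        raise ConfigError(f"unknown annotation dialect {dialect!r}")

    contigs = set(genome_contig_names(genome))
    models: list[GeneModel] = []
    for tid, rec in transcripts.items():
        if rec["chromosome"] not in contigs:
            raise InputError(
                f"transcript {tid}: chromosome {rec['chromosome']!r} absent from genome FASTA")
        if not rec["exons"]:
            log.warning("transcript %s has zero exons; record rejected", tid)
            continue
        exons = sorted(rec["exons"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        cds_span = None
        if rec["cds"]:
            cds_span = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        models.append(GeneModel(
            gene_id=rec["gene_id"], transcript_id=tid,
            chromosome=rec["chromosome"], strand=rec["strand"],
            exons=exons, cds_span=cds_span))
    return models
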