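"""Desk-scale alignment: trimming, an end-to-end k-mer aligner, a local
aligner (Blat surrogate) and an exact short-fragment matcher (Vmatch
surrogate), plus SAM import for pre-computed alignments.

The end-to-end aligner uses pigeonhole k-mer seeding with Hamming-distance
verification: a read with at most ``max_mismatches`` substitutions has at
least one error-free seed among ``max_mismatches + 1`` disjoint seeds, so all
placements within the budget are found whenever the read is long enough to
host the disjoint seeds. Read coordinates in every record refer to the
original read orientation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .config import PipelineConfig
from .errors import InputError

log = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    mate: int | None = None  # 1, 2 or None for single-end
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise InputError(f"read {self.read_id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise InputError(f"read {self.read_id}: quality/sequence length mismatch")


@dataclass
class AlignmentRecord:
    read_id: str
    target_kind: str  # genome | splice_junction | transcript | fusion_junction | exon
    target_id: str
    target_start: int
    read_start: int  # original read orientation, 0-based half-open
    read_end: int
    strand: str
    mismatches: int
    unique: bool
    mapped_fully: bool
    mate: int | None = None
    score: float | None = None
    read_length: int | None = None


def trim_reads(reads: Iterable[ReadRecord], n: int) -> list[ReadRecord]:
    """Trim ``n`` bases from the 3' end of every read (qualities in step)."""
    out = []
    for read in reads:
        if n >= len(read.sequence):
            raise InputError(
                f"cannot trim {n} bp from read {read.read_id} of length {len(read.sequence)}")
        if n == 0:
            out.append(ReadRecord(read.read_id, read.sequence, read.mate, read.quality))
            continue
        out.append(ReadRecord(
            read.read_id, read.sequence[:-n], read.mate,
            read.quality[:-n] if read.quality is not None else None))
    return out


def _hamming(a: str, b: str, cap: int) -> int:
    """Mismatch count, with early exit once the cap is exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


class EndToEndAligner:
    """Full-length read placement against an indexed target set."""

    def __init__(self, targets: Mapping[str, str], config: PipelineConfig | None = None,
                 target_kind: str = "genome"):
        if not targets:
            raise InputError("end-to-end alignment requires a non-empty target set")
        self.config = config or PipelineConfig()
        self.target_kind = target_kind
        self.targets = {tid: str(seq).upper() for tid, seq in targets.items()}
        self.k = self.config.seed_len
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid, seq in self.targets.items():
            for i in range(len(seq) - self.k + 1):
                self._index[seq[i:i + self.k]].append((tid, i))

    def _seed_offsets(self, length: int) -> list[int]:
        n_seeds = self.config.max_mismatches + 1
        if length >= n_seeds * self.k:
            return [i * self.k for i in range(n_seeds)]
        # read too short for disjoint pigeonhole seeds: spread what fits
        offsets = sorted({min(i * self.k, length - self.k) for i in range(n_seeds)})
        return [o for o in offsets if o >= 0]

    def _placements(self, seq: str) -> dict[tuple[str, int, str], int]:
        budget = self.config.max_mismatches
        length = len(seq)
        found: dict[tuple[str, int, str], int] = {}
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            if length < self.k:
                # brute-force scan for very short reads
                for tid, tseq in self.targets.items():
                    for start in range(len(tseq) - length + 1):
                        mm = _hamming(s, tseq[start:start + length], budget)
                        if mm <= budget:
                            found.setdefault((tid, start, strand), mm)
                continue
            for offset in self._seed_offsets(length):
                for tid, pos in self._index.get(s[offset:offset + self.k], ()):
                    start = pos - offset
                    tseq = self.targets[tid]
                    if start < 0 or start + length > len(tseq):
                        continue
                    key = (tid, start, strand)
                    if key in found:
                        continue
                    mm = _hamming(s, tseq[start:start + length], budget)
                    if mm <= budget:
                        found[key] = mm
        return found

    def align_read(self, read: ReadRecord) -> list[AlignmentRecord]:
        found = self._placements(read.sequence.upper())
        if not found:
            return []
        best = min(found.values())
        placements = [(key, mm) for key, mm in found.items() if mm == best]
        unique = len(placements) == 1
        length = len(read.sequence)
        return [
            AlignmentRecord(
                read_id=read.read_id, target_kind=self.target_kind, target_id=tid,
                target_start=start, read_start=0, read_end=length, strand=strand,
                mismatches=mm, unique=unique, mapped_fully=True, mate=read.mate,
                read_length=length)
            for (tid, start, strand), mm in placements
        ]

    def align(self, reads: Iterable[ReadRecord]) -> tuple[list[AlignmentRecord], list[ReadRecord]]:
        """Align all reads; return (alignment records, unmapped reads)."""
        records: list[AlignmentRecord] = []
        unmapped: list[ReadRecord] = []
        for read in reads:
            recs = self.align_read(read)
            if recs:
                records.extend(recs)
            else:
                unmapped.append(read)
        return records, unmapped


def align_end_to_end(reads: Iterable[ReadRecord], targets: Mapping[str, str],
                     config: PipelineConfig | None = None,
                     target_kind: str = "genome") -> tuple[list[AlignmentRecord], list[ReadRecord]]:
    return EndToEndAligner(targets, config, target_kind).align(reads)


# --- local alignment (Blat surrogate) ----------------------------------------


def _make_local_aligner(config: PipelineConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.local_match
    aligner.mismatch_score = config.local_mismatch
    aligner.open_gap_score = config.local_gap
    aligner.extend_gap_score = config.local_gap
    return aligner


def local_align(read: ReadRecord, targets: Mapping[str, str],
                config: PipelineConfig | None = None,
                target_kind: str = "transcript") -> list[AlignmentRecord]:
    """Best local alignment of the read against each target, both strands.

    Scoring is +1 match, -1 mismatch, -2 per gap position; placements scoring
    below ``local_min_score`` are dropped. Per target, only the higher-scoring
    strand's best alignment is reported. Records are sorted by score
    descending. ``read_start``/``read_end`` are in original read coordinates.
    """
    config = config or PipelineConfig()
    aligner = _make_local_aligner(config)
    seq = read.sequence.upper()
    length = len(seq)
    records: list[AlignmentRecord] = []
    for tid, tseq in targets.items():
        tseq = str(tseq).upper()
        best: tuple[float, str, object] | None = None
        for strand, q in (("+", seq), ("-", reverse_complement(seq))):
            score = aligner.score(tseq, q)
            if score < config.local_min_score:
                continue
            if best is None or score > best[0]:
                best = (score, strand, q)
        if best is None:
            continue
        score, strand, q = best
        aln = next(iter(aligner.align(tseq, q)))
        tblocks, qblocks = aln.aligned
        q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
        t0 = int(tblocks[0][0])
        mismatches = 0
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            mismatches += sum(a != b for a, b in zip(tseq[ts:te], q[qs:qe]))
        if strand == "+":
            r0, r1 = q0, q1
        else:
            r0, r1 = length - q1, length - q0
        records.append(AlignmentRecord(
            read_id=read.read_id, target_kind=target_kind, target_id=tid,
            target_start=t0, read_start=r0, read_end=r1, strand=strand,
            mismatches=mismatches, unique=False, mapped_fully=(q1 - q0 == length),
            mate=read.mate, score=score, read_length=length))
    records.sort(key=lambda r: (-(r.score or 0), r.target_id))
    if records:
        top = [r for r in records if r.score == records[0].score]
        if len(top) == 1:
            top[0].unique = True
    return records


# --- exact short-fragment matching (Vmatch surrogate) -------------------------


def exact_short_align(fragment: str, exon_set: Mapping[str, str],
                      config: PipelineConfig | None = None,
                      forward_only: bool = False) -> list[AlignmentRecord]:
    """All exact full-length placements of a short fragment in the exon set.

    Fragments below ``exact_min_len`` are rejected with a warning (empty
    result); every placement is reported, including repetitive ones.
    """
    config = config or PipelineConfig()
    fragment = fragment.upper()
    if len(fragment) < config.exact_min_len:
        log.warning("fragment of length %d below exact-match floor %d; rejected",
                    len(fragment), config.exact_min_len)
        return []
    hits: list[AlignmentRecord] = []
    strands = ("+",) if forward_only else ("+", "-")
    for tid, tseq in exon_set.items():
        tseq = str(tseq).upper()
        for strand in strands:
            q = fragment if strand == "+" else reverse_complement(fragment)
            start = tseq.find(q)
            while start != -1:
                hits.append(AlignmentRecord(
                    read_id="", target_kind="exon", target_id=tid,
                    target_start=start, read_start=0, read_end=len(fragment),
                    strand=strand, mismatches=0, unique=False, mapped_fully=True,
                    read_length=len(fragment)))
                start = tseq.find(q, start + 1)
    if len(hits) == 1:
        hits[0].unique = True
    return hits


# --- SAM import ---------------------------------------------------------------


@dataclass
class SamImport:
    alignments: list[AlignmentRecord]
    unmapped_reads: list[ReadRecord]
    reads_by_id: dict[tuple[str, int | None], ReadRecord] = field(default_factory=dict)


def import_sam(path: str | Path, config: PipelineConfig | None = None) -> SamImport:
    """Import pre-computed genomic alignments from SAM/BAM.

    A record is 'unique' when its MAPQ is at or above ``mapq_floor`` and it is
    not flagged secondary/supplementary; 'mapped_fully' requires an ungapped,
    unclipped CIGAR. Mismatches come from the NM tag (0 when absent).
    """
    config = config or PipelineConfig()
    alignments: list[AlignmentRecord] = []
    unmapped: list[ReadRecord] = []
    reads: dict[tuple[str, int | None], ReadRecord] = {}
    try:
        sam = pysam.AlignmentFile(str(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise InputError(f"cannot parse SAM/BAM {path}: {exc}") from exc
    with sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = 1 if rec.is_read1 else 2 if rec.is_read2 else None
            seq = rec.query_sequence or ""
            if seq:
                # stored in original read orientation
                stored = reverse_complement(seq) if rec.is_reverse else seq
                reads[(rec.query_name, mate)] = ReadRecord(rec.query_name, stored, mate)
            if rec.is_unmapped:
                if seq:
                    unmapped.append(reads[(rec.query_name, mate)])
                continue
            cigar = rec.cigartuples or []
            fully = bool(cigar) and all(op == 0 for op, _ in cigar)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alignments.append(AlignmentRecord(
                read_id=rec.query_name, target_kind="genome",
                target_id=rec.reference_name, target_start=rec.reference_start,
                read_start=0, read_end=rec.query_length, strand="-" if rec.is_reverse else "+",
                mismatches=int(nm), unique=rec.mapping_quality >= config.mapq_floor,
                mapped_fully=fully, mate=mate, read_length=rec.query_length))
    return SamImport(alignments=alignments, unmapped_reads=unmapped, reads_by_id=reads)
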