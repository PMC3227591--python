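"""Single-end fusion discovery via gene fusion candidate reads (GFCRs).

A read that failed full-length genomic and splice-junction alignment may span
a fusion junction. Its longer part is recovered as a partial local alignment
to a transcript at an exon boundary (Group A); the unaligned remainder is
exact-matched against exon sequences near exon ends (Group B). When the two
parts land in two different genes and jointly cover the read, the read is a
GFCR; gene pairs with at least ``min_unique_gfcr`` unique GFCRs are called
candidates.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

from .align import (AlignmentRecord, EndToEndAligner, ReadRecord,
                    exact_short_align, local_align)
from .annotation import (GeneModel, GenomeLike, build_splice_junction_library,
                         distance_to_exon_boundary)
from .config import PipelineConfig
from .errors import InputError

log = logging.getLogger(__name__)


@dataclass
class PartialHit:
    """Group A: a partial transcript alignment near an exon boundary."""

    read_id: str
    gene_id: str
    transcript_id: str
    aligned_frac: float
    boundary_dist: int
    read_block: tuple[int, int]   # original read coordinates
    sense_block: tuple[int, int]  # transcript-sense read coordinates
    strand: str
    n_genes_hit: int
    t_start: int
    remainder_side: str  # 'left' or 'right' of the block, in sense coordinates
    score: float


@dataclass
class GroupBHit:
    """Group B: exact placement of the unaligned remainder near an exon end."""

    read_id: str
    gene_id: str
    transcript_id: str
    exon_index: int
    match_start: int
    n_placements: int
    remainder: tuple[int, int]  # sense read coordinates
    partial: "PartialHit | None" = None  # the Group A hit this remainder came from


@dataclass
class GFCR:
    """A read whose two parts account for two genes at exon boundaries."""

    read_id: str
    gene5: str
    gene3: str
    interval5: tuple[int, int]  # sense read coordinates of the 5'-gene part
    interval3: tuple[int, int]
    junction_offset: int
    placement: tuple  # coordinates used for uniqueness collapse
    n_placements: int = 1
    n_genes_hit: int = 1

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3:
            raise InputError(f"GFCR {self.read_id}: both parts in {self.gene5}")
        a, b = sorted((self.interval5, self.interval3))
        if a[1] != b[0] or a[0] != 0:
            raise InputError(f"GFCR {self.read_id}: parts do not partition the read")


@dataclass
class SECandidate:
    gene5: str
    gene3: str
    n_unique_gfcr: int
    gfcrs: list[GFCR]
    flags: list[str] = field(default_factory=list)

    @property
    def read_ids(self) -> list[str]:
        return [g.read_id for g in self.gfcrs]


def _transcript_map(genes: Sequence[GeneModel], genome: GenomeLike) -> tuple[dict[str, str], dict[str, GeneModel]]:
    seqs, by_tid = {}, {}
    for gene in genes:
        seqs[gene.transcript_id] = gene.transcript_sequence(genome)
        by_tid[gene.transcript_id] = gene
    return seqs, by_tid


def find_group_a(unmapped_reads: Iterable[ReadRecord], genes: Sequence[GeneModel],
                 genome: GenomeLike, config: PipelineConfig | None = None) -> list[PartialHit]:
    """Partial transcript alignments covering 20-70% of the read near exon boundaries.

    Reads partially hitting more than ``max_partial_genes`` distinct genes are
    discarded as ambiguous; other failures are logged with the failing rule.
    """
    config = config or PipelineConfig()
    transcripts, by_tid = _transcript_map(genes, genome)
    hits: list[PartialHit] = []
    for read in unmapped_reads:
        length = len(read.sequence)
        alns = [a for a in local_align(read, transcripts, config) if not a.mapped_fully]
        partial = []
        genes_hit = set()
        for aln in alns:
            frac = (aln.read_end - aln.read_start) / length
            if 0 < frac < 1:
                genes_hit.add(by_tid[aln.target_id].gene_id)
            if not (config.partial_min_frac <= frac <= config.partial_max_frac):
                continue
            partial.append((aln, frac))
        if not partial:
            continue
        if len(genes_hit) > config.max_partial_genes:
            log.debug("read %s partially hits %d genes (> %d); discarded",
                      read.read_id, len(genes_hit), config.max_partial_genes)
            continue
        # every qualifying partial alignment is retained: the read may align
        # ambiguously and only one placement will combine with a Group B hit
        for aln, frac in partial:
            gene = by_tid[aln.target_id]
            if aln.strand == "+":
                q0, q1 = aln.read_start, aln.read_end
            else:
                q0, q1 = length - aln.read_end, length - aln.read_start
            side = "right" if (length - q1) >= q0 else "left"
            t_boundary = aln.target_start + (q1 - q0) if side == "right" else aln.target_start
            t_boundary = min(t_boundary, gene.transcript_length)
            dist = distance_to_exon_boundary(t_boundary, gene)
            if dist > config.boundary_tolerance:
                log.debug("read %s block %d bp from exon boundary (> %d); dropped",
                          read.read_id, dist, config.boundary_tolerance)
                continue
            hits.append(PartialHit(
                read_id=read.read_id, gene_id=gene.gene_id, transcript_id=gene.transcript_id,
                aligned_frac=frac, boundary_dist=dist,
                read_block=(aln.read_start, aln.read_end), sense_block=(q0, q1),
                strand=aln.strand, n_genes_hit=len(genes_hit), t_start=aln.target_start,
                remainder_side=side, score=aln.score or 0.0))
    return hits


def _exon_set(genes: Sequence[GeneModel], genome: GenomeLike) -> dict[str, str]:
    return {
        f"{g.gene_id}|{g.transcript_id}|{i}": g.exon_sequence(genome, i)
        for g in genes for i in range(1, g.n_exons + 1)
    }


def find_group_b(group_a: Iterable[PartialHit], reads_by_id: Mapping[str, ReadRecord],
                 genes: Sequence[GeneModel], genome: GenomeLike,
                 config: PipelineConfig | None = None) -> list[GroupBHit]:
    """Exact full-length placement of each remainder within 5 bp of an exon end."""
    config = config or PipelineConfig()
    exon_set = _exon_set(genes, genome)
    exon_lens = {tid: len(seq) for tid, seq in exon_set.items()}
    out: list[GroupBHit] = []
    for hit in group_a:
        read = reads_by_id[hit.read_id]
        sense = read.sequence if hit.strand == "+" else reverse_complement(read.sequence)
        q0, q1 = hit.sense_block
        remainder = (q1, len(sense)) if hit.remainder_side == "right" else (0, q0)
        frag = sense[remainder[0]:remainder[1]]
        if len(frag) < config.exact_min_len:
            log.debug("read %s remainder of %d bp below exact floor; dropped",
                      hit.read_id, len(frag))
            continue
        placements = exact_short_align(frag, exon_set, config, forward_only=True)
        tol = config.boundary_tolerance
        near_end = [
            p for p in placements
            if p.target_start <= tol
            or exon_lens[p.target_id] - (p.target_start + len(frag)) <= tol
        ]
        if not near_end:
            continue
        genes_b = {p.target_id.split("|")[0] for p in near_end}
        if len(genes_b) > 1:
            log.debug("read %s remainder matches %d genes near exon ends; ambiguous",
                      hit.read_id, len(genes_b))
            continue
        best = min(near_end, key=lambda p: (p.target_id, p.target_start))
        gid, tid, exon_idx = best.target_id.split("|")
        out.append(GroupBHit(
            read_id=hit.read_id, gene_id=gid, transcript_id=tid,
            exon_index=int(exon_idx), match_start=best.target_start,
            n_placements=len(placements), remainder=remainder, partial=hit))
    return out


def combine_to_gfcr(group_a: Iterable[PartialHit], group_b: Iterable[GroupBHit],
                    config: PipelineConfig | None = None) -> list[GFCR]:
    """Join Group A and Group B per read into GFCRs covering the whole read.

    Reads whose two parts fall in the same gene are normal splice evidence,
    not GFCRs, and are logged.
    """
    config = config or PipelineConfig()
    a_by_read = {h.read_id: h for h in group_a}
    gfcrs: list[GFCR] = []
    seen: set = set()
    for b in group_b:
        a = b.partial if b.partial is not None else a_by_read.get(b.read_id)
        if a is None:
            continue
        if a.gene_id == b.gene_id:
            log.debug("read %s: both parts in %s (splice evidence, not a GFCR)",
                      b.read_id, a.gene_id)
            continue
        gap = abs(b.remainder[0] - a.sense_block[1]) if a.remainder_side == "right" \
            else abs(a.sense_block[0] - b.remainder[1])
        if gap > config.gap_tolerance:
            log.debug("read %s: %d bp gap between parts (> %d); dropped",
                      b.read_id, gap, config.gap_tolerance)
            continue
        if a.remainder_side == "right":
            gene5, gene3 = a.gene_id, b.gene_id
            iv5, iv3 = a.sense_block, b.remainder
            junction = a.sense_block[1]
        else:
            gene5, gene3 = b.gene_id, a.gene_id
            iv5, iv3 = b.remainder, a.sense_block
            junction = b.remainder[1]
        placement = (a.transcript_id, a.t_start, b.transcript_id, b.exon_index,
                     b.match_start)
        key = (b.read_id, gene5, gene3, placement)
        if key in seen:
            continue
        seen.add(key)
        gfcrs.append(GFCR(
            read_id=b.read_id, gene5=gene5, gene3=gene3,
            interval5=iv5, interval3=iv3, junction_offset=junction,
            placement=placement,
            n_placements=b.n_placements, n_genes_hit=a.n_genes_hit))
    return gfcrs


def _family_root(name: str) -> str:
    return re.sub(r"\d+$", "", name)


def call_se_candidates(gfcrs: Iterable[GFCR],
                       config: PipelineConfig | None = None) -> list[SECandidate]:
    """Tally unique GFCRs per ordered gene pair and call candidates.

    Uniqueness collapses GFCRs with identical placement coordinates (PCR
    duplicates). Candidates are annotated, never removed, with false-positive
    flags: 'repetitive_region' when supporting remainders place at
    ``repeat_flag_hits`` or more loci, and 'same_family' when the two gene
    names share an alphabetic root and differ only by a numeric suffix.
    """
    config = config or PipelineConfig()
    groups: dict[tuple[str, str], list[GFCR]] = defaultdict(list)
    for g in gfcrs:
        groups[(g.gene5, g.gene3)].append(g)
    candidates = []
    for (gene5, gene3), members in sorted(groups.items()):
        unique = {m.placement for m in members}
        if len(unique) < config.min_unique_gfcr:
            continue
        flags = []
        if any(m.n_placements >= config.repeat_flag_hits for m in members):
            flags.append("repetitive_region")
        root5, root3 = _family_root(gene5), _family_root(gene3)
        if root5 and root5 == root3 and len(root5) >= config.family_prefix_len:
            flags.append("same_family")
        candidates.append(SECandidate(
            gene5=gene5, gene3=gene3, n_unique_gfcr=len(unique),
            gfcrs=members, flags=flags))
    candidates.sort(key=lambda c: (-c.n_unique_gfcr, c.gene5, c.gene3))
    return candidates


@dataclass
class SEResult:
    candidates: list[SECandidate]
    gfcrs: list[GFCR]
    counts: dict[str, int]


def run_se_pipeline(reads: Sequence[ReadRecord], genes: Sequence[GeneModel],
                    genome: GenomeLike, config: PipelineConfig | None = None) -> SEResult:
    """Full single-end workflow: genome -> splice junctions -> Group A/B -> GFCR -> candidates."""
    from .pe import genome_as_dict  # shared helper

    config = (config or PipelineConfig()).validate()
    counts = {"reads": len(reads)}
    chroms = genome_as_dict(genome)
    _, unmapped = EndToEndAligner(chroms, config, "genome").align(reads)
    counts["unmapped_genome"] = len(unmapped)
    x = max((len(r.sequence) for r in reads), default=config.read_length_x)
    jx = build_splice_junction_library(genes, x, genome)
    if jx:
        _, unmapped = EndToEndAligner(
            {r.name: r.junction_seq for r in jx}, config, "splice_junction").align(unmapped)
    counts["unmapped_junctions"] = len(unmapped)
    group_a = find_group_a(unmapped, genes, genome, config)
    counts["group_a"] = len(group_a)
    reads_by_id = {r.read_id: r for r in unmapped}
    group_b = find_group_b(group_a, reads_by_id, genes, genome, config)
    counts["group_b"] = len(group_b)
    gfcrs = combine_to_gfcr(group_a, group_b, config)
    counts["gfcrs"] = len(gfcrs)
    candidates = call_se_candidates(gfcrs, config)
    counts["candidates"] = len(candidates)
    return SEResult(candidates=candidates, gfcrs=gfcrs, counts=counts)
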