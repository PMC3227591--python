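"""Paired-end fusion discovery and the Paired-End Fusion Score (PEFS).

Discordant pairs — mates fully and uniquely mapped to different chromosomes,
or to the same chromosome at least ``min_intra_distance`` apart — nominate
gene pairs after transcript realignment. Each candidate is scored

    PEFS = 2*P - 1*D - 0.5*M

where P is the number of supporting pairs, D the number of duplicate
supporting reads (same start coordinate as another supporting read) and M the
total mismatches across supporting reads. Candidates with P >= 3 and
PEFS >= 5 are prioritized and confirmed by junction-spanning reads aligned to
the exhaustive 5'x3' exon junction library, which also reveals alternate
fusion isoforms; the predicted junction's CDS phases decide the in-frame call.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import AlignmentRecord, EndToEndAligner, ReadRecord, SamImport
from .annotation import (GeneModel, GenomeLike, build_fusion_junction_library,
                         build_splice_junction_library, genome_contig_names)
from .config import PipelineConfig
from .errors import InputError

log = logging.getLogger(__name__)

INTERCHROMOSOMAL = "interchromosomal"
LONG_INTRACHROMOSOMAL = "long_intrachromosomal"


@dataclass
class MatePlacement:
    read_id: str
    mate: int
    chromosome: str
    start: int
    strand: str
    mismatches: int
    read_length: int


@dataclass
class DiscordantPair:
    pair_id: str
    mate1: MatePlacement
    mate2: MatePlacement
    category: str

    def mates(self) -> tuple[MatePlacement, MatePlacement]:
        return (self.mate1, self.mate2)


@dataclass
class PairSupport:
    """A discordant pair placed onto a (5' gene, 3' gene) candidate."""

    pair: DiscordantPair
    gene5: str
    gene3: str
    #: per-mate transcript placements: mate index -> (gene_id, transcript_id,
    #: t_start, strand, mismatches, exon_index)
    mate_transcript: dict[int, tuple] = field(default_factory=dict)
    duplicate: bool = False


@dataclass
class SpanningRead:
    read_id: str
    exon5_index: int
    exon3_index: int
    junction_start: int
    mismatches: int


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    support_pairs: list[PairSupport]
    P: int = 0
    D: int = 0
    M: int = 0
    pefs: float | None = None
    spanning_reads: list[SpanningRead] = field(default_factory=list)
    predicted_junction: tuple[int, int] | None = None
    isoforms: list[tuple[int, int]] = field(default_factory=list)
    in_frame: str | None = None
    confirmed: bool = False
    flags: list[str] = field(default_factory=list)
    se_support: int | None = None


def genome_as_dict(genome: GenomeLike) -> dict[str, str]:
    return {name: str(genome[name][:]).upper() for name in genome_contig_names(genome)}


def select_discordant_pairs(alignments: Iterable[AlignmentRecord],
                            config: PipelineConfig | None = None) -> list[DiscordantPair]:
    """Keep pairs whose mates both map fully and uniquely, then classify.

    Interchromosomal: mates on different chromosomes. Long intrachromosomal:
    same chromosome, separation >= ``min_intra_distance``. Everything else
    (including orphan mates) is excluded.
    """
    config = config or PipelineConfig()
    by_pair: dict[str, dict[int, AlignmentRecord]] = defaultdict(dict)
    for rec in alignments:
        if rec.mate not in (1, 2):
            continue
        if not (rec.unique and rec.mapped_fully):
            continue
        by_pair[rec.read_id][rec.mate] = rec

    pairs: list[DiscordantPair] = []
    orphans = 0
    for pair_id, mates in sorted(by_pair.items()):
        if set(mates) != {1, 2}:
            orphans += 1
            continue
        m1, m2 = mates[1], mates[2]
        if m1.target_id != m2.target_id:
            category = INTERCHROMOSOMAL
        elif abs(m1.target_start - m2.target_start) >= config.min_intra_distance:
            category = LONG_INTRACHROMOSOMAL
        else:
            continue
        pairs.append(DiscordantPair(
            pair_id=pair_id,
            mate1=MatePlacement(pair_id, 1, m1.target_id, m1.target_start, m1.strand,
                                m1.mismatches, m1.read_end - m1.read_start),
            mate2=MatePlacement(pair_id, 2, m2.target_id, m2.target_start, m2.strand,
                                m2.mismatches, m2.read_end - m2.read_start),
            category=category))
    if orphans:
        log.info("skipped %d pairs with an orphan or disqualified mate", orphans)
    return pairs


def assign_pairs_to_genes(pairs: Sequence[DiscordantPair], genes: Sequence[GeneModel],
                          genome: GenomeLike,
                          reads_by_id: Mapping[tuple[str, int | None], ReadRecord],
                          config: PipelineConfig | None = None
                          ) -> dict[tuple[str, str], list[PairSupport]]:
    """Realign mates to transcripts and group pairs by oriented gene pair.

    The mate aligning to the mRNA forward strand sits upstream in the fragment
    and therefore belongs to the 5' partner. Pairs whose mates hit the same
    gene, no gene, or more than one gene ambiguously are dropped (logged);
    pairs with ambiguous orientation are emitted under both orientations.
    """
    config = config or PipelineConfig()
    transcripts = {g.transcript_id: g.transcript_sequence(genome) for g in genes}
    by_tid = {g.transcript_id: g for g in genes}
    aligner = EndToEndAligner(transcripts, config, "transcript")

    groups: dict[tuple[str, str], list[PairSupport]] = defaultdict(list)
    dropped = Counter()
    for pair in pairs:
        mate_info: dict[int, tuple] = {}
        ok = True
        for mate in pair.mates():
            read = reads_by_id.get((pair.pair_id, mate.mate))
            if read is None:
                dropped["missing_sequence"] += 1
                ok = False
                break
            recs = aligner.align_read(read)
            gene_ids = {by_tid[r.target_id].gene_id for r in recs}
            if not gene_ids:
                dropped["no_transcript"] += 1
                ok = False
                break
            if len(gene_ids) > 1:
                dropped["ambiguous_gene"] += 1
                ok = False
                break
            rec = recs[0]
            gene = by_tid[rec.target_id]
            # midpoint is robust to alignments overhanging an exon edge by a
            # couple of bases within the mismatch budget
            mid = rec.target_start + (rec.read_end - rec.read_start) // 2
            exon_idx = gene.exon_index_at(min(max(mid, 0), gene.transcript_length - 1))
            mate_info[mate.mate] = (gene.gene_id, rec.target_id, rec.target_start,
                                    rec.strand, rec.mismatches, exon_idx)
        if not ok:
            continue
        g1, g2 = mate_info[1][0], mate_info[2][0]
        if g1 == g2:
            dropped["same_gene"] += 1
            continue
        s1, s2 = mate_info[1][3], mate_info[2][3]
        if s1 == "+" and s2 == "-":
            orientations = [(g1, g2)]
        elif s1 == "-" and s2 == "+":
            orientations = [(g2, g1)]
        else:
            log.debug("pair %s: ambiguous 5'/3' orientation; emitting both", pair.pair_id)
            orientations = [(g1, g2), (g2, g1)]
        for gene5, gene3 in orientations:
            groups[(gene5, gene3)].append(PairSupport(
                pair=pair, gene5=gene5, gene3=gene3, mate_transcript=mate_info))
    if dropped:
        log.info("pairs dropped during gene assignment: %s", dict(dropped))
    return dict(groups)


def _count_duplicates(supports: Sequence[PairSupport]) -> int:
    """Duplicate reads: each supporting read beyond the first at an identical
    (chromosome, start) counts once."""
    seen: Counter = Counter()
    for sup in supports:
        for mate in sup.pair.mates():
            seen[(mate.chromosome, mate.start)] += 1
    dups = sum(n - 1 for n in seen.values())
    # flag pairs containing a duplicate read (every occurrence past the first)
    seen2: set = set()
    for sup in supports:
        for mate in sup.pair.mates():
            key = (mate.chromosome, mate.start)
            if key in seen2:
                sup.duplicate = True
            seen2.add(key)
    return dups


def build_candidates(groups: Mapping[tuple[str, str], Sequence[PairSupport]],
                     config: PipelineConfig | None = None) -> list[FusionCandidate]:
    """Assemble candidates, deriving P, D and M from the supporting pairs."""
    config = config or PipelineConfig()
    candidates = []
    for (gene5, gene3), supports in sorted(groups.items()):
        supports = list(supports)
        if config.mismatch_source == "transcript":
            mm = sum(info[4] for sup in supports for info in sup.mate_transcript.values())
        else:
            mm = sum(mate.mismatches for sup in supports for mate in sup.pair.mates())
        cand = FusionCandidate(
            gene5=gene5, gene3=gene3, support_pairs=supports,
            P=len(supports), D=_count_duplicates(supports), M=mm)
        compute_pefs(cand, config)
        candidates.append(cand)
    return candidates


def compute_pefs(candidate: FusionCandidate,
                 config: PipelineConfig | None = None) -> float:
    """PEFS = pair_reward*P - duplicate_penalty*D - mismatch_penalty*M."""
    config = config or PipelineConfig()
    if candidate.P < 1:
        raise InputError(
            f"{candidate.gene5}-{candidate.gene3}: PEFS requires at least one supporting pair")
    score = (config.pair_reward * candidate.P
             - config.duplicate_penalty * candidate.D
             - config.mismatch_penalty * candidate.M)
    candidate.pefs = round(score, 1)
    return candidate.pefs


def prioritize_candidates(candidates: Iterable[FusionCandidate],
                          config: PipelineConfig | None = None) -> list[FusionCandidate]:
    """Candidates with P >= min_support_pairs and PEFS >= min_pefs, ranked."""
    config = config or PipelineConfig()
    kept = [c for c in candidates
            if c.P >= config.min_support_pairs and (c.pefs or 0) >= config.min_pefs]
    kept.sort(key=lambda c: (-(c.pefs or 0), -c.P, (c.gene5, c.gene3)))
    return kept


def find_spanning_reads(candidate: FusionCandidate, unmapped_reads: Sequence[ReadRecord],
                        gene_models: Mapping[str, GeneModel], genome: GenomeLike,
                        x: int, config: PipelineConfig | None = None) -> FusionCandidate:
    """Confirm a candidate with reads spanning its fusion junction library.

    Unmapped reads are aligned full-length against every (exon i of the 5'
    gene, exon j of the 3' gene) junction sequence. Reads placed uniquely with
    at least 5 bp on each exon side count toward that junction; the modal
    junction becomes ``predicted_junction`` and every junction with support is
    kept as an isoform. With zero spanning reads the candidate stays
    unconfirmed and the junction falls back to the innermost exons touched by
    the flanking pairs.
    """
    config = config or PipelineConfig()
    gene5, gene3 = gene_models[candidate.gene5], gene_models[candidate.gene3]
    library = build_fusion_junction_library(gene5, gene3, x, genome)
    by_name = {rec.name: rec for rec in library}
    spanning: list[SpanningRead] = []
    if unmapped_reads:
        aligner = EndToEndAligner({rec.name: rec.junction_seq for rec in library},
                                  config, "fusion_junction")
        for read in unmapped_reads:
            recs = [r for r in aligner.align_read(read) if r.unique]
            for rec in recs:
                jrec = by_name[rec.target_id]
                left_overlap = jrec.left_arm_len - rec.target_start
                right_overlap = rec.target_start + (rec.read_end - rec.read_start) - jrec.left_arm_len
                if left_overlap < 5 or right_overlap < 5:
                    continue
                spanning.append(SpanningRead(
                    read_id=read.read_id, exon5_index=jrec.left_exon_index,
                    exon3_index=jrec.right_exon_index,
                    junction_start=rec.target_start, mismatches=rec.mismatches))
    candidate.spanning_reads = spanning
    if spanning:
        tally = Counter((s.exon5_index, s.exon3_index) for s in spanning)
        candidate.predicted_junction = max(tally.items(), key=lambda kv: (kv[1], kv[0]))[0]
        candidate.isoforms = sorted(tally)
        candidate.confirmed = True
    else:
        candidate.confirmed = False
        if "unconfirmed" not in candidate.flags:
            candidate.flags.append("unconfirmed")
        exon5 = [sup.mate_transcript[m][5] for sup in candidate.support_pairs
                 for m in sup.mate_transcript
                 if sup.mate_transcript[m][0] == candidate.gene5]
        exon3 = [sup.mate_transcript[m][5] for sup in candidate.support_pairs
                 for m in sup.mate_transcript
                 if sup.mate_transcript[m][0] == candidate.gene3]
        if exon5 and exon3:
            candidate.predicted_junction = (max(exon5), min(exon3))
            candidate.isoforms = []
    return candidate


def determine_in_frame(candidate: FusionCandidate,
                       gene_models: Mapping[str, GeneModel]) -> str:
    """In-frame call for the predicted junction.

    'Y' when the coding phase at the 5' partner's donor boundary equals the 3'
    partner's phase at the acceptor boundary; 'UTR-truncation' when the
    breakpoint lies in a 5' UTR (the downstream ORF survives intact); 'N' when
    phases disagree or the breakpoint leaves no fusion ORF; 'unknown' when a
    CDS is missing.
    """
    if candidate.predicted_junction is None:
        raise InputError(
            f"{candidate.gene5}-{candidate.gene3}: no predicted junction for in-frame call")
    e5, e3 = candidate.predicted_junction
    gene5, gene3 = gene_models[candidate.gene5], gene_models[candidate.gene3]
    cds5, cds3 = gene5.cds_transcript_span(), gene3.cds_transcript_span()
    if cds5 is None or cds3 is None:
        log.warning("%s-%s: missing CDS; in-frame call unknown",
                    candidate.gene5, candidate.gene3)
        candidate.in_frame = "unknown"
        return candidate.in_frame
    donor_t = gene5.exon_boundaries()[e5]          # end of exon e5, transcript coords
    acceptor_t = gene3.exon_boundaries()[e3 - 1]   # start of exon e3
    if donor_t <= cds5[0]:
        candidate.in_frame = "UTR-truncation"
    elif donor_t >= cds5[1] or acceptor_t >= cds3[1]:
        candidate.in_frame = "N"
    elif acceptor_t <= cds3[0]:
        candidate.in_frame = "UTR-truncation"
    else:
        phase5 = (donor_t - cds5[0]) % 3
        phase3 = (acceptor_t - cds3[0]) % 3
        candidate.in_frame = "Y" if phase5 == phase3 else "N"
    return candidate.in_frame


@dataclass
class PEResult:
    candidates: list[FusionCandidate]
    prioritized: list[FusionCandidate]
    counts: dict[str, int]


def run_pe_pipeline(reads: Sequence[ReadRecord], genes: Sequence[GeneModel],
                    genome: GenomeLike, config: PipelineConfig | None = None,
                    sam: SamImport | None = None) -> PEResult:
    """Full paired-end workflow.

    Genomic alignments come from the built-in aligner unless a
    :class:`SamImport` is supplied. Reads unmapped to both the genome and the
    within-gene splice junction library feed the spanning-read search.
    """
    config = (config or PipelineConfig()).validate()
    counts: dict[str, int] = {}
    reads_by_id: dict[tuple[str, int | None], ReadRecord] = {
        (r.read_id, r.mate): r for r in reads}
    counts["pairs"] = len({r.read_id for r in reads})

    if sam is not None:
        genome_alns, unmapped = sam.alignments, list(sam.unmapped_reads)
        for key, read in sam.reads_by_id.items():
            reads_by_id.setdefault(key, read)
    else:
        if not reads:
            return PEResult([], [], {"pairs": 0})
        genome_alns, unmapped = EndToEndAligner(
            genome_as_dict(genome), config, "genome").align(reads)
    counts["unmapped_genome"] = len(unmapped)

    x = max((len(r.sequence) for r in reads), default=config.read_length_x)
    splice_lib = build_splice_junction_library(genes, x, genome)
    if splice_lib and unmapped:
        _, unmapped = EndToEndAligner(
            {rec.name: rec.junction_seq for rec in splice_lib},
            config, "splice_junction").align(unmapped)
    counts["unmapped_junctions"] = len(unmapped)

    pairs = select_discordant_pairs(genome_alns, config)
    counts["discordant_pairs"] = len(pairs)
    groups = assign_pairs_to_genes(pairs, genes, genome, reads_by_id, config)
    counts["gene_assigned_pairs"] = sum(len(v) for v in groups.values())
    candidates = build_candidates(groups, config)
    counts["candidates"] = len(candidates)
    prioritized = prioritize_candidates(candidates, config)
    counts["prioritized"] = len(prioritized)

    gene_models = {g.gene_id: g for g in genes}
    for cand in prioritized:
        find_spanning_reads(cand, unmapped, gene_models, genome, x, config)
        if cand.predicted_junction is not None:
            determine_in_frame(cand, gene_models)
    counts["confirmed"] = sum(1 for c in prioritized if c.confirmed)
    return PEResult(candidates=candidates, prioritized=prioritized, counts=counts)
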