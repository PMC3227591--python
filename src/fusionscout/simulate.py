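"""Seeded generator of toy genomes, annotations, fusion transcripts and reads.

The generator emulates the data regime the detection stages are built for:
a small multi-chromosome genome carrying multi-exon genes; expressed
wild-type transcripts; fusion transcripts joining exon boundaries of two
genes (inter- or intrachromosomal, optionally reciprocal, optionally with a
5'-UTR breakpoint); single- or paired-end reads of configurable length with
i.i.d. substitution errors, PCR duplicates, and expression imbalance between
the 5' and 3' fusion partners. Every simulated read is recorded in a truth
table with its provenance, so each pipeline stage can be checked against
ground truth.

All randomness flows from a single ``numpy`` generator seeded by the spec, so
identical specs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .align import ReadRecord
from .annotation import GeneModel, build_fusion_junction_library
from .errors import ConfigError, InputError

_BASES = np.array(list("ACGT"))


@dataclass
class FusionEvent:
    gene5: str
    exon5: int  # last retained exon of the 5' partner (1-based)
    gene3: str
    exon3: int  # first retained exon of the 3' partner (1-based)
    expression: float = 1.0
    reciprocal: bool = False


@dataclass
class SimulationSpec:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 30_000
    n_genes: int = 8
    exon_count_range: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (80, 220)
    intron_length_range: tuple[int, int] = (60, 300)
    intergenic_range: tuple[int, int] = (300, 800)
    fusions: list[FusionEvent] = field(default_factory=list)
    read_mode: str = "pe"  # 'se' or 'pe'
    read_length: int = 50
    fragment_mean: float = 150.0
    fragment_sd: float = 20.0
    error_rate: float = 0.0
    duplicate_fraction: float = 0.0
    depth: float = 20.0
    #: per-gene wild-type abundance multipliers (default 1.0)
    gene_expression: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "SimulationSpec":
        if self.read_mode not in ("se", "pe"):
            raise ConfigError(f"read_mode must be 'se' or 'pe', got {self.read_mode!r}")
        for name in ("error_rate", "duplicate_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.read_mode == "pe" and self.read_length >= self.fragment_mean:
            raise ConfigError(
                f"read_length ({self.read_length}) must be below fragment_mean "
                f"({self.fragment_mean}) for paired-end mode")
        if self.depth < 1:
            raise ConfigError(f"depth must be >= 1, got {self.depth}")
        if self.exon_count_range[0] < 2:
            raise ConfigError("genes must have at least 2 exons")
        return self


@dataclass
class FusionTranscript:
    name: str
    sequence: str
    gene5: str
    exon5: int
    gene3: str
    exon3: int
    junction_pos: int  # transcript coordinate of the junction
    expression: float
    in_frame: str  # truth label: Y / N / UTR-truncation / unknown


@dataclass
class TruthTable:
    """Ground truth: fusion events and per-read provenance."""

    events: list[FusionTranscript] = field(default_factory=list)
    #: per event name: the expected junction sequence (x-5 rule)
    junction_seqs: dict[str, str] = field(default_factory=dict)
    reads: pd.DataFrame | None = None

    def to_tsv(self, path: str | Path) -> None:
        if self.reads is not None:
            self.reads.to_csv(path, sep="\t", index=False)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def generate_reference(spec: SimulationSpec) -> tuple[dict[str, str], list[GeneModel]]:
    """Deterministic toy genome + annotation.

    Genes are packed left to right with intergenic gaps; each has >= 2 exons
    and a CDS chosen so that both in-frame and out-of-frame fusions (and
    5'-UTR breakpoints) are constructible. Raises when the genes do not fit
    the requested chromosome length.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome = {f"chr{i + 1}": _random_dna(rng, spec.chromosome_length)
              for i in range(spec.n_chromosomes)}
    cursors = {name: 0 for name in genome}
    genes: list[GeneModel] = []
    for gi in range(spec.n_genes):
        chrom = f"chr{gi % spec.n_chromosomes + 1}"
        n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        exon_lens = rng.integers(spec.exon_length_range[0], spec.exon_length_range[1] + 1,
                                 size=n_exons)
        intron_lens = rng.integers(spec.intron_length_range[0], spec.intron_length_range[1] + 1,
                                   size=n_exons - 1)
        gap = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[chrom] + gap
        if start + span > spec.chromosome_length:
            raise InputError(
                f"cannot pack gene {gi + 1} on {chrom}: need {start + span} bp but the "
                f"chromosome is {spec.chromosome_length} bp; increase chromosome_length")
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k]) + (int(intron_lens[k]) if k < n_exons - 1 else 0)
        cursors[chrom] = pos
        strand = "+" if rng.random() < 0.5 else "-"
        ordered = exons if strand == "+" else exons[::-1]
        gene = GeneModel(
            gene_id=f"GENE{gi + 1:03d}", transcript_id=f"GENE{gi + 1:03d}.t1",
            chromosome=chrom, strand=strand, exons=ordered)
        # CDS in transcript coordinates: start within the first third, end near
        # the 3' end, length a multiple of 3
        tlen = gene.transcript_length
        cds_t_start = int(rng.integers(5, max(6, tlen // 3)))
        cds_t_end = tlen - int(rng.integers(5, max(6, tlen // 4)))
        cds_t_end = cds_t_start + 3 * max(10, (cds_t_end - cds_t_start) // 3)
        cds_t_end = min(cds_t_end, tlen - 1)
        gene.cds_span = _transcript_span_to_genomic(gene, cds_t_start, cds_t_end)
        gene.__post_init__()  # re-validate with the CDS attached
        genes.append(gene)
    return genome, genes


def _transcript_to_genomic(gene: GeneModel, tpos: int) -> int:
    offset = 0
    for s, e in gene.exons:
        length = e - s
        if tpos < offset + length:
            within = tpos - offset
            return s + within if gene.strand == "+" else e - within - 1
        offset += length
    raise InputError(f"{gene.gene_id}: transcript position {tpos} out of range")


def _transcript_span_to_genomic(gene: GeneModel, t_start: int, t_end: int) -> tuple[int, int]:
    g1 = _transcript_to_genomic(gene, t_start)
    g2 = _transcript_to_genomic(gene, t_end - 1)
    return (min(g1, g2), max(g1, g2) + 1)


def _truth_in_frame(gene5: GeneModel, exon5: int, gene3: GeneModel, exon3: int) -> str:
    cds5, cds3 = gene5.cds_transcript_span(), gene3.cds_transcript_span()
    if cds5 is None or cds3 is None:
        return "unknown"
    donor = gene5.exon_boundaries()[exon5]
    acceptor = gene3.exon_boundaries()[exon3 - 1]
    if donor <= cds5[0]:
        return "UTR-truncation"
    if donor >= cds5[1] or acceptor >= cds3[1]:
        return "N"
    if acceptor <= cds3[0]:
        return "UTR-truncation"
    return "Y" if (donor - cds5[0]) % 3 == (acceptor - cds3[0]) % 3 else "N"


def inject_fusion(spec: SimulationSpec, genes: Sequence[GeneModel],
                  genome: dict[str, str]) -> tuple[list[FusionTranscript], TruthTable]:
    """Build fusion transcript sequences and the truth table for the spec's events.

    A fusion transcript joins exons 1..e5 of the 5' partner with exons
    e3..last of the 3' partner, both in transcript orientation. A reciprocal
    event additionally joins (gene3, e3-1) to (gene5, e5+1).
    """
    by_id = {g.gene_id: g for g in genes}
    truth = TruthTable()
    transcripts: list[FusionTranscript] = []

    def _one(gene5_id: str, e5: int, gene3_id: str, e3: int, expression: float) -> None:
        g5, g3 = by_id.get(gene5_id), by_id.get(gene3_id)
        if g5 is None or g3 is None:
            raise InputError(f"fusion names unknown gene: {gene5_id} or {gene3_id}")
        if not (1 <= e5 <= g5.n_exons) or not (1 <= e3 <= g3.n_exons):
            raise InputError(
                f"fusion exon ordinal out of range: {gene5_id} exon {e5} "
                f"(1..{g5.n_exons}) / {gene3_id} exon {e3} (1..{g3.n_exons})")
        seq5 = "".join(g5.exon_sequence(genome, i) for i in range(1, e5 + 1))
        seq3 = "".join(g3.exon_sequence(genome, j) for j in range(e3, g3.n_exons + 1))
        name = f"{gene5_id}.e{e5}__{gene3_id}.e{e3}"
        ft = FusionTranscript(
            name=name, sequence=seq5 + seq3, gene5=gene5_id, exon5=e5,
            gene3=gene3_id, exon3=e3, junction_pos=len(seq5),
            expression=expression, in_frame=_truth_in_frame(g5, e5, g3, e3))
        transcripts.append(ft)
        truth.events.append(ft)
        lib = build_fusion_junction_library(g5, g3, spec.read_length, genome)
        for rec in lib:
            if rec.left_exon_index == e5 and rec.right_exon_index == e3:
                truth.junction_seqs[name] = rec.junction_seq
                break

    for event in spec.fusions:
        _one(event.gene5, event.exon5, event.gene3, event.exon3, event.expression)
        if event.reciprocal:
            g5, g3 = by_id[event.gene5], by_id[event.gene3]
            if event.exon3 - 1 < 1 or event.exon5 + 1 > g5.n_exons:
                raise InputError(
                    f"reciprocal of {event.gene5}-{event.gene3} needs exon "
                    f"{event.exon3 - 1} of {event.gene3} and exon {event.exon5 + 1} "
                    f"of {event.gene5}")
            _one(event.gene3, event.exon3 - 1, event.gene5, event.exon5 + 1,
                 event.expression)
    return transcripts, truth


@dataclass
class SimulatedReads:
    reads: list[ReadRecord]              # SE reads, or all mates for PE
    mates1: list[ReadRecord] = field(default_factory=list)
    mates2: list[ReadRecord] = field(default_factory=list)
    provenance: pd.DataFrame | None = None


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode(), len(hits)


def simulate_reads(spec: SimulationSpec, genes: Sequence[GeneModel],
                   genome: dict[str, str],
                   fusion_transcripts: Sequence[FusionTranscript] = (),
                   ) -> SimulatedReads:
    """Sample SE or PE reads from the wild-type + fusion transcript pool.

    Fragment starts are uniform along each transcript; the number of fragments
    per transcript is depth * abundance * length / (bases sequenced per
    fragment). A ``duplicate_fraction`` Bernoulli draw re-emits fragments at
    identical coordinates; substitution errors are i.i.d. per base.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from reference stream
    pool: list[tuple[str, str, float, int | None, str]] = []
    for gene in genes:
        abundance = spec.gene_expression.get(gene.gene_id, 1.0)
        if abundance > 0:
            pool.append((gene.transcript_id, gene.transcript_sequence(genome),
                         abundance, None, "wild_type"))
    for ft in fusion_transcripts:
        if ft.expression > 0:
            pool.append((ft.name, ft.sequence, ft.expression, ft.junction_pos,
                         "fusion_junction"))

    L = spec.read_length
    read_bases = L if spec.read_mode == "se" else 2 * L
    fragments: list[tuple[str, str, int, int, int | None, str, bool]] = []
    for name, seq, abundance, junction, source in pool:
        if len(seq) < L:
            raise InputError(f"transcript {name} ({len(seq)} bp) shorter than the read length")
        n_frag = max(1, math.ceil(spec.depth * abundance * len(seq) / read_bases))
        for _ in range(n_frag):
            if spec.read_mode == "se":
                frag_len = L
            else:
                frag_len = int(np.clip(rng.normal(spec.fragment_mean, spec.fragment_sd),
                                       L, len(seq)))
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            fragments.append((name, seq, start, frag_len, junction, source, False))

    # PCR duplicates: re-emit a Bernoulli-selected subset at identical coordinates
    if spec.duplicate_fraction > 0:
        dup_mask = rng.random(len(fragments)) < spec.duplicate_fraction
        for i in np.nonzero(dup_mask)[0]:
            name, seq, start, frag_len, junction, source, _ = fragments[int(i)]
            fragments.append((name, seq, start, frag_len, junction, source, True))

    result = SimulatedReads(reads=[])
    rows = []
    counter = 0

    def _spans(a: int, b: int, junction: int | None) -> bool:
        return junction is not None and a <= junction - 5 and b >= junction + 5

    for name, seq, start, frag_len, junction, source, is_dup in fragments:
        counter += 1
        rid = f"r{counter:06d}"
        frag = seq[start:start + frag_len]
        if spec.read_mode == "se":
            strand = "+" if rng.random() < 0.5 else "-"
            raw = frag if strand == "+" else reverse_complement(frag)
            errseq, n_err = _apply_errors(raw, rng, spec.error_rate)
            result.reads.append(ReadRecord(rid, errseq, None))
            rows.append(dict(read_id=rid, mate=0, transcript=name, source=source,
                             start=start, end=start + frag_len, strand=strand,
                             duplicate=is_dup, n_errors=n_err,
                             spans_junction=_spans(start, start + frag_len, junction)))
        else:
            flip = rng.random() < 0.5  # unstranded library: either end is read 1
            fwd = frag[:L]
            rev = reverse_complement(frag[-L:])
            seq1, seq2 = (fwd, rev) if not flip else (rev, fwd)
            s1, n1 = _apply_errors(seq1, rng, spec.error_rate)
            s2, n2 = _apply_errors(seq2, rng, spec.error_rate)
            m1, m2 = ReadRecord(rid, s1, 1), ReadRecord(rid, s2, 2)
            result.mates1.append(m1)
            result.mates2.append(m2)
            result.reads.extend([m1, m2])
            iv_fwd = (start, start + L)
            iv_rev = (start + frag_len - L, start + frag_len)
            iv1, iv2 = (iv_fwd, iv_rev) if not flip else (iv_rev, iv_fwd)
            for mate, iv, n_err in ((1, iv1, n1), (2, iv2, n2)):
                rows.append(dict(read_id=rid, mate=mate, transcript=name, source=source,
                                 start=iv[0], end=iv[1], strand="+",
                                 duplicate=is_dup, n_errors=n_err,
                                 spans_junction=_spans(iv[0], iv[1], junction)))
    result.provenance = pd.DataFrame(rows)
    return result


def simulate_dataset(spec: SimulationSpec) -> tuple[dict[str, str], list[GeneModel],
                                                    list[FusionTranscript], TruthTable,
                                                    SimulatedReads]:
    """One-call convenience: reference, fusions, reads and truth."""
    genome, genes = generate_reference(spec)
    fusion_transcripts, truth = inject_fusion(spec, genes, genome)
    reads = simulate_reads(spec, genes, genome, fusion_transcripts)
    truth.reads = reads.provenance
    return genome, genes, fusion_transcripts, truth, reads


# --- annotation writers -------------------------------------------------------


def _cds_segments(gene: GeneModel) -> list[tuple[int, int]]:
    if gene.cds_span is None:
        return []
    cs, ce = gene.cds_span
    return [(max(s, cs), min(e, ce)) for s, e in sorted(gene.exons)
            if max(s, cs) < min(e, ce)]


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.transcript_id}";'
            for s, e in sorted(gene.exons):
                fh.write("\t".join([gene.chromosome, "fusionscout", "exon",
                                    str(s + 1), str(e), ".", gene.strand, ".",
                                    attrs]) + "\n")
            for s, e in _cds_segments(gene):
                fh.write("\t".join([gene.chromosome, "fusionscout", "CDS",
                                    str(s + 1), str(e), ".", gene.strand, "0",
                                    attrs]) + "\n")


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            exons = sorted(gene.exons)
            start, end = exons[0][0], exons[-1][1]
            thick = gene.cds_span or (start, start)
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            offsets = ",".join(str(s - start) for s, _ in exons) + ","
            fh.write("\t".join([
                gene.chromosome, str(start), str(end),
                f"{gene.gene_id}|{gene.transcript_id}", "0", gene.strand,
                str(thick[0]), str(thick[1]), "0", str(len(exons)),
                sizes, offsets]) + "\n")
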