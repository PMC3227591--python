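"""Shared fixtures: a handcrafted two-chromosome toy genome with three genes,
plus helpers for constructing paired-end fragments and SAM files."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from Bio.Seq import reverse_complement

from fusionscout import GeneModel, ReadRecord

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    rng = np.random.default_rng(42)
    return {"chr1": random_dna(rng, 3000), "chr2": random_dna(rng, 2000)}


@pytest.fixture(scope="session")
def toy_genes(toy_genome) -> list[GeneModel]:
    """NFIA (+, chr1, 3 exons), BRD9 (-, chr1, 2 exons), EHF (+, chr2, 4 exons)."""
    nfia = GeneModel("NFIA", "NFIA.t1", "chr1", "+",
                     [(100, 160), (220, 300), (360, 460)], cds_span=(130, 430))
    brd9 = GeneModel("BRD9", "BRD9.t1", "chr1", "-",
                     [(820, 910), (700, 760)], cds_span=(705, 900))
    ehf = GeneModel("EHF", "EHF.t1", "chr2", "+",
                    [(100, 200), (300, 380), (500, 600), (700, 800)],
                    cds_span=(150, 750))
    return [nfia, brd9, ehf]


@pytest.fixture(scope="session")
def genes_by_id(toy_genes):
    return {g.gene_id: g for g in toy_genes}


def fusion_transcript(gene5: GeneModel, exon5: int, gene3: GeneModel, exon3: int,
                      genome: dict[str, str]) -> tuple[str, int]:
    """Fusion transcript sequence and the transcript coordinate of the junction."""
    seq5 = "".join(gene5.exon_sequence(genome, i) for i in range(1, exon5 + 1))
    seq3 = "".join(gene3.exon_sequence(genome, j) for j in range(exon3, gene3.n_exons + 1))
    return seq5 + seq3, len(seq5)


def make_pair(rid: str, transcript: str, start: int, frag_len: int,
              read_len: int = 50) -> list[ReadRecord]:
    """FR read pair from a transcript fragment (mate 1 forward, mate 2 reverse)."""
    frag = transcript[start:start + frag_len]
    assert len(frag) == frag_len, "fragment runs past the transcript end"
    return [ReadRecord(rid, frag[:read_len], 1),
            ReadRecord(rid, reverse_complement(frag[-read_len:]), 2)]


def write_sam(path, genome: dict[str, str], alignment_groups, unmapped_reads) -> None:
    """Write one SAM line per read.

    ``alignment_groups``: iterable of (ReadRecord, list[AlignmentRecord]) with
    genomic placements; a uniquely placed read gets MAPQ 60, a multi-placed
    read MAPQ 0 at its first placement. ``unmapped_reads`` are emitted with
    the unmapped flag.
    """
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()]}
    refs = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        def base_seg(read):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            if read.mate == 1:
                seg.flag |= 0x1 | 0x40
            elif read.mate == 2:
                seg.flag |= 0x1 | 0x80
            return seg

        for read, recs in alignment_groups:
            seg = base_seg(read)
            rec = recs[0]
            seg.reference_id = refs[rec.target_id]
            seg.reference_start = rec.target_start
            seg.mapping_quality = 60 if rec.unique else 0
            seg.cigarstring = f"{len(read.sequence)}M"
            seg.query_sequence = (read.sequence if rec.strand == "+"
                                  else reverse_complement(read.sequence))
            if rec.strand == "-":
                seg.flag |= 0x10
            seg.set_tag("NM", rec.mismatches)
            out.write(seg)
        for read in unmapped_reads:
            seg = base_seg(read)
            seg.flag |= 0x4
            seg.query_sequence = read.sequence
            out.write(seg)
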