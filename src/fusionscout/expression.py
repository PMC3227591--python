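"""Exon-level expression: unique-read counts, RPKM, and cross-sample fold change.

RPKM = count / (exon length / 1e3) / (total mapped reads / 1e6). The fold
change of exon e compares the fusion-bearing sample S against the mean of
fusion-negative reference samples R: FC = (RPKM_S + eps) / (RPKM_R + eps),
reported as log2(FC). A breakpoint-delineated expression step (e.g. the
3' partner transcribed from the 5' partner's promoter) appears as a block
shift in log2 FC at the fusion exon.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import AlignmentRecord
from .annotation import GeneModel
from .errors import InputError

log = logging.getLogger(__name__)


def count_reads_per_exon(alignments: Iterable[AlignmentRecord],
                         genes: Sequence[GeneModel]) -> tuple[dict[tuple[str, int], int], int]:
    """Count uniquely mapped reads per exon.

    A read overlapping an exon by >= 1 bp counts once for that exon; a read
    straddling two exons counts for both. Multi-mapped or partially mapped
    reads contribute nothing. Returns (counts keyed by (gene_id, exon ordinal),
    total unique mapped reads).
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chromosome, IntervalTree())
        for i, (s, e) in enumerate(gene.exons, start=1):
            tree.addi(s, e, (gene.gene_id, i))
    counts: Counter = Counter()
    total_unique = 0
    for rec in alignments:
        if not (rec.unique and rec.mapped_fully):
            continue
        total_unique += 1
        tree = trees.get(rec.target_id)
        if tree is None:
            continue
        length = rec.read_end - rec.read_start
        for iv in tree.overlap(rec.target_start, rec.target_start + length):
            counts[iv.data] += 1
    return dict(counts), total_unique


def compute_rpkm(count: int, exon_len_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_len_bp <= 0:
        raise InputError(f"exon length must be positive, got {exon_len_bp}")
    if total_mapped_reads <= 0:
        raise InputError(f"total mapped reads must be positive, got {total_mapped_reads}")
    return count / (exon_len_bp / 1e3) / (total_mapped_reads / 1e6)


@dataclass
class ExonExpressionProfile:
    """Per-exon RPKM for one gene in one sample, with optional fold changes."""

    gene_id: str
    sample: str
    exon_lengths: list[int]
    counts: list[int]
    rpkm: list[float]
    fc: list[float] | None = None
    log2_fc: list[float] | None = None
    zero_reference_exons: list[int] = field(default_factory=list)

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "gene": self.gene_id,
            "sample": self.sample,
            "exon": np.arange(1, self.n_exons + 1),
            "length_bp": self.exon_lengths,
            "count": self.counts,
            "rpkm": self.rpkm,
        }
        if self.fc is not None:
            data["fc"] = self.fc
            data["log2_fc"] = self.log2_fc
        return pd.DataFrame(data)


def build_profile(gene: GeneModel, counts: Mapping[tuple[str, int], int],
                  total_mapped_reads: int, sample: str = "sample") -> ExonExpressionProfile:
    lengths = gene.exon_lengths()
    exon_counts = [counts.get((gene.gene_id, i), 0) for i in range(1, gene.n_exons + 1)]
    rpkm = [compute_rpkm(c, l, total_mapped_reads) for c, l in zip(exon_counts, lengths)]
    return ExonExpressionProfile(
        gene_id=gene.gene_id, sample=sample, exon_lengths=lengths,
        counts=exon_counts, rpkm=rpkm)


def compute_fold_change(sample_profile: ExonExpressionProfile,
                        reference_profiles: Sequence[ExonExpressionProfile],
                        pseudocount: float = 0.1) -> ExonExpressionProfile:
    """Per-exon FC of the sample against the mean of the reference profiles.

    Exons with zero reference RPKM but positive sample RPKM get a finite FC
    through the pseudocount and are flagged in ``zero_reference_exons``.
    """
    if not reference_profiles:
        raise InputError("fold change requires at least one reference profile")
    n = sample_profile.n_exons
    for ref in reference_profiles:
        if ref.gene_id != sample_profile.gene_id or ref.n_exons != n:
            raise InputError(
                f"reference profile for {ref.gene_id} ({ref.n_exons} exons) does not "
                f"match sample profile for {sample_profile.gene_id} ({n} exons)")
    ref_mean = np.mean([ref.rpkm for ref in reference_profiles], axis=0)
    sample_rpkm = np.asarray(sample_profile.rpkm)
    fc = (sample_rpkm + pseudocount) / (ref_mean + pseudocount)
    sample_profile.fc = fc.tolist()
    sample_profile.log2_fc = np.log2(fc).tolist()
    sample_profile.zero_reference_exons = [
        i + 1 for i in range(n) if ref_mean[i] == 0 and sample_rpkm[i] > 0]
    if sample_profile.zero_reference_exons:
        log.info("%s: exons %s have zero reference RPKM; FC uses pseudocount %.3g",
                 sample_profile.gene_id, sample_profile.zero_reference_exons, pseudocount)
    return sample_profile


@dataclass
class DiscordanceSummary:
    mean_log2_fc_upstream: float | None
    mean_log2_fc_downstream: float | None
    difference: float | None  # downstream minus upstream


def breakpoint_discordance(profile: ExonExpressionProfile,
                           breakpoint_exon: int) -> DiscordanceSummary:
    """Mean log2 FC upstream (exons < breakpoint) vs downstream (>= breakpoint).

    The breakpoint exon belongs to the downstream block (the first exon
    retained from the 3' partner). A breakpoint at the first or last+1 exon
    leaves one block empty; that block's mean (and the difference) is None.
    """
    if profile.log2_fc is None:
        raise InputError("profile has no fold changes; run compute_fold_change first")
    if not (1 <= breakpoint_exon <= profile.n_exons):
        raise InputError(
            f"breakpoint exon {breakpoint_exon} outside 1..{profile.n_exons}")
    values = profile.log2_fc
    up = values[:breakpoint_exon - 1]
    down = values[breakpoint_exon - 1:]
    mean_up = float(np.mean(up)) if up else None
    mean_down = float(np.mean(down)) if down else None
    diff = mean_down - mean_up if (up and down) else None
    return DiscordanceSummary(mean_up, mean_down, diff)


def plot_profile(profile: ExonExpressionProfile, path: str,
                 breakpoint_exon: int | None = None) -> None:
    """Bar plot of per-exon log2 FC, with the fusion breakpoint marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if profile.log2_fc is None:
        raise InputError("profile has no fold changes to plot")
    fig, ax = plt.subplots(figsize=(max(4, profile.n_exons * 0.4), 3))
    exons = np.arange(1, profile.n_exons + 1)
    ax.bar(exons, profile.log2_fc, color="steelblue")
    if breakpoint_exon is not None:
        ax.axvline(breakpoint_exon - 0.5, color="firebrick", linestyle="--",
                   label="fusion breakpoint")
        ax.legend(frameon=False)
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_xlabel("exon")
    ax.set_ylabel("log2 FC")
    ax.set_title(f"{profile.gene_id} ({profile.sample})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
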