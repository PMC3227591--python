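"""Pipeline configuration.

All numeric thresholds used by the detection stages live here so that a run is
fully described by one object.  Defaults follow the published method: reads
partially covering 20-70% of their length, exon-boundary tolerance of 5 bp,
at least three unique gene-fusion candidate reads (SE), a 1 Mb minimum
intrachromosomal mate separation, at least three flanking pairs and a minimum
paired-end fusion score (PEFS) of 5 (PE), with PEFS = +2 per supporting pair,
-1 per duplicate read and -0.5 per mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Mapping

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # junction library / read geometry
    read_length_x: int = 50
    boundary_tolerance: int = 5

    # single-end (GFCR) stage
    partial_min_frac: float = 0.20
    partial_max_frac: float = 0.70
    max_partial_genes: int = 5
    min_unique_gfcr: int = 3

    # paired-end stage
    min_intra_distance: int = 1_000_000
    min_support_pairs: int = 3
    min_pefs: float = 5.0
    pair_reward: float = 2.0
    duplicate_penalty: float = 1.0
    mismatch_penalty: float = 0.5
    #: which alignment's mismatches feed PEFS: "genomic" or "transcript"
    mismatch_source: str = "genomic"

    # expression
    rpkm_pseudocount: float = 0.1

    # toy aligner surrogates
    max_mismatches: int = 2
    seed_len: int = 12
    local_match: int = 1
    local_mismatch: int = -1
    local_gap: int = -2
    local_min_score: int = 16
    exact_min_len: int = 8
    mapq_floor: int = 1
    #: allowed gap (bp) between the Group A and Group B blocks of a GFCR
    gap_tolerance: int = 0
    #: flag a candidate as repetitive when a supporting read has this many
    #: placements or more
    repeat_flag_hits: int = 5
    #: minimum shared alphabetic prefix for the same-gene-family flag
    family_prefix_len: int = 3

    def validate(self) -> "PipelineConfig":
        if not (0.0 < self.partial_min_frac < self.partial_max_frac < 1.0):
            raise ConfigError(
                "partial alignment fractions must satisfy "
                f"0 < min ({self.partial_min_frac}) < max ({self.partial_max_frac}) < 1"
            )
        for name in ("max_partial_genes", "min_unique_gfcr", "min_support_pairs",
                     "min_intra_distance", "read_length_x", "seed_len",
                     "exact_min_len"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("pair_reward", "duplicate_penalty", "mismatch_penalty",
                     "rpkm_pseudocount", "boundary_tolerance", "max_mismatches",
                     "gap_tolerance"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.read_length_x < 10:
            raise ConfigError(
                f"read_length_x must be >= 10 so junction arms are >= 5 bp, "
                f"got {self.read_length_x}"
            )
        if self.mismatch_source not in ("genomic", "transcript"):
            raise ConfigError(
                f"mismatch_source must be 'genomic' or 'transcript', got "
                f"{self.mismatch_source!r}"
            )
        return self

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(mapping)).validate()

    def replace(self, **overrides: Any) -> "PipelineConfig":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update({k: v for k, v in overrides.items() if v is not None})
        return type(self).from_mapping(values)

    def as_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
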