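"""Run manifests and candidate report writers."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .pe import FusionCandidate
from .se import SECandidate

PE_COLUMNS = ["gene5", "gene3", "P", "D", "M", "pefs", "n_spanning",
              "predicted_junction", "isoforms", "in_frame", "flags"]
SE_COLUMNS = ["gene5", "gene3", "unique_gfcr_count", "flags", "read_ids"]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, command: str, config: PipelineConfig | None,
                   inputs: Mapping[str, str | Path], counts: Mapping[str, int],
                   seed: int | None = None, extra: Mapping[str, Any] | None = None) -> dict:
    manifest = {
        "tool": "fusionscout",
        "version": __version__,
        "command": command,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seed": seed,
        "config": config.as_dict() if config is not None else None,
        "inputs": {name: {"path": str(p), "sha256": file_digest(p)}
                   for name, p in inputs.items()},
        "counts": dict(counts),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _fmt_junction(j: tuple[int, int] | None) -> str:
    return f"{j[0]}-{j[1]}" if j else "NA"


def pe_candidates_frame(candidates: Sequence[FusionCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "gene5": c.gene5, "gene3": c.gene3, "P": c.P, "D": c.D, "M": c.M,
            "pefs": c.pefs, "n_spanning": len(c.spanning_reads),
            "predicted_junction": _fmt_junction(c.predicted_junction),
            "isoforms": ";".join(_fmt_junction(i) for i in c.isoforms) or "NA",
            "in_frame": c.in_frame or "NA",
            "flags": ";".join(c.flags) or "-",
        })
    return pd.DataFrame(rows, columns=PE_COLUMNS)


def se_candidates_frame(candidates: Sequence[SECandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "gene5": c.gene5, "gene3": c.gene3,
            "unique_gfcr_count": c.n_unique_gfcr,
            "flags": ";".join(c.flags) or "-",
            "read_ids": ";".join(c.read_ids),
        })
    return pd.DataFrame(rows, columns=SE_COLUMNS)


def write_pe_detail(candidates: Sequence[FusionCandidate], path: str | Path) -> None:
    detail = []
    for c in candidates:
        detail.append({
            "gene5": c.gene5, "gene3": c.gene3, "P": c.P, "D": c.D, "M": c.M,
            "pefs": c.pefs, "in_frame": c.in_frame,
            "predicted_junction": list(c.predicted_junction) if c.predicted_junction else None,
            "isoforms": [list(i) for i in c.isoforms],
            "support_pairs": [
                {"pair_id": s.pair.pair_id, "category": s.pair.category,
                 "duplicate": s.duplicate,
                 "mate1": asdict(s.pair.mate1), "mate2": asdict(s.pair.mate2)}
                for s in c.support_pairs],
            "spanning_reads": [asdict(s) for s in c.spanning_reads],
            "flags": c.flags,
        })
    with open(path, "w") as fh:
        json.dump(detail, fh, indent=2)
        fh.write("\n")
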