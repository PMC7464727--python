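"""Pipeline configuration: input paths plus every tunable threshold.

The config can be built in code or loaded from a flat YAML key-value file
(see :func:`load_config`); unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # inputs
    chimeric_junctions: Optional[str] = None
    chimeric_sam: Optional[str] = None
    exons_gtf: Optional[str] = None  # list 1: reference annotation
    exons_lnc_bed: Optional[str] = None  # list 2: lncRNA exons
    exons_novel_bed: Optional[str] = None  # list 3: candidate novel exons
    genome_fasta: Optional[str] = None
    sj_file: Optional[str] = None
    # chromosome selection; empty = keep all
    chromosomes: list[str] = field(default_factory=list)
    # CCR selection
    min_segment: int = 15
    offset_acceptor: int = 1
    offset_donor: int = -1
    # LAC threshold
    min_ccr: int = 5
    min_distinct: int = 4
    # exonic labelling
    max_rounds: int = 20
    min_promote_support: int = 0
    # non-canonical classification
    min_tail: int = 1
    branch_window: int = 0
    min_subexonic_size: int = 55
    confident_subexonic_size: int = 70
    # junction refinement
    max_shift: int = 5
    junction_k: int = 15
    mismatch_tol: int = 2
    mismatch_window: int = 5

    @property
    def offsets(self) -> tuple[int, int]:
        return (self.offset_acceptor, self.offset_donor)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat YAML key-value file into a :class:`PipelineConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
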