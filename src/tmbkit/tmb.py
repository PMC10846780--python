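"""TMB scoring: somatic count over exome target size.

TMB = (number of filtered true somatic mutations) / (capture size in Mb),
in mutations per megabase.  SNVs and small indels count equally.  The target
size is a required configuration value — the shipped default of 30.0 Mb is a
conventional human whole-exome capture scale, and any laboratory must set its
own panel's size to get comparable scores.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .model import SampleCallset, write_tsv_table

__all__ = ["DEFAULT_TARGET_SIZE_MB", "TMBResult", "compute_tmb", "tmb_for_sample", "write_tmb_tsv"]

DEFAULT_TARGET_SIZE_MB = 30.0

Workflow = Literal["tumor_only", "tumor_normal"]


@dataclass(frozen=True)
class TMBResult:
    """Per-sample TMB outcome; ``tmb == somatic_count / target_size_mb``."""

    sample_id: str
    somatic_count: int
    target_size_mb: float
    tmb: float
    workflow: Workflow


def compute_tmb(somatic_count: int, target_size_mb: float) -> float:
    """Mutations per megabase: ``somatic_count / target_size_mb``."""
    if somatic_count < 0:
        raise ValueError(f"somatic_count must be >= 0, got {somatic_count}")
    if target_size_mb <= 0:
        raise ValueError(f"target_size_mb must be > 0, got {target_size_mb}")
    return somatic_count / target_size_mb


def tmb_for_sample(
    cs: SampleCallset,
    target_size_mb: float,
    workflow: Workflow,
) -> TMBResult:
    """Score an already-filtered somatic callset."""
    if workflow not in ("tumor_only", "tumor_normal"):
        raise ValueError(f"unknown workflow {workflow!r}")
    count = len(cs.records)
    return TMBResult(
        sample_id=cs.sample_id,
        somatic_count=count,
        target_size_mb=target_size_mb,
        tmb=compute_tmb(count, target_size_mb),
        workflow=workflow,
    )


def write_tmb_tsv(
    results: Sequence[TMBResult],
    path: str | os.PathLike,
    cancer_types: dict[str, str] | None = None,
    qc_passed: dict[str, bool] | None = None,
    comment: str | None = None,
) -> None:
    """Per-sample TMB table: sample_id, cancer_type, workflow, somatic_count,
    target_size_mb, tmb, qc_passed."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "cancer_type": (cancer_types or {}).get(r.sample_id),
                "workflow": r.workflow,
                "somatic_count": r.somatic_count,
                "target_size_mb": r.target_size_mb,
                "tmb": r.tmb,
                "qc_passed": (qc_passed or {}).get(r.sample_id, True),
            }
        )
    write_tsv_table(pd.DataFrame(rows), path, comment=comment)
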