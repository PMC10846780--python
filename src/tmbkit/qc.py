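"""Sequencing-QC scoring and cohort gating.

Each sample is scored on four post-alignment metrics — mean target coverage,
uniformity of coverage, percent duplicate aligned reads, and base
enrichment — with equal weight: 0, 1 or 2 points per metric, cumulative
score 0-8.  Samples are categorized good (6-8), intermediate (3-5) or
poor (0-2); a cumulative score >= 3 passes the sample into the cohort.

The numeric cut-points separating the 0/1/2 bands are configurable through
:class:`QCThresholds`.  The shipped defaults are conventional exome-QC
operating points; a laboratory with its own validated bands substitutes them
via the pipeline config.  Boundary values always earn the HIGHER score.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .model import read_tsv_table, write_tsv_table

__all__ = [
    "QCMetrics",
    "MetricBands",
    "QCThresholds",
    "QCScore",
    "score_metric",
    "score_sample",
    "gate_cohort",
    "read_metrics_tsv",
    "write_qc_report",
]

METRIC_NAMES = (
    "mean_target_coverage",
    "uniformity",
    "pct_duplicates",
    "base_enrichment",
)


@dataclass(frozen=True)
class QCMetrics:
    """Four per-sample sequencing metrics.

    mean_target_coverage in x (>= 0); uniformity, pct_duplicates and
    base_enrichment are percentages in [0, 100].
    """

    mean_target_coverage: float
    uniformity: float
    pct_duplicates: float
    base_enrichment: float

    def __post_init__(self) -> None:
        if self.mean_target_coverage < 0:
            raise ValueError(
                f"mean_target_coverage must be >= 0, got {self.mean_target_coverage}"
            )
        for name in ("uniformity", "pct_duplicates", "base_enrichment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class MetricBands:
    """Two cut-points splitting one metric's range into 0/1/2 score bands.

    For a higher-is-better metric, values >= ``cut_best`` score 2 and values
    >= ``cut_mid`` score 1.  For lower-is-better the comparisons flip to <=.
    Boundary values take the higher score.
    """

    cut_mid: float
    cut_best: float
    higher_is_better: bool = True
    valid_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.higher_is_better:
            if not self.cut_mid <= self.cut_best:
                raise ValueError("higher-is-better bands require cut_mid <= cut_best")
        else:
            if not self.cut_best <= self.cut_mid:
                raise ValueError("lower-is-better bands require cut_best <= cut_mid")


@dataclass(frozen=True)
class QCThresholds:
    """Per-metric score bands; defaults are conventional exome operating
    points, fully overridable via the pipeline config."""

    mean_target_coverage: MetricBands = field(
        default_factory=lambda: MetricBands(100.0, 150.0, True, (0.0, float("inf")))
    )
    uniformity: MetricBands = field(
        default_factory=lambda: MetricBands(80.0, 90.0, True, (0.0, 100.0))
    )
    pct_duplicates: MetricBands = field(
        default_factory=lambda: MetricBands(40.0, 20.0, False, (0.0, 100.0))
    )
    base_enrichment: MetricBands = field(
        default_factory=lambda: MetricBands(60.0, 80.0, True, (0.0, 100.0))
    )


@dataclass(frozen=True)
class QCScore:
    """Per-metric scores, cumulative 0-8, category and pass flag."""

    per_metric: tuple[int, int, int, int]
    cumulative: int
    category: Literal["good", "intermediate", "poor"]
    passed: bool

    @classmethod
    def from_per_metric(cls, per_metric: Sequence[int]) -> "QCScore":
        per = tuple(int(s) for s in per_metric)
        if len(per) != 4 or any(s not in (0, 1, 2) for s in per):
            raise ValueError(f"per_metric must be four scores in {{0,1,2}}, got {per}")
        cum = sum(per)
        category = "good" if cum >= 6 else "intermediate" if cum >= 3 else "poor"
        return cls(per_metric=per, cumulative=cum, category=category, passed=cum >= 3)


def score_metric(value: float, bands: MetricBands) -> int:
    """Score one metric value 0, 1 or 2 against its bands.

    Piecewise-constant and monotone in the metric's quality direction;
    boundary values belong to the higher-score band.
    """
    lo, hi = bands.valid_range
    if not lo <= value <= hi:
        raise ValueError(f"metric value {value} outside valid range [{lo}, {hi}]")
    if bands.higher_is_better:
        if value >= bands.cut_best:
            return 2
        if value >= bands.cut_mid:
            return 1
        return 0
    if value <= bands.cut_best:
        return 2
    if value <= bands.cut_mid:
        return 1
    return 0


def score_sample(m: QCMetrics, t: QCThresholds | None = None) -> QCScore:
    """Score all four metrics and aggregate into a :class:`QCScore`."""
    t = t or QCThresholds()
    per = tuple(
        score_metric(getattr(m, name), getattr(t, name)) for name in METRIC_NAMES
    )
    return QCScore.from_per_metric(per)


def gate_cohort(
    scores: Sequence[tuple[str, QCScore]],
) -> tuple[list[str], list[str]]:
    """Partition sample ids into (passed, failed) by the >= 3 rule,
    preserving order.  Duplicate sample ids are a hard error."""
    seen: set[str] = set()
    passed: list[str] = []
    failed: list[str] = []
    for sample_id, score in scores:
        if sample_id in seen:
            raise ValueError(f"duplicate sample_id {sample_id!r}")
        seen.add(sample_id)
        (passed if score.passed else failed).append(sample_id)
    return passed, failed


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_metrics_tsv(path: str | os.PathLike) -> list[tuple[str, QCMetrics]]:
    df = read_tsv_table(path)
    out = []
    for r in df.itertuples():
        out.append(
            (
                str(r.sample_id),
                QCMetrics(
                    mean_target_coverage=float(r.mean_target_coverage),
                    uniformity=float(r.uniformity),
                    pct_duplicates=float(r.pct_duplicates),
                    base_enrichment=float(r.base_enrichment),
                ),
            )
        )
    return out


def write_qc_report(
    samples: Sequence[tuple[str, QCMetrics, QCScore]],
    path: str | os.PathLike,
    comment: str | None = None,
) -> None:
    rows = []
    for sample_id, m, s in samples:
        row: dict[str, object] = {"sample_id": sample_id}
        for name in METRIC_NAMES:
            row[name] = getattr(m, name)
        for name, sc in zip(METRIC_NAMES, s.per_metric):
            row[f"score_{name}"] = sc
        row.update(cumulative=s.cumulative, category=s.category, passed=s.passed)
        rows.append(row)
    write_tsv_table(pd.DataFrame(rows), path, comment=comment)
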