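"""Cohort-level TMB statistics.

Covers the descriptive and comparative layer applied after per-sample TMB
scoring: percentile distributions (a single linear-interpolation definition
shared by every consumer, including medians), the bootstrap "phantom cohort"
estimate of the ninth decile (resample the cohort with replacement, take the
90th percentile, average over iterations), per-cancer summaries, two-cohort
Kruskal-Wallis comparisons restricted to cancer types with adequate n, and
the tumor-only vs matched-normal correlation used to validate the
tumor-only workflow.

Cohort tables are plain :class:`pandas.DataFrame` objects with columns
``sample_id``, ``cancer_type``, ``tmb`` and (optionally) ``qc_passed``;
:func:`validate_cohort_table` enforces the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootstrapResult",
    "CohortComparison",
    "validate_cohort_table",
    "percentile",
    "percentile_table",
    "bootstrap_decile",
    "per_cancer_summary",
    "compare_cohorts",
    "correlation_validation",
]

DEFAULT_PERCENTILE_GRID = tuple(range(5, 100, 5))


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample TMB table contract; returns the frame."""
    for col in ("sample_id", "cancer_type", "tmb"):
        if col not in df.columns:
            raise ValueError(f"cohort table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dups[:5]}")
    if (df["tmb"] < 0).any():
        raise ValueError("tmb values must be >= 0")
    return df


def percentile(scores: Sequence[float], level: float) -> float:
    """Percentile by linear interpolation between order statistics
    (Hyndman-Fan type 7).  Level 0 is the minimum, 100 the maximum."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of an empty score list is undefined")
    if not 0.0 <= level <= 100.0:
        raise ValueError(f"level must be in [0, 100], got {level}")
    return float(np.percentile(arr, level, method="linear"))


def percentile_table(
    cohorts: dict[str, pd.DataFrame],
    levels: Sequence[float] = DEFAULT_PERCENTILE_GRID,
    by_cancer: bool = True,
) -> pd.DataFrame:
    """TMB value at each percentile level, per cohort and (optionally) per
    cancer type; the pan-cancer series is labelled ``all``."""
    rows = []
    for cohort_name, df in cohorts.items():
        validate_cohort_table(df)
        groups: list[tuple[str, np.ndarray]] = [
            ("all", df["tmb"].to_numpy(dtype=float))
        ]
        if by_cancer:
            for ct, sub in df.groupby("cancer_type", sort=True):
                groups.append((str(ct), sub["tmb"].to_numpy(dtype=float)))
        for label, vals in groups:
            for lv in levels:
                rows.append(
                    {
                        "cohort": cohort_name,
                        "cancer_type": label,
                        "level": float(lv),
                        "tmb": percentile(vals, float(lv)),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapResult:
    """Phantom-cohort bootstrap of one percentile level."""

    n_iterations: int
    percentile_level: float
    per_iteration_values: tuple[float, ...]
    mean_value: float
    seed: int | None

    @property
    def monte_carlo_se(self) -> float:
        """Spread of the bootstrap percentile distribution — the Monte-Carlo
        uncertainty of a single resampled-cohort percentile."""
        return float(np.std(self.per_iteration_values, ddof=1))


def bootstrap_decile(
    scores: Sequence[float],
    n_iterations: int = 1000,
    level: float = 90.0,
    seed: int | np.random.Generator | None = None,
) -> BootstrapResult:
    """Resample the cohort with replacement ``n_iterations`` times, take the
    ``level`` percentile of each phantom cohort, and average.

    Defaults are the reference procedure: 1,000 iterations at the
    ninth decile (90th percentile).  Fully reproducible given ``seed``.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("bootstrap of an empty score list is undefined")
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed
    idx = rng.integers(0, arr.size, size=(n_iterations, arr.size))
    values = np.percentile(arr[idx], level, axis=1, method="linear")
    return BootstrapResult(
        n_iterations=n_iterations,
        percentile_level=level,
        per_iteration_values=tuple(float(v) for v in values),
        mean_value=float(values.mean()),
        seed=seed_out,
    )


def per_cancer_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per cancer type: n, min, max and median TMB (median is the
    shared percentile definition at level 50)."""
    validate_cohort_table(cohort)
    rows = []
    for ct, sub in cohort.groupby("cancer_type", sort=True):
        vals = sub["tmb"].to_numpy(dtype=float)
        rows.append(
            {
                "cancer_type": ct,
                "n": int(vals.size),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "median": percentile(vals, 50.0),
            }
        )
    return pd.DataFrame(rows, columns=["cancer_type", "n", "min", "max", "median"])


@dataclass(frozen=True)
class CohortComparison:
    """Per-cancer two-group Kruskal-Wallis comparison between cohorts.

    ``table`` columns: cancer_type, n_a, n_b, median_a, median_b,
    kw_h, p_value.  p-values are raw (unadjusted for multiple testing).
    """

    table: pd.DataFrame
    min_n: int

    def __post_init__(self) -> None:
        if not self.table.empty:
            if (self.table["kw_h"] < -1e-12).any():
                raise ValueError("Kruskal-Wallis H must be non-negative")
            p = self.table["p_value"]
            if ((p < 0) | (p > 1)).any():
                raise ValueError("p-values must lie in [0, 1]")


def compare_cohorts(
    a: pd.DataFrame, b: pd.DataFrame, min_n: int = 30
) -> CohortComparison:
    """Kruskal-Wallis (tie-corrected, asymptotic chi-square) per cancer type,
    restricted to types with at least ``min_n`` samples in BOTH cohorts."""
    validate_cohort_table(a)
    validate_cohort_table(b)
    rows = []
    types = sorted(set(a["cancer_type"]) & set(b["cancer_type"]))
    for ct in types:
        va = a.loc[a["cancer_type"] == ct, "tmb"].to_numpy(dtype=float)
        vb = b.loc[b["cancer_type"] == ct, "tmb"].to_numpy(dtype=float)
        if va.size < min_n or vb.size < min_n:
            continue
        if np.all(va == va[0]) and np.all(vb == vb[0]) and va[0] == vb[0]:
            h, p = 0.0, 1.0  # all observations tied; no separation by construction
        else:
            h, p = stats.kruskal(va, vb)
        rows.append(
            {
                "cancer_type": ct,
                "n_a": int(va.size),
                "n_b": int(vb.size),
                "median_a": percentile(va, 50.0),
                "median_b": percentile(vb, 50.0),
                "kw_h": max(float(h), 0.0),
                "p_value": float(p),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cancer_type", "n_a", "n_b", "median_a", "median_b", "kw_h", "p_value"],
    )
    return CohortComparison(table=table, min_n=min_n)


def correlation_validation(
    paired: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Pearson r (and r^2) between tumor-only and tumor-normal TMB estimates
    over matched pairs.  Requires >= 3 pairs and non-zero variance in both
    coordinates."""
    if len(paired) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(paired)}")
    x = np.asarray([p[0] for p in paired], dtype=float)
    y = np.asarray([p[1] for p in paired], dtype=float)
    for name, v in (("tumor_only", x), ("tumor_normal", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in the {name} coordinate")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r
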