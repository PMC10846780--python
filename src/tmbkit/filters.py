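"""Somatic-variant filtration for tumor-only and matched tumor-normal samples.

The tumor-only route is a four-step sequence:

* **Stage 1** keeps high-confidence coding variants: quality >= 10, depth
  >= 30x, synonymous (and non-coding) calls removed.
* **Level 1** (tolerant, population frequency) removes polymorphisms seen at
  > 1% allele frequency in any annotated population database.
* **Level 2** (stringent, VAF) removes the germline VAF signature: calls with
  VAF <= 0.05 (noise and contamination) and calls inside the heterozygous band
  0.5 +/- 0.05.  An optional high-VAF cut for germline homozygotes is off by
  default.
* **Level 3** (baseline) removes any variant whose normalized key occurs in a
  panel of healthy-donor germline calls.

The matched tumor-normal route applies the same Stage-1 thresholds to the
tumor and then subtracts every variant present in the matched normal; it is
the validation oracle the tumor-only route is benchmarked against.

Levels 1-3 are per-record predicates, so their application order cannot
change the resulting set; the sequential order is preserved only so the
:class:`FilterTrace` audit counts match the workflow description.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import (
    SampleCallset,
    VariantKey,
    VariantRecord,
    read_tsv_table,
    variant_key,
    write_tsv_table,
)

__all__ = [
    "FilterConfig",
    "BaselinePanel",
    "FilterTrace",
    "stage1_filter",
    "level1_population_filter",
    "level2_vaf_filter",
    "level3_baseline_filter",
    "tumor_only_somatic",
    "matched_subtraction",
]


@dataclass(frozen=True)
class FilterConfig:
    """All Stage-1 / Stage-2 thresholds in one place.

    Defaults are the workflow's reference operating point: quality >= 10, depth >= 30x,
    population AF > 1% removed, VAF <= 0.05 removed, heterozygous band
    [0.45, 0.55] removed.  ``hom_vaf_cut`` enables an additional high-VAF
    germline-homozygous removal (e.g. 0.95) and is disabled by default.
    """

    min_qual: float = 10.0
    min_depth: int = 30
    max_pop_af: float = 0.01
    low_vaf_cut: float = 0.05
    germ_het_band: tuple[float, float] = (0.45, 0.55)
    hom_vaf_cut: Optional[float] = None
    drop_synonymous: bool = True
    drop_noncoding: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.germ_het_band
        if not 0.0 <= self.low_vaf_cut < lo < hi <= 1.0:
            raise ValueError(
                "require 0 <= low_vaf_cut < germ_het_band lower < upper <= 1, "
                f"got low_vaf_cut={self.low_vaf_cut}, band={self.germ_het_band}"
            )
        if self.min_depth < 0:
            raise ValueError(f"min_depth must be >= 0, got {self.min_depth}")
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValueError(f"max_pop_af must be in [0, 1], got {self.max_pop_af}")
        if self.hom_vaf_cut is not None and not hi < self.hom_vaf_cut <= 1.0:
            raise ValueError(
                f"hom_vaf_cut must lie in ({hi}, 1], got {self.hom_vaf_cut}"
            )


@dataclass
class BaselinePanel:
    """Pooled germline variant keys from healthy-donor exomes."""

    keys: frozenset[VariantKey]
    n_donors: int

    def __post_init__(self) -> None:
        self.keys = frozenset(self.keys)
        if self.n_donors < 1:
            raise ValueError(f"n_donors must be >= 1, got {self.n_donors}")

    def __len__(self) -> int:
        return len(self.keys)

    def write_tsv(self, path: str | os.PathLike) -> None:
        rows = sorted(
            ({"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt}
             for k in self.keys),
            key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]),
        )
        write_tsv_table(
            pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]),
            path,
            comment=f"baseline panel\tn_donors={self.n_donors}",
        )

    @classmethod
    def read_tsv(cls, path: str | os.PathLike, n_donors: int = 1) -> "BaselinePanel":
        header = Path(path).read_text(encoding="utf-8").splitlines()
        for line in header:
            if line.startswith("#") and "n_donors=" in line:
                n_donors = int(line.rsplit("n_donors=", 1)[1].strip())
            if not line.startswith("#"):
                break
        df = read_tsv_table(path)
        keys = frozenset(
            VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples()
        )
        return cls(keys=keys, n_donors=n_donors)


@dataclass(frozen=True)
class FilterTrace:
    """Record counts surviving each step, in workflow order."""

    input: int
    stage1: int
    level1: int
    level2: int
    level3: int

    def __post_init__(self) -> None:
        seq = (self.input, self.stage1, self.level1, self.level2, self.level3)
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"trace counts must be non-increasing, got {seq}")


# ---------------------------------------------------------------------------
# Per-record retain-predicates
# ---------------------------------------------------------------------------

def passes_stage1(r: VariantRecord, cfg: FilterConfig) -> bool:
    if r.qual < cfg.min_qual or r.depth < cfg.min_depth:
        return False
    if cfg.drop_synonymous and r.consequence == "coding_synonymous":
        return False
    if cfg.drop_noncoding and r.consequence == "noncoding":
        return False
    return True


def passes_level1(r: VariantRecord, cfg: FilterConfig) -> bool:
    for label, af in r.pop_afs.items():
        if not 0.0 <= af <= 1.0:
            raise ValueError(
                f"population AF out of [0, 1]: {label}={af} at {r.chrom}:{r.pos}"
            )
        if af > cfg.max_pop_af:
            return False
    return True


def passes_level2(r: VariantRecord, cfg: FilterConfig) -> bool:
    if r.vaf <= cfg.low_vaf_cut:
        return False
    lo, hi = cfg.germ_het_band
    if lo <= r.vaf <= hi:
        return False
    if cfg.hom_vaf_cut is not None and r.vaf >= cfg.hom_vaf_cut:
        return False
    return True


def passes_level3(r: VariantRecord, panel: BaselinePanel) -> bool:
    return variant_key(r) not in panel.keys


# ---------------------------------------------------------------------------
# Filters (each returns a subset callset, order preserved)
# ---------------------------------------------------------------------------

def stage1_filter(cs: SampleCallset, cfg: FilterConfig) -> SampleCallset:
    """Keep high-quality coding non-synonymous calls (quality/depth gates)."""
    return cs.replace_records(r for r in cs.records if passes_stage1(r, cfg))


def level1_population_filter(cs: SampleCallset, cfg: FilterConfig) -> SampleCallset:
    """Remove common polymorphisms: AF > ``max_pop_af`` in ANY annotated
    database.  Records with no AF annotations are retained."""
    return cs.replace_records(r for r in cs.records if passes_level1(r, cfg))


def level2_vaf_filter(cs: SampleCallset, cfg: FilterConfig) -> SampleCallset:
    """Remove the germline/noise VAF signature (low-VAF and het band)."""
    return cs.replace_records(r for r in cs.records if passes_level2(r, cfg))


def level3_baseline_filter(cs: SampleCallset, panel: BaselinePanel) -> SampleCallset:
    """Remove variants whose normalized key occurs in the baseline panel."""
    if len(panel) == 0:
        raise ValueError("baseline panel is empty")
    return cs.replace_records(r for r in cs.records if passes_level3(r, panel))


def tumor_only_somatic(
    cs: SampleCallset, panel: BaselinePanel, cfg: FilterConfig
) -> tuple[SampleCallset, FilterTrace]:
    """Full tumor-only route: stage 1 then germline levels 1-3, with an
    audit trail of surviving counts."""
    if cs.source != "tumor":
        raise ValueError(f"tumor_only_somatic requires a tumor callset, got {cs.source!r}")
    s1 = stage1_filter(cs, cfg)
    l1 = level1_population_filter(s1, cfg)
    l2 = level2_vaf_filter(l1, cfg)
    l3 = level3_baseline_filter(l2, panel)
    trace = FilterTrace(
        input=len(cs), stage1=len(s1), level1=len(l1), level2=len(l2), level3=len(l3)
    )
    return l3, trace


def matched_subtraction(
    tumor: SampleCallset, normal: SampleCallset, cfg: FilterConfig
) -> SampleCallset:
    """Matched tumor-normal route: stage-1 filter the tumor with the same
    thresholds, then subtract every variant key present in the normal."""
    if tumor.source != "tumor":
        raise ValueError(f"expected tumor callset, got {tumor.source!r}")
    if normal.source != "normal":
        raise ValueError(f"expected normal callset, got {normal.source!r}")
    s1 = stage1_filter(tumor, cfg)
    normal_keys = normal.keys()
    return s1.replace_records(
        r for r in s1.records if variant_key(r) not in normal_keys
    )
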