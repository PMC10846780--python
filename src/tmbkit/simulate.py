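"""Synthetic matched tumor/normal exome callsets with known ground truth.

The generator emulates the statistical structure the germline filters rely
on, at the level of called variants (no read-level simulation):

* **Germline variants** are drawn from a shared population pool so the same
  sites recur across patients and healthy donors (the premise of the baseline
  panel).  Heterozygous calls get VAF ~ Normal(0.5, ``het_vaf_sd``) truncated
  to [0, 1], drawn independently in tumor and normal; homozygous calls get
  VAF ~ Uniform(0.95, 1.0).  A ``frac_common`` share of pool sites carries a
  population AF above 1% (log-uniform in (0.01, 0.5]); the rest are rare
  (log-uniform AF in (1e-5, 0.01], a share with no AF annotation at all).
* **Somatic variants** appear only in the tumor, at VAF = purity x clonal
  fraction (Beta(2, 2)).  By default every somatic VAF is nudged into the
  filter-recoverable bands (0.05, 0.45) u (0.55, 0.95); lowering
  ``recoverable_frac`` leaves a share at its raw VAF so tests can measure
  what the stringent VAF filter costs.
* **Noise calls** (sequencing/FFPE artifacts) appear in the tumor only, at
  VAF <= 0.05.
* Depth ~ Poisson(``depth_mean``) floored at 1; quality >= 10 except for a
  ``qual_low_frac`` share; consequence is coding non-synonymous with a
  configurable synonymous/non-coding admixture.

All randomness flows from one integer seed through ``numpy`` seed sequences
with fixed stream tags, so per-sample generation is order-independent and a
cohort and a baseline panel built from the same seed share one germline pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .filters import BaselinePanel
from .model import SampleCallset, VariantKey, VariantRecord, normalize_allele
from .qc import METRIC_NAMES, MetricBands, QCMetrics, QCThresholds, score_sample

__all__ = [
    "SimParams",
    "SampleTruth",
    "GermlineSite",
    "GermlinePool",
    "generate_matched_pair",
    "generate_cohort",
    "generate_baseline_panel",
    "generate_qc_metrics",
    "DEFAULT_POOL_SIZE",
]

DEFAULT_POOL_SIZE = 9000
_CHROMS = tuple(f"chr{i}" for i in range(1, 23))
_BASES = ("A", "C", "G", "T")

# stream tags: one seed fans out into independent, purpose-bound streams
_TAG_POOL = 101
_TAG_SAMPLE = 202
_TAG_DONORS = 303
_TAG_QC = 404


@dataclass(frozen=True)
class SimParams:
    """Per-sample generator settings.

    ``true_tmb`` is the ground-truth somatic density in mutations per
    megabase; the generated somatic count is ``round(true_tmb x
    target_size_mb)``.  Defaults describe a 30 Mb exome sequenced to a mean
    depth of 200x with a realistic germline load (3,000 heterozygous + 1,500
    homozygous coding non-synonymous calls, 70% of them common
    polymorphisms), 150 low-VAF artifact calls and a 2% share of
    low-quality records.
    """

    true_tmb: float = 10.0
    target_size_mb: float = 30.0
    purity: float = 0.5
    n_germline_het: int = 3000
    n_germline_hom: int = 1500
    frac_common: float = 0.7
    het_vaf_sd: float = 0.03
    n_noise: int = 150
    depth_mean: float = 200.0
    qual_low_frac: float = 0.02
    recoverable_frac: float = 1.0
    syn_frac: float = 0.0
    noncoding_frac: float = 0.0
    indel_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_tmb < 0:
            raise ValueError(f"true_tmb must be >= 0, got {self.true_tmb}")
        if self.target_size_mb <= 0:
            raise ValueError(f"target_size_mb must be > 0, got {self.target_size_mb}")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        for name in ("n_germline_het", "n_germline_hom", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_common", "qual_low_frac", "recoverable_frac",
                     "syn_frac", "noncoding_frac", "indel_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.syn_frac + self.noncoding_frac > 1.0:
            raise ValueError("syn_frac + noncoding_frac must be <= 1")
        if self.het_vaf_sd < 0 or self.depth_mean <= 0:
            raise ValueError("het_vaf_sd must be >= 0 and depth_mean > 0")

    @property
    def n_somatic(self) -> int:
        return int(round(self.true_tmb * self.target_size_mb))


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    true_somatic_keys: frozenset[VariantKey]
    true_tmb: float


@dataclass(frozen=True)
class GermlineSite:
    key: VariantKey
    af_label: Optional[str]  # 'global' | 'south_asian' | None
    af: Optional[float]
    is_common: bool


@dataclass(frozen=True)
class GermlinePool:
    """Shared population pool of germline sites.

    Patients and healthy donors draw their germline variants from the same
    pool, which is what makes a donor-derived baseline panel informative
    about patient germline calls.
    """

    sites: tuple[GermlineSite, ...]

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def keys(self) -> frozenset[VariantKey]:
        return frozenset(s.key for s in self.sites)

    @property
    def rare_keys(self) -> frozenset[VariantKey]:
        return frozenset(s.key for s in self.sites if not s.is_common)

    def to_panel(self, n_donors: int = 1) -> BaselinePanel:
        """Baseline panel covering every pool site (exhaustive donor pool)."""
        return BaselinePanel(keys=self.keys, n_donors=n_donors)

    @classmethod
    def generate(
        cls, size: int, frac_common: float, rng: np.random.Generator,
        indel_frac: float = 0.1,
    ) -> "GermlinePool":
        keys = _draw_keys(rng, size, set(), indel_frac)
        n_common = int(round(frac_common * size))
        is_common = np.zeros(size, dtype=bool)
        is_common[rng.choice(size, n_common, replace=False)] = True
        sites = []
        for i, key in enumerate(keys):
            if is_common[i]:
                af = float(np.exp(rng.uniform(np.log(0.01), np.log(0.5))))
                af = min(max(af, 0.010001), 0.5)
                label = "global" if rng.random() < 0.5 else "south_asian"
            elif rng.random() < 0.3:
                af, label = None, None  # never observed in any database
            else:
                af = float(np.exp(rng.uniform(np.log(1e-5), np.log(0.01))))
                af = min(af, 0.01)
                label = "global" if rng.random() < 0.5 else "south_asian"
            sites.append(GermlineSite(key=key, af_label=label, af=af, is_common=bool(is_common[i])))
        return cls(sites=tuple(sites))


def _draw_keys(
    rng: np.random.Generator,
    n: int,
    used_positions: set[tuple[str, int]],
    indel_frac: float,
) -> list[VariantKey]:
    """Draw n variant keys at distinct (chrom, pos) not colliding with
    ``used_positions`` (which is updated in place)."""
    keys: list[VariantKey] = []
    while len(keys) < n:
        m = n - len(keys)
        chrom_idx = rng.integers(0, len(_CHROMS), size=m)
        pos = rng.integers(1, 120_000_000, size=m)
        for ci, p in zip(chrom_idx, pos):
            site = (_CHROMS[ci], int(p))
            if site in used_positions:
                continue
            used_positions.add(site)
            ref_b = _BASES[rng.integers(0, 4)]
            if rng.random() < indel_frac:
                tail = "".join(_BASES[j] for j in rng.integers(0, 4, size=int(rng.integers(1, 4))))
                if rng.random() < 0.5:
                    ref, alt = ref_b, ref_b + tail          # insertion
                else:
                    ref, alt = ref_b + tail, ref_b          # deletion
            else:
                alt_choices = [b for b in _BASES if b != ref_b]
                ref, alt = ref_b, alt_choices[rng.integers(0, 3)]
            keys.append(normalize_allele(site[0], site[1], ref, alt))
    return keys


def _depths(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    return np.maximum(rng.poisson(mean, size=n), 1)


def _quals(rng: np.random.Generator, n: int, low_frac: float) -> np.ndarray:
    q = rng.uniform(20.0, 99.0, size=n)
    low = rng.random(n) < low_frac
    q[low] = rng.uniform(0.0, 9.99, size=int(low.sum()))
    return q


def _consequences(rng: np.random.Generator, n: int, p: SimParams) -> list[str]:
    u = rng.random(n)
    out = []
    for v in u:
        if v < p.syn_frac:
            out.append("coding_synonymous")
        elif v < p.syn_frac + p.noncoding_frac:
            out.append("noncoding")
        else:
            out.append("coding_nonsynonymous")
    return out


def _recoverable_vaf(v: float, rng: np.random.Generator) -> float:
    """Nudge a raw somatic VAF into (0.05, 0.45) u (0.55, 0.95)."""
    if v <= 0.05:
        return float(rng.uniform(0.055, 0.10))
    if 0.45 <= v <= 0.55:
        return float(rng.uniform(0.56, 0.60)) if v > 0.5 else float(rng.uniform(0.40, 0.449))
    if v >= 0.95:
        return float(rng.uniform(0.90, 0.945))
    return v


def generate_matched_pair(
    params: SimParams,
    pool: GermlinePool | None = None,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
) -> tuple[SampleCallset, SampleCallset, SampleTruth]:
    """Generate one matched tumor/normal callset pair plus its ground truth.

    Germline variants appear in both callsets (with independently drawn
    VAF/depth/quality); somatic and noise variants appear only in the tumor.
    Deterministic given ``params.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, _TAG_SAMPLE]))
    n_germ = params.n_germline_het + params.n_germline_hom
    if pool is None:
        pool_rng = np.random.default_rng(np.random.SeedSequence([params.seed, _TAG_POOL]))
        pool = GermlinePool.generate(
            max(DEFAULT_POOL_SIZE, 2 * n_germ), params.frac_common, pool_rng,
            params.indel_frac,
        )
    if n_germ > len(pool):
        raise ValueError(
            f"germline pool of {len(pool)} sites cannot supply {n_germ} variants"
        )

    germ_idx = rng.choice(len(pool), size=n_germ, replace=False) if n_germ else np.array([], dtype=int)
    germ_sites = [pool.sites[i] for i in germ_idx]
    zygosity = ["het"] * params.n_germline_het + ["hom"] * params.n_germline_hom

    used_positions = {(s.key.chrom, s.key.pos) for s in pool.sites}
    n_som = params.n_somatic
    som_keys = _draw_keys(rng, n_som, used_positions, params.indel_frac)
    noise_keys = _draw_keys(rng, params.n_noise, used_positions, params.indel_frac)

    def germline_records(n_records_rng: np.random.Generator) -> list[VariantRecord]:
        depths = _depths(n_records_rng, n_germ, params.depth_mean)
        quals = _quals(n_records_rng, n_germ, params.qual_low_frac)
        csqs = _consequences(n_records_rng, n_germ, params)
        recs = []
        for i, site in enumerate(germ_sites):
            if zygosity[i] == "het":
                vaf = float(np.clip(n_records_rng.normal(0.5, params.het_vaf_sd), 0.0, 1.0))
            else:
                vaf = float(n_records_rng.uniform(0.95, 1.0))
            pop_afs = {site.af_label: site.af} if site.af_label is not None else {}
            recs.append(
                VariantRecord(
                    chrom=site.key.chrom, pos=site.key.pos,
                    ref=site.key.ref, alt=site.key.alt,
                    qual=float(quals[i]), depth=int(depths[i]), vaf=vaf,
                    consequence=csqs[i], pop_afs=pop_afs,
                )
            )
        return recs

    tumor_records = germline_records(rng)
    normal_records = germline_records(rng)

    # somatic: tumor only
    depths = _depths(rng, n_som, params.depth_mean)
    quals = _quals(rng, n_som, params.qual_low_frac)
    csqs = _consequences(rng, n_som, params)
    for i, key in enumerate(som_keys):
        raw = params.purity * float(rng.beta(2.0, 2.0))
        raw = min(max(raw, 1e-4), 1.0)
        vaf = _recoverable_vaf(raw, rng) if rng.random() < params.recoverable_frac else raw
        tumor_records.append(
            VariantRecord(
                chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                qual=float(quals[i]), depth=int(depths[i]), vaf=vaf,
                consequence=csqs[i], pop_afs={},
            )
        )

    # artifact noise: tumor only, VAF <= 0.05
    depths = _depths(rng, params.n_noise, params.depth_mean)
    quals = _quals(rng, params.n_noise, params.qual_low_frac)
    for i, key in enumerate(noise_keys):
        tumor_records.append(
            VariantRecord(
                chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                qual=float(quals[i]), depth=int(depths[i]),
                vaf=float(rng.uniform(0.005, 0.05)),
                consequence="coding_nonsynonymous", pop_afs={},
            )
        )

    tumor = SampleCallset(sample_id=sample_id, records=tumor_records, source="tumor")
    normal = SampleCallset(sample_id=sample_id, records=normal_records, source="normal")
    truth = SampleTruth(
        sample_id=sample_id,
        true_somatic_keys=frozenset(som_keys),
        true_tmb=params.true_tmb,
    )
    return tumor, normal, truth


def default_params_sampler(rng: np.random.Generator, base: SimParams | None = None) -> SimParams:
    """Cohort-level parameter draw: true TMB ~ Uniform(1, 40) mut/Mb,
    purity ~ Uniform(0.3, 0.7); everything else at ``base`` defaults."""
    base = base or SimParams()
    return replace(
        base,
        true_tmb=float(rng.uniform(1.0, 40.0)),
        purity=float(rng.uniform(0.3, 0.7)),
    )


def generate_cohort(
    n_samples: int,
    cancer_labels: Sequence[str],
    params_sampler: Callable[[np.random.Generator], SimParams] | None = None,
    seed: int = 0,
    pool: GermlinePool | None = None,
    pool_size: int = DEFAULT_POOL_SIZE,
    base_params: SimParams | None = None,
) -> tuple[
    list[tuple[SampleCallset, SampleCallset, SampleTruth]],
    pd.DataFrame,
    GermlinePool,
]:
    """Generate a multi-cancer cohort of matched pairs with a truth table.

    Cancer labels are assigned round-robin.  All samples share one germline
    pool (built from ``seed`` when not supplied), and
    :func:`generate_baseline_panel` called with the same seed uses the same
    pool.  Returns (pairs, truth table, pool); truth-table columns:
    sample_id, cancer_type, true_tmb, n_true_somatic.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if not cancer_labels:
        raise ValueError("cancer_labels must be non-empty")
    base = base_params or SimParams()
    if pool is None:
        pool_rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_POOL]))
        need = 2 * (base.n_germline_het + base.n_germline_hom)
        pool = GermlinePool.generate(
            max(pool_size, need), base.frac_common, pool_rng, base.indel_frac
        )
    sampler = params_sampler or (lambda rng: default_params_sampler(rng, base))

    pairs = []
    rows = []
    for i in range(n_samples):
        rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_SAMPLE, i]))
        params = sampler(rng)
        sample_id = f"S{i + 1:04d}"
        tumor, normal, truth = generate_matched_pair(
            params, pool=pool, sample_id=sample_id, rng=rng
        )
        pairs.append((tumor, normal, truth))
        rows.append(
            {
                "sample_id": sample_id,
                "cancer_type": cancer_labels[i % len(cancer_labels)],
                "true_tmb": params.true_tmb,
                "n_true_somatic": len(truth.true_somatic_keys),
            }
        )
    return pairs, pd.DataFrame(rows), pool


def generate_baseline_panel(
    n_donors: int,
    shared_germline_pool_size: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
    pool: GermlinePool | None = None,
    donor_site_frac: float = 0.6,
    frac_common: float = 0.7,
) -> BaselinePanel:
    """Pool healthy-donor germline keys into a baseline panel.

    Each donor carries an independent ``donor_site_frac`` subset of the
    shared germline pool; the panel is the union, so recurrent sites are
    represented and coverage of the pool grows with ``n_donors``.  With the
    same ``seed`` the pool is identical to the one :func:`generate_cohort`
    uses.
    """
    if n_donors < 1:
        raise ValueError(f"n_donors must be >= 1, got {n_donors}")
    if pool is None:
        pool_rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_POOL]))
        pool = GermlinePool.generate(shared_germline_pool_size, frac_common, pool_rng)
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_DONORS]))
    keys: set[VariantKey] = set()
    for _ in range(n_donors):
        mask = rng.random(len(pool)) < donor_site_frac
        keys.update(s.key for s, m in zip(pool.sites, mask) if m)
    if not keys:  # a pathological donor draw may be empty; keep the panel valid
        keys.add(pool.sites[0].key)
    return BaselinePanel(keys=frozenset(keys), n_donors=n_donors)


def _value_in_band(bands: MetricBands, score: int, rng: np.random.Generator) -> float:
    lo, hi = bands.valid_range
    hi_eff = min(hi, bands.cut_best * 2 if bands.higher_is_better else hi)
    if bands.higher_is_better:
        edges = {
            2: (bands.cut_best, max(hi_eff, bands.cut_best + 1.0)),
            1: (bands.cut_mid, bands.cut_best),
            0: (lo, bands.cut_mid),
        }[score]
        a, b = edges
        v = float(rng.uniform(a, b))
        return min(v, hi) if score == 2 else min(v, b - 1e-6)
    edges = {
        2: (lo, bands.cut_best),
        1: (bands.cut_best, bands.cut_mid),
        0: (bands.cut_mid, hi),
    }[score]
    a, b = edges
    v = float(rng.uniform(a, b))
    # open lower edge for scores 1 and 0 (the boundary belongs to the better band)
    return v if score == 2 else max(v, a + 1e-6)


def generate_qc_metrics(
    tier: str,
    seed: int = 0,
    thresholds: QCThresholds | None = None,
    rng: np.random.Generator | None = None,
) -> QCMetrics:
    """Draw QC metric values that land in the requested category
    ('good', 'intermediate' or 'poor') under the given thresholds."""
    if tier not in ("good", "intermediate", "poor"):
        raise ValueError(f"tier must be good|intermediate|poor, got {tier!r}")
    t = thresholds or QCThresholds()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_QC]))
    while True:  # rejection-sample a per-metric score combination in the tier
        scores = rng.integers(0, 3, size=4)
        cum = int(scores.sum())
        cat = "good" if cum >= 6 else "intermediate" if cum >= 3 else "poor"
        if cat == tier:
            break
    values = {
        name: _value_in_band(getattr(t, name), int(s), rng)
        for name, s in zip(METRIC_NAMES, scores)
    }
    m = QCMetrics(**values)
    assert score_sample(m, t).category == tier  # by construction
    return m
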