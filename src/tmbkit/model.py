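"""Variant domain model and VCF / TSV input-output.

The pipeline consumes small-variant call sets (one VCF per sample) that carry,
per record: a Phred-like quality, total read depth, the variant allele
fraction (VAF), a collapsed consequence class, and optional population allele
frequencies.  Everything downstream (germline filtration, TMB scoring) works
on the in-memory types defined here.

Conventions
-----------
* Coordinates are VCF-native: 1-based, fully closed.
* Multi-allelic VCF lines are split on read into one record per alternate
  allele, each with its own allele-specific VAF.
* Variant identity is the parsimony-normalized (chrom, pos, ref, alt) tuple:
  shared suffix bases are trimmed first, then shared prefix bases (advancing
  the position), so equivalent indel spellings compare equal.
* Consequence classes are collapsed to three values carried in the INFO field
  ``CSQCLASS``; functional annotation itself is an input contract, not a
  computation performed here.
* Population allele frequencies are carried as INFO fields named ``AF_<LABEL>``
  (``AF_GLOBAL``, ``AF_SAS``, ...); an absent entry means "not observed".
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "CONSEQUENCES",
    "VariantKey",
    "VariantRecord",
    "SampleCallset",
    "variant_key",
    "normalize_allele",
    "read_vcf",
    "write_vcf",
    "read_tsv_table",
    "write_tsv_table",
]

CONSEQUENCES = frozenset({"coding_nonsynonymous", "coding_synonymous", "noncoding"})

#: INFO-field spelling for each population-frequency label.
_AF_LABELS = {"global": "AF_GLOBAL", "south_asian": "AF_SAS"}
_AF_FIELDS = {v: k for k, v in _AF_LABELS.items()}

Source = Literal["tumor", "normal"]


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Canonical identity of a variant after parsimony normalization."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One called small variant with the annotations the filters need.

    ``vaf`` is the variant allele fraction in [0, 1]; ``pop_afs`` maps a
    database label (``global``, ``south_asian``) to an allele frequency,
    with missing labels meaning the allele was not observed there.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    vaf: float
    consequence: str
    pop_afs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty allele strings")
        if self.qual < 0:
            raise ValueError(f"qual must be non-negative, got {self.qual}")
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"consequence must be one of {sorted(CONSEQUENCES)}, got {self.consequence!r}"
            )

    @property
    def key(self) -> VariantKey:
        return variant_key(self)


def normalize_allele(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Parsimony-normalize an allele pair.

    Trims bases shared between ref and alt — suffix first, then prefix
    (advancing ``pos``) — while both alleles keep at least one base, so
    alternative spellings of the same indel map to one key.
    """
    ref_l, alt_l = list(ref), list(alt)
    while len(ref_l) > 1 and len(alt_l) > 1 and ref_l[-1] == alt_l[-1]:
        ref_l.pop()
        alt_l.pop()
    while len(ref_l) > 1 and len(alt_l) > 1 and ref_l[0] == alt_l[0]:
        ref_l.pop(0)
        alt_l.pop(0)
        pos += 1
    return VariantKey(chrom, pos, "".join(ref_l), "".join(alt_l))


def variant_key(r: VariantRecord) -> VariantKey:
    """Canonical :class:`VariantKey` for a record (deterministic)."""
    return normalize_allele(r.chrom, r.pos, r.ref, r.alt)


@dataclass(slots=True)
class SampleCallset:
    """All records called for one sample, sorted by (chrom, pos)."""

    sample_id: str
    records: list[VariantRecord]
    source: Source

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.source not in ("tumor", "normal"):
            raise ValueError(f"source must be 'tumor' or 'normal', got {self.source!r}")
        self.records = sorted(
            self.records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)
        )

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[VariantKey]:
        return {variant_key(r) for r in self.records}

    def replace_records(self, records: Iterable[VariantRecord]) -> "SampleCallset":
        return SampleCallset(self.sample_id, list(records), self.source)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, source: Source) -> SampleCallset:
    """Read a single-sample VCF into a :class:`SampleCallset`.

    Multi-allelic lines are split into one record per alternate allele.  VAF
    comes from the FORMAT ``AF`` field when present, otherwise from
    ``AD[alt] / depth``; depth from FORMAT ``DP``, falling back to the sum of
    ``AD``.  Missing both depth sources, or both VAF sources, is a hard error
    naming the sample and offending line.
    """
    path = Path(path)
    vcf = VCF(str(path))
    try:
        samples = list(vcf.samples)
        sample_id = samples[0] if samples else path.stem
        records: list[VariantRecord] = []
        for var in vcf:
            where = f"sample {sample_id!r}, line {var.CHROM}:{var.POS}"
            qual = float(var.QUAL) if var.QUAL is not None else 0.0
            csq = var.INFO.get("CSQCLASS")
            if csq is None:
                raise ValueError(f"missing INFO CSQCLASS at {where}")
            if csq not in CONSEQUENCES:
                raise ValueError(f"unknown CSQCLASS {csq!r} at {where}")

            pop_afs: dict[str, float] = {}
            for info_field, label in _AF_FIELDS.items():
                val = var.INFO.get(info_field)
                if val is not None:
                    try:
                        pop_afs[label] = float(val)
                    except (TypeError, ValueError) as exc:
                        raise ValueError(
                            f"unparseable {info_field}={val!r} at {where}"
                        ) from exc

            def fmt(field: str):
                try:
                    return var.format(field)
                except KeyError:  # field absent from the header entirely
                    return None

            dp_arr = fmt("DP")
            ad_arr = fmt("AD")
            if dp_arr is None and ad_arr is None:
                raise ValueError(f"missing FORMAT DP and AD at {where}")
            af_arr = fmt("AF")
            if af_arr is None and ad_arr is None:
                raise ValueError(f"missing FORMAT AF and AD at {where}")

            if dp_arr is not None:
                depth = int(dp_arr[0][0])
            else:
                depth = int(sum(max(int(x), 0) for x in ad_arr[0]))

            alts = var.ALT
            for i, alt in enumerate(alts):
                if af_arr is not None:
                    row = af_arr[0]
                    vaf = float(row[i] if i < len(row) else row[0])
                else:
                    alt_depth = int(ad_arr[0][i + 1])
                    vaf = alt_depth / depth if depth > 0 else 0.0
                if not 0.0 <= vaf <= 1.0:
                    raise ValueError(f"unparseable AF {vaf} at {where}")
                records.append(
                    VariantRecord(
                        chrom=var.CHROM,
                        pos=int(var.POS),
                        ref=var.REF,
                        alt=alt,
                        qual=qual,
                        depth=depth,
                        vaf=vaf,
                        consequence=csq,
                        pop_afs=pop_afs,
                    )
                )
    finally:
        vcf.close()
    return SampleCallset(sample_id=sample_id, records=records, source=source)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Collapsed consequence class">
##INFO=<ID=AF_GLOBAL,Number=1,Type=Float,Description="Global population allele frequency">
##INFO=<ID=AF_SAS,Number=1,Type=Float,Description="South Asian population allele frequency">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">
"""


def _fmt_float(x: float) -> str:
    return format(float(x), ".6g")


def write_vcf(cs: SampleCallset, path: str | os.PathLike) -> None:
    """Write a callset as a single-sample VCF 4.2 text file.

    The inverse of :func:`read_vcf` on (key, qual, depth, vaf, consequence,
    pop_afs) up to 6-significant-digit float round-trip.
    """
    path = Path(path)
    chroms = sorted({r.chrom for r in cs.records})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{cs.sample_id}\n"
        )
        for r in cs.records:
            info = [f"CSQCLASS={r.consequence}"]
            for label in sorted(r.pop_afs):
                info.append(f"{_AF_LABELS[label]}={_fmt_float(r.pop_afs[label])}")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{_fmt_float(r.qual)}\t"
                f"PASS\t{';'.join(info)}\tDP:AF\t{r.depth}:{_fmt_float(r.vaf)}\n"
            )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_tsv_table(
    rows: pd.DataFrame | Sequence[Mapping[str, object]],
    path: str | os.PathLike,
    comment: str | None = None,
) -> None:
    """Write tabular data as a UTF-8 TSV with a header row.

    Missing values render as ``"."``; reals are rendered to 6 significant
    digits so a read-back reproduces string/int fields bit-exactly and floats
    to 6 significant digits.  ``comment`` prepends a ``#``-prefixed line.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    with open(path, "w", encoding="utf-8") as fh:
        if comment is not None:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".", float_format="%.6g")


def read_tsv_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv_table` (``#`` lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["."])
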