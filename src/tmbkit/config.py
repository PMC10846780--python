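"""Pipeline configuration: one YAML file governs every threshold.

The workflow's reference thresholds (quality, depth, population AF, VAF
bands, QC score bands) and the package's own defaults (QC cut-points, exome target
size) live side by side in one document, so a laboratory can substitute its
validated values without touching code.  Unknown keys are rejected — a typo
in a threshold name must not silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .filters import FilterConfig
from .qc import METRIC_NAMES, MetricBands, QCThresholds
from .simulate import DEFAULT_POOL_SIZE, SimParams
from .tmb import DEFAULT_TARGET_SIZE_MB

__all__ = ["PipelineConfig", "load_config", "default_config_dict"]


def _check_keys(section: str, given: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {section}: {sorted(unknown)}")


@dataclass(frozen=True)
class BootstrapSettings:
    n_iterations: int = 1000
    level: float = 90.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("bootstrap n_iterations must be >= 1")
        if not 0.0 <= self.level <= 100.0:
            raise ValueError("bootstrap level must be in [0, 100]")


@dataclass(frozen=True)
class SimulateSettings:
    n_samples: int = 20
    cancer_labels: tuple[str, ...] = (
        "breast", "lung", "colorectal", "ovary", "head_and_neck", "sarcoma",
    )
    pool_size: int = DEFAULT_POOL_SIZE
    n_panel_donors: int = 20
    tmb_range: tuple[float, float] = (1.0, 40.0)
    purity_range: tuple[float, float] = (0.3, 0.7)
    #: good/intermediate/poor mix giving an expected QC pass rate of ~0.79
    tier_weights: tuple[float, float, float] = (0.589, 0.200, 0.211)
    params: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not self.cancer_labels:
            raise ValueError("cancer_labels must be non-empty")
        if abs(sum(self.tier_weights) - 1.0) > 1e-9:
            raise ValueError("tier_weights must sum to 1")


@dataclass(frozen=True)
class PipelineConfig:
    target_size_mb: float = DEFAULT_TARGET_SIZE_MB
    filter: FilterConfig = field(default_factory=FilterConfig)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    bootstrap: BootstrapSettings = field(default_factory=BootstrapSettings)
    simulate: SimulateSettings = field(default_factory=SimulateSettings)

    def __post_init__(self) -> None:
        if self.target_size_mb <= 0:
            raise ValueError(f"target_size_mb must be > 0, got {self.target_size_mb}")

    @property
    def config_hash(self) -> str:
        """Short stable digest of the full configuration, stamped into every
        output file header."""
        blob = json.dumps(_to_plain(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _to_plain(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dc_fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj


def _bands_from_dict(name: str, d: Mapping[str, Any], default: MetricBands) -> MetricBands:
    _check_keys(f"qc_thresholds.{name}", d,
                {"cut_mid", "cut_best", "higher_is_better", "valid_range"})
    vr = d.get("valid_range")
    valid_range = tuple(float(x) for x in vr) if vr else default.valid_range
    return MetricBands(
        cut_mid=float(d.get("cut_mid", default.cut_mid)),
        cut_best=float(d.get("cut_best", default.cut_best)),
        higher_is_better=bool(d.get("higher_is_better", default.higher_is_better)),
        valid_range=valid_range,  # type: ignore[arg-type]
    )


def config_from_dict(doc: Mapping[str, Any]) -> PipelineConfig:
    _check_keys("config", doc,
                {"target_size_mb", "filter", "qc_thresholds", "bootstrap", "simulate"})

    fdoc = dict(doc.get("filter") or {})
    allowed = {f.name for f in dc_fields(FilterConfig)}
    _check_keys("filter", fdoc, allowed)
    if "germ_het_band" in fdoc:
        fdoc["germ_het_band"] = tuple(float(x) for x in fdoc["germ_het_band"])
    filt = FilterConfig(**fdoc)

    qdoc = dict(doc.get("qc_thresholds") or {})
    _check_keys("qc_thresholds", qdoc, set(METRIC_NAMES))
    defaults = QCThresholds()
    qc = QCThresholds(**{
        name: _bands_from_dict(name, qdoc.get(name) or {}, getattr(defaults, name))
        for name in METRIC_NAMES
    })

    bdoc = dict(doc.get("bootstrap") or {})
    _check_keys("bootstrap", bdoc, {"n_iterations", "level"})
    boot = BootstrapSettings(**bdoc)

    sdoc = dict(doc.get("simulate") or {})
    allowed = {f.name for f in dc_fields(SimulateSettings)}
    _check_keys("simulate", sdoc, allowed)
    if "params" in sdoc:
        pdoc = dict(sdoc["params"] or {})
        _check_keys("simulate.params", pdoc, {f.name for f in dc_fields(SimParams)})
        sdoc["params"] = SimParams(**pdoc)
    for key in ("cancer_labels", "tmb_range", "purity_range", "tier_weights"):
        if key in sdoc:
            sdoc[key] = tuple(sdoc[key])
    sim = SimulateSettings(**sdoc)

    return PipelineConfig(
        target_size_mb=float(doc.get("target_size_mb", DEFAULT_TARGET_SIZE_MB)),
        filter=filt, qc_thresholds=qc, bootstrap=boot, simulate=sim,
    )


def load_config(path: str | os.PathLike | None) -> PipelineConfig:
    """Load a YAML config; a missing path yields the full default config."""
    if path is None:
        return PipelineConfig()
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(doc, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    return config_from_dict(doc)


def default_config_dict() -> dict[str, Any]:
    """Plain-dict rendering of the default config (for ``--dump-config``)."""
    return _to_plain(PipelineConfig())
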