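import numpy as np
import pytest

from tmbkit.filters import BaselinePanel, FilterConfig
from tmbkit.model import SampleCallset, VariantRecord, variant_key

CSQ = ("coding_nonsynonymous", "coding_synonymous", "noncoding")


def random_record(rng: np.random.Generator) -> VariantRecord:
    """A record with quality/depth/VAF/AF values spread across every filter
    boundary, including exact boundary values."""
    qual = float(rng.choice([rng.uniform(0, 60), 10.0, 9.99]))
    depth = int(rng.choice([rng.integers(0, 120), 30, 29]))
    vaf = float(rng.choice([rng.uniform(0, 1), 0.05, 0.45, 0.5, 0.55]))
    pop_afs = {}
    if rng.random() < 0.5:
        pop_afs["global"] = float(rng.choice([rng.uniform(0, 0.2), 0.01]))
    if rng.random() < 0.3:
        pop_afs["south_asian"] = float(rng.uniform(0, 0.2))
    return VariantRecord(
        chrom=f"chr{rng.integers(1, 5)}",
        pos=int(rng.integers(1, 10_000)),
        ref="A",
        alt="G",
        qual=qual,
        depth=depth,
        vaf=vaf,
        consequence=str(rng.choice(CSQ)),
        pop_afs=pop_afs,
    )


def random_callset(rng: np.random.Generator, n: int, source: str = "tumor") -> SampleCallset:
    return SampleCallset(
        sample_id="rand", records=[random_record(rng) for _ in range(n)], source=source
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230047)


@pytest.fixture
def cfg() -> FilterConfig:
    return FilterConfig()


@pytest.fixture
def small_panel(rng) -> BaselinePanel:
    cs = random_callset(rng, 40)
    keys = {variant_key(r) for r in cs.records[:20]}
    return BaselinePanel(keys=frozenset(keys), n_donors=3)
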