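import numpy as np
import pandas as pd
import pytest

from circgrade.annotation import AnnotationDB, GeneRecord
from circgrade.intervals import GenomicInterval
from circgrade.synthetic import (
    SamplePlan,
    SpikeConfig,
    generate_annotation,
    generate_cohort,
)


@pytest.fixture(scope="session")
def toy_annotation() -> AnnotationDB:
    """Two genes on chr1 (one forward, one reverse), hand-built exon/UTR/CDS
    structure with known coordinates, plus intergenic space around them."""
    iv = GenomicInterval
    genes = [
        GeneRecord("GA", "GA", iv("chr1", 1000, 3000, "+")),
        GeneRecord("GB", "GB", iv("chr1", 5000, 7000, "-")),
    ]
    exons = {
        "GA": [iv("chr1", 1000, 1400, "+"), iv("chr1", 2000, 2400, "+"),
               iv("chr1", 2600, 3000, "+")],
        "GB": [iv("chr1", 5000, 5500, "-"), iv("chr1", 6500, 7000, "-")],
    }
    cds = {
        "GA": [iv("chr1", 1200, 1400, "+"), iv("chr1", 2000, 2400, "+"),
               iv("chr1", 2600, 2800, "+")],
        "GB": [iv("chr1", 5200, 5500, "-"), iv("chr1", 6500, 6800, "-")],
    }
    utr5 = {
        "GA": [iv("chr1", 1000, 1200, "+")],
        "GB": [iv("chr1", 6800, 7000, "-")],
    }
    utr3 = {
        "GA": [iv("chr1", 2800, 3000, "+")],
        "GB": [iv("chr1", 5000, 5200, "-")],
    }
    db = AnnotationDB(genes=genes, exons=exons, cds_regions=cds,
                      utr5_regions=utr5, utr3_regions=utr3)
    db.validate()
    return db


@pytest.fixture(scope="session")
def sim_annotation() -> AnnotationDB:
    return generate_annotation(seed=11, n_genes=300)


@pytest.fixture(scope="session")
def small_cohort(sim_annotation):
    """A read-level cohort small enough for per-test reuse: 400 junctions,
    40 of them spiked one log2 unit in G3."""
    return generate_cohort(
        sim_annotation,
        n_junctions=400,
        spike=SpikeConfig(n_spiked=40, effect_size=1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_samples(small_cohort) -> pd.DataFrame:
    return small_cohort.samples


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(424242)


@pytest.fixture(scope="session")
def default_plan() -> SamplePlan:
    return SamplePlan()
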