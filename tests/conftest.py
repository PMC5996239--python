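import random

import pytest

from capsforge.io_formats import PileupColumn, count_bases
from capsforge.pipeline import PipelineConfig, run_pipeline
from capsforge.synthetic_cohort import CohortConfig


def make_column(chrom: str, pos: int, ref: str, bases: str) -> PileupColumn:
    """Hand-build a pileup column for tests."""
    return PileupColumn(
        chrom=chrom, pos=pos, ref_base=ref, depth=len(bases),
        base_string=bases, counts=count_bases(bases, ref),
    )


@pytest.fixture(scope="session")
def small_cohort_result(tmp_path_factory):
    """A small but complete pipeline run shared across tests."""
    config = PipelineConfig(
        cohort=CohortConfig(
            genome_length=25_000, n_samples=5, snp_rate=0.002,
            depth_means=(12.0, 18.0, 25.0, 9.0, 33.0),
            planted_caps_sites=4, seed=11,
        )
    )
    outdir = tmp_path_factory.mktemp("small_cohort")
    return config, run_pipeline(config, outdir)


@pytest.fixture
def rnd():
    return random.Random(20240917)
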