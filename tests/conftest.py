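import numpy as np
import pytest
from hypothesis import settings

import acghcnv as ac

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    return ac.toy_genome()


@pytest.fixture(scope="session")
def small_cohort():
    """A miniature simulated study (two small autosomes, 9 samples)."""
    genome = ac.GenomeModel(
        (
            ac.Chromosome("chr1", 2_000_000, True),
            ac.Chromosome("chr2", 1_500_000, True),
        )
    )
    spec = ac.CohortSpec(
        groups={"NASH": 6, "SS": 3},
        regions=(
            ac.PlantedRegion(
                "gain1", "chr1", 500_000, 620_000, 3,
                {"NASH": 0.5, "SS": 0.3}, db_coverage_pct=100.0, n_genes=2,
            ),
            ac.PlantedRegion(
                "loss1", "chr2", 400_000, 480_000, 1,
                {"NASH": 0.4, "SS": 0.0}, db_coverage_pct=0.0, n_genes=1,
            ),
        ),
    )
    return ac.simulate_cohort(
        spec, genome, ac.NoiseModel(sd=0.12, outlier_prob=0.0), seed=7
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One full default study (39 + 10 samples on the toy genome)."""
    return ac.simulate_cohort(seed=20)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
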