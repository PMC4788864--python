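import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from matekit.simulate import (  # noqa: E402
    BlockSpec,
    GenomeSpec,
    SimConfig,
    TandemSpec,
    gen_genome,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact genome: 2 tandem clusters, 1 collinear block, 4 singles."""
    return SimConfig(
        seed=11,
        genome=GenomeSpec(
            n_chromosomes=4,
            loci_per_chromosome=80,
            n_family=20,
            tandem=TandemSpec(n_clusters=2, cluster_size=2),
            blocks=BlockSpec(n_blocks=1, anchors_per_block=6),
        ),
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return gen_genome(small_config)


@pytest.fixture()
def rng():
    # fresh, fixed-seed stream per test: results do not depend on test order
    return np.random.default_rng(20160311)
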