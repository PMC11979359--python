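import numpy as np
import pytest

from gswave.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture()
def rng(request):
    """Per-test deterministic generator: independent of execution order."""
    import zlib

    seed = zlib.crc32(request.node.nodeid.encode()) % (2**31)
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny but complete cohort reused by read-only tests."""
    spec = CohortSpec(
        n_per_group=6,
        sequence_lengths=(128,) * 6,
        n_regions=12,
        seed=11,
        group_lowfreq_scale=1.3,
        order_variance_slope=0.06,
        artifact_strength=0.6,
        spike_rate=0.002,
    )
    return generate_cohort(spec)
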