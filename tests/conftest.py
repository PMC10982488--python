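import numpy as np
import pytest

from cnvburden import CnvCall, SyntheticCohortSpec, simulate_cohort


def random_call(rng, sample_id="S1", chrom=1, cnv_type=None, max_len=10_000,
                max_pos=100_000):
    """A random valid call with toy-scale coordinates."""
    if cnv_type is None:
        cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
    start = int(rng.integers(0, max_pos))
    length = int(rng.integers(1, max_len))
    cn = int(rng.choice([0, 1])) if cnv_type == "DEL" else int(rng.choice([3, 4]))
    return CnvCall(sample_id, chrom, start, start + length, cnv_type, cn,
                   num_probes=max(1, length // 1000))


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic small cohort shared across tests."""
    spec = SyntheticCohortSpec(n_cases=250, n_controls=750, seed=42)
    return simulate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
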