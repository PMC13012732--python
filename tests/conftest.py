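import numpy as np
import pytest

from hicmamba.contact import ContactMap
from hicmamba.synthetic import SyntheticSpec, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_pair():
    """A 100-bin synthetic high/low pair with planted TADs and loops."""
    spec = SyntheticSpec(n_bins=100, bin_size=10000, total_reads=300_000,
                         tads=[(10, 35, 2.5), (50, 90, 3.0)],
                         loops=[(12, 33, 6.0, 1.0), (55, 85, 6.0, 1.0),
                                (60, 75, 6.0, 1.0)],
                         seed=7)
    high, low, loops, bounds = generate_pair(spec, 1 / 16)
    return {"spec": spec, "high": high, "low": low, "loops": loops,
            "bounds": bounds}


@pytest.fixture
def random_symmetric_map(rng):
    a = rng.uniform(0.2, 3.0, (60, 60))
    return ContactMap(chrom="chrT", bin_size=10000, values=(a + a.T) / 2)
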