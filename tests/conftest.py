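import numpy as np
import pytest

from aasig.opportunity import _fold64_to_32, _trinuc_counts
from aasig.simulate import (
    SyntheticConfig,
    bundled_signatures,
    make_reference,
    simulate_catalog,
)


@pytest.fixture(scope="session")
def signatures():
    return bundled_signatures()


@pytest.fixture(scope="session")
def fixture_opportunities():
    """Opportunities of a generated fixture chromosome (near-flat)."""
    ref, _ = make_reference(seed=7)
    return _fold64_to_32(_trinuc_counts(next(iter(ref.values()))))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Four-sample simulated cohort written to disk: 2 AA-exposed, 2 background."""
    w_aa = np.array([0.7, 0.0, 0.0, 0.3])
    w_bg = np.array([0.0, 0.0, 0.0, 1.0])
    config = SyntheticConfig(
        samples=4,
        exposures=np.vstack([w_aa, w_aa, w_bg, w_bg]),
        burden=700,
        strand_bias_q=0.75,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("cohort")
    data = simulate_catalog(config, outdir=outdir)
    return config, data, outdir
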