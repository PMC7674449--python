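import numpy as np
import pytest
from hypothesis import settings

from cbfmrd.synthetic_cohort import SimConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A desk-scale synthetic cohort shared across file-level tests.

    Sequencing depth is scaled down (20k mapped reads, junction means
    200/80) so FASTQ emission and counting stay fast; the statistical
    structure (residual-fraction law, clearance, hazards) is unchanged.
    """
    out = tmp_path_factory.mktemp("cohort")
    cfg = SimConfig(n_patients=10, seed=42, mapped_reads_mean=20000,
                    dx_junction_mean={"t821": 200.0, "inv16": 80.0})
    truth = simulate_cohort(cfg, out)
    return cfg, out, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
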