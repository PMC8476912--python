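import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mirvar.simulate import SimulationConfig, simulate_target_cohort


@pytest.fixture(scope="session")
def cohort():
    """One shared synthetic cohort at the default study conditions."""
    return simulate_target_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_files(cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return cohort.write(out)
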