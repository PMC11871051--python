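import pytest

from tucei import build_s0, explode_ensemble, thermal_ensemble
from tucei.frames import CoincidenceEvent

#: ensemble used by the ground-state benchmark tests: 2000 thermally
#: smeared copies of the planar molecule, exploded from rest with all
#: charges +1
ENSEMBLE_N = 2000
ENSEMBLE_SEED = 2025


@pytest.fixture(scope="session")
def s0():
    return build_s0()


@pytest.fixture(scope="session")
def s0_results(s0):
    ens = thermal_ensemble(s0, n=ENSEMBLE_N, seed=ENSEMBLE_SEED)
    return explode_ensemble(ens)


@pytest.fixture(scope="session")
def s0_events(s0_results):
    return [CoincidenceEvent.from_result(r) for r in s0_results]


@pytest.fixture(scope="session")
def small_events(s0_events):
    return s0_events[:200]
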