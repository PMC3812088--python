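import numpy as np
import pytest

from sfscl import Demography, HistoricalEvent, Parameter, ParameterSpace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def one_deme():
    """Constant-size single deme, n=20."""
    return Demography(sizes=[10_000], sample_sizes=[20])


@pytest.fixture
def pair_deme():
    """Two demes fusing at t=1000, no migration before the fusion."""
    return Demography(
        sizes=[5_000, 500],
        sample_sizes=[6, 4],
        events=[HistoricalEvent(time=1_000, source=1, sink=0, new_size=5_000)],
    )


@pytest.fixture
def bottleneck_space():
    from sfscl.benchmarks import scenario_preset

    return scenario_preset("bottleneck").space


def constant_size_space(n=20, lo=100.0, hi=1e6):
    """One free parameter: the (constant) deme size."""
    return ParameterSpace(
        parameters=[Parameter("N", "size", lo, hi)],
        builder=lambda p: Demography(sizes=[p["N"]], sample_sizes=[n]),
    )
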