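import numpy as np
import pytest

from latentgeo import (
    TimeSeries,
    distance_matrix_from_fixture,
    fmm_spline,
    simulate_cascade,
)
from latentgeo.synthetic import bottleneck_scenario


@pytest.fixture(scope="session")
def individual1_matrix():
    """The 6x6 case-study distance matrix of Individual 1."""
    return distance_matrix_from_fixture(1)


@pytest.fixture(scope="session")
def scenario_curves():
    """Spline-densified curves of the engineered bottleneck cascade."""
    spec, graph = bottleneck_scenario(seed=11)
    tss = simulate_cascade(spec)
    curves = {s.label: fmm_spline(s, n_out=100) for s in tss}
    return curves, graph


@pytest.fixture()
def cubic_series():
    t = np.linspace(0.0, 5.0, 8)
    return TimeSeries("cubic", t, t**3 - 2 * t + 12.0)
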