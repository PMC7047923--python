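import numpy as np
import pytest

from ldasim import CovarianceSpec, SimulationDesign, TrendSpec, TruncationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_design():
    """Factory for designs with sensible defaults, overridable per test."""

    def _make(**kw):
        base = dict(
            n_control=20,
            n_treat=20,
            control_mean=2.0,
            covariance=CovarianceSpec("compound", sigma=1.0, rho=0.7),
            trend=TrendSpec("quadratic", beta=(0.0, 3.0, -0.5)),
            num_timepoints=7,
            t_interval=(0.0, 6.0),
            seed=42,
        )
        base.update(kw)
        return SimulationDesign(**base)

    return _make


@pytest.fixture
def no_trunc():
    return TruncationSpec(enabled=False)
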