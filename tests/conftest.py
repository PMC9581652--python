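import numpy as np
import pytest

from bayar import GibbsConfig, MonthlySeries, PriorSpec, generate_pure_ar


@pytest.fixture
def tiny_series():
    """Three months of counts starting January 2015."""
    return MonthlySeries(values=np.array([10.0, 20.0, 30.0]), start=(2015, 1))


@pytest.fixture
def recurrence_series():
    """Noise-free y_t = 10 + 0.5 y_{t-1} from y_0 = 100: exactly AR(1).

    Kept short: once the recurrence converges to its fixed point the lag
    columns become constant and the design degenerates.
    """
    y = [100.0]
    for _ in range(24):
        y.append(10.0 + 0.5 * y[-1])
    return MonthlySeries(values=np.array(y), start=(2010, 1))


@pytest.fixture(scope="session")
def ar2_series():
    """A fixed seeded AR(2) draw used across sampler tests."""
    return generate_pure_ar(50.0, (0.5, 0.3), 5.0, 200, seed=7)


@pytest.fixture(scope="session")
def ar2_draws(ar2_series):
    """Default-prior posterior draws on the shared AR(2) series (short chain)."""
    from bayar import gibbs_sample

    return gibbs_sample(
        ar2_series, 2, config=GibbsConfig(iterations=3000, burn_in=500, seed=1)
    )


@pytest.fixture
def vague_prior():
    return PriorSpec(coef_var=1e6)
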