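import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lorenzfit as lf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hypothetical_sample() -> lf.SizeSample:
    """99 observations of size 1 plus one of size 99 (n=100, total=198)."""
    return lf.make_hypothetical()


@pytest.fixture(scope="session")
def hypothetical_points(hypothetical_sample) -> lf.LorenzPoints:
    return lf.empirical_lorenz(hypothetical_sample)


@pytest.fixture(scope="session")
def hypothetical_fit(hypothetical_points) -> lf.FitResult:
    """Proposed-model fit of the extreme-inequality benchmark (exact)."""
    return lf.fit(hypothetical_points, lf.FitConfig(model="proposed"))


def lorenz_points_from_curve(model: str, params, n: int = 200) -> lf.LorenzPoints:
    """Noise-free Lorenz points sampled from a model curve at x_i = i/n."""
    x = np.arange(1, n + 1, dtype=float) / n
    y = np.asarray(lf.evaluate_model(model, x, params), dtype=float)
    y[-1] = 1.0
    return lf.LorenzPoints(x=x, y=np.minimum(y, x))
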