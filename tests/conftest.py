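import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from recyclegame import GameParameters, StrategyState, baseline_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def baseline() -> GameParameters:
    return baseline_scenario()


@pytest.fixture
def center() -> StrategyState:
    return StrategyState(0.5, 0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_parameters(rng: np.random.Generator) -> GameParameters:
    """A strictly positive random game instance spanning all feasible regimes."""
    return GameParameters(
        s=float(rng.uniform(1.0, 1200.0)),
        c1=float(rng.uniform(0.5, 400.0)),
        c2=float(rng.uniform(0.0, 600.0)),
        t1=float(rng.uniform(0.0, 150.0)),
        t2=float(rng.uniform(0.5, 150.0)),
        m=float(rng.uniform(0.0, 400.0)),
    )


def random_interior_state(rng: np.random.Generator, margin: float = 0.01) -> StrategyState:
    phi, omega = rng.uniform(margin, 1.0 - margin, size=2)
    return StrategyState(float(phi), float(omega))
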