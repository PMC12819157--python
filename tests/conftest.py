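import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aerogate.pore_transport import (
    Electrolyte,
    IVCurve,
    LumenCharge,
    PoreGeometry,
    TransportProblem,
    iv_curve,
)
from aerogate.synthetic_data import load_pore, load_scenario


@pytest.fixture(scope="session")
def neutral_problem() -> TransportProblem:
    return TransportProblem()


@pytest.fixture(scope="session")
def wt_problem() -> TransportProblem:
    return load_pore("wt_like")


@pytest.fixture(scope="session")
def equal_d_electrolyte() -> Electrolyte:
    """Electrolyte with D+ = D-, for which the charge/voltage symmetries are exact."""
    return Electrolyte(diffusion_cation_m2s=2.0e-9, diffusion_anion_m2s=2.0e-9)


@pytest.fixture(scope="session")
def wt_open_iv(wt_problem) -> IVCurve:
    return iv_curve(wt_problem, np.linspace(-0.25, 0.25, 101))


@pytest.fixture(scope="session")
def neutral_open_iv(neutral_problem) -> IVCurve:
    return iv_curve(neutral_problem, np.linspace(-0.25, 0.25, 101))


def random_charge_problem(rng: np.random.Generator,
                          electrolyte: Electrolyte) -> TransportProblem:
    """A random lumen charge set on the default geometry."""
    n = int(rng.integers(1, 4))
    charges = [
        LumenCharge(float(rng.uniform(0.0, 10.0)), int(rng.choice([-1, 1])),
                    int(rng.integers(1, 8)))
        for _ in range(n)
    ]
    return TransportProblem(charges=charges, electrolyte=electrolyte)
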