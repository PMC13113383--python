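import numpy as np
import pytest

from prfield import (CircuitParameters, FieldStimulus, NeuronParameters,
                     NeuronState, SimulationConfig)


@pytest.fixture(scope="session")
def params() -> NeuronParameters:
    return NeuronParameters()


@pytest.fixture(scope="session")
def circuit() -> CircuitParameters:
    return CircuitParameters.from_rout(10.0, RDSin=80.0)


@pytest.fixture
def short_config(circuit) -> SimulationConfig:
    """Cheap driven run for functional tests (not the full study protocol)."""
    return SimulationConfig(circuit=circuit,
                            stimulus=FieldStimulus(A=100.0, f=10.0),
                            t_end=1200.0, burn_in=400.0, sample_dt=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


class StudyProtocol:
    """Full study protocol (5 s runs, 1 s burn-in) with memoised cells."""

    RDSIN = 80.0  # MOhm

    def __init__(self) -> None:
        self._cache: dict = {}

    def rate(self, Rout: float, f: float, A: float,
             VK: float = -38.56) -> float:
        from prfield import detect_spikes, mean_firing_rate, simulate

        key = (Rout, f, A, VK)
        if key not in self._cache:
            cfg = SimulationConfig(
                params=NeuronParameters(VK=VK),
                circuit=CircuitParameters.from_rout(Rout, RDSin=self.RDSIN),
                stimulus=FieldStimulus(A=A, f=f))
            self._cache[key] = mean_firing_rate(detect_spikes(simulate(cfg)))
        return self._cache[key]

    def locking(self, Rout: float, f: float, A: float,
                VK: float = -38.56) -> float:
        return self.rate(Rout, f, A, VK) / f


@pytest.fixture(scope="session")
def protocol() -> StudyProtocol:
    return StudyProtocol()


def random_states(rng, n):
    """Physiologically plausible random state vectors."""
    states = []
    for _ in range(n):
        states.append(NeuronState(
            Vs=float(rng.uniform(-30, 110)),
            Vd=float(rng.uniform(-30, 110)),
            h=float(rng.uniform(0, 1)), n=float(rng.uniform(0, 1)),
            s=float(rng.uniform(0, 1)), c=float(rng.uniform(0, 1)),
            q=float(rng.uniform(0, 1)),
            Ca=float(rng.uniform(0, 500)),
            Si=float(rng.uniform(0, 150)), Wi=float(rng.uniform(0, 2))))
    return states
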