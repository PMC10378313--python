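import numpy as np
import pytest

from gearshift import Pathway, TransducerSystem


@pytest.fixture
def two_gear_system() -> TransducerSystem:
    """Reference dual-pathway system: phi=0.2, n1=1, n2=2, L=dGc=1, no leak."""
    return TransducerSystem.two_pathway(phi=0.2, n1=1.0, n2=2.0)


def random_system(rng: np.random.Generator, allow_leak: bool = True) -> TransducerSystem:
    """Draw a random valid transducer system (1-4 pathways)."""
    k = int(rng.integers(1, 5))
    stoich = rng.uniform(0.0, 5.0, size=k)
    weights = rng.dirichlet(np.ones(k))
    leak = float(rng.uniform(0.0, 0.5)) if (allow_leak and rng.random() < 0.5) else 0.0
    return TransducerSystem(
        pathways=tuple(
            Pathway(float(n), float(w)) for n, w in zip(stoich, weights)
        ),
        capacity=float(rng.uniform(0.1, 10.0)),
        gibbs_catabolic=float(rng.uniform(0.1, 10.0)),
        leak=leak,
    )
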