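import numpy as np
import pytest

from tectumds import circuit
from tectumds.protocol import make_protocol


@pytest.fixture(scope="session")
def protocol12():
    return make_protocol(n_directions=12, seed=7)


@pytest.fixture(scope="session")
def refined_circuit():
    """Default circuit with concentrations refined to the observed preference.

    Session-scoped: the refinement grid search is deterministic and shared by
    every circuit-level test.
    """
    spec = circuit.default_circuit()
    return spec.with_kappas(circuit.refine_kappas(spec))


@pytest.fixture(scope="session")
def battery_table(refined_circuit):
    return circuit.perturbation_battery(refined_circuit)
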