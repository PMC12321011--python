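import warnings

import numpy as np
import pytest

from mesosaxs import (
    NoiseSpec,
    PhaseSpec,
    KineticSpec,
    generate_kinetic_series,
    generate_pattern,
)
from mesosaxs.phases import Reflection

# the coexisting-structure set of the 80:20 mixture: lamellar stack plus
# both bicontinuous cubics
THREE_PHASE_LATTICES = {"lamellar": 6.9, "Pn3m": 11.6, "Im3m": 12.7}


@pytest.fixture(scope="session")
def three_phase_pattern():
    """Noiseless pattern with lamellar + Pn3m + Im3m coexistence."""
    phases = [
        PhaseSpec("lamellar", THREE_PHASE_LATTICES["lamellar"], amplitude=2000),
        PhaseSpec("Pn3m", THREE_PHASE_LATTICES["Pn3m"], amplitude=1200),
        PhaseSpec("Im3m", THREE_PHASE_LATTICES["Im3m"], amplitude=800),
    ]
    return generate_pattern(phases, NoiseSpec(model="none"))


@pytest.fixture(scope="session")
def transition_spec():
    """Lamellar -> Pn3m photoswitching series with an Im3m spectator."""
    return KineticSpec(
        initial=[PhaseSpec("lamellar", 6.9, amplitude=2000),
                 PhaseSpec("Im3m", 12.7, amplitude=800)],
        final=[PhaseSpec("Pn3m", 11.6, amplitude=1200),
               PhaseSpec("Im3m", 12.7, amplitude=800)],
    )


@pytest.fixture(scope="session")
def noiseless_series(transition_spec):
    return generate_kinetic_series(transition_spec, NoiseSpec(model="none"))


@pytest.fixture()
def tracked_reflections():
    return [("lamellar", Reflection.lamellar(1)),
            ("lamellar", Reflection.lamellar(2)),
            ("Pn3m", Reflection.cubic(1, 1, 0))]


@pytest.fixture()
def im3m_reference():
    return ("Im3m", Reflection.cubic(2, 1, 1))


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", message=".*lamellar phase absent.*")
        yield
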