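import numpy as np
import pytest

from optofluidics import pump


@pytest.fixture(scope="session")
def default_system() -> pump.PumpSystem:
    return pump.PumpSystem()


@pytest.fixture(scope="session")
def big_reservoir_system() -> pump.PumpSystem:
    """Default pump with a reservoir large enough not to truncate flows."""
    return pump.PumpSystem(reservoir_volume=5e-9)


def random_small_mstar_system(rng: np.random.Generator):
    """Randomized pump parameters in the closed form's validity regime.

    Geometry and membrane parameters are perturbed by up to +-25% around
    the defaults; the drive current is kept low so the normalized viscous
    resistance M* stays well below 1e-3.
    """
    s = lambda: rng.uniform(0.8, 1.25)
    membrane = pump.MembraneSpec(
        radius_R0=1.2e-3 * s(), modulus_E=4e6 * s(), thickness_h=150e-6 * s()
    )
    system = pump.PumpSystem(
        channel=pump.ChannelGeometry(side_a=30e-6 * s(), length_L=7e-3 * s()),
        membrane=membrane,
        reservoir_volume=5e-9,
    )
    current = rng.uniform(2e-6, 1e-5)
    return system, current
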