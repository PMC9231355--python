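import numpy as np
import pytest

from dosestab import DoseGrid, PhantomSettings, RoiMask, generate_patient


@pytest.fixture(scope="session")
def default_patient():
    """One default 64^3 virtual patient, shared across tests."""
    return generate_patient(PhantomSettings(seed=42))


@pytest.fixture(scope="session")
def small_patient():
    """A smaller, faster phantom for pipeline-level tests."""
    settings = PhantomSettings(
        shape=(48, 48, 48),
        gtv_radius_mm=10.0,
        seed=7,
    )
    return generate_patient(settings)


@pytest.fixture()
def toy_pair():
    """A tiny 4x4x2 dose/mask pair with a fixed integer-ish pattern."""
    dose = np.array(
        [
            [[5.2, 2.1], [5.8, 4.4], [3.3, 3.9], [1.2, 0.4]],
            [[2.5, 2.9], [5.1, 1.7], [0.9, 6.1], [2.8, 6.6]],
            [[4.1, 4.9], [6.8, 2.2], [2.4, 4.8], [6.3, 0.2]],
            [[3.7, 5.5], [5.9, 1.1], [4.2, 3.0], [1.5, 2.6]],
        ]
    )
    mask = np.ones(dose.shape, dtype=bool)
    mask[0, 3, 1] = False
    mask[2, 1, 0] = False
    grid = DoseGrid(dose, spacing=(2.0, 2.0, 3.0))
    roi = RoiMask(mask, "GTV", spacing=(2.0, 2.0, 3.0))
    return grid, roi
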