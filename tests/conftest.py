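import numpy as np
import pytest

from ringorder import CrystalSpec, WaterFrame, build_oxygen_lattice, make_ice

OH = 0.9572


def water_pair(r_oo: float, angle_deg: float, box: float = 30.0) -> WaterFrame:
    """Two waters: donor's first O-H makes ``angle_deg`` with the O-O axis.

    Remaining hydrogens point away from the partner so only the constructed
    bond can register.
    """
    o1 = np.array([10.0, 10.0, 10.0])
    o2 = o1 + [r_oo, 0.0, 0.0]
    a = np.radians(angle_deg)
    h1a = o1 + OH * np.array([np.cos(a), np.sin(a), 0.0])
    h1b = o1 + OH * np.array([-0.3, -0.8, -0.52])  # points away
    h2a = o2 + OH * np.array([0.3, 0.8, 0.52])
    h2b = o2 + OH * np.array([0.52, -0.3, 0.8])
    return WaterFrame(
        np.array([o1, o2]),
        np.array([[h1a, h1b], [h2a, h2b]]),
        np.array([box, box, box]),
    )


@pytest.fixture(scope="session")
def ih_small():
    """Proton-disordered ice Ih, 128 waters."""
    return make_ice(CrystalSpec("Ih", (4, 2, 2), seed=11))


@pytest.fixture(scope="session")
def ic_small():
    """Proton-disordered ice Ic, 216 waters."""
    return make_ice(CrystalSpec("Ic", (3, 3, 3), seed=7))


@pytest.fixture(scope="session")
def vii_small():
    """Proton-disordered ice VII, 128 waters."""
    return make_ice(CrystalSpec("VII", (2, 2, 2), seed=3))


@pytest.fixture(scope="session")
def ih_oxygens():
    return build_oxygen_lattice(CrystalSpec("Ih", (4, 2, 2)))
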