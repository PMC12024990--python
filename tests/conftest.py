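import numpy as np
import pytest

from nanodiff.geometry import GeometrySpec, Label, PorousLattice, generate_ecm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_ecm():
    """One reusable 30^3 fiber network at porosity 0.95."""
    spec = GeometrySpec(
        domain_kind="ecm", shape=(30, 30, 30), spacing=50e-9,
        target_porosity=0.95, seed=7,
    )
    return generate_ecm(spec)


@pytest.fixture()
def empty_lattice():
    """All-fluid 16^3 lattice with 50 nm spacing."""
    return PorousLattice(np.zeros((16, 16, 16), dtype=np.uint8), 50e-9)


@pytest.fixture()
def channel_lattice():
    """Slit channel: solid walls on the y-faces, periodic elsewhere."""
    occ = np.zeros((4, 21, 4), dtype=np.uint8)
    occ[:, 0, :] = Label.FIBER
    occ[:, -1, :] = Label.FIBER
    return PorousLattice(occ, 1.0)
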