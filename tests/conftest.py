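import numpy as np
import pytest

from mpslab import (
    FixtureSpec,
    MembraneGeometry,
    build_bundle,
    build_dimer,
    build_helix,
    detect_spans,
)
from mpslab.core import RigidTransform, rotation_about_axis


@pytest.fixture(scope="session")
def geom():
    return MembraneGeometry()


@pytest.fixture(scope="session")
def helix21():
    """Ideal 21-residue poly-A transmembrane helix, axis +z, centered."""
    return build_helix(FixtureSpec(n_res=21))


@pytest.fixture(scope="session")
def helix_polyL():
    return build_helix(FixtureSpec(n_res=21, sequence="L" * 21))


@pytest.fixture(scope="session")
def helix_topology(helix21, geom):
    return detect_spans(helix21, geom)


@pytest.fixture(scope="session")
def dimer_native():
    """Polished groove-docking fixture (chains A, C fixed; B moving)."""
    return build_dimer(FixtureSpec(kind="dimer"))


@pytest.fixture(scope="session")
def bundle_c4_native():
    """Polished C4 poly-A bundle, the symmetric-assembly native."""
    return build_bundle(FixtureSpec(kind="bundle", n_helices=4, radius=5.4))


def random_rigid_transform(rng: np.random.Generator) -> RigidTransform:
    axis = rng.normal(size=3)
    angle = rng.uniform(0, 2 * np.pi)
    R = rotation_about_axis(axis, angle)
    t = rng.normal(scale=20.0, size=3)
    return RigidTransform(R, t)
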