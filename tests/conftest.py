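import numpy as np
import pytest

from jawlever import JawGeometry, reference


@pytest.fixture(scope="session")
def constants():
    return reference.REFERENCE_CONSTANTS


@pytest.fixture(scope="session")
def arch_m2851():
    return reference.architecture_records("M2851")


@pytest.fixture(scope="session")
def arch_m1496():
    return reference.architecture_records("M1496")


@pytest.fixture(scope="session")
def planar_m2851():
    return reference.planar_model_m2851()


@pytest.fixture(scope="session")
def ref_geometry():
    return reference.reference_geometry()


@pytest.fixture(scope="session")
def ref_forces(planar_m2851):
    return {pm.muscle: pm.f3dmax for pm in planar_m2851.muscles}


def random_landmark_geometry(rng: np.random.Generator, n_muscles: int = 5):
    """A random, non-degenerate landmark set with at least one jaw closer."""
    from jawlever import derive_action_line

    while True:
        condyle = rng.uniform(-5, 5, 3)
        origins, insertions = {}, {}
        for i in range(n_muscles):
            name = f"mu{i}"
            insertions[name] = condyle + rng.uniform(-10, 10, 3)
            origins[name] = insertions[name] + rng.uniform(-10, 10, 3)
        bite = {"bp": condyle + np.r_[rng.uniform(5, 25), rng.uniform(-5, 5), 0.0]}
        try:
            geom = JawGeometry(condyle, origins, insertions, bite)
            lines = [derive_action_line(geom, m) for m in geom.muscles]
        except Exception:
            continue
        if any(line.moment_sign < 0 for line in lines):
            return geom
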