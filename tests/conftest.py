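import numpy as np
import pytest

from reachvigor import biomech, constants


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def arm():
    """Reference arm for a 70 kg, 1.75 m adult."""
    return biomech.build_arm_model(70.0, 1.75)


@pytest.fixture(scope="session")
def printed_metabolic():
    return constants.METABOLIC_PARAMS


def random_arm(rng) -> biomech.ArmModel:
    """A random physically plausible arm, for property tests."""
    l1 = rng.uniform(0.25, 0.40)
    l2 = rng.uniform(0.25, 0.45)
    m1 = rng.uniform(1.0, 3.0)
    m2 = rng.uniform(0.8, 2.5)
    return biomech.ArmModel(
        l1=l1,
        l2=l2,
        m1=m1,
        m2=m2,
        r1=rng.uniform(0.3, 0.6) * l1,
        r2=rng.uniform(0.3, 0.6) * l2,
        I_com1=m1 * (rng.uniform(0.2, 0.4) * l1) ** 2,
        I_com2=m2 * (rng.uniform(0.2, 0.5) * l2) ** 2,
    )


def random_posture(rng) -> biomech.Posture:
    return biomech.Posture(
        theta_s=rng.uniform(-np.pi / 2, np.pi),
        theta_e=rng.uniform(0.2, np.pi - 0.2),
    )
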