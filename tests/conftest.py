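import numpy as np
import pytest

from kctree.data import KCStudy, MeasurementResult
from kctree.fixtures import fixture


@pytest.fixture(scope="session")
def k45():
    return fixture("K45")


@pytest.fixture(scope="session")
def k145_zn():
    return fixture("K145_Zn")


@pytest.fixture(scope="session")
def k145_ni():
    return fixture("K145_Ni")


@pytest.fixture(scope="session")
def k88_all():
    return fixture("K88").including_all()


@pytest.fixture(scope="session")
def k30():
    return fixture("K30_1")


@pytest.fixture(scope="session")
def sr90():
    return fixture("Sr90")


@pytest.fixture(scope="session")
def ccem():
    return fixture("CCEM_RF_K25W")


@pytest.fixture(scope="session")
def zn65():
    return fixture("Zn65")


def make_study(x, u, dof=None, include=None, name="toy", unit="a.u."):
    """Small helper to assemble ad-hoc studies in tests."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    n = len(x)
    dof = [float("inf")] * n if dof is None else dof
    include = [True] * n if include is None else include
    return KCStudy(
        name,
        unit,
        tuple(
            MeasurementResult(f"L{j}", x[j], u[j], dof[j], include[j])
            for j in range(n)
        ),
    )


@pytest.fixture
def toy_study():
    return make_study([10.0, 10.5, 9.8, 10.2, 10.1], [0.3, 0.4, 0.2, 0.5, 0.3])
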