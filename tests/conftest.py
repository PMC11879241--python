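import numpy as np
import pytest

import ddgforge as dg


@pytest.fixture(scope="session")
def params_by_version():
    return {v: dg.get_params(v) for v in dg.VERSIONS}


@pytest.fixture(scope="session")
def ctx():
    return dg.PHContext()


@pytest.fixture(scope="session")
def helix_ser():
    return dg.make_helix_peptide(10, ncap_aa="SER")


@pytest.fixture(scope="session")
def helix_ala():
    return dg.make_helix_peptide(10, ncap_aa="ALA")


@pytest.fixture(scope="session")
def bundle():
    from ddgforge.fixtures import make_helix_bundle

    return make_helix_bundle()


@pytest.fixture(scope="session")
def salt_bridge():
    return dg.make_salt_bridge()


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
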