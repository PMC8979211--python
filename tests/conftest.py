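import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from geudplan.dose import DoseCorrelationMatrix, MixedFieldTable, PhotonResponse
from geudplan.phantom import (
    VOIMask,
    build_dose_matrix,
    build_phantom,
    build_radiosensitivity,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def single_gland():
    """single_gland phantom with its dose matrix and default tables."""
    phantom = build_phantom("single_gland", 42)
    matrix = build_dose_matrix(phantom)
    table = build_radiosensitivity(phantom, matrix)
    return phantom, matrix, table


@pytest.fixture(scope="session")
def two_glands():
    phantom = build_phantom("two_glands_multi_oar", 7)
    matrix = build_dose_matrix(phantom)
    table = build_radiosensitivity(phantom, matrix)
    return phantom, matrix, table


def random_instance(seed, n_voxels=8, n_spots=5, density=0.9, photon=None):
    """Small random dose matrix + radiosensitivity tables + target/OAR
    split, for gradient and stepsize oracles."""
    rng = np.random.default_rng(seed)
    d = sp.random(
        n_voxels,
        n_spots,
        density=density,
        random_state=int(rng.integers(2**31)),
        data_rvs=lambda n: rng.uniform(0.1, 1.0, n),
    ).tocsr()
    matrix = DoseCorrelationMatrix(d=d)
    alpha = d.copy()
    alpha.data = rng.uniform(0.1, 0.4, d.nnz)
    sqrt_beta = d.copy()
    sqrt_beta.data = np.full(d.nnz, np.sqrt(0.05))
    table = MixedFieldTable(
        alpha=alpha, sqrt_beta=sqrt_beta, photon=PhotonResponse(0.1, 0.05, 30.0)
    )
    half = n_voxels // 2
    target = VOIMask("t", "target", np.arange(half))
    oar = VOIMask("o", "oar", np.arange(half, n_voxels))
    return matrix, table, target, oar, rng
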