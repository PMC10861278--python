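import numpy as np
import pytest

from ftactd.dwi_model import eigendecompose, fit_tensor
from ftactd.phantom import (
    PhantomSpec,
    default_gradient_table,
    make_tensor_field,
    simulate_dwi,
)


@pytest.fixture(scope="session")
def gtab():
    return default_gradient_table()


@pytest.fixture(scope="session")
def straight_field():
    """Noiseless straight-bundle phantom: (tensor field, mask, ground truth)."""
    return make_tensor_field(PhantomSpec(geometry="straight"))


@pytest.fixture(scope="session")
def crossing_field():
    """Noiseless 60-degree crossing phantom."""
    return make_tensor_field(PhantomSpec(geometry="crossing", crossing_angle=60.0))


@pytest.fixture(scope="session")
def curved_field():
    """Noiseless quarter-arc phantom."""
    return make_tensor_field(PhantomSpec(geometry="curved"))


@pytest.fixture(scope="session")
def straight_fit(straight_field, gtab):
    """Tensor field re-estimated from the noiseless straight phantom's DWI."""
    tensors, mask, gt = straight_field
    dwi = simulate_dwi(tensors, gtab)
    fitted = fit_tensor(dwi, gtab, mask)
    return fitted, mask, gt


def random_spd_tensors(rng, n, scale=1e-3):
    """Random symmetric positive-definite diffusion-like tensors, (n, 3, 3)."""
    evals = rng.uniform(0.1, 2.5, (n, 3)) * scale
    a = rng.standard_normal((n, 3, 3))
    q, _ = np.linalg.qr(a)
    return np.einsum("nij,nj,nkj->nik", q, evals, q)
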