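import numpy as np
import pandas as pd
import pytest

from melsdiag.data import LongDataset
from melsdiag.model import MELSModel, MELSParams


def make_mels_data(
    n_subjects=5,
    n_obs=50,
    beta=(1.0, 0.5),
    tau=(0.2, 0.3),
    var_nu=4.0,
    var_omega=0.5,
    cov_nuomega=0.3,
    seed=0,
):
    """Small MELS dataset with a continuous covariate, no truncation."""
    rng = np.random.default_rng(seed)
    cov = np.array([[var_nu, cov_nuomega], [cov_nuomega, var_omega]])
    eff = rng.multivariate_normal([0.0, 0.0], cov, size=n_subjects)
    frames = []
    for i in range(n_subjects):
        nu, om = eff[i]
        x = rng.normal(0.0, 1.0, n_obs)
        sd = np.sqrt(np.exp(tau[0] + om + tau[1] * x))
        y = beta[0] + nu + beta[1] * x + rng.standard_normal(n_obs) * sd
        frames.append(pd.DataFrame({"subject": f"s{i}", "x": x, "y": y}))
    return LongDataset(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def small_data():
    return make_mels_data(n_subjects=5, n_obs=50, seed=1)


@pytest.fixture(scope="session")
def small_model(small_data):
    return MELSModel.from_dataset(small_data, location=["x"], scale=["x"])


@pytest.fixture(scope="session")
def small_fit(small_model):
    res = small_model.fit()
    assert res.converged
    return res


@pytest.fixture(scope="session")
def true_params():
    return MELSParams(
        np.array([1.0, 0.5]), np.array([0.2, 0.3]), 4.0, 0.5, 0.3
    )
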