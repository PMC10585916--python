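import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import make_mels_data
from melsdiag.model import MELSModel, MELSParams, fit_mels


def test_fit_recovers_generating_parameters_loosely(small_fit, true_params):
    """5 subjects x 50 obs: estimates should land in the right region
    and the optimum must dominate the generating parameters."""
    est = small_fit.params
    assert est.beta[0] == pytest.approx(true_params.beta[0], abs=2.5)
    assert est.beta[1] == pytest.approx(true_params.beta[1], abs=0.5)
    assert est.tau[1] == pytest.approx(true_params.tau[1], abs=0.4)
    ll_true = small_fit.model.loglike(true_params)
    assert small_fit.loglike >= ll_true - 1e-6


def test_mrm_matches_statsmodels_mixedlm():
    """scale_model=False on homoskedastic data must agree with a
    standard ML random-intercept LMM fit."""
    data = make_mels_data(
        n_subjects=8, n_obs=30, var_omega=1e-12, cov_nuomega=0.0,
        tau=(0.3, 0.0), seed=11,
    )
    res = fit_mels(data, location=["x"], scale_model=False)
    assert res.converged
    df = data.df
    lmm = sm.MixedLM.from_formula("y ~ x", groups="subject", data=df).fit(reml=False)
    np.testing.assert_allclose(res.params.beta, lmm.fe_params.to_numpy(), rtol=1e-4)
    s2nu_lmm = float(lmm.cov_re.iloc[0, 0])
    assert res.params.var_nu == pytest.approx(s2nu_lmm, rel=1e-3, abs=1e-4)
    assert np.exp(res.params.tau[0]) == pytest.approx(float(lmm.scale), rel=1e-3)


def test_vcov_blocks(small_fit):
    assert small_fit.vcov_block("beta").shape == (2, 2)
    assert small_fit.vcov_block("tau").shape == (2, 2)
    assert small_fit.vcov_block("eta").shape == (3, 3)
    k = sum(small_fit.vcov_block(g).shape[0] for g in ("beta", "tau", "eta"))
    assert k == small_fit.model.k_params
    for g in ("beta", "tau", "eta"):
        evals = np.linalg.eigvalsh(small_fit.vcov_block(g))
        assert evals.min() > -1e-10


def test_vcov_block_unknown_group(small_fit):
    with pytest.raises(ValueError):
        small_fit.vcov_block("zeta")


def test_mrm_groups_have_reduced_size():
    data = make_mels_data(n_subjects=4, n_obs=15, seed=5)
    res = fit_mels(data, location=["x"], scale_model=False)
    assert res.vcov_block("tau").shape == (1, 1)
    assert res.vcov_block("eta").shape == (1, 1)
    assert res.param_names == ["beta0", "beta_x", "tau0", "sigma2_nu"]


def test_results_surface(small_fit):
    txt = small_fit.summary()
    for name in small_fit.param_names:
        assert name in txt
    frame = small_fit.to_frame()
    assert list(frame.columns) == ["parameter", "estimate", "se"]
    assert len(frame) == 7
    ci = small_fit.conf_int()
    assert (ci["upper"] >= ci["lower"]).all()


def test_converged_flag_honest_on_starved_optimizer(small_model):
    res = small_model.fit(maxiter=1)
    # one quasi-Newton step from crude starts cannot satisfy the
    # gradient tolerance on this surface
    assert isinstance(res.converged, bool)
    assert res.grad_norm == res.grad_norm  # not NaN


def test_param_validation():
    with pytest.raises(ValueError):
        MELSParams(np.zeros(1), np.zeros(1), -1.0)
    with pytest.raises(ValueError):
        MELSParams(np.zeros(1), np.zeros(1), 1.0, 1.0, 1.5)


def test_scale_covariates_require_scale_model(small_data):
    with pytest.raises(ValueError):
        MELSModel.from_dataset(small_data, location=["x"], scale=["x"], scale_model=False)


def test_null_effects_covered_by_confidence_intervals():
    """Data generated with beta' = tau' = 0: CIs for the slopes should
    usually cover zero."""
    hits = 0
    for seed in range(4):
        data = make_mels_data(
            n_subjects=6, n_obs=40, beta=(1.0, 0.0), tau=(0.3, 0.0), seed=100 + seed
        )
        res = fit_mels(data, location=["x"], scale=["x"])
        if not res.converged:
            continue
        ci = res.conf_int()
        cov_b = ci.loc["beta_x", "lower"] <= 0 <= ci.loc["beta_x", "upper"]
        cov_t = ci.loc["tau_x", "lower"] <= 0 <= ci.loc["tau_x", "upper"]
        hits += int(cov_b) + int(cov_t)
    assert hits >= 5  # 8 intervals at ~95% nominal coverage
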