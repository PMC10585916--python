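import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_mels_data
from melsdiag.influence import (
    MELSInfluence,
    cooks_distance,
    covratio,
    covtrace,
    dfbetas,
    fdr_adjust,
    influence_table,
    lr_statistic,
)
from melsdiag.loo import LOOResults, fit_all_loo
from melsdiag.model import fit_mels


def test_lr_statistic_arithmetic():
    assert lr_statistic(-1000.0, -1000.0) == 0.0
    assert lr_statistic(-1000.0, -997.3) == pytest.approx(5.4)
    assert lr_statistic(-1000.0, -1000.1) == 0.0  # clamped


def test_fdr_adjust_bh_arithmetic():
    q, rej = fdr_adjust(np.array([0.01, 0.02, 0.03]), q=0.05)
    np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
    assert rej.all()
    q, rej = fdr_adjust(np.ones(5), q=0.05)
    assert not rej.any()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30))
def test_fdr_qvalues_monotone_in_p(pvals):
    q, _ = fdr_adjust(np.array(pvals), q=0.05)
    order = np.argsort(pvals)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_cooks_distance_values():
    c, ill = cooks_distance([1.0, 2.0], [1.0, 2.0], np.eye(2), 2)
    assert c == 0.0 and not ill
    c, _ = cooks_distance([1.0, 2.0], [0.9, 2.1], np.eye(2), 2)
    assert c == pytest.approx(0.01)


def test_cooks_distance_singular_uses_pinv():
    c, ill = cooks_distance([1.0, 2.0], [0.5, 2.0], np.zeros((2, 2)), 2)
    assert ill and c == 0.0


def test_dfbetas_values():
    assert dfbetas(1.0, 1.0, 0.1) == 0.0
    assert dfbetas(1.0, 0.8, 0.1) == pytest.approx(2.0)
    assert np.isnan(dfbetas(1.0, 0.8, 0.0))


def test_covtrace_values():
    v, ill = covtrace(np.eye(2), np.eye(2), 2)
    assert v == 0.0 and not ill
    v, _ = covtrace(np.diag([1.0, 1.0]), np.diag([2.0, 3.0]), 2)
    assert v == pytest.approx(3.0)
    # 1-D specialization: |sigma2_loo / sigma2 - 1|
    v, _ = covtrace(np.array([[2.0]]), np.array([[3.0]]), 1)
    assert v == pytest.approx(0.5)


def test_covratio_values():
    assert covratio(np.eye(2), np.eye(2)) == pytest.approx(1.0)
    assert covratio(np.diag([2.0, 2.0]), np.diag([1.0, 1.0])) == pytest.approx(0.25)
    assert np.isnan(covratio(np.diag([0.0, 1.0]), np.eye(2)))


def test_zero_influence_identities(small_fit):
    """A leave-one-out fit identical to the baseline must yield exactly
    neutral influence measures."""
    fake = LOOResults(
        target=small_fit.model.subject_ids[0],
        results=small_fit,
        c_star=0.0,
        d_star=0.0,
    )
    table = influence_table(small_fit, [fake], q=0.05)
    row = table.iloc[0]
    assert row["LR"] == pytest.approx(0.0, abs=1e-10)
    for g in ("beta", "tau", "eta"):
        assert row[f"C_{g}"] == pytest.approx(0.0, abs=1e-10)
        assert row[f"COVTRACE_{g}"] == pytest.approx(0.0, abs=1e-10)
        assert row[f"COVRATIO_{g}"] == pytest.approx(1.0, abs=1e-10)
    for name in small_fit.param_names:
        assert row[f"DFBETAS_{name}"] == pytest.approx(0.0, abs=1e-10)


def test_influence_table_structure_and_flags(small_model, small_fit):
    loos = fit_all_loo(small_model, small_fit)
    table = influence_table(small_fit, loos, q=0.05)
    N = small_model.n_subjects
    assert len(table) == N
    dfb_cols = [c for c in table.columns if c.startswith("DFBETAS_")]
    assert len(dfb_cols) == small_model.k_params
    # flags consistent with the rule-of-thumb cutoffs
    assert (
        table["flag_C_tau"]
        == table["C_tau"].gt(4.0 / N).fillna(False)
    ).all()
    assert (
        table["flag_DFBETAS_tau0"]
        == table["DFBETAS_tau0"].abs().gt(2.0 / np.sqrt(N)).fillna(False)
    ).all()
    r = 2
    out = (table["COVRATIO_tau"] < 1 - 3 * r / N) | (table["COVRATIO_tau"] > 1 + 3 * r / N)
    assert (table["flag_COVRATIO_tau"] == out.fillna(False)).all()
    # positivity invariants on converged rows
    conv = table["converged"].astype(bool)
    assert (table.loc[conv, ["C_beta", "C_tau", "C_eta"]] >= 0).all().all()
    assert (table.loc[conv, "COVRATIO_beta"] > 0).all()
    # q-values respect the step-up ordering of raw p-values
    srt = table.dropna(subset=["p_value"]).sort_values("p_value")
    assert (np.diff(srt["q_value"]) >= -1e-12).all()


def test_mrm_mode_table_has_no_scale_measures():
    data = make_mels_data(n_subjects=5, n_obs=20, seed=13)
    res = fit_mels(data, location=["x"], scale_model=False)
    infl = MELSInfluence.from_results(res)
    cols = infl.table.columns
    assert "C_tau" not in cols and "COVRATIO_tau" not in cols
    assert "DFBETAS_tau0" not in cols
    assert "C_beta" in cols and "DFBETAS_sigma2_nu" in cols


def test_influence_summary_mentions_significant_subjects():
    cfg_data = make_mels_data(n_subjects=5, n_obs=25, seed=3)
    res = fit_mels(cfg_data, location=["x"], scale=["x"])
    infl = MELSInfluence.from_results(res)
    txt = infl.summary()
    assert "leave-one-out" in txt
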