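import numpy as np
import pytest
from scipy import stats

from melsdiag.simulate import (
    ScenarioConfig,
    gen_scenario1,
    gen_scenario2,
    run_detection_study,
    scenario_config,
)


def test_scenario1_careless_pattern_and_truncation():
    cfg = scenario_config(1, n_subjects=6, n_obs=40, n_influential=1, seed=7,
                          standardize=False)
    data, labels = gen_scenario1(cfg)
    assert labels == [1]
    df = data.df
    s1 = df[df["subject"] == 1]
    assert set(s1["y"]) == {150.0, 155.0}
    assert set(s1["x"]) == {3.0, 4.0}
    # every response value occurs at both covariate values (no exact
    # collinearity, which would degenerate the likelihood)
    assert len(set(zip(s1["x"], s1["y"]))) == 4
    assert (df["y"] >= 0).all()


def test_scenario1_standardization_pooled():
    cfg = scenario_config(1, n_subjects=6, n_obs=40, n_influential=1, seed=7)
    data, _ = gen_scenario1(cfg)
    x = data.covariate("x")
    assert abs(x.mean()) < 1e-10
    assert abs(x.std(ddof=1) - 1.0) < 1e-10
    assert "x" in data.standardizations


def test_scenario1_moments_match_generating_model():
    """Untruncated scenario-1 draws: empirical moments of regular
    subjects against moments computed by numerical integration."""
    cfg = scenario_config(1, n_subjects=40, n_obs=200, seed=13,
                          standardize=False, truncate=False)
    data, _ = gen_scenario1(cfg)
    y = data.y
    # E|N(3,1)| and E[x^2] for the folded normal covariate
    ex = 3.0 * (1 - 2 * stats.norm.cdf(-3.0)) + 2 * stats.norm.pdf(3.0)
    ex2 = 10.0  # E[N(3,1)^2]
    mean_y = 100.0 + 10.0 * ex
    # Var(y) = 100 Var(x) + var_nu + E[exp(7 + omega + 0.5 x)]
    e_exp_x = np.mean(np.exp(0.5 * np.abs(np.random.default_rng(0).normal(3, 1, 200000))))
    var_y = 100.0 * (ex2 - ex**2) + 20.09 + np.exp(7.0 + 0.5) * e_exp_x
    assert y.mean() == pytest.approx(mean_y, rel=0.02)
    assert y.var() == pytest.approx(var_y, rel=0.15)


def test_scenario2_structure_and_consistent_subject():
    cfg = scenario_config(2, n_subjects=6, n_obs=10, n_influential=1, seed=3)
    data, labels = gen_scenario2(cfg)
    df = data.df
    assert set(df["x"]) == set(float(k) for k in range(8))
    assert (df.groupby("subject").size() <= 80).all()
    # influential subject's within-period variance ~ exp(0.6 x); a
    # regular subject's ~ exp(3 + omega + 0.6 x): ratio ~ e^3
    v_inf = df[df["subject"] == 1].groupby("x")["y"].var()
    v_reg = df[df["subject"] != 1].groupby(["subject", "x"])["y"].var().groupby("x").mean()
    log_ratio = np.log(v_reg / v_inf).mean()
    assert log_ratio == pytest.approx(3.0, abs=1.2)


@pytest.mark.parametrize("scenario", [1, 2])
def test_generators_seed_deterministic(scenario):
    cfg = scenario_config(scenario, n_subjects=4, n_obs=12, n_influential=1, seed=42)
    gen = gen_scenario1 if scenario == 1 else gen_scenario2
    d1, l1 = gen(cfg)
    d2, l2 = gen(cfg)
    assert l1 == l2
    assert d1.df.equals(d2.df)


def test_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(scenario=3)
    with pytest.raises(ValueError):
        ScenarioConfig(scenario=1, n_subjects=2, n_influential=2)


def test_detection_study_structure_and_determinism():
    cfg = scenario_config(2, n_subjects=6, n_obs=5, n_influential=1, seed=0)
    s1 = run_detection_study(cfg, n_reps=2, mode="MELS", base_seed=11)
    s2 = run_detection_study(cfg, n_reps=2, mode="MELS", base_seed=11)
    assert s1.attempted == 2
    assert s1.excluded + s1.included == 2
    assert s1.table.equals(s2.table)
    assert ((s1.table >= 0) & (s1.table <= 100)).all().all()
    assert "COVRATIO_tau" in s1.table.index


def test_detection_study_mrm_mode_lacks_scale_measures():
    cfg = scenario_config(2, n_subjects=6, n_obs=5, n_influential=1, seed=0)
    s = run_detection_study(cfg, n_reps=2, mode="MRM", base_seed=11)
    assert not any(m.endswith("_tau") for m in s.table.index)
    assert "DFBETAS_sigma2_nu" in s.table.index


def test_detection_study_rejects_bad_args():
    cfg = scenario_config(2, n_subjects=6, n_obs=5, seed=0)
    with pytest.raises(ValueError):
        run_detection_study(cfg, n_reps=0)
    with pytest.raises(ValueError):
        run_detection_study(cfg, n_reps=1, mode="nope")
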