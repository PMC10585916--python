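"""Synthetic intensive-longitudinal data and the detection study.

Two scenarios emulate daily physical-activity minutes (negative draws
are removed):

Scenario 1 — continuous covariate (portions of fiber intake),
x ~ |N(3, 1)|, generated from

    y = 100 + nu + 10 x + eps,   Var(eps) = exp(7 + omega + 0.5 x),
    (nu, omega) ~ N2(0, [[20.09, 0.45], [0.45, 1]]).

Careless responders are injected by replacing all of a designated
subject's rows with responses alternating 150/155 paired with
covariates 3/4 (before the pooled standardization of the covariate),
i.e. near-zero within-subject variability.

Scenario 2 — discrete time periods x in 0..7, a fixed number of
observations per period, generated from

    y = 100 + nu + 15 x + eps,   Var(eps) = exp(3 + omega + 0.6 x),
    (nu, omega) ~ N2(0, [[20.09, 0.22], [0.22, 0.25]]).

Exceptionally consistent subjects are injected by zeroing the scale
intercept (tau_0 -> 0 and omega = 0), leaving the location side
untouched; the covariate is not standardized.

The detection study generates replicate datasets, fits the baseline
model and every leave-one-out model, excludes replicates with any
non-converged fit, and records per influence measure how often the
designated subject(s) attain the extreme rank (all k designated
subjects among the top/bottom k).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import LongDataset, standardize_covariate
from .influence import influence_table
from .loo import fit_all_loo
from .model import MELSModel, MELSParams

__all__ = [
    "ScenarioConfig",
    "scenario_config",
    "gen_scenario1",
    "gen_scenario2",
    "generate",
    "run_detection_study",
    "SimulationSummary",
]

_S1_PARAMS = dict(beta=(100.0, 10.0), tau=(7.0, 0.5), var_nu=20.09, var_omega=1.0, cov_nuomega=0.45)
_S2_PARAMS = dict(beta=(100.0, 15.0), tau=(3.0, 0.6), var_nu=20.09, var_omega=0.25, cov_nuomega=0.22)


@dataclass
class ScenarioConfig:
    """Generating configuration for one simulation scenario."""

    scenario: int
    n_subjects: int = 50
    n_obs: int = 500  # scenario 1: obs per subject; scenario 2: per period
    n_periods: int = 8  # scenario 2 only
    params: MELSParams = field(default=None)  # type: ignore[assignment]
    n_influential: int = 0
    seed: int = 0
    standardize: bool | None = None  # default: scenario 1 yes, scenario 2 no
    truncate: bool = True  # remove negative responses

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.params is None:
            d = _S1_PARAMS if self.scenario == 1 else _S2_PARAMS
            self.params = MELSParams(
                np.array(d["beta"]), np.array(d["tau"]),
                d["var_nu"], d["var_omega"], d["cov_nuomega"],
            )
        if self.standardize is None:
            self.standardize = self.scenario == 1
        if not self.n_influential < self.n_subjects:
            raise ValueError("n_influential must be < n_subjects")


def scenario_config(scenario: int, scaled: bool = False, **overrides) -> ScenarioConfig:
    """Full-scale defaults (50 subjects, 500 obs / 25 per period), or a
    reduced desk-scale configuration (20 subjects, 100 obs / 13 per
    period) suitable for repeated replication."""
    base: dict = {"scenario": scenario}
    if scaled:
        base.update(
            {"n_subjects": 20, "n_obs": 100 if scenario == 1 else 13}
        )
    elif scenario == 2:
        base["n_obs"] = 25
    base.update(overrides)
    return ScenarioConfig(**base)


def _draw_effects(rng: np.random.Generator, p: MELSParams, n: int) -> np.ndarray:
    cov = np.array([[p.var_nu, p.cov_nuomega], [p.cov_nuomega, p.var_omega]])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    return rng.standard_normal((n, 2)) @ L.T


def gen_scenario1(config: ScenarioConfig) -> tuple[LongDataset, list[int]]:
    """Scenario-1 dataset plus the designated influential subject ids.

    Influential subjects (ids 1..n_influential) have all rows replaced
    by the careless pattern before standardization; rows with negative
    responses are removed; the covariate is then standardized pooled
    over all retained observations (``config.standardize``).
    """
    if config.scenario != 1:
        raise ValueError("config is not a scenario-1 config")
    rng = np.random.default_rng(config.seed)
    p = config.params
    N, n = config.n_subjects, config.n_obs
    eff = _draw_effects(rng, p, N)
    frames = []
    for i in range(N):
        nu, om = eff[i]
        x = np.abs(rng.normal(3.0, 1.0, size=n))
        sd = np.sqrt(np.exp(p.tau[0] + om + p.tau[1] * x))
        y = p.beta[0] + nu + p.beta[1] * x + rng.standard_normal(n) * sd
        if i < config.n_influential:
            # careless responder: answers cycle through 150/155 while the
            # covariate cycles through 3/4, balanced so each response
            # occurs at both covariate values.  The subject's variance is
            # tiny (~6) against a typical within-subject variance in the
            # thousands, but its responses are not an exact affine
            # function of the covariate: exact collinearity would make
            # the location-scale likelihood degenerate (unbounded).
            j = np.arange(n)
            x = 3.0 + (j % 2)
            y = 150.0 + 5.0 * ((j // 2) % 2)
        keep = y >= 0 if config.truncate else np.ones(n, dtype=bool)
        frames.append(pd.DataFrame({"subject": i + 1, "x": x[keep], "y": y[keep]}))
    df = pd.concat(frames, ignore_index=True)
    data = LongDataset(df, subject_col="subject", response_col="y")
    if config.standardize:
        data, _ = standardize_covariate(data, "x")
    return data, list(range(1, config.n_influential + 1))


def gen_scenario2(config: ScenarioConfig) -> tuple[LongDataset, list[int]]:
    """Scenario-2 dataset plus the designated influential subject ids.

    Influential subjects keep their location model but are generated
    with a scale-model intercept of 0 (tau_0 -> 0, omega = 0): their
    within-subject variance is exp(0.6 x) instead of exp(3 + omega +
    0.6 x).  The covariate (time period 0..7) is not standardized.
    """
    if config.scenario != 2:
        raise ValueError("config is not a scenario-2 config")
    rng = np.random.default_rng(config.seed)
    p = config.params
    N = config.n_subjects
    x = np.repeat(np.arange(config.n_periods, dtype=float), config.n_obs)
    n = x.size
    eff = _draw_effects(rng, p, N)
    frames = []
    for i in range(N):
        nu, om = eff[i]
        tau0 = p.tau[0]
        if i < config.n_influential:
            tau0, om = 0.0, 0.0
        sd = np.sqrt(np.exp(tau0 + om + p.tau[1] * x))
        y = p.beta[0] + nu + p.beta[1] * x + rng.standard_normal(n) * sd
        keep = y >= 0 if config.truncate else np.ones(n, dtype=bool)
        frames.append(pd.DataFrame({"subject": i + 1, "x": x[keep], "y": y[keep]}))
    df = pd.concat(frames, ignore_index=True)
    data = LongDataset(df, subject_col="subject", response_col="y")
    if config.standardize:
        data, _ = standardize_covariate(data, "x")
    return data, list(range(1, config.n_influential + 1))


def generate(config: ScenarioConfig) -> tuple[LongDataset, list[int]]:
    return gen_scenario1(config) if config.scenario == 1 else gen_scenario2(config)


@dataclass
class SimulationSummary:
    """Detection-rate summary over replicates (Table-3-style).

    ``table`` has one row per influence measure with the percentage of
    included replicates in which the designated subject(s) attain the
    largest / smallest values.
    """

    table: pd.DataFrame
    attempted: int
    excluded: int
    mode: str
    scenario: int
    n_influential: int
    base_seed: int
    excluded_seeds: list[int] = field(default_factory=list)

    @property
    def included(self) -> int:
        return self.attempted - self.excluded

    def rate(self, measure: str, side: str = "large") -> float:
        """Detection percentage for one measure ('large' or 'small')."""
        return float(self.table.loc[measure, f"{side}_pct"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _measure_columns(table: pd.DataFrame) -> list[str]:
    return [
        c
        for c in table.columns
        if c.startswith(("C_", "COVTRACE_", "COVRATIO_", "DFBETAS_"))
    ]


def _detect(table: pd.DataFrame, designated: list, col: str) -> tuple[bool, bool]:
    """Whether all designated subjects occupy the top-k / bottom-k ranks."""
    k = len(designated)
    vals = table.set_index("subject")[col]
    order = vals.sort_values()
    large = set(order.index[-k:]) == set(designated)
    small = set(order.index[:k]) == set(designated)
    return large, small


def run_detection_study(
    config: ScenarioConfig,
    n_reps: int,
    mode: str = "MELS",
    base_seed: int = 0,
    quad_points: int = 7,
) -> SimulationSummary:
    """Run the replicate study and summarize detection percentages.

    A replicate is excluded when the baseline or any leave-one-out fit
    fails to converge.  Replicate r uses seed ``base_seed + r`` so any
    single replicate can be re-run exactly.  For n_influential = 0 the
    first subject is tracked instead (its extreme-rank frequency should
    match 1/N by exchangeability).
    """
    if mode not in ("MELS", "MRM"):
        raise ValueError("mode must be 'MELS' or 'MRM'")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mels = mode == "MELS"
    counts_large: dict[str, int] = {}
    counts_small: dict[str, int] = {}
    excluded = 0
    excluded_seeds: list[int] = []
    for rep in range(n_reps):
        cfg = replace(config, seed=base_seed + rep)
        data, designated = generate(cfg)
        if not designated:
            designated = [data.subject_ids[0]]
        model = MELSModel.from_dataset(
            data,
            location=["x"],
            scale=["x"] if mels else None,
            scale_model=mels,
            quad_points=quad_points,
        )
        baseline = model.fit()
        ok = baseline.converged
        table = None
        if ok:
            loos = fit_all_loo(model, baseline, stop_on_failure=True)
            ok = len(loos) == model.n_subjects and all(l.converged for l in loos)
            if ok:
                table = influence_table(baseline, loos)
        if not ok:
            excluded += 1
            excluded_seeds.append(cfg.seed)
            continue
        for col in _measure_columns(table):
            large, small = _detect(table, designated, col)
            counts_large[col] = counts_large.get(col, 0) + int(large)
            counts_small[col] = counts_small.get(col, 0) + int(small)
    included = n_reps - excluded
    if included == 0:
        raise RuntimeError("no usable replicates: all runs failed to converge")
    measures = sorted(counts_large)
    table = pd.DataFrame(
        {
            "large_pct": [100.0 * counts_large[m] / included for m in measures],
            "small_pct": [100.0 * counts_small[m] / included for m in measures],
        },
        index=pd.Index(measures, name="measure"),
    )
    return SimulationSummary(
        table=table,
        attempted=n_reps,
        excluded=excluded,
        mode=mode,
        scenario=config.scenario,
        n_influential=config.n_influential,
        base_seed=base_seed,
        excluded_seeds=excluded_seeds,
    )
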