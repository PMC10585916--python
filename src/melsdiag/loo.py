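"""Leave-one-out MELS models.

To evaluate subject i*'s influence, the subject is not deleted from the
data.  Instead it is separated from level-2 estimation: an indicator
variable 1(i = i*) replaces both the fixed intercept and the
random-intercept loading for that subject, whose coefficient c_i* is a
subject-specific fixed location effect; the scale sub-model is treated
analogously with a subject-specific fixed scale effect d_i*.  The
time-varying covariate coefficients remain shared by all subjects, so
the baseline model is nested in each leave-one-out model (2 extra
parameters for a MELS model, 1 for an MRM, which has no scale effect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import MELSModel, MELSParams, MELSResults

logger = logging.getLogger(__name__)

__all__ = ["LOOResults", "make_loo_model", "fit_loo", "fit_all_loo"]


@dataclass
class LOOResults:
    """Augmented-model fit for one separated subject."""

    target: object  # subject id
    results: MELSResults
    c_star: float
    d_star: float | None  # None in MRM mode

    @property
    def converged(self) -> bool:
        return self.results.converged

    @property
    def loglike(self) -> float:
        return self.results.loglike


def make_loo_model(model: MELSModel, target) -> MELSModel:
    """Build the augmented design separating ``target`` from level 2.

    The location design's intercept column becomes 1(i != i*), a new
    trailing column 1(i = i*) carries c_i*; the scale design is
    augmented the same way with d_i* (full MELS mode only).  The target
    subject's random-effect loading is exactly zero.
    """
    if target not in model.subject_ids:
        raise KeyError(f"unknown subject id {target!r}")
    t_code = model.subject_ids.index(target)
    is_t = (model.codes == t_code).astype(float)
    not_t = 1.0 - is_t

    X = model.X.copy()
    X[:, 0] = not_t
    X = np.column_stack([X, is_t])
    xnames = model.xnames + ["c_star"]
    group_x = np.arange(model.X.shape[1])

    if model.scale_model:
        W = model.W.copy()
        W[:, 0] = not_t
        W = np.column_stack([W, is_t])
        wnames = model.wnames + ["d_star"]
        group_w = np.arange(model.W.shape[1])
    else:
        W = model.W
        wnames = model.wnames
        group_w = np.arange(model.W.shape[1])

    random_mask = np.ones(model.n_subjects, dtype=bool)
    random_mask[t_code] = False
    return MELSModel(
        model.y,
        X,
        W,
        model.codes,
        model.subject_ids,
        xnames,
        wnames,
        scale_model=model.scale_model,
        quad_points=model.quad_points,
        random_mask=random_mask,
        group_x_idx=group_x,
        group_w_idx=group_w,
    )


def _loo_start(model: MELSModel, baseline: MELSResults, target) -> MELSParams:
    """Warm start: baseline estimates, c at the target's mean location
    residual, d at the log sample variance of those residuals."""
    t_code = model.subject_ids.index(target)
    rows = model.codes == t_code
    # covariate part of the location predictor (exclude the intercept)
    m = model.X[rows, 1:] @ baseline.params.beta[1:] if model.X.shape[1] > 1 else 0.0
    resid = model.y[rows] - m
    c0 = float(np.mean(resid))
    p = baseline.params
    beta = np.concatenate([p.beta, [c0]])
    if model.scale_model:
        v = float(np.var(resid - c0, ddof=1)) if resid.size > 1 else 1.0
        d0 = float(np.log(max(v, 1e-8)))
        tau = np.concatenate([p.tau, [d0]])
        return MELSParams(beta, tau, p.var_nu, max(p.var_omega, 1e-8), p.cov_nuomega)
    return MELSParams(beta, p.tau.copy(), p.var_nu)


def fit_loo(model: MELSModel, baseline: MELSResults, target) -> LOOResults:
    """Fit the leave-one-out model for one subject, warm-started from
    the converged baseline fit."""
    loo_model = make_loo_model(model, target)
    start = _loo_start(model, baseline, target)
    res = loo_model.fit(start=start)
    if res.converged and res.loglike < baseline.loglike - 1e-6:
        # nesting violated numerically: retry from scratch defaults
        res2 = loo_model.fit()
        if res2.loglike > res.loglike:
            res = res2
    c = res.estimate("c_star")
    d = res.estimate("d_star") if model.scale_model else None
    return LOOResults(target=target, results=res, c_star=c, d_star=d)


def fit_all_loo(
    model: MELSModel,
    baseline: MELSResults,
    n_jobs: int = 1,
    progress: bool = False,
    stop_on_failure: bool = False,
) -> list[LOOResults]:
    """Leave-one-out fits for every subject, in subject order.

    Parallel execution (joblib) is result-identical to serial: each fit
    is deterministic given the data and the baseline warm start.  With
    ``stop_on_failure`` the sweep returns early after a non-converged
    fit (replication drivers that exclude such datasets anyway).
    """
    if not baseline.converged:
        raise ValueError("baseline fit did not converge")
    ids = model.subject_ids
    if n_jobs != 1 and not stop_on_failure:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=n_jobs)(
            delayed(fit_loo)(model, baseline, t) for t in ids
        )
        return list(out)
    out = []
    for k, t in enumerate(ids):
        out.append(fit_loo(model, baseline, t))
        if progress:
            logger.info("leave-one-out fit %d/%d (subject %r)", k + 1, len(ids), t)
        if stop_on_failure and not out[-1].converged:
            logger.warning("leave-one-out fit for subject %r did not converge", t)
            break
    return out
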