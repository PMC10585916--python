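"""Mixed-effects location scale (MELS) model estimation.

The MELS model jointly describes the mean (location) and the
within-subject variance (scale) of an intensive longitudinal outcome:

    y_ij = beta_0 + nu_i + x_ij' beta' + eps_ij
    Var(eps_ij) = exp(tau_0 + omega_i + w_ij' tau')
    (nu_i, omega_i) ~ N2(0, [[s2_nu, s_nuom], [s_nuom, s2_omega]])

Estimation is by maximum marginal likelihood with bivariate adaptive
Gauss-Hermite quadrature.  The random-effect covariance is optimized
through its Cholesky factor (log-diagonal), so the search is
unconstrained and the reported covariance is always positive
semi-definite; natural-scale estimates and their covariance matrix are
recovered by the delta method from the observed information.

Setting ``scale_model=False`` drops the scale sub-model entirely and
fits a standard mixed-effects regression model (MRM) with a single
random location intercept and homoskedastic level-1 variance
exp(tau_0); its marginal likelihood is evaluated in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._likelihood import MarginalLikelihood, NumericalError
from ._numdiff import central_gradient, central_hessian
from .data import LongDataset, build_design

__all__ = ["MELSParams", "MELSModel", "MELSResults", "fit_mels", "marginal_loglik"]


@dataclass
class MELSParams:
    """Natural-scale parameter set (beta, tau, eta).

    eta = (var_nu, var_omega, cov_nuomega) is the covariance of the
    random location and scale intercepts; for an MRM var_omega and
    cov_nuomega are identically zero and tau is the single log level-1
    variance.
    """

    beta: np.ndarray
    tau: np.ndarray
    var_nu: float
    var_omega: float = 0.0
    cov_nuomega: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if not self.var_nu > 0:
            raise ValueError("var_nu must be > 0")
        if self.var_omega < 0:
            raise ValueError("var_omega must be >= 0")
        if self.cov_nuomega**2 > self.var_nu * self.var_omega + 1e-12:
            raise ValueError("random-effect covariance matrix not PSD")

    @property
    def eta(self) -> np.ndarray:
        return np.array([self.var_nu, self.var_omega, self.cov_nuomega])


class MELSModel:
    """MELS (or MRM) model bound to a long-format dataset.

    Usually constructed with :meth:`from_dataset` /
    :meth:`from_dataframe`, naming the covariate columns that enter the
    location and scale sub-models (intercepts are always included).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        W: np.ndarray,
        codes: np.ndarray,
        subject_ids: list,
        xnames: list[str],
        wnames: list[str],
        scale_model: bool = True,
        quad_points: int = 7,
        random_mask: np.ndarray | None = None,
        group_x_idx: np.ndarray | None = None,
        group_w_idx: np.ndarray | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.W = np.asarray(W, dtype=float)
        self.codes = np.asarray(codes, dtype=np.int64)
        self.subject_ids = list(subject_ids)
        self.n_subjects = len(self.subject_ids)
        self.xnames = list(xnames)
        self.wnames = list(wnames)
        self.scale_model = bool(scale_model)
        self.quad_points = int(quad_points)
        self.group_x_idx = (
            np.arange(self.X.shape[1]) if group_x_idx is None else np.asarray(group_x_idx)
        )
        self.group_w_idx = (
            np.arange(self.W.shape[1]) if group_w_idx is None else np.asarray(group_w_idx)
        )
        self._core = MarginalLikelihood(
            self.y,
            self.X,
            self.W,
            self.codes,
            self.n_subjects,
            random_mask=random_mask,
            scale_model=self.scale_model,
            quad_points=self.quad_points,
        )

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_dataset(
        cls,
        data: LongDataset,
        location: list[str] | None = None,
        scale: list[str] | None = None,
        scale_model: bool = True,
        quad_points: int = 7,
    ) -> "MELSModel":
        location = list(location or [])
        scale = list(scale or [])
        if not scale_model and scale:
            raise ValueError("scale covariates require scale_model=True")
        X, W = build_design(data, location, scale)
        xnames = ["beta0"] + [f"beta_{c}" for c in location]
        wnames = ["tau0"] + [f"tau_{c}" for c in scale]
        return cls(
            data.y,
            X,
            W,
            data.subject_codes,
            data.subject_ids,
            xnames,
            wnames,
            scale_model=scale_model,
            quad_points=quad_points,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject: str = "subject",
        response: str = "y",
        location: list[str] | None = None,
        scale: list[str] | None = None,
        scale_model: bool = True,
        quad_points: int = 7,
    ) -> "MELSModel":
        data = LongDataset(df, subject_col=subject, response_col=response)
        return cls.from_dataset(
            data, location, scale, scale_model=scale_model, quad_points=quad_points
        )

    # -- parameter bookkeeping -------------------------------------------
    @property
    def k_beta(self) -> int:
        return self.X.shape[1]

    @property
    def k_tau(self) -> int:
        return self.W.shape[1]

    @property
    def k_eta(self) -> int:
        return 3 if self.scale_model else 1

    @property
    def k_params(self) -> int:
        return self.k_beta + self.k_tau + self.k_eta

    @property
    def param_names(self) -> list[str]:
        eta = (
            ["sigma2_nu", "sigma2_omega", "sigma_nuomega"]
            if self.scale_model
            else ["sigma2_nu"]
        )
        return self.xnames + self.wnames + eta

    def group_indices(self, group: str) -> np.ndarray:
        """Natural-parameter positions of a parameter group.

        beta = fixed location effects, tau = fixed scale effects,
        eta = random-effect (co)variances.
        """
        kx, kw = self.k_beta, self.k_tau
        if group == "beta":
            return np.asarray(self.group_x_idx)
        if group == "tau":
            return kx + np.asarray(self.group_w_idx)
        if group == "eta":
            return kx + kw + np.arange(self.k_eta)
        raise ValueError(f"unknown parameter group {group!r}")

    # -- internal <-> natural mapping ------------------------------------
    def _internal_from_params(self, p: MELSParams) -> np.ndarray:
        if self.scale_model:
            l11 = np.sqrt(p.var_nu)
            l21 = p.cov_nuomega / l11
            rem = max(p.var_omega - l21**2, 1e-12)
            re = [np.log(l11), l21, 0.5 * np.log(rem)]
        else:
            re = [np.log(p.var_nu)]
        return np.concatenate([p.beta, p.tau, re])

    def _params_from_internal(self, v: np.ndarray) -> MELSParams:
        kx, kw = self.k_beta, self.k_tau
        beta = v[:kx]
        tau = v[kx : kx + kw]
        if self.scale_model:
            a, b, c = v[kx + kw :]
            l11 = np.exp(a)
            l22 = np.exp(c)
            return MELSParams(beta, tau, l11**2, b**2 + l22**2, l11 * b)
        return MELSParams(beta, tau, float(np.exp(v[kx + kw])))

    def _re_from_internal(self, v: np.ndarray):
        kx, kw = self.k_beta, self.k_tau
        if self.scale_model:
            a, b, c = v[kx + kw :]
            l11 = np.exp(a)
            l22 = np.exp(c)
            return (l11**2, b**2 + l22**2, l11 * b)
        return float(np.exp(v[kx + kw]))

    def _jacobian_natural(self, v: np.ndarray) -> np.ndarray:
        """d(natural)/d(internal) at internal vector v (delta method)."""
        k = self.k_params
        J = np.eye(k)
        kx, kw = self.k_beta, self.k_tau
        if self.scale_model:
            a, b, c = v[kx + kw :]
            l11 = np.exp(a)
            l22 = np.exp(c)
            blk = np.array(
                [
                    [2.0 * l11**2, 0.0, 0.0],  # var_nu
                    [0.0, 2.0 * b, 2.0 * l22**2],  # var_omega
                    [l11 * b, l11, 0.0],  # cov_nuomega
                ]
            )
            J[kx + kw :, kx + kw :] = blk
        else:
            J[-1, -1] = np.exp(v[-1])
        return J

    # -- likelihood -------------------------------------------------------
    def loglike(self, params: MELSParams) -> float:
        """Marginal log-likelihood at natural-scale parameters."""
        return float(self.loglike_by_subject(params).sum())

    def loglike_by_subject(self, params: MELSParams) -> np.ndarray:
        re = (
            (params.var_nu, params.var_omega, params.cov_nuomega)
            if self.scale_model
            else params.var_nu
        )
        ll = self._core.loglik_by_subject(params.beta, params.tau, re, check=False)
        if ll is None:
            raise NumericalError("non-finite integrand (overflow in linear predictor)")
        if not np.all(np.isfinite(ll)):
            bad = int(np.where(~np.isfinite(ll))[0][0])
            raise NumericalError(
                f"non-finite log-likelihood for subject {self.subject_ids[bad]!r}"
            )
        return ll

    def _loglik_internal(self, v: np.ndarray) -> float:
        return self._core.loglik(v[: self.k_beta], v[self.k_beta : self.k_beta + self.k_tau], self._re_from_internal(v))

    # -- starting values ---------------------------------------------------
    def start_params(self) -> MELSParams:
        """Cheap, robust defaults from pooled OLS.

        Location effects from OLS; var_nu from the between-subject
        variance of subject-mean residuals.  The scale side starts at
        the per-subject log residual variances: tau_0 at their mean and
        var_omega at their variance, so the random scale effects are
        centred and generously scaled from the first iteration.  (A
        token var_omega such as 0.1 systematically understates scale
        heterogeneity and pushes a scale-outlying subject's misfit onto
        the location effects instead.)
        """
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        r = self.y - self.X @ beta
        v = max(float(np.var(r, ddof=min(self.X.shape[1], r.size - 1))), 1e-8)
        n_i = np.bincount(self.codes, minlength=self.n_subjects).astype(float)
        means = np.bincount(self.codes, weights=r, minlength=self.n_subjects)
        means = means / np.maximum(n_i, 1.0)
        s2nu = float(np.var(means, ddof=1)) if self.n_subjects > 1 else 0.1 * v
        s2nu = max(s2nu, 1e-3 * v)
        tau = np.zeros(self.k_tau)
        if not self.scale_model:
            tau[0] = np.log(v)
            return MELSParams(beta, tau, s2nu)
        # per-subject residual variances around own mean, on log scale
        ss = np.bincount(self.codes, weights=r**2, minlength=self.n_subjects)
        with np.errstate(divide="ignore"):
            logv = np.log(np.maximum(ss / np.maximum(n_i, 1.0) - means**2, 1e-8))
        ok = n_i >= 2
        tau[0] = float(np.mean(logv[ok])) if ok.any() else np.log(v)
        s2om = float(np.var(logv[ok], ddof=1)) if ok.sum() > 1 else 0.1
        s2om = min(max(s2om, 0.05), 25.0)
        return MELSParams(beta, tau, s2nu, s2om, 0.0)

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        start: MELSParams | None = None,
        maxiter: int = 500,
        gtol: float = 1e-3,
        compute_vcov: bool = True,
    ) -> "MELSResults":
        """Maximize the marginal likelihood.

        Never raises on optimizer failure: the returned results carry an
        honest ``converged`` flag so callers (e.g. the simulation
        driver) can apply their own exclusion rules.
        """
        if self.n_subjects < 2 and self._core.random_mask.sum() > 0:
            raise ValueError("random effects need at least 2 subjects")
        x0 = self._internal_from_params(start if start is not None else self.start_params())

        def negll(v: np.ndarray) -> float:
            val = self._loglik_internal(v)
            if not np.isfinite(val):
                return 1e15
            return -val

        def polish(vhat, llval):
            """Newton refinement: the quasi-Newton stop by relative ll
            change can leave a gradient above tolerance."""
            H = None
            grad_norm = np.inf
            grad = central_gradient(self._loglik_internal, vhat)
            if np.all(np.isfinite(grad)):
                grad_norm = float(np.max(np.abs(grad)))
            for _ in range(3):
                if not (np.isfinite(grad_norm) and grad_norm > 0.5 * gtol):
                    break
                H = central_hessian(self._loglik_internal, vhat)
                try:
                    step = np.linalg.solve(-H, grad)
                except np.linalg.LinAlgError:
                    break
                t = 1.0
                cand = -np.inf
                for _ in range(30):
                    cand = -negll(vhat + t * step)
                    if cand >= llval - 1e-9:
                        break
                    t *= 0.5
                if cand < llval - 1e-9:
                    break
                vhat = vhat + t * step
                llval = cand
                grad = central_gradient(self._loglik_internal, vhat)
                if not np.all(np.isfinite(grad)):
                    grad_norm = np.inf
                    break
                grad_norm = float(np.max(np.abs(grad)))
            return vhat, llval, grad_norm, H

        vhat = x0
        llval = -negll(x0)
        grad_norm = np.inf
        H = None
        for attempt in range(2):
            res = optimize.minimize(
                negll,
                vhat,
                method="L-BFGS-B",
                options={
                    "maxiter": maxiter,
                    "ftol": 1e-9 if attempt == 0 else 1e-12,
                    "gtol": 1e-6 if attempt == 0 else 1e-8,
                    "maxcor": 25,
                },
            )
            cand = -negll(res.x)
            if np.isfinite(cand) and cand >= llval - 1e-9:
                vhat = res.x
                llval = cand
            if not np.isfinite(llval):
                break
            vhat, llval, grad_norm, H = polish(vhat, llval)
            if grad_norm <= gtol:
                break
        converged = bool(np.isfinite(llval)) and grad_norm <= gtol
        params = self._params_from_internal(vhat)

        vcov = None
        ill = False
        if compute_vcov and np.isfinite(llval):
            if H is None:
                H = central_hessian(self._loglik_internal, vhat)
            if np.all(np.isfinite(H)):
                info = -H
                try:
                    vcov_int = np.linalg.inv(info)
                    if not np.all(np.isfinite(vcov_int)):
                        raise np.linalg.LinAlgError
                except np.linalg.LinAlgError:
                    try:
                        vcov_int = np.linalg.pinv(info)
                        ill = True
                    except np.linalg.LinAlgError:
                        vcov_int = None
                if vcov_int is not None:
                    evals = np.linalg.eigvalsh(0.5 * (vcov_int + vcov_int.T))
                    if evals.min() < -1e-8 * max(1.0, evals.max()):
                        ill = True
                    J = self._jacobian_natural(vhat)
                    vcov = J @ (0.5 * (vcov_int + vcov_int.T)) @ J.T
                    vcov = 0.5 * (vcov + vcov.T)
            else:
                ill = True
        if vcov is None:
            converged = False

        return MELSResults(
            model=self,
            params=params,
            loglike=llval,
            vcov=vcov,
            converged=converged,
            grad_norm=grad_norm,
            n_iter=int(res.nit),
            ill_conditioned=ill,
            internal_params=vhat,
        )


@dataclass
class MELSResults:
    """Fit results: estimates, uncertainty, diagnostics.

    ``vcov`` is on the natural scale of
    (beta, tau, var_nu[, var_omega, cov_nuomega]).
    """

    model: MELSModel
    params: MELSParams
    loglike: float
    vcov: np.ndarray | None
    converged: bool
    grad_norm: float
    n_iter: int
    ill_conditioned: bool = False
    internal_params: np.ndarray | None = field(default=None, repr=False)

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def estimates(self) -> np.ndarray:
        p = self.params
        eta = p.eta if self.model.scale_model else np.array([p.var_nu])
        return np.concatenate([p.beta, p.tau, eta])

    @property
    def bse(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(self.model.k_params, np.nan)
        return np.sqrt(np.maximum(np.diag(self.vcov), 0.0))

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.param_names.index(name)])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        est, se = self.estimates, self.bse
        return pd.DataFrame(
            {"lower": est - z * se, "upper": est + z * se}, index=self.param_names
        )

    def vcov_block(self, group: str) -> np.ndarray:
        """Variance-covariance sub-block for a parameter group."""
        if self.vcov is None:
            raise ValueError("fit has no variance-covariance matrix")
        idx = self.model.group_indices(group)
        return self.vcov[np.ix_(idx, idx)]

    def estimates_block(self, group: str) -> np.ndarray:
        return self.estimates[self.model.group_indices(group)]

    def group_param_names(self, group: str) -> list[str]:
        names = self.param_names
        return [names[i] for i in self.model.group_indices(group)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.param_names, "estimate": self.estimates, "se": self.bse}
        )

    def summary(self) -> str:
        kind = "MELS" if self.model.scale_model else "MRM"
        lines = [
            f"{kind} model fit ({self.model.n_subjects} subjects, "
            f"{len(self.model.y)} observations)",
            f"log-likelihood: {self.loglike:.4f}   converged: {self.converged}"
            f"   |grad|_inf: {self.grad_norm:.2e}   iterations: {self.n_iter}",
            "-" * 58,
            f"{'parameter':<18}{'estimate':>14}{'std.err.':>14}",
        ]
        for name, est, se in zip(self.param_names, self.estimates, self.bse):
            lines.append(f"{name:<18}{est:>14.4f}{se:>14.4f}")
        return "\n".join(lines)

    def influence(self, q: float = 0.05, n_jobs: int = 1, progress: bool = False):
        """Full leave-one-out influence analysis (see influence module)."""
        from .influence import MELSInfluence

        return MELSInfluence.from_results(self, q=q, n_jobs=n_jobs, progress=progress)


# -- module-level convenience wrappers --------------------------------------
def fit_mels(
    data: LongDataset,
    location: list[str] | None = None,
    scale: list[str] | None = None,
    scale_model: bool = True,
    quad_points: int = 7,
    start: MELSParams | None = None,
) -> MELSResults:
    """Fit a MELS model (or MRM) to a long-format dataset."""
    model = MELSModel.from_dataset(
        data, location, scale, scale_model=scale_model, quad_points=quad_points
    )
    return model.fit(start=start)


def marginal_loglik(
    params: MELSParams,
    data: LongDataset,
    location: list[str] | None = None,
    scale: list[str] | None = None,
    scale_model: bool = True,
    quad_points: int = 7,
) -> float:
    """Marginal log-likelihood of a parameter set on a dataset."""
    model = MELSModel.from_dataset(
        data, location, scale, scale_model=scale_model, quad_points=quad_points
    )
    return model.loglike(params)
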