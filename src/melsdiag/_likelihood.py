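"""Marginal likelihood of mixed-effects location scale (MELS) models.

The response of subject i at visit j is

    y_ij = x_ij' beta + nu_i + eps_ij,
    eps_ij ~ N(0, exp(w_ij' tau + omega_i)),
    (nu_i, omega_i) ~ N2(0, Sigma_re),

so each subject contributes a double integral over its random location
(nu) and scale (omega) effects.  The integral is approximated by
adaptive Gauss--Hermite quadrature: the integrand's mode and curvature
are located per subject by a damped Newton iteration, and the product
Hermite grid is centred and scaled there.

Key computational device: for fixed (beta, tau) the per-subject
integrand depends on (nu, omega) only through the sufficient statistics

    A_i = sum_j e_ij r_ij^2,  B_i = sum_j e_ij r_ij,  C_i = sum_j e_ij,

with r_ij = y_ij - x_ij' beta and e_ij = exp(-w_ij' tau), because

    sum_j (r_ij - nu)^2 exp(-w_ij' tau - omega)
        = exp(-omega) (A_i - 2 nu B_i + nu^2 C_i).

Hence one likelihood evaluation costs O(n_obs) for the statistics plus
O(N * nodes) for the quadrature, independent of cluster size.  This is
what makes the N leave-one-out refits of the influence analysis cheap.

Subjects with ``random_mask`` False (the separated subject of a
leave-one-out model) carry no random-effect mass: their contribution is
the plain Gaussian product likelihood.

When ``scale_model`` is False the model is a standard mixed-effects
regression (MRM): homoskedastic level-1 variance exp(tau_0), a single
random location intercept, and the marginal likelihood is evaluated in
closed form via the Woodbury identity rather than by quadrature.
"""

from __future__ import annotations

import numpy as np

_LOG2PI = np.log(2.0 * np.pi)
# bounds on exp() arguments keeping double precision finite
_EXP_CLIP = 500.0
# per-subject mode search confined to this many prior SDs (see _aghq),
# with an absolute ceiling on the log-variance direction: beyond a
# within-subject variance ratio of exp(12) the spike of a degenerate
# (exactly interpolable) subject would otherwise grow without bound
_MODE_TRUST = 8.0
_OMEGA_CAP = 12.0
# cap on the curvature cross-correlation in the 2x2 Newton solves
_CORR_MAX = 1.0 - 1e-8


class NumericalError(RuntimeError):
    """Non-finite integrand during likelihood evaluation."""


def gauss_hermite_grid(points: int) -> tuple[np.ndarray, np.ndarray]:
    """Product Gauss-Hermite grid for a 2-D integral.

    Returns (z, logw): node coordinates (K, 2) and log-weights with the
    exp(|z|^2) re-weighting folded in, K = points**2.
    """
    z1, w1 = np.polynomial.hermite.hermgauss(points)
    zz1, zz2 = np.meshgrid(z1, z1, indexing="ij")
    z = np.column_stack([zz1.ravel(), zz2.ravel()])
    lw = np.add.outer(np.log(w1), np.log(w1)).ravel() + (z**2).sum(axis=1)
    return z, lw


class MarginalLikelihood:
    """Evaluator bound to one dataset/design.

    Parameters
    ----------
    y, X, W : response and location/scale design matrices (row-aligned).
    codes : integer subject code per row, 0..n_subjects-1.
    n_subjects : number of subjects.
    random_mask : bool per subject; False for subjects excluded from the
        random effects (leave-one-out targets).  Default all True.
    scale_model : False selects the MRM closed form (W must be the
        intercept-only design).
    quad_points : Gauss-Hermite points per dimension (odd, >= 3).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        W: np.ndarray,
        codes: np.ndarray,
        n_subjects: int,
        random_mask: np.ndarray | None = None,
        scale_model: bool = True,
        quad_points: int = 7,
    ) -> None:
        if quad_points < 3 or quad_points % 2 == 0:
            raise ValueError("quad_points must be odd and >= 3")
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.W = np.asarray(W, dtype=float)
        self.codes = np.asarray(codes, dtype=np.int64)
        self.n_subjects = int(n_subjects)
        if random_mask is None:
            random_mask = np.ones(self.n_subjects, dtype=bool)
        self.random_mask = np.asarray(random_mask, dtype=bool)
        self.scale_model = bool(scale_model)
        self.quad_points = int(quad_points)
        self.n_i = np.bincount(self.codes, minlength=self.n_subjects).astype(float)
        if self.scale_model:
            self._z, self._logw = gauss_hermite_grid(self.quad_points)

    # -- sufficient statistics ------------------------------------------
    def _suffstats(self, beta: np.ndarray, tau: np.ndarray):
        m = self.X @ beta
        s = self.W @ tau
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(s))):
            return None
        s = np.clip(s, -_EXP_CLIP, _EXP_CLIP)
        e = np.exp(-s)
        r = self.y - m
        er = e * r
        N = self.n_subjects
        S = np.bincount(self.codes, weights=s, minlength=N)
        C = np.bincount(self.codes, weights=e, minlength=N)
        B = np.bincount(self.codes, weights=er, minlength=N)
        A = np.bincount(self.codes, weights=er * r, minlength=N)
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B)) and np.all(np.isfinite(C))):
            return None
        base = -0.5 * (self.n_i * _LOG2PI + S)
        return A, B, C, base

    # -- public evaluation ----------------------------------------------
    def loglik(self, beta, tau, re) -> float:
        """Total marginal log-likelihood; -inf on numerical failure."""
        ll = self.loglik_by_subject(beta, tau, re, check=False)
        if ll is None or not np.all(np.isfinite(ll)):
            return -np.inf
        return float(ll.sum())

    def loglik_by_subject(self, beta, tau, re, check: bool = True):
        """Per-subject marginal log-likelihood contributions.

        ``re`` is (sigma2_nu, sigma2_omega, sigma_nuomega) for a MELS
        model, or the scalar sigma2_nu for an MRM.
        """
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        stats = self._suffstats(beta, tau)
        if stats is None:
            if check:
                raise NumericalError("non-finite linear predictor")
            return None
        A, B, C, base = stats
        ll = np.empty(self.n_subjects)
        fix = ~self.random_mask
        ll[fix] = base[fix] - 0.5 * A[fix]
        rnd = self.random_mask
        if rnd.any():
            if self.scale_model:
                out = self._aghq(A[rnd], B[rnd], C[rnd], base[rnd], self.n_i[rnd], re)
            else:
                out = self._mrm_closed(A[rnd], B[rnd], C[rnd], base[rnd], float(re))
            if out is None:
                if check:
                    bad = np.where(rnd)[0]
                    raise NumericalError(
                        f"non-finite integrand (first subject code {bad[0]})"
                    )
                return None
            ll[rnd] = out
        if check and not np.all(np.isfinite(ll)):
            bad = int(np.where(~np.isfinite(ll))[0][0])
            raise NumericalError(f"non-finite log-likelihood for subject code {bad}")
        return ll

    # -- MRM closed form -------------------------------------------------
    @staticmethod
    def _mrm_closed(A, B, C, base, s2nu):
        if not (s2nu >= 0 and np.isfinite(s2nu)):
            return None
        denom = 1.0 + s2nu * C
        return base - 0.5 * (np.log(denom) + A - s2nu * B**2 / denom)

    # -- adaptive Gauss-Hermite quadrature -------------------------------
    def _aghq(self, A, B, C, base, n, re):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._aghq_impl(A, B, C, base, n, re)

    def _aghq_impl(self, A, B, C, base, n, re):
        s2nu, s2om, snuom = (np.float64(v) for v in re)
        if not (np.isfinite(s2nu) and np.isfinite(s2om) and np.isfinite(snuom)):
            return None
        det = s2nu * s2om - snuom * snuom
        if not (s2nu > 0 and s2om > 0 and det > 0 and np.isfinite(det)):
            return None
        # precision matrix of the random effects
        p11 = s2om / det
        p22 = s2nu / det
        p12 = -snuom / det
        logdet = np.log(det)

        def h_val(nu, om):
            # nu/om are (Nr,) or (Nr, K); align the per-subject stats
            if nu.ndim > A.ndim:
                A_, B_, C_, base_, n_ = (v[:, None] for v in (A, B, C, base, n))
            else:
                A_, B_, C_, base_, n_ = A, B, C, base, n
            expw = np.exp(np.clip(-om, -_EXP_CLIP, _EXP_CLIP))
            Q = A_ - 2.0 * nu * B_ + nu**2 * C_
            g = base_ - 0.5 * (n_ * om + expw * Q)
            pen = p11 * nu**2 + 2.0 * p12 * nu * om + p22 * om**2
            return g - 0.5 * pen - _LOG2PI - 0.5 * logdet

        # Trust region for the adaptive centering: the per-subject mode
        # search is confined to +/- 8 prior SDs.  A subject whose
        # responses are exactly collinear with the design makes the
        # location-scale likelihood degenerate (conditional residual
        # variance 0, spike at omega -> -inf growing with var_omega);
        # bounding the centering keeps the quadrature on the interior
        # optimum, which is the estimate such data admit.
        # only the log-variance (omega) direction is confined: the
        # location integrand is Gaussian in nu and cannot degenerate
        r_nu = np.inf
        r_om = min(_MODE_TRUST * np.sqrt(s2om), _OMEGA_CAP)

        def clip_region(nu, om):
            return np.clip(nu, -r_nu, r_nu), np.clip(om, -r_om, r_om)

        # initialize at the no-prior mode: nu = weighted residual mean,
        # omega = log of the matching within-subject variance; the
        # Newton steps then mainly apply the prior shrinkage
        nu = B / np.maximum(C, 1e-300)
        qv = np.maximum(A - 2.0 * nu * B + nu**2 * C, 1e-300)
        om = np.log(qv / np.maximum(n, 1.0))
        nu, om = clip_region(nu, om)
        zero = np.zeros_like(A)
        h0 = h_val(nu, om)
        hz = h_val(zero, zero)
        use0 = ~(h0 >= hz)  # prior-dominated subjects: start at the origin
        nu = np.where(use0, zero, nu)
        om = np.where(use0, zero, om)
        h0 = np.maximum(h0, hz)
        if not np.all(np.isfinite(h0)):
            return None
        tol = 1e-9 * (1.0 + n)
        for _ in range(200):
            expw = np.exp(np.clip(-om, -_EXP_CLIP, _EXP_CLIP))
            Q = A - 2.0 * nu * B + nu**2 * C
            Bn = B - nu * C
            g1 = expw * Bn - (p11 * nu + p12 * om)
            g2 = -0.5 * (n - expw * Q) - (p12 * nu + p22 * om)
            if not (np.all(np.isfinite(g1)) and np.all(np.isfinite(g2))):
                return None
            if np.all(np.abs(g1) < tol) and np.all(np.abs(g2) < tol):
                break
            # M = -(Hessian of h): both diagonal entries are positive
            # (Q >= 0 by Cauchy-Schwarz); equilibrate and clip the
            # off-diagonal correlation so the solve is positive definite
            # and immune to extreme curvature anisotropy
            m11 = expw * C + p11
            m12 = expw * Bn + p12
            m22 = 0.5 * expw * Q + p22
            s1 = np.sqrt(np.maximum(m11, 1e-300))
            s2 = np.sqrt(np.maximum(m22, 1e-300))
            r = np.clip(m12 / (s1 * s2), -_CORR_MAX, _CORR_MAX)
            omc = 1.0 - r**2
            d1 = (g1 / s1 - r * g2 / s2) / (s1 * omc)
            d2 = (g2 / s2 - r * g1 / s1) / (s2 * omc)
            t = np.ones_like(A)
            for _ in range(50):
                h1 = h_val(nu + t * d1, om + t * d2)
                bad = ~(h1 >= h0 - 1e-10)
                if not bad.any():
                    break
                t[bad] *= 0.5
            else:
                t[bad] = 0.0  # no admissible step: stay put
            nu, om = clip_region(nu + t * d1, om + t * d2)
            h0 = h_val(nu, om)
        if not np.all(np.isfinite(h0)):
            return None
        # curvature at the mode -> quadrature scaling
        expw = np.exp(np.clip(-om, -_EXP_CLIP, _EXP_CLIP))
        Q = A - 2.0 * nu * B + nu**2 * C
        Bn = B - nu * C
        m11 = expw * C + p11
        m12 = expw * Bn + p12
        m22 = 0.5 * expw * Q + p22
        s1 = np.sqrt(np.maximum(m11, 1e-300))
        s2 = np.sqrt(np.maximum(m22, 1e-300))
        r = np.clip(m12 / (s1 * s2), -_CORR_MAX, _CORR_MAX)
        # Cholesky of M^{-1} in closed form after equilibration
        L11 = 1.0 / (s1 * np.sqrt(1.0 - r**2))
        L21 = -r / (s2 * np.sqrt(1.0 - r**2))
        L22 = 1.0 / s2
        z1 = self._z[:, 0]
        z2 = self._z[:, 1]
        sq2 = np.sqrt(2.0)
        nu_k = nu[:, None] + sq2 * L11[:, None] * z1[None, :]
        om_k = om[:, None] + sq2 * (L21[:, None] * z1[None, :] + L22[:, None] * z2[None, :])
        # evaluate within the trust region only (truncated-support
        # integration: outside it a degenerate subject's integrand is
        # not trustworthy and the prior mass is negligible for any
        # well-behaved one)
        nu_k = np.clip(nu_k, -r_nu, r_nu)
        om_k = np.clip(om_k, -r_om, r_om)
        h_k = h_val(nu_k, om_k) + self._logw[None, :]
        hmax = h_k.max(axis=1)
        lse = hmax + np.log(np.exp(h_k - hmax[:, None]).sum(axis=1))
        return np.log(2.0) + np.log(L11) + np.log(L22) + lse
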