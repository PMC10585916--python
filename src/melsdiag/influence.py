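"""Subject-level influence analysis for MELS models.

For every subject the baseline fit is compared with that subject's
leave-one-out fit through:

* LR (difference in deviance): 2(loglik_loo - loglik), chi-square
  tested with df = number of added parameters, Benjamini-Hochberg
  FDR-corrected across the N subjects;
* Cook's distance per parameter group gamma in {beta, tau, eta}:
  (1/r) (g - g_loo)' Sigma_loo^{-1} (g - g_loo);
* DFBETAS per single parameter: (theta - theta_loo) / SE(theta_loo);
* COVTRACE: |Tr(Sigma^{-1} Sigma_loo) - r|;
* COVRATIO: det(Sigma_loo) / det(Sigma) — below 1 means separating the
  subject gains precision.

Rule-of-thumb cutoffs: 4/N for Cook's distance, 2/sqrt(N) for
|DFBETAS|, 1 +/- 3 r/N for COVRATIO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .loo import LOOResults, fit_all_loo
from .model import MELSResults

logger = logging.getLogger(__name__)

__all__ = [
    "lr_statistic",
    "fdr_adjust",
    "cooks_distance",
    "dfbetas",
    "covtrace",
    "covratio",
    "influence_table",
    "MELSInfluence",
]


def lr_statistic(baseline_loglike: float, loo_loglike: float) -> float:
    """Difference in deviance, clamped at 0 (the baseline is nested in
    the leave-one-out model, so negative values are numerical noise)."""
    lr = 2.0 * (loo_loglike - baseline_loglike)
    if lr < 0.0:
        if lr < -1e-6:
            logger.warning("negative LR %.3g clamped to 0", lr)
        return 0.0
    return float(lr)


def fdr_adjust(p_values: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns (q_values, rejected).  NaN p-values (non-converged fits)
    are left out of the correction and propagate as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    qv = np.full_like(p, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        r, qvals, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        qv[ok] = qvals
        rej[ok] = r
    return qv, rej


def _inv_or_pinv(mat: np.ndarray):
    try:
        inv = np.linalg.inv(mat)
        if np.all(np.isfinite(inv)):
            return inv, False
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(mat), True


def cooks_distance(est, est_loo, vcov_loo, r_gamma: int):
    """Cook's distance for a parameter group; (value, ill_conditioned)."""
    d = np.asarray(est, dtype=float) - np.asarray(est_loo, dtype=float)
    inv, ill = _inv_or_pinv(np.asarray(vcov_loo, dtype=float))
    val = float(d @ inv @ d) / r_gamma
    return max(val, 0.0), ill


def dfbetas(est: float, est_loo: float, se_loo: float) -> float:
    """Standardized (signed) change in a single parameter estimate."""
    if not (np.isfinite(se_loo) and se_loo > 0):
        return np.nan
    return (est - est_loo) / se_loo


def covtrace(vcov, vcov_loo, r_gamma: int):
    """|Tr(Sigma^{-1} Sigma_loo) - r|; (value, ill_conditioned)."""
    inv, ill = _inv_or_pinv(np.asarray(vcov, dtype=float))
    return abs(float(np.trace(inv @ np.asarray(vcov_loo, dtype=float))) - r_gamma), ill


def covratio(vcov, vcov_loo) -> float:
    """det(Sigma_loo)/det(Sigma); NaN when a determinant is not positive."""
    d0 = float(np.linalg.det(np.asarray(vcov, dtype=float)))
    d1 = float(np.linalg.det(np.asarray(vcov_loo, dtype=float)))
    if d0 <= 0 or d1 <= 0:
        return np.nan
    return d1 / d0


def influence_table(
    baseline: MELSResults, loos: list[LOOResults], q: float = 0.05
) -> pd.DataFrame:
    """Assemble the per-subject influence table.

    One row per subject with LR/p/q, Cook's distances, DFBETAS,
    COVTRACE and COVRATIO per parameter group, plus cutoff flags.  In
    MRM mode only the location group (beta) and the random location
    variance are reported; scale-side measures do not exist there.
    """
    if not baseline.converged:
        raise ValueError("baseline fit did not converge")
    model = baseline.model
    N = model.n_subjects
    mels = model.scale_model
    groups = ["beta", "tau", "eta"] if mels else ["beta", "eta"]
    df_lr = 2 if mels else 1
    names = baseline.param_names
    dfb_params = names if mels else [n for n in names if not n.startswith("tau")]

    cook_cut = 4.0 / N
    dfb_cut = 2.0 / np.sqrt(N)

    rows = []
    for loo in loos:
        row: dict = {"subject": loo.target, "converged": loo.converged}
        row["c_star"] = loo.c_star
        row["d_star"] = loo.d_star if mels else np.nan
        ill = bool(loo.results.ill_conditioned or baseline.ill_conditioned)
        usable = loo.converged and loo.results.vcov is not None
        if usable:
            lr = lr_statistic(baseline.loglike, loo.loglike)
            row["LR"] = lr
            row["p_value"] = float(stats.chi2.sf(lr, df_lr))
        else:
            row["LR"] = np.nan
            row["p_value"] = np.nan
        for g in groups:
            r_g = len(model.group_indices(g))
            if usable:
                est = baseline.estimates_block(g)
                est_loo = loo.results.estimates_block(g)
                v0 = baseline.vcov_block(g)
                v1 = loo.results.vcov_block(g)
                c, ill1 = cooks_distance(est, est_loo, v1, r_g)
                ct, ill2 = covtrace(v0, v1, r_g)
                cr = covratio(v0, v1)
                ill = ill or ill1 or ill2
            else:
                c = ct = cr = np.nan
            row[f"C_{g}"] = c
            row[f"COVTRACE_{g}"] = ct
            row[f"COVRATIO_{g}"] = cr
            row[f"flag_C_{g}"] = bool(np.isfinite(c) and c > cook_cut)
            lo, hi = 1.0 - 3.0 * r_g / N, 1.0 + 3.0 * r_g / N
            row[f"flag_COVRATIO_{g}"] = bool(np.isfinite(cr) and (cr < lo or cr > hi))
        for name in dfb_params:
            if usable:
                val = dfbetas(
                    baseline.estimate(name),
                    loo.results.estimate(name),
                    loo.results.se(name),
                )
            else:
                val = np.nan
            row[f"DFBETAS_{name}"] = val
            row[f"flag_DFBETAS_{name}"] = bool(np.isfinite(val) and abs(val) > dfb_cut)
        row["ill_conditioned"] = ill
        rows.append(row)

    table = pd.DataFrame(rows)
    qv, rej = fdr_adjust(table["p_value"].to_numpy(), q=q)
    table["q_value"] = qv
    table["flag_LR"] = rej
    # stable column order: ids, fit stats, measures, flags
    front = ["subject", "converged", "LR", "p_value", "q_value", "flag_LR"]
    rest = [c for c in table.columns if c not in front]
    return table[front + rest]


@dataclass
class MELSInfluence:
    """Leave-one-out influence analysis bound to a baseline fit."""

    baseline: MELSResults
    loos: list[LOOResults]
    q: float = 0.05
    table: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]

    @classmethod
    def from_results(
        cls,
        results: MELSResults,
        q: float = 0.05,
        n_jobs: int = 1,
        progress: bool = False,
    ) -> "MELSInfluence":
        loos = fit_all_loo(results.model, results, n_jobs=n_jobs, progress=progress)
        obj = cls(baseline=results, loos=loos, q=q)
        obj.table = influence_table(results, loos, q=q)
        return obj

    @property
    def significant_subjects(self) -> list:
        """Subjects whose LR q-value falls at or below the FDR level."""
        t = self.table
        return t.loc[t["flag_LR"].astype(bool), "subject"].tolist()

    def extreme_measures(self, subject) -> list[str]:
        """Measures on which a subject attains the most extreme value."""
        t = self.table.set_index("subject")
        out = []
        for col in t.columns:
            if col.startswith(("C_", "COVTRACE_")) or col.startswith("DFBETAS_"):
                if t[col].idxmax() == subject:
                    out.append(f"largest {col}")
                if col.startswith("DFBETAS_") and t[col].idxmin() == subject:
                    out.append(f"smallest {col}")
            elif col.startswith("COVRATIO_"):
                if t[col].idxmin() == subject:
                    out.append(f"smallest {col}")
                if t[col].idxmax() == subject:
                    out.append(f"largest {col}")
        return out

    def summary(self) -> str:
        lines = [
            f"Influence analysis: {len(self.loos)} leave-one-out fits, "
            f"FDR level q = {self.q}",
        ]
        sig = self.significant_subjects
        if not sig:
            lines.append("No subject significantly influences the model fit.")
        for s in sig:
            lines.append(f"subject {s!r}: significant influence on model fit")
            for m in self.extreme_measures(s):
                lines.append(f"    - {m}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
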