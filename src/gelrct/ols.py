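"""ANOVA/ANCOVA comparator with classical and HC3 robust standard errors.

OLS of y on [1, z, x1..xk]; the adjusted mean difference is minus the
coefficient on z (Delta = control minus intervention).  With k=0 this is
the pooled-variance two-sample t procedure.  Confidence intervals use
t(n-p) quantiles for both the classical and the HC3 covariance; HC3
inflates each squared residual by (1 - h_ii)^-2, h_ii the leverage,
which repairs the coverage of the classical interval under
heteroscedasticity with unequal group sizes.  No treatment-by-covariate
interaction terms are included: that deliberate misspecification is
exactly what the heteroscedastic/interaction scenarios stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dgp import TrialData

__all__ = ["ANCOVA", "ANCOVAResults", "fit_ancova", "hc3_covariance"]


def hc3_covariance(design: np.ndarray, residuals: np.ndarray,
                   leverages: np.ndarray) -> np.ndarray:
    """HC3 covariance (X'X)^-1 X' diag(e_i^2/(1-h_ii)^2) X (X'X)^-1."""
    design = np.asarray(design, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    leverages = np.asarray(leverages, dtype=float)
    if np.any(leverages >= 1.0 - 1e-12):
        raise ValueError("leverage of 1: degenerate observation")
    xtx_inv = np.linalg.inv(design.T @ design)
    w = residuals**2 / (1.0 - leverages) ** 2
    meat = (design * w[:, None]).T @ design
    return xtx_inv @ meat @ xtx_inv


@dataclass
class ANCOVAResults:
    """Least-squares fit with classical and HC3 inference for Delta."""

    delta_hat: float
    se_classical: float
    se_hc3: float
    ci_classical: tuple[float, float]
    ci_hc3: tuple[float, float]
    beta: np.ndarray
    beta_x: np.ndarray
    residuals: np.ndarray
    leverages: np.ndarray
    cov_classical: np.ndarray
    cov_hc3: np.ndarray
    df_resid: int
    nobs: int
    k: int

    @property
    def sigma2(self) -> float:
        return float(self.residuals @ self.residuals / self.df_resid)

    def conf_int(self, cov_type: str = "classical") -> tuple[float, float]:
        return self.ci_hc3 if cov_type.lower() == "hc3" else self.ci_classical

    def summary(self, level: float = 0.95) -> str:
        name = "ANCOVA" if self.k else "ANOVA"
        lines = [
            f"{name} (OLS), n = {self.nobs}, covariates = {self.k}",
            f"{'':>10} {'estimate':>12} {'classical CI':>24} {'HC3 CI':>24}",
            f"{'delta':>10} {self.delta_hat:>12.5f} "
            f"({self.ci_classical[0]:.5f}; {self.ci_classical[1]:.5f})"
            f"    ({self.ci_hc3[0]:.5f}; {self.ci_hc3[1]:.5f})",
        ]
        for j, b in enumerate(self.beta_x, 1):
            lines.append(f"{'beta_x' + str(j):>10} {b:>12.5f}")
        return "\n".join(lines)


class ANCOVA:
    """OLS comparator model for the adjusted mean difference.

    Parameters mirror :class:`gelrct.gel.GELAdjustment`: a
    :class:`TrialData` and the number of adjustment covariates ``k``.
    """

    def __init__(self, data: TrialData, k: int | None = None):
        if k is None:
            k = data.k
        if k > data.k:
            raise ValueError(f"requested k={k} but data has {data.k} covariates")
        self.data = data
        self.k = int(k)
        self.design = np.column_stack(
            [np.ones(data.n), data.z.astype(float), data.X[:, : self.k]])

    @classmethod
    def from_dataframe(cls, df, k: int | None = None):
        return cls(TrialData.from_dataframe(df), k=k)

    def fit(self, level: float = 0.95) -> ANCOVAResults:
        D = self.design
        n, p = D.shape
        if np.linalg.matrix_rank(D) < p:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        xtx = D.T @ D
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (D.T @ self.data.y)
        resid = self.data.y - D @ beta
        lev = np.einsum("ij,jk,ik->i", D, xtx_inv, D)
        df = n - p
        s2 = resid @ resid / df
        cov_c = s2 * xtx_inv
        cov_h = hc3_covariance(D, resid, lev)
        delta_hat = -beta[1]
        se_c = float(np.sqrt(cov_c[1, 1]))
        se_h = float(np.sqrt(cov_h[1, 1]))
        tcrit = float(stats.t.ppf(0.5 + level / 2.0, df))
        return ANCOVAResults(
            delta_hat=float(delta_hat),
            se_classical=se_c,
            se_hc3=se_h,
            ci_classical=(delta_hat - tcrit * se_c, delta_hat + tcrit * se_c),
            ci_hc3=(delta_hat - tcrit * se_h, delta_hat + tcrit * se_h),
            beta=beta,
            beta_x=beta[2:].copy(),
            residuals=resid,
            leverages=lev,
            cov_classical=cov_c,
            cov_hc3=cov_h,
            df_resid=df,
            nobs=n,
            k=self.k,
        )


def fit_ancova(data: TrialData, k: int | None = None) -> ANCOVAResults:
    """Functional entry point: OLS fit with both covariance types."""
    return ANCOVA(data, k=k).fit()
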