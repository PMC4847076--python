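"""Saddle-point estimation for the generalized empirical likelihood family.

A GEL estimator solves

    theta_hat = argmin_theta  sup_lambda  (1/n) sum_i rho(lambda' g_i(theta))

where ``g_i`` are the per-observation moment conditions and ``rho`` is a
concave carrier function normalised so that rho(0)=0, rho'(0)=-1 and
rho''(0)=-1.  The three members used here:

    EL   rho(v) = log(1 - v)        (empirical likelihood)
    ET   rho(v) = 1 - exp(v)        (exponential tilting)
    CUE  rho(v) = -v - v^2/2        (continuous-updating / Euclidean)

The inner problem is strictly concave; EL uses Owen's pseudo-logarithm
(quadratic extension of log below 1/n) so the inner maximum stays finite
and smooth even when the hypothesised moment value sits outside the
convex hull of the data — in that case the profiled criterion is large
and the hypothesis is simply rejected.  For CUE the inner maximiser has
the closed form lambda = -S(theta)^{-1} gbar(theta) with
S = n^{-1} sum g_i g_i', and the profiled objective equals the
continuous-updating GMM criterion (1/2) gbar' S^{-1} gbar.

The outer minimisation uses BFGS with the exact envelope gradient (the
moments are linear in theta), started from the closed-form sample-mean
initialiser, with a Nelder–Mead fallback.  The estimate of the mean
difference is the difference of the implied-probability-weighted group
outcome means; the implied probabilities w_i are proportional to
-rho'(lambda' g_i) and enforce covariate balance across the two arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from .dgp import TrialData
from .moments import MomentModel, ParamVector

__all__ = [
    "FAMILIES",
    "RhoSpec",
    "LambdaResult",
    "GELAdjustment",
    "GELResults",
    "solve_lambda",
    "gel_objective",
    "estimate",
]


# -- carrier functions ----------------------------------------------------

def _logstar(x, eps):
    """Owen's pseudo-log: log(x) for x >= eps, quadratic extension below."""
    x = np.asarray(x, dtype=float)
    safe = np.maximum(x, eps)
    return np.where(x >= eps, np.log(safe),
                    np.log(eps) - 1.5 + 2.0 * x / eps - x * x / (2.0 * eps**2))


def _logstar1(x, eps):
    x = np.asarray(x, dtype=float)
    safe = np.maximum(x, eps)
    return np.where(x >= eps, 1.0 / safe, 2.0 / eps - x / eps**2)


def _logstar2(x, eps):
    x = np.asarray(x, dtype=float)
    safe = np.maximum(x, eps)
    return np.where(x >= eps, -1.0 / safe**2, -1.0 / eps**2)


@dataclass(frozen=True)
class RhoSpec:
    """A GEL carrier function and its first two derivatives.

    ``eps`` (used only by EL) is the pseudo-log threshold, normally 1/n.
    All members satisfy rho(0)=0, rho'(0)=-1, rho''(0)=-1.
    """

    name: str

    def rho(self, v, eps=None):
        if self.name == "el":
            return _logstar(1.0 - np.asarray(v), eps)
        if self.name == "et":
            with np.errstate(over="ignore"):
                return 1.0 - np.exp(v)
        return -np.asarray(v) - np.asarray(v) ** 2 / 2.0

    def rho1(self, v, eps=None):
        if self.name == "el":
            return -_logstar1(1.0 - np.asarray(v), eps)
        if self.name == "et":
            with np.errstate(over="ignore"):
                return -np.exp(v)
        return -1.0 - np.asarray(v)

    def rho2(self, v, eps=None):
        if self.name == "el":
            return _logstar2(1.0 - np.asarray(v), eps)
        if self.name == "et":
            with np.errstate(over="ignore"):
                return -np.exp(v)
        return np.full_like(np.asarray(v, dtype=float), -1.0)


FAMILIES: dict[str, RhoSpec] = {
    "el": RhoSpec("el"),
    "et": RhoSpec("et"),
    "cue": RhoSpec("cue"),
}


def _family(family) -> RhoSpec:
    if isinstance(family, RhoSpec):
        return family
    try:
        return FAMILIES[str(family).lower()]
    except KeyError:
        raise ValueError(f"unknown GEL family {family!r}; use el/et/cue") from None


@dataclass
class LambdaResult:
    """Solution of the inner Lagrange-multiplier maximisation."""

    lmbda: np.ndarray
    value: float
    converged: bool
    iterations: int
    grad_norm: float
    singular: bool = False


def solve_lambda(theta_or_G, data=None, family="cue", tol=1e-10,
                 max_iter=100, lam0=None, k=None) -> LambdaResult:
    """Maximise (1/n) sum rho(lambda' g_i) over lambda.

    Accepts either a precomputed n x q moment matrix or ``(theta, data)``.
    CUE is solved in closed form; EL/ET by safeguarded Newton with
    backtracking.  A singular second-moment matrix falls back to the
    pseudo-inverse with ``singular=True`` (CUE) or raises (no descent
    direction available) for EL/ET.
    """
    if data is not None:
        mm = MomentModel(data, k if k is not None else None)
        theta = theta_or_G.as_array() if isinstance(theta_or_G, ParamVector) \
            else np.asarray(theta_or_G, dtype=float)
        G = mm.moment_matrix(theta)
    else:
        G = np.asarray(theta_or_G, dtype=float)
    if not np.isfinite(G).all():
        raise ValueError("moment matrix contains non-finite values")
    n, q = G.shape
    spec = _family(family)
    eps = 1.0 / n

    if spec.name == "cue":
        S = G.T @ G / n
        gbar = G.mean(axis=0)
        singular = False
        try:
            c = sla.cho_factor(S)
            lam = -sla.cho_solve(c, gbar)
        except (sla.LinAlgError, ValueError):
            lam = -np.linalg.pinv(S, rcond=1e-12) @ gbar
            singular = True
        value = float(-lam @ gbar - 0.5 * lam @ S @ lam)
        grad = -gbar - S @ lam
        return LambdaResult(lam, value, True, 0, float(np.linalg.norm(grad)),
                            singular)

    lam = np.zeros(q) if lam0 is None else np.asarray(lam0, dtype=float).copy()
    is_el = spec.name == "el"

    def value_of(vv):
        if is_el:
            return float(np.mean(_logstar(1.0 - vv, eps)))
        with np.errstate(over="ignore"):
            return float(np.mean(1.0 - np.exp(vv)))

    v = G @ lam
    f = value_of(v)
    if not np.isfinite(f):  # bad warm start
        lam = np.zeros(q)
        v = np.zeros(n)
        f = 0.0
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        if is_el:
            r1 = -_logstar1(1.0 - v, eps)
            r2 = _logstar2(1.0 - v, eps)
        else:
            with np.errstate(over="ignore"):
                r1 = -np.exp(np.minimum(v, 700.0))
            r2 = r1
        grad = G.T @ r1 / n
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm <= tol:
            return LambdaResult(lam, f, True, it - 1, grad_norm)
        H = (G * r2[:, None]).T @ G / n  # negative definite
        try:
            direction = sla.cho_solve(sla.cho_factor(-H), grad)
        except (sla.LinAlgError, ValueError):
            try:
                direction = np.linalg.solve(-H + 1e-10 * np.eye(q), grad)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    "rank-deficient moment second-moment matrix"
                ) from None
        slope = float(grad @ direction)
        gdir = G @ direction
        t = 1.0
        for _ in range(50):
            v_new = v + t * gdir
            f_new = value_of(v_new)
            if np.isfinite(f_new) and f_new >= f + 1e-4 * t * slope:
                break
            t *= 0.5
        else:
            break  # no progress possible
        lam = lam + t * direction
        v = v_new
        f = f_new
    return LambdaResult(lam, f, grad_norm <= max(tol, 1e-7), grad_norm=grad_norm,
                        iterations=it)


def gel_objective(theta, data, family="cue", k=None, lam0=None) -> float:
    """Profiled saddle objective sup_lambda (1/n) sum rho(lambda' g_i(theta))."""
    mm = data if isinstance(data, MomentModel) else MomentModel(data, k)
    theta = theta.as_array() if isinstance(theta, ParamVector) \
        else np.asarray(theta, dtype=float)
    return solve_lambda(mm.moment_matrix(theta), family=family, lam0=lam0).value


# -- outer minimisation ---------------------------------------------------

def _profile_fit(mm: MomentModel, spec: RhoSpec, fixed: dict[int, float],
                 x0: np.ndarray | None, tol: float, maxiter: int):
    """Minimise the profiled objective over the non-fixed parameters.

    Returns (theta_full, objective, lambda, converged, n_iter,
    inner_failures).
    """
    free = np.array([i for i in range(mm.p) if i not in fixed], dtype=int)
    template = mm.initial_theta()
    for i, v in fixed.items():
        template[i] = v
    if x0 is None:
        x0 = template.copy()
    theta_full = np.asarray(x0, dtype=float).copy()
    for i, v in fixed.items():
        theta_full[i] = v

    eps = 1.0 / mm.n
    warm = {"lam": None, "fails": 0}

    def fun(xfree):
        th = theta_full.copy()
        th[free] = xfree
        G = mm.moment_matrix(th)
        res = solve_lambda(G, family=spec, lam0=warm["lam"])
        warm["lam"] = res.lmbda
        if not res.converged:
            warm["fails"] += 1
        r1 = spec.rho1(G @ res.lmbda, eps)
        grad = mm.profile_gradient(res.lmbda, r1)
        return res.value, grad[free]

    if free.size == 0:
        obj, _ = fun(np.empty(0))
        G = mm.moment_matrix(theta_full)
        lam = solve_lambda(G, family=spec).lmbda
        return theta_full, obj, lam, True, 0, warm["fails"]

    res = optimize.minimize(fun, theta_full[free], jac=True, method="BFGS",
                            options={"gtol": tol * 1e-1, "maxiter": maxiter})
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-6)
    if not converged:
        res_nm = optimize.minimize(lambda x: fun(x)[0], res.x,
                                   method="Nelder-Mead",
                                   options={"xatol": tol, "fatol": 1e-12,
                                            "maxiter": 400 * free.size})
        if res_nm.fun <= res.fun:
            res = res_nm
        converged = bool(res.success)
    theta_full[free] = res.x
    G = mm.moment_matrix(theta_full)
    inner = solve_lambda(G, family=spec, lam0=warm["lam"])
    return (theta_full, float(inner.value), inner.lmbda, converged,
            int(res.nit), warm["fails"])


class GELAdjustment:
    """GEL mean-difference model for a two-arm trial.

    Parameters
    ----------
    data : TrialData
        Outcome, group indicator and covariates.
    family : {"el", "et", "cue"}
        Carrier function: empirical likelihood, exponential tilting, or
        continuous updating.
    k : int, optional
        Number of covariates used for balance (defaults to all columns
        of ``data.X``).
    """

    def __init__(self, data: TrialData, family: str = "cue",
                 k: int | None = None):
        self.data = data
        self.spec = _family(family)
        self.model = MomentModel(data, k)
        self.k = self.model.k

    @classmethod
    def from_dataframe(cls, df, family: str = "cue", k: int | None = None):
        return cls(TrialData.from_dataframe(df), family=family, k=k)

    @property
    def family(self) -> str:
        return self.spec.name

    def fit(self, start=None, tol: float = 1e-8,
            maxiter: int = 200) -> "GELResults":
        """Minimise the profiled saddle objective over all parameters."""
        theta, obj, lam, conv, nit, fails = _profile_fit(
            self.model, self.spec, {}, start, tol, maxiter)
        return GELResults(self, theta, obj, lam, conv, nit, fails)

    def fit_fixed(self, fixed: dict[int, float], start=None,
                  tol: float = 1e-8, maxiter: int = 200) -> "GELResults":
        """Restricted fit with the given parameter indices held fixed."""
        theta, obj, lam, conv, nit, fails = _profile_fit(
            self.model, self.spec, dict(fixed), start, tol, maxiter)
        return GELResults(self, theta, obj, lam, conv, nit, fails,
                          fixed=dict(fixed))

    def fit_restricted(self, delta0: float, start=None, **kw) -> "GELResults":
        """Restricted fit with the mean difference fixed at ``delta0``."""
        return self.fit_fixed({1: float(delta0)}, start=start, **kw)


class GELResults:
    """Estimates, multipliers and implied probabilities of a GEL fit."""

    def __init__(self, model: GELAdjustment, theta: np.ndarray,
                 objective: float, lmbda: np.ndarray, converged: bool,
                 iterations: int, inner_failures: int = 0,
                 fixed: dict[int, float] | None = None):
        self.model = model
        self.theta = ParamVector.from_array(theta)
        self.params = np.asarray(theta, dtype=float)
        self.objective = float(objective)
        self.lmbda = np.asarray(lmbda, dtype=float)
        self.converged = bool(converged)
        self.iterations = int(iterations)
        self.inner_failures = int(inner_failures)
        self.fixed = fixed or {}

        mm = model.model
        G = mm.moment_matrix(self.params)
        v = G @ self.lmbda
        w = -model.spec.rho1(v, 1.0 / mm.n)
        self.has_negative_weights = bool((w < 0).any())
        self.weights = w / w.sum()
        self.gradient_norm = float(np.linalg.norm(
            mm.profile_gradient(self.lmbda, model.spec.rho1(v, 1.0 / mm.n))))

    # -- convenience accessors -------------------------------------------
    @property
    def mu1(self) -> float:
        return self.theta.mu1

    @property
    def delta(self) -> float:
        return self.theta.delta

    @property
    def mux(self) -> np.ndarray:
        return self.theta.mux

    def balance_residuals(self) -> np.ndarray:
        """Weighted covariate-balance moments at the solution (should be ~0)."""
        mm = self.model.model
        G = mm.moment_matrix(self.params)
        return self.weights @ G[:, 2:] if mm.k else np.empty(0)

    # -- inference (delegates to the test-inversion machinery) -----------
    def lr_test(self, delta0: float):
        from .inference import lr_statistic, pvalue
        d = lr_statistic(delta0, self.model.data, self.model.family,
                         self.model.k, fit=self)
        return d, pvalue(delta0, self.model.data, self.model.family,
                         self.model.k, fit=self)

    def conf_int(self, level: float = 0.95):
        from .inference import invert_ci
        return invert_ci(self.model.data, self.model.family, self.model.k,
                         level=level, fit=self)

    def summary(self, level: float = 0.95, compute_ci: bool = True) -> str:
        lines = [
            f"GEL covariate adjustment ({self.model.family.upper()})",
            f"n = {self.model.data.n}, adjustment covariates = {self.model.k}",
            f"converged = {self.converged}, saddle objective = "
            f"{self.objective:.6g}",
            "",
            f"{'param':>8} {'estimate':>12}",
            f"{'mu1':>8} {self.mu1:>12.5f}",
            f"{'delta':>8} {self.delta:>12.5f}",
        ]
        for j, m in enumerate(self.mux, 1):
            lines.append(f"{'mux' + str(j):>8} {m:>12.5f}")
        if compute_ci:
            ci = self.conf_int(level)
            lines += ["", f"{int(level * 100)}% test-inversion CI for delta: "
                          f"({ci.lower:.5f}; {ci.upper:.5f})"]
        return "\n".join(lines)


def estimate(data: TrialData, family: str = "cue", k: int | None = None,
             init=None, tol: float = 1e-8) -> GELResults:
    """Functional entry point: fit the GEL model and return the results."""
    return GELAdjustment(data, family=family, k=k).fit(start=init, tol=tol)
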