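"""Synthetic data generation for two-arm randomized-trial simulations.

The generator draws a continuous outcome ``y`` together with up to two
baseline covariates from one of three multivariate families — normal,
t with 3 degrees of freedom, and centered lognormal — each standardised
so that every marginal has mean 0 and variance 1 and every pairwise
correlation equals ``rho`` (equicorrelation).  Group membership is a
deterministic block assignment (first ``n(1-delta)`` observations are
controls, ``z=0``).  The treated outcome can then be made
heteroscedastic and/or interacting with the covariates: for ``z=1``,

    y = sqrt(v1) * y0 + beta2 * (x1 + x2),

while controls receive only the true mean shift ``y = y0 + delta_true``.
Closed-form expressions for the induced group-2 variance and
outcome-covariate correlation are provided for validation.

A second generator emulates a lead-exposure prevention trial: bivariate
normal (outcome, baseline covariate) with means (1.82 + Delta for
controls, 1.82 for treated; 1.07 for the covariate), standard deviations
0.58 and 0.52, correlation 0.35, and 100 subjects per arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Scenario",
    "TrialData",
    "CASES",
    "equicorrelation_matrix",
    "sample_base",
    "assign_groups",
    "apply_treatment_transform",
    "theoretical_group2_moments",
    "sample_part3",
]

#: Parameter combinations (delta, v1, beta2) for the unequal-size /
#: heteroscedasticity / interaction scenarios; rho = 0.5 throughout.
CASES: dict[int, tuple[float, float, float]] = {
    1: (0.2, 2.0, 0.5),
    2: (0.5, 1.0, 0.5),
    3: (0.2, 1.0, 0.0),
    4: (0.5, 2.0, 0.0),
    5: (0.2, 2.0, 0.0),
}

_DISTS = ("normal", "t3", "lognormal")

# Golden ratio: solves a^2 - a - 1 = 0, i.e. (e^{s2}-1)e^{s2} = 1 with
# a = e^{s2}; the latent Gaussian variance for a unit-variance lognormal.
_PHI = (1.0 + math.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class TrialData:
    """One simulated (or real) two-arm trial.

    Attributes
    ----------
    y : outcome vector, length n.
    z : group indicator, 0 = control (group 1), 1 = intervention (group 2).
    X : n x k matrix of baseline covariates (k may be 0).
    """

    y: np.ndarray
    z: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        z = np.asarray(self.z)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.size == 0:
            X = X.reshape(len(y), 0)
        if X.shape[0] != len(y) or len(z) != len(y):
            raise ValueError("y, z and X must have matching lengths")
        if not np.isin(z, (0, 1)).all():
            raise ValueError("z must contain only 0/1")
        if not (np.any(z == 0) and np.any(z == 1)):
            raise ValueError("both groups must be represented")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("non-finite values in y or X")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z.astype(np.int8))
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"y": self.y, "z": self.z}
        for j in range(self.k):
            cols[f"x{j + 1}"] = self.X[:, j]
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialData":
        if "y" not in df or "z" not in df:
            raise ValueError("data must have columns y and z")
        xcols = sorted(
            (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        return cls(
            df["y"].to_numpy(float),
            df["z"].to_numpy(),
            df[xcols].to_numpy(float) if xcols else np.empty((len(df), 0)),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of one simulated-trial configuration.

    ``k`` is the number of covariates used for *adjustment*; when
    ``beta2 != 0`` both covariates are always generated because the
    interaction term involves them regardless of adjustment.
    ``delta_true`` is the control-minus-intervention mean difference.
    """

    dist: str = "normal"
    rho: float = 0.5
    delta: float = 0.5
    v1: float = 1.0
    beta2: float = 0.0
    n: int = 200
    k: int = 1
    delta_true: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.dist not in _DISTS:
            raise ValueError(f"dist must be one of {_DISTS}")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        n1 = self.n * (1.0 - self.delta)
        if abs(n1 - round(n1)) > 1e-9 or round(n1) in (0, self.n):
            raise ValueError("n*delta and n*(1-delta) must be positive integers")
        if self.v1 <= 0:
            raise ValueError("v1 must be positive")
        if self.beta2 < 0:
            raise ValueError("beta2 must be nonnegative")
        if self.k not in (0, 1, 2):
            raise ValueError("k must be 0, 1 or 2")
        kdim = self.n_generated + 1
        if not (-1.0 / max(kdim - 1, 1) < self.rho < 1.0):
            raise ValueError("rho outside the positive-definite range")

    @property
    def n_generated(self) -> int:
        """Number of covariates actually drawn (2 whenever beta2 != 0)."""
        return 2 if self.beta2 != 0 else self.k

    def sample(self, rng: np.random.Generator | None = None) -> TrialData:
        """Draw one trial: base draws, block assignment, treatment transform."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        y0, X = sample_base(self, rng)
        z = assign_groups(self.n, self.delta)
        y = apply_treatment_transform(y0, X, z, self.v1, self.beta2, self.delta_true)
        return TrialData(y, z, X)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "Scenario":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text()
        else:
            text = source
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_case(cls, case: int, dist: str = "normal", k: int = 1,
                  n: int = 200, seed: int | None = None) -> "Scenario":
        delta, v1, beta2 = CASES[case]
        return cls(dist=dist, rho=0.5, delta=delta, v1=v1, beta2=beta2,
                   n=n, k=k, seed=seed)


def equicorrelation_matrix(dim: int, rho: float) -> np.ndarray:
    """Unit-diagonal matrix with all off-diagonal entries ``rho``.

    Positive definite iff ``-1/(dim-1) < rho < 1`` (eigenvalues are
    ``1 - rho`` with multiplicity ``dim - 1`` and ``1 + (dim-1) rho``).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if dim > 1 and not (-1.0 / (dim - 1) < rho < 1.0):
        raise ValueError(
            f"rho={rho} gives a non-positive-definite {dim}x{dim} matrix"
        )
    C = np.full((dim, dim), float(rho))
    np.fill_diagonal(C, 1.0)
    return C


def _lognormal_latent_cov(dim: int, rho: float) -> np.ndarray:
    # Latent variance s2 solves (e^{s2}-1)e^{s2} = 1  =>  e^{s2} = golden
    # ratio; latent covariance solves e^{s2}(e^{s_ij}-1) = rho.
    s2 = math.log(_PHI)
    off = math.log1p(rho / _PHI)
    L = np.full((dim, dim), off)
    np.fill_diagonal(L, s2)
    return L


def sample_base(scenario: Scenario, rng: np.random.Generator):
    """Draw the pre-treatment outcome and covariates.

    Returns ``(y0, X)`` where each marginal has mean 0 and variance 1
    and all pairwise correlations equal ``scenario.rho``.
    """
    dim = scenario.n_generated + 1
    n = scenario.n
    rho = scenario.rho
    if scenario.dist == "normal":
        L = np.linalg.cholesky(equicorrelation_matrix(dim, rho))
        V = rng.standard_normal((n, dim)) @ L.T
    elif scenario.dist == "t3":
        # multivariate t_3 with scale = C/3 so marginal variances are
        # nu/(nu-2) * 1/3 = 1
        L = np.linalg.cholesky(equicorrelation_matrix(dim, rho) / 3.0)
        g = rng.chisquare(3.0, size=n) / 3.0
        V = (rng.standard_normal((n, dim)) @ L.T) / np.sqrt(g)[:, None]
    else:  # lognormal
        if rho < 0:
            raise ValueError("lognormal family requires rho >= 0")
        Llat = np.linalg.cholesky(_lognormal_latent_cov(dim, rho))
        V = np.exp(rng.standard_normal((n, dim)) @ Llat.T) - math.sqrt(_PHI)
    return V[:, 0], V[:, 1:]


def assign_groups(n: int, delta: float) -> np.ndarray:
    """Deterministic block assignment: first ``n(1-delta)`` zeros, rest ones."""
    n1 = n * (1.0 - delta)
    if abs(n1 - round(n1)) > 1e-9:
        raise ValueError(f"n*(1-delta) = {n1} is not an integer")
    n1 = int(round(n1))
    if n1 <= 0 or n1 >= n:
        raise ValueError("both groups must be non-empty")
    z = np.zeros(n, dtype=np.int8)
    z[n1:] = 1
    return z


def apply_treatment_transform(y0, X, z, v1, beta2, delta_true) -> np.ndarray:
    """Heteroscedasticity/interaction transform of the treated outcome.

    Controls (z=0) receive only the true mean shift; treated outcomes are
    scaled by sqrt(v1) and shifted by beta2 times the covariate sum.
    Controls are left bit-identical when ``delta_true == 0``.
    """
    y0 = np.asarray(y0, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        X = X.reshape(len(y0), 0)
    z = np.asarray(z)
    if len(z) != len(y0) or X.shape[0] != len(y0):
        raise ValueError("shape mismatch between y0, X and z")
    if beta2 != 0 and X.shape[1] == 0:
        raise ValueError("interaction requested but no covariates present")
    treated = z == 1
    y = y0.copy()
    if delta_true != 0:
        y[~treated] += delta_true
    y[treated] = math.sqrt(v1) * y0[treated] + beta2 * X[treated].sum(axis=1)
    return y


def theoretical_group2_moments(rho: float, k: int, v1: float, beta2: float):
    """Closed-form Var(y|z=1) and Cor(y, x_j | z=1) after the transform.

    With base variances 1 and equicorrelation rho over (y0, x1..xk):

        Var(y|z=1) = v1 + 2 rho k beta2 sqrt(v1) + beta2^2 k (1 + (k-1) rho)
        Cor(y,x_j|z=1) = [rho sqrt(v1) + beta2 (1 + (k-1) rho)] / sqrt(Var)
    """
    if v1 <= 0:
        raise ValueError("v1 must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    sv = math.sqrt(v1)
    var = v1 + 2.0 * rho * k * beta2 * sv + beta2**2 * k * (1.0 + (k - 1) * rho)
    cor = (rho * sv + beta2 * (1.0 + (k - 1) * rho)) / math.sqrt(var)
    return var, cor


# -- lead-trial look-alike generator --------------------------------------

#: Summary statistics of the log blood-lead concentrations: outcome mean
#: (intervention), covariate mean, outcome/covariate SDs, correlation.
PART3_MU_Y = 1.82
PART3_MU_X = 1.07
PART3_SD_Y = 0.58
PART3_SD_X = 0.52
PART3_COR = 0.35


def sample_part3(delta_grid_value: float, n_per_group: int,
                 rng: np.random.Generator) -> TrialData:
    """Bivariate-normal trial emulating the lead-exposure study.

    ``delta_grid_value`` is the effect size in outcome-SD units:
    controls (z=0) have outcome mean ``1.82 + 0.58*Delta``; the
    intervention group has mean 1.82.  The covariate mean is 1.07 in
    both groups, SDs are 0.58 (outcome) and 0.52 (covariate),
    correlation 0.35.
    """
    if delta_grid_value < 0:
        raise ValueError("Delta must be nonnegative")
    n = 2 * n_per_group
    cov = np.array([
        [PART3_SD_Y**2, PART3_COR * PART3_SD_Y * PART3_SD_X],
        [PART3_COR * PART3_SD_Y * PART3_SD_X, PART3_SD_X**2],
    ])
    L = np.linalg.cholesky(cov)
    V = rng.standard_normal((n, 2)) @ L.T + np.array([PART3_MU_Y, PART3_MU_X])
    z = assign_groups(n, 0.5)
    y = V[:, 0].copy()
    y[z == 0] += delta_grid_value * PART3_SD_Y
    return TrialData(y, z, V[:, 1:2])
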