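"""Moment conditions for the two-group mean-difference model.

The parameter vector is theta = (mu1, Delta, mux_1..mux_k) where mu1 is
the intervention-group (z=1) outcome mean, Delta the control-minus-
intervention mean difference and mux the common covariate means.  The
per-observation moment function stacks, for observation i,

    [ z_i (y_i - mu1),
      (1-z_i)(y_i - mu1 - Delta),
      z_i (x_i1 - mux_1), (1-z_i)(x_i1 - mux_1),
      ...,
      z_i (x_ik - mux_k), (1-z_i)(x_ik - mux_k) ]

q = 2 + 2k conditions for p = 2 + k parameters: the k overidentifying
restrictions force the weighted covariate means of the two groups to
coincide (covariate balance), which is what delivers the efficiency
gain of the adjusted estimators.  All conditions are linear in theta,
so the Jacobian of the sample moment means is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParamVector", "MomentModel", "moment_matrix", "moment_jacobian"]


@dataclass(frozen=True)
class ParamVector:
    """(mu1, Delta, mux) with Delta = E[y|z=0] - E[y|z=1]."""

    mu1: float
    delta: float
    mux: np.ndarray

    def __post_init__(self):
        mux = np.atleast_1d(np.asarray(self.mux, dtype=float))
        if not (np.isfinite(self.mu1) and np.isfinite(self.delta)
                and np.isfinite(mux).all()):
            raise ValueError("parameters must be finite")
        object.__setattr__(self, "mux", mux)

    @property
    def k(self) -> int:
        return len(self.mux)

    def as_array(self) -> np.ndarray:
        return np.concatenate(([self.mu1, self.delta], self.mux))

    @classmethod
    def from_array(cls, arr) -> "ParamVector":
        arr = np.asarray(arr, dtype=float)
        return cls(arr[0], arr[1], arr[2:])


class MomentModel:
    """Precomputed moment-function structure for one dataset.

    The moment matrix is affine in theta:  G(theta)[:, c] =
    A[:, c] - U[:, c] * (W[c] @ theta), with A the data part, U the
    group-indicator column (z or 1-z) and W a constant selection matrix.
    """

    def __init__(self, data, k: int | None = None):
        if k is None:
            k = data.k
        if k > data.k:
            raise ValueError(f"requested k={k} but data has {data.k} covariates")
        self.data = data
        self.k = int(k)
        self.q = 2 + 2 * self.k
        self.p = 2 + self.k
        self.n = data.n

        z = data.z.astype(float)
        one_z = 1.0 - z
        cols_A = [z * data.y, one_z * data.y]
        cols_U = [z, one_z]
        W = np.zeros((self.q, self.p))
        W[0, 0] = 1.0              # mu1
        W[1, 0] = 1.0              # mu1 + Delta
        W[1, 1] = 1.0
        for j in range(self.k):
            cols_A += [z * data.X[:, j], one_z * data.X[:, j]]
            cols_U += [z, one_z]
            W[2 + 2 * j, 2 + j] = 1.0
            W[3 + 2 * j, 2 + j] = 1.0
        self._A = np.column_stack(cols_A)
        self._U = np.column_stack(cols_U)
        self._W = W
        # Jacobian of the column means w.r.t. theta (constant):
        # d gbar_c / d theta = -mean(U[:, c]) * W[c]
        self._jac = -self._U.mean(axis=0)[:, None] * W

    def moment_matrix(self, theta) -> np.ndarray:
        """n x q matrix of per-observation moment contributions."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.p,):
            raise ValueError(f"theta must have length {self.p}")
        return self._A - self._U * (self._W @ theta)

    def moment_means(self, theta) -> np.ndarray:
        return self.moment_matrix(theta).mean(axis=0)

    def jacobian(self) -> np.ndarray:
        """q x p Jacobian of the moment-mean vector (constant in theta)."""
        return self._jac.copy()

    def initial_theta(self) -> np.ndarray:
        """Closed-form start: group outcome means and covariate grand means."""
        d = self.data
        mu1 = d.y[d.z == 1].mean()
        delta = d.y[d.z == 0].mean() - mu1
        mux = d.X[:, : self.k].mean(axis=0) if self.k else np.empty(0)
        return np.concatenate(([mu1, delta], mux))

    # Envelope-gradient helper: d/dtheta of (1/n) sum rho(lambda' g_i)
    # at fixed lambda, using dg_ic/dtheta_p = -U_ic W_cp.
    def profile_gradient(self, lmbda, rho1_values) -> np.ndarray:
        t = self._U.T @ rho1_values / self.n
        return -self._W.T @ (lmbda * t)


def moment_matrix(theta: ParamVector, data) -> np.ndarray:
    """Functional form of :meth:`MomentModel.moment_matrix`."""
    return MomentModel(data, theta.k).moment_matrix(theta.as_array())


def moment_jacobian(theta: ParamVector, data) -> np.ndarray:
    """q x p derivative of the moment means; constant for this model."""
    return MomentModel(data, theta.k).jacobian()
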