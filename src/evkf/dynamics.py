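"""Conditional exponential-family dynamics models p_theta(z_t | z_{t-1}).

A dynamics model is a map ``lambda_theta(.)`` from the previous latent
state to a valid natural-parameter vector of the latent family, with a
flat trainable parameter vector ``theta``.  Because the training loss
used by the filter is a plain squared error on natural parameters, all a
model has to expose besides the forward map is a vector-Jacobian product
with respect to ``theta``; the networks here are small multilayer
perceptrons whose forward and backward passes are written out explicitly
(and checked against finite differences in the test suite).

Shipped models:

* :class:`LinearGaussianDynamics` — ``z_t ~ N(A z_{t-1}, Q)``; admits an
  exact expected-natural-parameter prediction, so the filter reduces to
  the Kalman filter on linear-Gaussian problems.
* :class:`NNGaussianDynamics` — ``z_t ~ N(f_theta(z_{t-1}), Q)`` with an
  MLP mean map.
* :class:`CallableGaussianDynamics` — a frozen (non-trainable) Gaussian
  conditional around an arbitrary mean function; used for ground-truth
  systems.
* :class:`NNCBDynamics` / :class:`NNGammaDynamics` — MLPs emitting the
  naturals of factorised continuous-Bernoulli / Gamma conditionals.
* :class:`ConstantDynamics` — a single free natural-parameter vector,
  constant in ``z`` (a "table-lookup" model useful for analysing the
  learning rule in isolation).
"""

from __future__ import annotations

import numpy as np

from .expfam import (
    ContinuousBernoulliFamily,
    DomainError,
    ExponentialFamily,
    GammaFamily,
    GaussianFamily,
    NaturalParams,
    _spd_inverse,
    _vech2,
)

__all__ = [
    "MLP",
    "ConditionalDynamics",
    "LinearGaussianDynamics",
    "NNGaussianDynamics",
    "CallableGaussianDynamics",
    "NNCBDynamics",
    "NNGammaDynamics",
    "ConstantDynamics",
    "eval_lambda",
    "transition_sample",
    "mean_jacobian",
]


# ----------------------------------------------------------------------
# multilayer perceptron with explicit forward/backward
# ----------------------------------------------------------------------

class MLP:
    """Small tanh MLP with a linear output head.

    Parameters live in a flat vector (weights then biases, layer by
    layer) so optimisers can treat the network as a plain vector-valued
    function of ``theta``.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator | None = None,
                 weight_scale: float = 1.0):
        self.sizes = [int(s) for s in sizes]
        if len(self.sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        rng = rng or np.random.default_rng(0)
        self.Ws = []
        self.bs = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            self.Ws.append(rng.standard_normal((fan_out, fan_in))
                           * weight_scale / np.sqrt(fan_in))
            self.bs.append(np.zeros(fan_out))

    # flat-parameter plumbing -------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.Ws, self.bs))

    def get_params(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b])
                               for W, b in zip(self.Ws, self.bs)])

    def set_params(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        k = 0
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            self.Ws[i] = theta[k:k + W.size].reshape(W.shape)
            k += W.size
            self.bs[i] = theta[k:k + b.size].copy()
            k += b.size
        if k != theta.size:
            raise ValueError(f"theta length {theta.size} != {self.n_params}")

    # forward / backward -------------------------------------------------
    def forward(self, Z: np.ndarray, cache: bool = False):
        """Batch forward pass; Z is (n, in). Returns (n, out) [and cache]."""
        A = np.atleast_2d(Z)
        acts = [A]
        n_layers = len(self.Ws)
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            A = A @ W.T + b
            if i < n_layers - 1:
                A = np.tanh(A)
            acts.append(A)
        return (A, acts) if cache else A

    def __call__(self, Z: np.ndarray) -> np.ndarray:
        return self.forward(Z)

    def vjp_params(self, acts: list[np.ndarray], G: np.ndarray) -> np.ndarray:
        """d/dtheta of sum_i <G_i, f(Z_i)> given cached activations."""
        G = np.atleast_2d(G)
        grads_W = [None] * len(self.Ws)
        grads_b = [None] * len(self.bs)
        delta = G
        for i in range(len(self.Ws) - 1, -1, -1):
            grads_W[i] = delta.T @ acts[i]
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.Ws[i]) * (1.0 - acts[i] ** 2)
        return np.concatenate([np.concatenate([gW.ravel(), gb])
                               for gW, gb in zip(grads_W, grads_b)])

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        """Jacobian of the network output with respect to its input."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        _, acts = self.forward(z[None, :], cache=True)
        J = self.Ws[0].copy()
        for i in range(1, len(self.Ws)):
            J = (1.0 - acts[i][0] ** 2)[:, None] * J
            J = self.Ws[i] @ J
        return J


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


# ----------------------------------------------------------------------
# dynamics interface
# ----------------------------------------------------------------------

class ConditionalDynamics:
    """Base class: z_{t-1} -> natural parameters of z_t."""

    family: ExponentialFamily
    trainable: bool = False

    # forward ------------------------------------------------------------
    def eval_lambda_batch(self, Z: np.ndarray) -> np.ndarray:
        """Natural parameters for each row of Z, shape (n, dim_lambda)."""
        raise NotImplementedError

    def eval_lambda(self, z: np.ndarray) -> NaturalParams:
        lam = self.eval_lambda_batch(np.atleast_2d(z))[0]
        return self.family.natural(lam)  # validates the domain

    # training -----------------------------------------------------------
    def get_theta(self) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} is not trainable")

    def set_theta(self, theta: np.ndarray) -> None:
        raise NotImplementedError(f"{type(self).__name__} is not trainable")

    def backprop_theta(self, Z: np.ndarray, dLam: np.ndarray) -> np.ndarray:
        """Gradient of ``sum_i <dLam_i, lambda_theta(Z_i)>`` w.r.t. theta."""
        raise NotImplementedError(f"{type(self).__name__} is not trainable")

    # misc ---------------------------------------------------------------
    def transition_sample(self, z_prev: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
        lam = self.eval_lambda(z_prev)
        return self.family._sample(lam.values, 1, rng)[0]

    def mean_jacobian(self, z: np.ndarray) -> np.ndarray:
        raise DomainError(
            f"mean_jacobian is only defined for Gaussian-family dynamics, "
            f"not {type(self).__name__}")


# ----------------------------------------------------------------------
# Gaussian-family dynamics
# ----------------------------------------------------------------------

class _GaussianDynamicsBase(ConditionalDynamics):
    """Shared machinery: lambda(z) = (Q^{-1} m(z), vech2(-1/2 Q^{-1})).

    Optionally, Q is trainable through a lower-triangular Cholesky factor
    with a softplus-transformed diagonal (kept positive by construction).
    """

    def __init__(self, dim_z: int, Q: np.ndarray, train_Q: bool = False):
        self.family = GaussianFamily(dim_z)
        self.dim_z = int(dim_z)
        self.train_Q = bool(train_Q)
        self._set_Q(np.atleast_2d(np.asarray(Q, dtype=float)))

    def _set_Q(self, Q: np.ndarray) -> None:
        self.Q = 0.5 * (Q + Q.T)
        self.Qinv = _spd_inverse(self.Q)
        self._chol = np.linalg.cholesky(self.Q)
        self._lam2 = _vech2(-0.5 * self.Qinv)

    # Q <-> raw lower-triangular parameters -----------------------------
    def _q_raw(self) -> np.ndarray:
        Lc = self._chol
        raw = Lc[np.tril_indices(self.dim_z)].copy()
        # invert the softplus on the diagonal entries
        diag_pos = _tril_diag_positions(self.dim_z)
        raw[diag_pos] = _inv_softplus(raw[diag_pos])
        return raw

    def _q_from_raw(self, raw: np.ndarray) -> None:
        L = self.dim_z
        Lc = np.zeros((L, L))
        Lc[np.tril_indices(L)] = raw
        diag_pos = np.diag_indices(L)
        Lc[diag_pos] = _softplus(Lc[diag_pos])
        self._set_Q(Lc @ Lc.T)

    def _mean_batch(self, Z: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def eval_lambda_batch(self, Z: np.ndarray) -> np.ndarray:
        M = self._mean_batch(np.atleast_2d(Z))
        eta1 = M @ self.Qinv.T
        lam2 = np.broadcast_to(self._lam2, (M.shape[0], self._lam2.size))
        return np.concatenate([eta1, lam2], axis=1)

    def _backprop_q_raw(self, dS_full: np.ndarray) -> np.ndarray:
        """Chain dJ/dS (S = Q^{-1}, entries independent) back to raw params."""
        S = self.Qinv
        dQ = -S @ dS_full @ S  # d(inv) chain rule; S symmetric
        Lc = self._chol
        dL = (dQ + dQ.T) @ Lc
        g = dL[np.tril_indices(self.dim_z)]
        diag_pos = _tril_diag_positions(self.dim_z)
        raw_diag = _inv_softplus(np.diag(Lc))
        g[diag_pos] = g[diag_pos] * _sigmoid(raw_diag)
        return g

    def _split_dlam(self, dLam: np.ndarray):
        """Split upstream gradients into the eta1 block and a dJ/dS matrix
        contribution coming from the vech2(-1/2 S) block."""
        L = self.dim_z
        dLam = np.atleast_2d(dLam)
        d1 = dLam[:, :L]
        dvec = dLam[:, L:].sum(axis=0)
        iu = np.triu_indices(L)
        dS = np.zeros((L, L))
        dS[iu] = -dvec          # off-diagonal entries of vech2 are -S_ij
        dS[np.diag_indices(L)] *= 0.5  # diagonal entries are -1/2 S_ii
        return d1, dS


def _tril_diag_positions(L: int) -> np.ndarray:
    rows, cols = np.tril_indices(L)
    return np.flatnonzero(rows == cols)


def _inv_softplus(y):
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


class LinearGaussianDynamics(_GaussianDynamicsBase):
    """z_t ~ N(A z_{t-1}, Q) with lambda(z) = (Q^{-1} A z, -1/2 Q^{-1})."""

    trainable = True

    def __init__(self, A: np.ndarray, Q: np.ndarray, train_Q: bool = False):
        A = np.atleast_2d(np.asarray(A, dtype=float))
        super().__init__(A.shape[0], Q, train_Q)
        self.A = A

    def _mean_batch(self, Z):
        return Z @ self.A.T

    def mean_jacobian(self, z):
        return self.A.copy()

    def expected_lambda(self, q_prev: NaturalParams) -> np.ndarray:
        """Closed-form E_q[lambda_theta(z)] = (Q^{-1} A m, -1/2 Q^{-1})."""
        m, _ = self.family.to_moments(q_prev.values)
        return np.concatenate([self.Qinv @ self.A @ m, self._lam2])

    def get_theta(self):
        th = self.A.ravel().copy()
        return np.concatenate([th, self._q_raw()]) if self.train_Q else th

    def set_theta(self, theta):
        L = self.dim_z
        self.A = np.asarray(theta[: L * L], dtype=float).reshape(L, L)
        if self.train_Q:
            self._q_from_raw(np.asarray(theta[L * L:], dtype=float))

    def backprop_theta(self, Z, dLam):
        Z = np.atleast_2d(Z)
        d1, dS = self._split_dlam(dLam)
        # eta1 = S A z  =>  dJ/dA = S^T (sum_i d1_i z_i^T)
        G = self.Qinv.T @ (d1.T @ Z)
        grads = [G.ravel()]
        if self.train_Q:
            dS_full = dS + d1.T @ (Z @ self.A.T)  # + sum_i d1_i (A z_i)^T
            grads.append(self._backprop_q_raw(dS_full))
        return np.concatenate(grads)


class NNGaussianDynamics(_GaussianDynamicsBase):
    """z_t ~ N(f_theta(z_{t-1}), Q) with an MLP mean map.

    With ``residual=True`` the mean map is ``f(z) = z + g_theta(z)`` —
    the natural parameterisation for dynamics arising from a
    discretised flow, where the one-step map is a perturbation of the
    identity.  A small-weight initialisation then starts the filter at
    a random walk (an honest "no dynamics knowledge" prior) and keeps
    the mean Jacobian near the identity, so the EKF-like variance
    correction propagates uncertainty from the first step.
    """

    trainable = True

    def __init__(self, mlp: MLP, Q: np.ndarray, train_Q: bool = False,
                 residual: bool = False):
        if mlp.sizes[0] != mlp.sizes[-1]:
            raise ValueError("dynamics MLP must map R^L -> R^L")
        super().__init__(mlp.sizes[0], Q, train_Q)
        self.mlp = mlp
        self.residual = bool(residual)

    def _mean_batch(self, Z):
        out = self.mlp(Z)
        return Z + out if self.residual else out

    def mean_jacobian(self, z):
        J = self.mlp.jacobian(z)
        return np.eye(self.dim_z) + J if self.residual else J

    def get_theta(self):
        th = self.mlp.get_params()
        return np.concatenate([th, self._q_raw()]) if self.train_Q else th

    def set_theta(self, theta):
        n = self.mlp.n_params
        self.mlp.set_params(np.asarray(theta[:n], dtype=float))
        if self.train_Q:
            self._q_from_raw(np.asarray(theta[n:], dtype=float))

    def backprop_theta(self, Z, dLam):
        Z = np.atleast_2d(Z)
        d1, dS = self._split_dlam(dLam)
        F, acts = self.mlp.forward(Z, cache=True)
        G_out = d1 @ self.Qinv  # S^T d1_i per sample (S symmetric)
        grads = [self.mlp.vjp_params(acts, G_out)]
        if self.train_Q:
            M = Z + F if self.residual else F  # the conditional means
            dS_full = dS + d1.T @ M
            grads.append(self._backprop_q_raw(dS_full))
        return np.concatenate(grads)


class CallableGaussianDynamics(_GaussianDynamicsBase):
    """Frozen Gaussian conditional N(f(z), Q) around a given mean map.

    Used for ground-truth simulators (Van der Pol, chaotic RNN); supply
    an analytic Jacobian where available, otherwise central differences
    with step 1e-6 are used.
    """

    trainable = False

    def __init__(self, f, Q: np.ndarray, dim_z: int, jac=None):
        super().__init__(dim_z, Q, train_Q=False)
        self.f = f
        self.jac = jac

    def _mean_batch(self, Z):
        return np.atleast_2d(self.f(Z))

    def mean_jacobian(self, z):
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if self.jac is not None:
            return np.atleast_2d(self.jac(z))
        h = 1e-6
        J = np.empty((self.dim_z, self.dim_z))
        for j in range(self.dim_z):
            e = np.zeros(self.dim_z)
            e[j] = h
            J[:, j] = (self.f((z + e)[None, :])[0] - self.f((z - e)[None, :])[0]) / (2 * h)
        return J


# ----------------------------------------------------------------------
# non-Gaussian network dynamics
# ----------------------------------------------------------------------

class NNCBDynamics(ConditionalDynamics):
    """Factorised continuous-Bernoulli conditional with MLP naturals.

    The network output is used directly as the natural-parameter vector;
    every real vector is valid for this family, so no link function is
    needed.
    """

    trainable = True

    def __init__(self, mlp: MLP):
        self.family = ContinuousBernoulliFamily(mlp.sizes[-1])
        self.mlp = mlp

    def eval_lambda_batch(self, Z):
        return self.mlp(np.atleast_2d(Z))

    def get_theta(self):
        return self.mlp.get_params()

    def set_theta(self, theta):
        self.mlp.set_params(theta)

    def backprop_theta(self, Z, dLam):
        _, acts = self.mlp.forward(np.atleast_2d(Z), cache=True)
        return self.mlp.vjp_params(acts, np.atleast_2d(dLam))


class NNGammaDynamics(ConditionalDynamics):
    """Factorised Gamma conditional with softplus-linked MLP naturals.

    The network emits ``2 L`` raw outputs ``(o1, o2)`` mapped to
    ``eta1 = softplus(o1) - 1 > -1`` and ``eta2 = -softplus(o2) < 0`` so
    the conditional always satisfies the Gamma domain constraints.
    """

    trainable = True

    def __init__(self, mlp: MLP):
        if mlp.sizes[-1] % 2:
            raise ValueError("Gamma dynamics MLP must emit 2L outputs")
        self.family = GammaFamily(mlp.sizes[-1] // 2)
        self.mlp = mlp

    def eval_lambda_batch(self, Z):
        O = self.mlp(np.atleast_2d(Z))
        L = self.family.dim_z
        return np.concatenate(
            [_softplus(O[:, :L]) - 1.0, -_softplus(O[:, L:])], axis=1)

    def get_theta(self):
        return self.mlp.get_params()

    def set_theta(self, theta):
        self.mlp.set_params(theta)

    def backprop_theta(self, Z, dLam):
        Z = np.atleast_2d(Z)
        dLam = np.atleast_2d(dLam)
        O, acts = self.mlp.forward(Z, cache=True)
        L = self.family.dim_z
        G = np.concatenate(
            [dLam[:, :L] * _sigmoid(O[:, :L]),
             -dLam[:, L:] * _sigmoid(O[:, L:])], axis=1)
        return self.mlp.vjp_params(acts, G)


class ConstantDynamics(ConditionalDynamics):
    """A single trainable natural-parameter vector, constant in z."""

    trainable = True

    def __init__(self, family: ExponentialFamily, lam0: np.ndarray):
        self.family = family
        self.lam0 = np.asarray(lam0, dtype=float).copy()
        family._check_natural(self.lam0)

    def eval_lambda_batch(self, Z):
        n = np.atleast_2d(Z).shape[0]
        return np.broadcast_to(self.lam0, (n, self.lam0.size)).copy()

    def get_theta(self):
        return self.lam0.copy()

    def set_theta(self, theta):
        self.lam0 = np.asarray(theta, dtype=float).copy()

    def backprop_theta(self, Z, dLam):
        return np.atleast_2d(dLam).sum(axis=0)


# ----------------------------------------------------------------------
# functional aliases matching the module's public operation names
# ----------------------------------------------------------------------

def eval_lambda(dyn: ConditionalDynamics, z_prev: np.ndarray) -> NaturalParams:
    """Natural parameters of z_t given the previous state."""
    return dyn.eval_lambda(z_prev)


def transition_sample(dyn: ConditionalDynamics, z_prev: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """One draw from p_theta(z_t | z_prev)."""
    return dyn.transition_sample(z_prev, rng)


def mean_jacobian(dyn: ConditionalDynamics, z: np.ndarray) -> np.ndarray:
    """Jacobian of the conditional-mean map (Gaussian dynamics only)."""
    return dyn.mean_jacobian(z)
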