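"""Classical filters: exact Kalman, extended Kalman, bootstrap particle
and ensemble Kalman filters.

The Kalman filter is the exact recursion for linear-Gaussian state-space
models and serves as the oracle against which the variational filter is
checked; the others are the standard approximate filters used as
comparison methods on nonlinear systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Likelihood
from .dynamics import ConditionalDynamics
from .expfam import DomainError

__all__ = [
    "GaussianBelief",
    "kalman_filter",
    "kalman_step",
    "ekf_step",
    "ekf_filter",
    "ParticleEnsemble",
    "bpf_init",
    "bpf_step",
    "bpf_filter",
    "enkf_init",
    "enkf_step",
    "enkf_filter",
]


@dataclass
class GaussianBelief:
    """A Gaussian belief N(m, P) over the latent state."""

    m: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.P = 0.5 * (self.P + self.P.T)
        w = np.linalg.eigvalsh(self.P)
        if w.min() <= 0:
            raise DomainError(f"belief covariance not SPD (min eig {w.min():.3e})")


# ----------------------------------------------------------------------
# Kalman filter
# ----------------------------------------------------------------------

def kalman_step(belief: GaussianBelief, y: np.ndarray, A, Q, C, b, R
                ) -> GaussianBelief:
    """One exact predict + update with the Joseph-form covariance update."""
    A = np.atleast_2d(A); Q = np.atleast_2d(Q)
    C = np.atleast_2d(C); R = np.atleast_2d(R)
    b = np.atleast_1d(b); y = np.atleast_1d(y)
    m_pred = A @ belief.m
    P_pred = A @ belief.P @ A.T + Q
    S = C @ P_pred @ C.T + R
    K = np.linalg.solve(S, C @ P_pred).T
    m = m_pred + K @ (y - C @ m_pred - b)
    I_KC = np.eye(A.shape[0]) - K @ C
    P = I_KC @ P_pred @ I_KC.T + K @ R @ K.T
    return GaussianBelief(m, P)


def kalman_filter(ys: np.ndarray, A, Q, C, b, R,
                  prior: GaussianBelief) -> list[GaussianBelief]:
    """Exact filtering beliefs for each row of ``ys`` (T x N)."""
    A = np.atleast_2d(A); Q = np.atleast_2d(Q)
    C = np.atleast_2d(C); R = np.atleast_2d(R)
    if A.shape[0] != A.shape[1] or Q.shape != A.shape:
        raise ValueError("A and Q must be square and conformable")
    if C.shape[1] != A.shape[0]:
        raise ValueError("C columns must match the latent dimension")
    beliefs = []
    belief = prior
    for y in np.atleast_2d(ys):
        belief = kalman_step(belief, y, A, Q, C, b, R)
        beliefs.append(belief)
    return beliefs


# ----------------------------------------------------------------------
# extended Kalman filter
# ----------------------------------------------------------------------

def ekf_step(belief: GaussianBelief, y: np.ndarray, dyn: ConditionalDynamics,
             lik: Likelihood) -> GaussianBelief:
    """EKF step: linearise the dynamics mean map about the filtered mean.

    The observation model must be linear-Gaussian (``lik.kind ==
    'gaussian'``); the dynamics may be any Gaussian-family conditional
    exposing ``mean_jacobian``.
    """
    if lik.kind != "gaussian":
        raise NotImplementedError("EKF update implemented for Gaussian likelihoods")
    M = dyn.mean_jacobian(belief.m)
    m_pred = dyn._mean_batch(belief.m[None, :])[0]
    P_pred = M @ belief.P @ M.T + dyn.Q
    C, b, R = lik.C, lik.b, lik.R
    S = C @ P_pred @ C.T + R
    K = np.linalg.solve(S, C @ P_pred).T
    m = m_pred + K @ (np.atleast_1d(y) - C @ m_pred - b)
    I_KC = np.eye(m.size) - K @ C
    P = I_KC @ P_pred @ I_KC.T + K @ R @ K.T
    return GaussianBelief(m, P)


def ekf_filter(ys, dyn, lik, prior: GaussianBelief) -> list[GaussianBelief]:
    beliefs = []
    belief = prior
    for y in np.atleast_2d(ys):
        belief = ekf_step(belief, y, dyn, lik)
        beliefs.append(belief)
    return beliefs


# ----------------------------------------------------------------------
# bootstrap particle filter
# ----------------------------------------------------------------------

@dataclass
class ParticleEnsemble:
    """Weighted (BPF) or uniform (EnKF) particle set."""

    particles: np.ndarray          # (n_p, L)
    log_weights: np.ndarray        # (n_p,), normalised in log domain

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.log_weights - self.log_weights.max())
        return w / w.sum()

    def mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def ess(self) -> float:
        w = self.weights
        return 1.0 / float(np.sum(w**2))


def bpf_init(n_p: int, prior: GaussianBelief,
             rng: np.random.Generator) -> ParticleEnsemble:
    chol = np.linalg.cholesky(prior.P)
    parts = prior.m + rng.standard_normal((n_p, prior.m.size)) @ chol.T
    return ParticleEnsemble(parts, np.full(n_p, -np.log(n_p)))


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator
                         ) -> np.ndarray:
    n = weights.size
    positions = (rng.uniform() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def bpf_step(ens: ParticleEnsemble, y: np.ndarray, dyn: ConditionalDynamics,
             lik: Likelihood, rng: np.random.Generator) -> ParticleEnsemble:
    """Bootstrap proposal, likelihood reweighting, systematic resampling
    when the effective sample size drops below half the particle count."""
    n_p = ens.particles.shape[0]
    Lam = dyn.eval_lambda_batch(ens.particles)
    new_parts = np.empty_like(ens.particles)
    # one draw per particle from its own conditional
    for i in range(n_p):
        new_parts[i] = dyn.family._sample(Lam[i], 1, rng)[0]
    log_w = ens.log_weights + lik.log_density(y, new_parts)
    if not np.any(np.isfinite(log_w)):
        raise FloatingPointError(
            f"all particle weights underflowed; max log-weight "
            f"{log_w.max():.3e}, min {log_w.min():.3e}")
    log_w = log_w - (np.logaddexp.reduce(log_w))
    ens = ParticleEnsemble(new_parts, log_w)
    if ens.ess() < n_p / 2:
        idx = _systematic_resample(ens.weights, rng)
        ens = ParticleEnsemble(new_parts[idx].copy(), np.full(n_p, -np.log(n_p)))
    return ens


def bpf_filter(ys, dyn, lik, n_p: int, prior: GaussianBelief,
               rng: np.random.Generator) -> list[ParticleEnsemble]:
    ens = bpf_init(n_p, prior, rng)
    out = []
    for y in np.atleast_2d(ys):
        ens = bpf_step(ens, y, dyn, lik, rng)
        out.append(ens)
    return out


# ----------------------------------------------------------------------
# ensemble Kalman filter
# ----------------------------------------------------------------------

def enkf_init(n_p: int, prior: GaussianBelief,
              rng: np.random.Generator) -> np.ndarray:
    chol = np.linalg.cholesky(prior.P)
    return prior.m + rng.standard_normal((n_p, prior.m.size)) @ chol.T


def enkf_step(ensemble: np.ndarray, y: np.ndarray, dyn: ConditionalDynamics,
              lik: Likelihood, rng: np.random.Generator) -> np.ndarray:
    """Stochastic-perturbation EnKF analysis with a linear-Gaussian
    observation model; no inflation or localisation is applied."""
    if lik.kind != "gaussian":
        raise NotImplementedError("EnKF update implemented for Gaussian likelihoods")
    n_p = ensemble.shape[0]
    Lam = dyn.eval_lambda_batch(ensemble)
    fore = np.empty_like(ensemble)
    for i in range(n_p):
        fore[i] = dyn.family._sample(Lam[i], 1, rng)[0]
    P_hat = np.cov(fore, rowvar=False).reshape(fore.shape[1], fore.shape[1])
    C, b, R = lik.C, lik.b, lik.R
    S = C @ P_hat @ C.T + R
    K = np.linalg.solve(S, C @ P_hat).T
    chol_R = np.linalg.cholesky(R)
    pert = rng.standard_normal((n_p, R.shape[0])) @ chol_R.T
    innov = (np.atleast_1d(y) + pert) - (fore @ C.T + b)
    return fore + innov @ K.T


def enkf_filter(ys, dyn, lik, n_p: int, prior: GaussianBelief,
                rng: np.random.Generator) -> list[np.ndarray]:
    ens = enkf_init(n_p, prior, rng)
    out = []
    for y in np.atleast_2d(ys):
        ens = enkf_step(ens, y, dyn, lik, rng)
        out.append(ens)
    return out
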