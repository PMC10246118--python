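"""Synthetic state-space systems for exercising the filter end to end.

Four generators, each returning ground-truth latents, observations, the
true conditional dynamics (as a :class:`~evkf.dynamics.ConditionalDynamics`)
and the observation parameters used:

* ``lds``  — linear-Gaussian state-space model (the exact-oracle system);
* ``crnn`` — chaotic recurrent network ``z' = z + dt/tau (gamma W tanh z - z)``
  with additive Gaussian state noise, the standard random-weight
  benchmark for latent filtering;
* ``vdp``  — noise-corrupted Van der Pol oscillator observed through a
  Poisson spike-count readout ``y ~ Poisson(dt exp(C z + b))``;
* ``cb``   — a two-dimensional system with conditionally
  continuous-Bernoulli transitions whose conditional-mean field has a
  limit cycle, observed through a linear-Gaussian readout.

All randomness flows from the config seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .core import Likelihood
from .dynamics import (
    CallableGaussianDynamics,
    ConditionalDynamics,
    LinearGaussianDynamics,
)
from .expfam import ContinuousBernoulliFamily

__all__ = [
    "LDSConfig", "CRNNConfig", "VDPConfig", "CBConfig",
    "SimOutput", "LimitCycleCBDynamics",
    "simulate_lds", "simulate_crnn", "simulate_vdp", "simulate_cb",
    "simulate",
]


@dataclass
class SimOutput:
    """Latents, observations and the generative model that produced them."""

    zs: np.ndarray                      # (T, L)
    ys: np.ndarray                      # (T, N)
    true_dynamics: ConditionalDynamics
    likelihood: Likelihood
    params: dict

    def write(self, outdir) -> None:
        """observations.csv (t + N cols), latents.csv (t + L cols), params.json."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        T, N = self.ys.shape
        L = self.zs.shape[1]
        pd.DataFrame(
            self.ys, columns=[f"y_{i}" for i in range(N)]
        ).assign(t=np.arange(1, T + 1)).set_index("t").to_csv(
            outdir / "observations.csv")
        pd.DataFrame(
            self.zs, columns=[f"z_{i}" for i in range(L)]
        ).assign(t=np.arange(1, T + 1)).set_index("t").to_csv(
            outdir / "latents.csv")
        with open(outdir / "params.json", "w") as f:
            json.dump(_jsonify(self.params), f, indent=2)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _validate(T, noise_scales):
    if T < 1:
        raise ValueError("T must be >= 1")
    for name, s in noise_scales.items():
        if s <= 0:
            raise ValueError(f"noise scale {name} must be > 0")


# ----------------------------------------------------------------------
# linear-Gaussian SSM
# ----------------------------------------------------------------------

@dataclass
class LDSConfig:
    system: str = "lds"
    L: int = 2
    N: int = 5
    T: int = 200
    seed: int = 0
    A: Optional[np.ndarray] = None       # default: random, spectral radius 0.9
    Q_scale: float = 0.1
    C: Optional[np.ndarray] = None
    b: Optional[np.ndarray] = None
    R_scale: float = 0.1


def simulate_lds(cfg: LDSConfig) -> SimOutput:
    _validate(cfg.T, {"Q_scale": cfg.Q_scale, "R_scale": cfg.R_scale})
    rng = np.random.default_rng(cfg.seed)
    L, N = cfg.L, cfg.N
    if cfg.A is None:
        A = rng.standard_normal((L, L))
        A *= 0.9 / max(np.abs(np.linalg.eigvals(A)))
    else:
        A = np.atleast_2d(np.asarray(cfg.A, dtype=float))
    Q = cfg.Q_scale * np.eye(L)
    C = (np.atleast_2d(np.asarray(cfg.C, dtype=float)) if cfg.C is not None
         else rng.standard_normal((N, L)))
    b = (np.atleast_1d(np.asarray(cfg.b, dtype=float)) if cfg.b is not None
         else np.zeros(N))
    R = cfg.R_scale * np.eye(N)
    chol_Q = np.sqrt(cfg.Q_scale)
    chol_R = np.sqrt(cfg.R_scale)
    zs = np.empty((cfg.T, L))
    z = np.zeros(L)
    for t in range(cfg.T):
        z = A @ z + chol_Q * rng.standard_normal(L)
        zs[t] = z
    ys = zs @ C.T + b + chol_R * rng.standard_normal((cfg.T, N))
    dyn = LinearGaussianDynamics(A, Q)
    lik = Likelihood("gaussian", C, b, R=R)
    return SimOutput(zs, ys, dyn, lik,
                     {"system": "lds", "A": A, "Q": Q, "C": C, "b": b, "R": R,
                      "seed": cfg.seed})


# ----------------------------------------------------------------------
# chaotic recurrent network
# ----------------------------------------------------------------------

@dataclass
class CRNNConfig:
    system: str = "crnn"
    L: int = 2
    N: int = 10
    T: int = 250
    seed: int = 0
    gamma: float = 2.5    # coupling gain; > 1 puts the network in the
    tau: float = 0.025    # chaotic regime for large L
    dt: float = 0.001
    Q_scale: float = 1e-3
    R_scale: float = 0.01


def _crnn_mean(W, gamma, alpha):
    def f(Z):
        Z = np.atleast_2d(Z)
        return Z + alpha * (gamma * np.tanh(Z) @ W.T - Z)
    return f


def simulate_crnn(cfg: CRNNConfig) -> SimOutput:
    _validate(cfg.T, {"Q_scale": cfg.Q_scale, "R_scale": cfg.R_scale})
    rng = np.random.default_rng(cfg.seed)
    L, N = cfg.L, cfg.N
    W = rng.standard_normal((L, L)) / np.sqrt(L)
    alpha = cfg.dt / cfg.tau
    f = _crnn_mean(W, cfg.gamma, alpha)

    def jac(z):
        sech2 = 1.0 - np.tanh(z) ** 2
        return (1.0 - alpha) * np.eye(L) + alpha * cfg.gamma * W * sech2[None, :]

    chol_Q = np.sqrt(cfg.Q_scale)
    zs = np.empty((cfg.T, L))
    z = 0.5 * rng.standard_normal(L)
    for t in range(cfg.T):
        z = f(z[None, :])[0] + chol_Q * rng.standard_normal(L)
        zs[t] = z
    C = rng.standard_normal((N, L)) / np.sqrt(L)
    b = np.zeros(N)
    R = cfg.R_scale * np.eye(N)
    ys = zs @ C.T + b + np.sqrt(cfg.R_scale) * rng.standard_normal((cfg.T, N))
    dyn = CallableGaussianDynamics(f, cfg.Q_scale * np.eye(L), L, jac=jac)
    lik = Likelihood("gaussian", C, b, R=R)
    return SimOutput(zs, ys, dyn, lik,
                     {"system": "crnn", "W": W, "gamma": cfg.gamma,
                      "tau": cfg.tau, "dt": cfg.dt, "Q_scale": cfg.Q_scale,
                      "C": C, "b": b, "R": R, "seed": cfg.seed})


# ----------------------------------------------------------------------
# Van der Pol oscillator with Poisson observations
# ----------------------------------------------------------------------

@dataclass
class VDPConfig:
    system: str = "vdp"
    L: int = 2                 # fixed by the oscillator; kept for uniformity
    N: int = 50
    T: int = 4000
    seed: int = 0
    tau1: float = 0.1
    tau2: float = 0.1
    gamma: float = 1.5         # damping / nonlinearity strength
    sigma: float = 0.05        # additive state-noise scale per step
    dt: float = 0.01           # time-bin width (drives both dynamics & rates)
    C_scale: float = 0.5       # readout entries ~ N(0, C_scale^2)
    target_rate: float = 0.1   # mean spike count per bin the offset b is set to
    z0: tuple = (1.0, 0.0)


def vdp_mean(tau1: float, tau2: float, gamma: float, dt: float):
    """One deterministic Euler step of the Van der Pol vector field."""
    def f(Z):
        Z = np.atleast_2d(Z)
        z1, z2 = Z[:, 0], Z[:, 1]
        return np.stack(
            [z1 + (dt / tau1) * z2,
             z2 + (dt / tau2) * (gamma * (1.0 - z1**2) * z2 - z1)], axis=1)
    return f


def vdp_jacobian(tau1, tau2, gamma, dt):
    def jac(z):
        z1, z2 = z
        return np.array([
            [1.0, dt / tau1],
            [(dt / tau2) * (-2.0 * gamma * z1 * z2 - 1.0),
             1.0 + (dt / tau2) * gamma * (1.0 - z1**2)],
        ])
    return jac


def simulate_vdp(cfg: VDPConfig) -> SimOutput:
    if cfg.L != 2:
        raise ValueError("the Van der Pol oscillator is two-dimensional")
    _validate(cfg.T, {"sigma": cfg.sigma})
    rng = np.random.default_rng(cfg.seed)
    f = vdp_mean(cfg.tau1, cfg.tau2, cfg.gamma, cfg.dt)
    zs = np.empty((cfg.T, 2))
    z = np.asarray(cfg.z0, dtype=float)
    for t in range(cfg.T):
        # independent standard-normal noise per coordinate, scaled by sigma
        z = f(z[None, :])[0] + cfg.sigma * rng.standard_normal(2)
        zs[t] = z
    C = cfg.C_scale * rng.standard_normal((cfg.N, 2))
    # offset per neuron so the average count per bin is ~ target_rate
    with np.errstate(over="ignore"):
        mean_gain = np.exp(zs @ C.T).mean(axis=0)
    if not np.all(np.isfinite(mean_gain)):
        raise FloatingPointError(
            "Poisson rate overflow while calibrating offsets: reduce C_scale")
    b = np.log(cfg.target_rate / (cfg.dt * mean_gain))
    log_rate = np.log(cfg.dt) + zs @ C.T + b
    if np.any(zs @ C.T + b > 30.0):
        raise FloatingPointError(
            "Poisson rate overflow: C/b scaling puts exp argument above 30")
    ys = rng.poisson(np.exp(log_rate)).astype(float)
    dyn = CallableGaussianDynamics(
        f, cfg.sigma**2 * np.eye(2), 2,
        jac=vdp_jacobian(cfg.tau1, cfg.tau2, cfg.gamma, cfg.dt))
    lik = Likelihood("poisson", C, b, dt=cfg.dt)
    return SimOutput(zs, ys, dyn, lik,
                     {"system": "vdp", "tau1": cfg.tau1, "tau2": cfg.tau2,
                      "gamma": cfg.gamma, "sigma": cfg.sigma, "dt": cfg.dt,
                      "C": C, "b": b, "seed": cfg.seed})


# ----------------------------------------------------------------------
# continuous-Bernoulli limit-cycle system
# ----------------------------------------------------------------------

class LimitCycleCBDynamics(ConditionalDynamics):
    """Ground-truth conditionally continuous-Bernoulli dynamics on [0,1]^2.

    The conditional mean follows an Euler step of a Hopf-type field on
    centred coordinates ``u = 2z - 1`` (rotation at angular rate
    ``omega`` plus radial attraction of strength ``rho`` toward radius
    ``r0``); the resulting target mean is mapped back to a CB natural
    parameter and amplified by ``kappa > 1``, which produces the strong
    parameter-space attraction that makes trajectories saturate near the
    boundary while remaining cyclic in the mean.  Not trainable: this is
    the synthetic data-generating process, not a model class.
    """

    trainable = False

    def __init__(self, omega: float = 0.6, rho: float = 2.0, r0: float = 0.75,
                 dt: float = 0.25, kappa: float = 3.0, margin: float = 0.02):
        self.family = ContinuousBernoulliFamily(2)
        self.omega = omega
        self.rho = rho
        self.r0 = r0
        self.dt = dt
        self.kappa = kappa
        self.margin = margin

    def eval_lambda_batch(self, Z):
        Z = np.atleast_2d(Z)
        U = 2.0 * Z - 1.0
        r2 = np.sum(U**2, axis=1, keepdims=True)
        rot = np.stack([-U[:, 1], U[:, 0]], axis=1)
        V = self.omega * rot + self.rho * (self.r0**2 - r2) * U
        U_next = U + self.dt * V
        m_next = np.clip(0.5 * (1.0 + U_next), self.margin, 1.0 - self.margin)
        fam = self.family
        lam = np.empty_like(m_next)
        for i in range(m_next.shape[0]):
            lam[i] = fam._mean_to_natural(m_next[i])
        return self.kappa * lam


@dataclass
class CBConfig:
    system: str = "cb"
    L: int = 2
    N: int = 10
    T: int = 1000
    seed: int = 0
    omega: float = 0.6
    rho: float = 2.0
    r0: float = 0.75
    dt_cycle: float = 0.25
    kappa: float = 3.0
    C_scale: float = 1.0
    R_scale: float = 0.01      # observation noise variance r^2


def simulate_cb(cfg: CBConfig) -> SimOutput:
    if cfg.L != 2:
        raise ValueError("the shipped CB limit-cycle system is two-dimensional")
    _validate(cfg.T, {"R_scale": cfg.R_scale})
    rng = np.random.default_rng(cfg.seed)
    dyn = LimitCycleCBDynamics(cfg.omega, cfg.rho, cfg.r0, cfg.dt_cycle,
                               cfg.kappa)
    zs = np.empty((cfg.T, 2))
    z = np.array([0.8, 0.5])
    for t in range(cfg.T):
        z = dyn.transition_sample(z, rng)
        zs[t] = z
    C = cfg.C_scale * rng.standard_normal((cfg.N, 2))
    b = np.zeros(cfg.N)
    R = cfg.R_scale * np.eye(cfg.N)
    ys = zs @ C.T + b + np.sqrt(cfg.R_scale) * rng.standard_normal((cfg.T, cfg.N))
    lik = Likelihood("gaussian", C, b, R=R)
    return SimOutput(zs, ys, dyn, lik,
                     {"system": "cb", "omega": cfg.omega, "rho": cfg.rho,
                      "r0": cfg.r0, "dt_cycle": cfg.dt_cycle,
                      "kappa": cfg.kappa, "C": C, "b": b, "R": R,
                      "seed": cfg.seed})


_SIMULATORS = {"lds": (LDSConfig, simulate_lds),
               "crnn": (CRNNConfig, simulate_crnn),
               "vdp": (VDPConfig, simulate_vdp),
               "cb": (CBConfig, simulate_cb)}


def simulate(cfg) -> SimOutput:
    """Dispatch on ``cfg.system``; accepts a config dataclass or a dict."""
    if isinstance(cfg, dict):
        system = cfg.get("system")
        if system not in _SIMULATORS:
            raise ValueError(f"unknown system {system!r}; "
                             f"choose from {sorted(_SIMULATORS)}")
        cls, fn = _SIMULATORS[system]
        valid = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(cfg) - valid
        if unknown:
            raise ValueError(f"unknown config fields for {system}: {sorted(unknown)}")
        return fn(cls(**cfg))
    return _SIMULATORS[cfg.system][1](cfg)
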