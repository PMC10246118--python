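"""Evaluation measures for filtering and dynamics learning.

Four measures: latent-state RMSE, the temporal-average log density of
the filtering posteriors at the true latents, a one-step conditional KL
between true and learned dynamics evaluated on jittered attractor
samples, and a symmetrised log Chamfer distance that compares the global
geometry of trajectories generated by learned versus true dynamics.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import expfam
from .core import VariationalPosterior
from .dynamics import ConditionalDynamics
from .expfam import FamilyMismatchError

__all__ = [
    "rmse",
    "filtering_log_density",
    "dynamics_kl",
    "chamfer",
    "sym_log_chamfer",
    "attractor_points",
    "metrics_report",
]


def rmse(means: np.ndarray, zs_true: np.ndarray) -> float:
    """Root mean squared error over all T x L entries."""
    means = np.asarray(means, dtype=float)
    zs_true = np.asarray(zs_true, dtype=float)
    if means.shape != zs_true.shape:
        raise ValueError(f"shape mismatch {means.shape} vs {zs_true.shape}")
    return float(np.sqrt(np.mean((means - zs_true) ** 2)))


def filtering_log_density(posteriors: Sequence[VariationalPosterior],
                          zs_true: np.ndarray) -> float:
    """T^{-1} sum_t log q(z_t^true; lambda_t^*).

    Raises if a true latent falls outside the posterior family's support
    (e.g. a negative value under a Gamma posterior).
    """
    zs_true = np.atleast_2d(np.asarray(zs_true, dtype=float))
    if len(posteriors) != zs_true.shape[0]:
        raise ValueError("number of posteriors must match number of latents")
    total = 0.0
    for q, z in zip(posteriors, zs_true):
        _check_support(q.family, z)
        total += float(expfam.log_density(q.lam, z)[0])
    return total / len(posteriors)


def _check_support(family, z):
    s = family.support
    if s.startswith("[0,1]") and (np.any(z < 0) or np.any(z > 1)):
        raise ValueError(f"latent {z} outside the unit-interval support")
    if s.startswith("positive") and np.any(z <= 0):
        raise ValueError(f"latent {z} outside the positive support")


def dynamics_kl(true_dyn: ConditionalDynamics, learned_dyn: ConditionalDynamics,
                attractor_samples: np.ndarray, perturb_scale: float = 0.1,
                rng: np.random.Generator | None = None) -> float:
    """Mean one-step KL(learned || true) over jittered attractor points.

    Each attractor point is perturbed with isotropic Gaussian noise of
    scale ``perturb_scale`` (clipped back into the support for bounded
    families) and the conditional distributions of both dynamics at the
    perturbed point are compared with the exact exponential-family KL.
    The learned conditional is the first (left) KL argument.
    """
    if true_dyn.family != learned_dyn.family:
        raise FamilyMismatchError("dynamics to compare must share a family")
    pts = np.atleast_2d(np.asarray(attractor_samples, dtype=float))
    if rng is not None and perturb_scale > 0:
        pts = pts + perturb_scale * rng.standard_normal(pts.shape)
        s = true_dyn.family.support
        if s.startswith("[0,1]"):
            pts = np.clip(pts, 1e-3, 1 - 1e-3)
        elif s.startswith("positive"):
            pts = np.abs(pts) + 1e-6
    lam_true = true_dyn.eval_lambda_batch(pts)
    lam_learned = learned_dyn.eval_lambda_batch(pts)
    fam = true_dyn.family
    kls = [expfam.kl_divergence(fam.natural(lq), fam.natural(lp))
           for lq, lp in zip(lam_learned, lam_true)]
    return float(np.mean(kls))


def chamfer(s1: np.ndarray, s2: np.ndarray) -> float:
    """Two-directional average nearest-neighbour squared distance.

    ``|S1|^{-1} sum_{x in S1} min_y ||x-y||^2 +
    |S2|^{-1} sum_{y in S2} min_x ||y-x||^2``.
    As printed this already sums both directions; the symmetrised wrapper
    below is therefore idempotent on it, but both are provided since the
    directional version is the primitive.
    """
    s1 = np.atleast_2d(np.asarray(s1, dtype=float))
    s2 = np.atleast_2d(np.asarray(s2, dtype=float))
    if s1.size == 0 or s2.size == 0:
        raise ValueError("point sets must be non-empty")
    if s1.shape[1] != s2.shape[1]:
        raise ValueError("point sets must share a dimension")
    d12 = cKDTree(s2).query(s1)[0]
    d21 = cKDTree(s1).query(s2)[0]
    return float(np.mean(d12**2) + np.mean(d21**2))


def sym_log_chamfer(s1: np.ndarray, s2: np.ndarray) -> float:
    """log(1/2 (chamfer(s1, s2) + chamfer(s2, s1))).

    Identical point sets give Chamfer distance 0 and the value ``-inf``
    is returned as the documented sentinel.
    """
    c = 0.5 * (chamfer(s1, s2) + chamfer(s2, s1))
    with np.errstate(divide="ignore"):
        return float(np.log(c))


def attractor_points(dyn: ConditionalDynamics, z0: np.ndarray,
                     n_warmup: int = 500, n_keep: int = 500,
                     rng: np.random.Generator | None = None,
                     noiseless: bool = True) -> np.ndarray:
    """Roll out the dynamics and keep the last ``n_keep`` states.

    With ``noiseless=True`` the conditional mean map is iterated, tracing
    the attractor of the mean field; otherwise ``rng`` drives sampled
    transitions.
    """
    z = np.atleast_1d(np.asarray(z0, dtype=float))
    out = np.empty((n_keep, z.size))
    for t in range(n_warmup + n_keep):
        if noiseless:
            lam = dyn.eval_lambda_batch(z[None, :])[0]
            z = _conditional_mean(dyn.family, lam)
        else:
            if rng is None:
                raise ValueError("sampled rollout requires an rng")
            z = dyn.transition_sample(z, rng)
        if t >= n_warmup:
            out[t - n_warmup] = z
    return out


def _conditional_mean(family, lam: np.ndarray) -> np.ndarray:
    """E[z] under the family member with naturals ``lam``."""
    from .expfam import GammaFamily, GaussianFamily

    if isinstance(family, GaussianFamily):
        m, _ = family.to_moments(lam)
        return m
    if isinstance(family, GammaFamily):
        alpha, beta = family.shape_rate(lam)
        return alpha / beta
    return family._natural_to_mean(lam)  # t(z) = z families


def metrics_report(means, zs_true, posteriors=None, true_dyn=None,
                   learned_dyn=None, attractor=None, gen_points=None,
                   true_points=None, perturb_scale: float = 0.1,
                   rng=None) -> dict:
    """Flat JSON-ready report with whichever measures the inputs allow."""
    rep = {"rmse": rmse(means, zs_true)}
    if posteriors is not None:
        rep["log_density"] = filtering_log_density(posteriors, zs_true)
    if true_dyn is not None and learned_dyn is not None and attractor is not None:
        rep["dynamics_kl"] = dynamics_kl(true_dyn, learned_dyn, attractor,
                                         perturb_scale, rng)
    if gen_points is not None and true_points is not None:
        rep["sym_log_chamfer"] = sym_log_chamfer(gen_points, true_points)
    return rep
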