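"""Minimal constant-base-measure exponential families.

Every latent-state distribution used by the filter is a member of a
*minimal* exponential family with a base measure that is constant over the
support,

    p(z) = h * exp(lambda . t(z) - A(lambda)),

so that the natural parameters ``lambda`` and the mean parameters
``mu = E[t(z)]`` are linked by the bijection ``mu = grad A(lambda)``.  The
families shipped here are the ones the filter needs: a full-covariance
Gaussian (minimal via half-vectorised second moments), a factorised
continuous Bernoulli on ``[0,1]^L``, a factorised Gamma on the positive
orthant, and a factorised Bernoulli used in conjugacy tests.

All numerical parameter vectors are flat 1-D ``numpy`` arrays; the thin
:class:`NaturalParams` / :class:`MeanParams` wrappers carry the owning
family and are what the public module-level functions accept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special, stats

__all__ = [
    "DomainError",
    "FamilyMismatchError",
    "ConvergenceError",
    "ExponentialFamily",
    "GaussianFamily",
    "ContinuousBernoulliFamily",
    "GammaFamily",
    "BernoulliFamily",
    "NaturalParams",
    "MeanParams",
    "log_partition",
    "natural_to_mean",
    "mean_to_natural",
    "sample",
    "kl_divergence",
    "entropy",
    "log_density",
    "vech",
    "unvech",
]

_EIG_TOL = 1e-10  # relative eigenvalue tolerance for SPD checks


def _assert_spd(w: np.ndarray, what: str) -> None:
    # relative test: admits well-conditioned but tiny-scale matrices
    if w.min() <= max(_EIG_TOL * abs(w.max()), 0.0):
        raise DomainError(
            f"{what} not positive-definite (eigs in [{w.min():.3e}, {w.max():.3e}])")


class DomainError(ValueError):
    """Parameter vector outside the family's valid domain."""


class FamilyMismatchError(ValueError):
    """Operation mixing members of different families."""


class ConvergenceError(RuntimeError):
    """Iterative inverse parameter map failed to converge."""


# ----------------------------------------------------------------------
# symmetric-matrix half-vectorisation helpers (upper triangle, row-major)
# ----------------------------------------------------------------------

def vech(M: np.ndarray) -> np.ndarray:
    """Half-vectorise a symmetric matrix (upper triangle, row-major)."""
    L = M.shape[0]
    iu = np.triu_indices(L)
    return np.asarray(M)[iu]


def unvech(v: np.ndarray, L: int) -> np.ndarray:
    """Inverse of :func:`vech`; rebuilds the full symmetric matrix."""
    M = np.zeros((L, L))
    iu = np.triu_indices(L)
    M[iu] = v
    M = M + M.T
    M[np.diag_indices(L)] /= 2.0
    return M


def _vech2(M: np.ndarray) -> np.ndarray:
    # doubled off-diagonals: the natural-parameter storage convention that
    # makes lambda . vech(zz^T) == z^T M z and keeps mu = grad A exact
    L = M.shape[0]
    out = 2.0 * np.asarray(M, dtype=float).copy()
    out[np.diag_indices(L)] /= 2.0
    return out[np.triu_indices(L)]


def _unvech2(v: np.ndarray, L: int) -> np.ndarray:
    M = unvech(v, L)
    off = ~np.eye(L, dtype=bool)
    M[off] /= 2.0
    return M


# ----------------------------------------------------------------------
# family base class and parameter wrappers
# ----------------------------------------------------------------------

class ExponentialFamily:
    """Abstract minimal exponential family with constant base measure."""

    name: str = "abstract"
    dim_z: int
    dim_lambda: int
    support: str = ""
    log_h: float = 0.0  # log of the constant base measure

    # --- array-level interface implemented by subclasses ---
    def _check_natural(self, lam: np.ndarray) -> None:
        raise NotImplementedError

    def _check_mean(self, mu: np.ndarray) -> None:
        raise NotImplementedError

    def _log_partition(self, lam: np.ndarray) -> float:
        raise NotImplementedError

    def _natural_to_mean(self, lam: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _mean_to_natural(self, mu: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _sample(self, lam: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def _suff_stats(self, z: np.ndarray) -> np.ndarray:
        """t(z) for a batch of points, shape (n, dim_lambda)."""
        raise NotImplementedError

    # --- derived quantities shared by all families ---
    def _log_density(self, z: np.ndarray, lam: np.ndarray) -> np.ndarray:
        t = self._suff_stats(np.atleast_2d(z))
        return self.log_h + t @ lam - self._log_partition(lam)

    def _entropy(self, lam: np.ndarray) -> float:
        mu = self._natural_to_mean(lam)
        return float(self._log_partition(lam) - lam @ mu - self.log_h)

    def natural(self, values: np.ndarray) -> "NaturalParams":
        return NaturalParams(np.asarray(values, dtype=float), self)

    def mean(self, values: np.ndarray) -> "MeanParams":
        return MeanParams(np.asarray(values, dtype=float), self)

    def is_valid_natural(self, lam: np.ndarray) -> bool:
        try:
            self._check_natural(np.asarray(lam, dtype=float))
            return True
        except DomainError:
            return False

    def __eq__(self, other) -> bool:
        return (
            type(self) is type(other)
            and self.dim_z == other.dim_z
            and self.dim_lambda == other.dim_lambda
        )

    def __hash__(self):
        return hash((type(self).__name__, self.dim_z))

    def __repr__(self):
        return f"{type(self).__name__}(L={self.dim_z})"


@dataclass(frozen=True)
class NaturalParams:
    """A natural-parameter vector tagged with its family (validated)."""

    values: np.ndarray
    family: ExponentialFamily

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())
        if self.values.shape != (self.family.dim_lambda,):
            raise DomainError(
                f"natural parameter length {self.values.size} != "
                f"dim_lambda {self.family.dim_lambda} of {self.family!r}"
            )
        self.family._check_natural(self.values)

    def to_json(self) -> dict:
        return {"family": self.family.name, "dim_z": self.family.dim_z,
                "values": self.values.tolist()}


@dataclass(frozen=True)
class MeanParams:
    """A mean-parameter vector mu = E[t(z)] tagged with its family."""

    values: np.ndarray
    family: ExponentialFamily

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())
        if self.values.shape != (self.family.dim_lambda,):
            raise DomainError("mean parameter length mismatch")
        self.family._check_mean(self.values)


# ----------------------------------------------------------------------
# Gaussian
# ----------------------------------------------------------------------

class GaussianFamily(ExponentialFamily):
    """Full-covariance multivariate Gaussian in minimal form.

    Sufficient statistics ``t(z) = (z, vech(z z^T))``.  A member with
    moments ``(m, P)`` has natural parameters ``eta1 = P^{-1} m`` and
    ``Lam2 = -1/2 P^{-1}``; the storage layout is ``[eta1,
    vech2(Lam2)]`` where ``vech2`` doubles the off-diagonal entries so
    that the inner product with plain ``vech`` mean parameters equals the
    matrix trace pairing and ``mu = grad A(lambda)`` holds exactly in the
    stored coordinates.
    """

    name = "gaussian"
    support = "real^L"

    def __init__(self, dim_z: int):
        self.dim_z = int(dim_z)
        self.dim_lambda = self.dim_z + self.dim_z * (self.dim_z + 1) // 2
        self.log_h = -0.5 * self.dim_z * np.log(2.0 * np.pi)

    # layout helpers -----------------------------------------------------
    def split_natural(self, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(eta1, Lam2)`` with Lam2 the full symmetric matrix."""
        L = self.dim_z
        return lam[:L], _unvech2(lam[L:], L)

    def join_natural(self, eta1: np.ndarray, Lam2: np.ndarray) -> np.ndarray:
        return np.concatenate([np.asarray(eta1, float).ravel(), _vech2(Lam2)])

    def from_moments(self, m: np.ndarray, P: np.ndarray) -> NaturalParams:
        m = np.atleast_1d(np.asarray(m, dtype=float))
        P = np.atleast_2d(np.asarray(P, dtype=float))
        Prec = _spd_inverse(P)
        return self.natural(self.join_natural(Prec @ m, -0.5 * Prec))

    def to_moments(self, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eta1, Lam2 = self.split_natural(lam)
        P = _spd_inverse(-2.0 * Lam2)
        return P @ eta1, P

    # core interface -----------------------------------------------------
    def _check_natural(self, lam: np.ndarray) -> None:
        _, Lam2 = self.split_natural(lam)
        Prec = -2.0 * Lam2
        _assert_spd(np.linalg.eigvalsh(Prec), "Gaussian precision")
        try:  # the same factorisation every downstream operation relies on
            np.linalg.cholesky(Prec)
        except np.linalg.LinAlgError as e:
            raise DomainError(f"Gaussian precision not factorisable: {e}") from e

    def _check_mean(self, mu: np.ndarray) -> None:
        L = self.dim_z
        m = mu[:L]
        M = unvech(mu[L:], L)
        _assert_spd(np.linalg.eigvalsh(M - np.outer(m, m)),
                    "second-moment block minus outer(m, m)")

    def _log_partition(self, lam: np.ndarray) -> float:
        eta1, Lam2 = self.split_natural(lam)
        Prec = -2.0 * Lam2
        c, low = linalg.cho_factor(Prec, lower=True)
        m = linalg.cho_solve((c, low), eta1)
        logdet_prec = 2.0 * np.sum(np.log(np.diag(c)))
        return float(0.5 * eta1 @ m - 0.5 * logdet_prec)

    def _natural_to_mean(self, lam: np.ndarray) -> np.ndarray:
        m, P = self.to_moments(lam)
        return np.concatenate([m, vech(P + np.outer(m, m))])

    def _mean_to_natural(self, mu: np.ndarray) -> np.ndarray:
        L = self.dim_z
        m = mu[:L]
        P = unvech(mu[L:], L) - np.outer(m, m)
        Prec = _spd_inverse(P)
        return self.join_natural(Prec @ m, -0.5 * Prec)

    def _sample(self, lam, n, rng):
        m, P = self.to_moments(lam)
        chol = np.linalg.cholesky(P)
        eps = rng.standard_normal((n, self.dim_z))
        return m + eps @ chol.T

    def _suff_stats(self, z):
        z = np.atleast_2d(z)
        iu = np.triu_indices(self.dim_z)
        outer = z[:, :, None] * z[:, None, :]
        return np.concatenate([z, outer[:, iu[0], iu[1]]], axis=1)


def _spd_inverse(M: np.ndarray) -> np.ndarray:
    M = 0.5 * (M + M.T)
    _assert_spd(np.linalg.eigvalsh(M), "matrix")
    try:
        c, low = linalg.cho_factor(M, lower=True)
    except np.linalg.LinAlgError as e:  # borderline indefinite after rounding
        raise DomainError(f"Cholesky failed on near-singular matrix: {e}") from e
    inv = linalg.cho_solve((c, low), np.eye(M.shape[0]))
    return 0.5 * (inv + inv.T)


# ----------------------------------------------------------------------
# continuous Bernoulli
# ----------------------------------------------------------------------

_CB_SMALL = 1e-4  # below this |lambda| the closed forms are 0/0; use series


def _cb_log_partition(lam):
    """log((exp(lam)-1)/lam) per coordinate, numerically stable."""
    lam = np.asarray(lam, dtype=float)
    out = np.empty_like(lam)
    small = np.abs(lam) < _CB_SMALL
    ls = lam[small]
    out[small] = ls / 2.0 + ls**2 / 24.0 - ls**4 / 2880.0
    lb = lam[~small]
    pos = lb > 0
    res = np.empty_like(lb)
    res[pos] = lb[pos] + np.log1p(-np.exp(-lb[pos])) - np.log(lb[pos])
    res[~pos] = np.log1p(-np.exp(lb[~pos])) - np.log(-lb[~pos])
    out[~small] = res
    return out


def _cb_mean(lam):
    """A'(lambda) = 1/(1-exp(-lambda)) - 1/lambda, elementwise."""
    lam = np.asarray(lam, dtype=float)
    out = np.empty_like(lam)
    small = np.abs(lam) < _CB_SMALL
    ls = lam[small]
    out[small] = 0.5 + ls / 12.0 - ls**3 / 720.0
    lb = lam[~small]
    out[~small] = 1.0 / (-np.expm1(-np.clip(lb, -700, 700))) - 1.0 / lb
    return out


def _cb_var(lam):
    """A''(lambda) = 1/lambda^2 - 1/(4 sinh^2(lambda/2))."""
    lam = np.asarray(lam, dtype=float)
    out = np.empty_like(lam)
    small = np.abs(lam) < _CB_SMALL
    ls = lam[small]
    out[small] = 1.0 / 12.0 - ls**2 / 240.0 + ls**4 / 6048.0
    lb = lam[~small]
    big = np.abs(lb) > 40.0  # sinh term underflows the 1/lambda^2 term
    r = np.empty_like(lb)
    r[big] = 1.0 / lb[big] ** 2
    lm = lb[~big]
    r[~big] = 1.0 / lm**2 - 0.25 / np.sinh(lm / 2.0) ** 2
    out[~small] = r
    return out


def _cb_dvar(lam):
    """A'''(lambda) = -2/lambda^3 + cosh(lambda/2)/(4 sinh^3(lambda/2))."""
    lam = np.asarray(lam, dtype=float)
    out = np.empty_like(lam)
    small = np.abs(lam) < _CB_SMALL
    ls = lam[small]
    out[small] = -ls / 120.0 + ls**3 / 1512.0
    lb = lam[~small]
    big = np.abs(lb) > 40.0
    r = np.empty_like(lb)
    r[big] = -2.0 / lb[big] ** 3
    lm = lb[~big]
    r[~big] = -2.0 / lm**3 + 0.25 * np.cosh(lm / 2.0) / np.sinh(lm / 2.0) ** 3
    out[~small] = r
    return out


class ContinuousBernoulliFamily(ExponentialFamily):
    """Factorised continuous Bernoulli on the unit hypercube.

    Each coordinate has density proportional to ``exp(lambda_i z_i)`` on
    ``[0, 1]``; any real ``lambda_i`` is valid.  Sampling is by inverse
    CDF.  The inverse mean map has no closed form and is solved by a
    safeguarded Newton iteration per coordinate.
    """

    name = "continuous_bernoulli"
    support = "[0,1]^L"

    def __init__(self, dim_z: int):
        self.dim_z = int(dim_z)
        self.dim_lambda = self.dim_z

    def _check_natural(self, lam):
        if not np.all(np.isfinite(lam)):
            raise DomainError("continuous Bernoulli naturals must be finite")

    def _check_mean(self, mu):
        if np.any(mu <= 0.0) or np.any(mu >= 1.0):
            raise DomainError("continuous Bernoulli means must lie in (0, 1)")

    def _log_partition(self, lam):
        return float(np.sum(_cb_log_partition(lam)))

    def _natural_to_mean(self, lam):
        return _cb_mean(lam)

    def variance(self, lam: np.ndarray) -> np.ndarray:
        """Per-coordinate variance A''(lambda)."""
        return _cb_var(lam)

    def _mean_to_natural(self, mu, tol=1e-12, max_iter=100):
        lam = np.empty_like(np.asarray(mu, dtype=float))
        for i, m in enumerate(np.atleast_1d(mu)):
            lam[i] = _cb_invert_mean(float(m), tol, max_iter)
        return lam

    def _sample(self, lam, n, rng):
        lam = np.clip(np.asarray(lam, dtype=float), -700, 700)
        u = rng.uniform(size=(n, self.dim_z))
        out = np.empty_like(u)
        small = np.abs(lam) < _CB_SMALL
        ls = lam[small]
        us = u[:, small]
        out[:, small] = us + 0.5 * ls * us * (1.0 - us)
        lb = lam[~small]
        out[:, ~small] = np.log1p(u[:, ~small] * np.expm1(lb)) / lb
        return np.clip(out, 0.0, 1.0)

    def _suff_stats(self, z):
        return np.atleast_2d(z)


def _cb_invert_mean(m: float, tol: float, max_iter: int) -> float:
    if m == 0.5:
        return 0.0
    # initial guess from the near-uniform and saturated regimes
    if 0.2 < m < 0.8:
        lam = 12.0 * (m - 0.5)
    elif m >= 0.8:
        lam = 1.0 / (1.0 - m)
    else:
        lam = -1.0 / m
    for _ in range(max_iter):
        f = float(_cb_mean(np.array([lam]))[0]) - m
        fp = float(_cb_var(np.array([lam]))[0])
        step = f / fp
        new = lam - step
        if abs(step) <= tol * max(1.0, abs(lam)):
            return new
        lam = new
    # Newton stalled (can happen deep in the saturated tails): bisection
    lo, hi = (0.0, max(lam, 1.0)) if m > 0.5 else (min(lam, -1.0), 0.0)
    while float(_cb_mean(np.array([hi]))[0]) < m:
        hi *= 2.0
        if hi > 1e12:
            raise ConvergenceError(f"CB mean inversion diverged for mu={m}")
    while float(_cb_mean(np.array([lo]))[0]) > m:
        lo *= 2.0
        if lo < -1e12:
            raise ConvergenceError(f"CB mean inversion diverged for mu={m}")
    return float(optimize.brentq(
        lambda x: float(_cb_mean(np.array([x]))[0]) - m, lo, hi, xtol=1e-12))


# ----------------------------------------------------------------------
# Gamma
# ----------------------------------------------------------------------

class GammaFamily(ExponentialFamily):
    """Factorised Gamma on the positive orthant.

    Sufficient statistics per coordinate are ``(log z, z)`` with naturals
    ``(alpha - 1, -beta)``; the layout is ``[eta1 (L), eta2 (L)]``.  The
    base measure is the constant 1, which is what lets the filter use a
    Gamma latent state.  The inverse mean map solves
    ``log(alpha) - digamma(alpha) = log E[z] - E[log z]`` by Newton.
    """

    name = "gamma"
    support = "positive^L"

    def __init__(self, dim_z: int):
        self.dim_z = int(dim_z)
        self.dim_lambda = 2 * self.dim_z

    def split(self, lam):
        return lam[: self.dim_z], lam[self.dim_z:]

    def shape_rate(self, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e1, e2 = self.split(np.asarray(lam, dtype=float))
        return e1 + 1.0, -e2

    def from_shape_rate(self, alpha, beta) -> NaturalParams:
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        return self.natural(np.concatenate([alpha - 1.0, -beta]))

    def _check_natural(self, lam):
        e1, e2 = self.split(lam)
        if np.any(e1 <= -1.0) or np.any(e2 >= 0.0):
            raise DomainError(
                "Gamma naturals require eta1 > -1 (shape > 0) and eta2 < 0 (rate > 0)"
            )

    def _check_mean(self, mu):
        m_log, m_z = self.split(mu)
        if np.any(m_z <= 0.0):
            raise DomainError("Gamma mean E[z] must be positive")
        if np.any(np.log(m_z) - m_log <= 0.0):
            raise DomainError("Gamma means must satisfy log E[z] > E[log z]")

    def _log_partition(self, lam):
        alpha, beta = self.shape_rate(lam)
        return float(np.sum(special.gammaln(alpha) - alpha * np.log(beta)))

    def _natural_to_mean(self, lam):
        alpha, beta = self.shape_rate(lam)
        return np.concatenate([special.digamma(alpha) - np.log(beta), alpha / beta])

    def _mean_to_natural(self, mu, tol=1e-12, max_iter=100):
        m_log, m_z = self.split(np.asarray(mu, dtype=float))
        s = np.log(m_z) - m_log  # > 0 strictly, by Jensen
        alpha = np.empty_like(s)
        for i, si in enumerate(s):
            alpha[i] = _gamma_invert_shape(float(si), tol, max_iter)
        beta = alpha / m_z
        return np.concatenate([alpha - 1.0, -beta])

    def _sample(self, lam, n, rng):
        alpha, beta = self.shape_rate(lam)
        return rng.gamma(shape=alpha, scale=1.0 / beta, size=(n, self.dim_z))

    def _suff_stats(self, z):
        z = np.atleast_2d(z)
        return np.concatenate([np.log(z), z], axis=1)


def _gamma_invert_shape(s: float, tol: float, max_iter: int) -> float:
    """Solve log(alpha) - digamma(alpha) = s for alpha > 0 (s > 0)."""
    # classic closed-form starting point for this equation
    alpha = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = np.log(alpha) - special.digamma(alpha) - s
        fp = 1.0 / alpha - special.polygamma(1, alpha)
        step = f / fp
        new = alpha - step
        if new <= 0:
            new = alpha / 2.0
        if abs(new - alpha) <= tol * max(1.0, alpha):
            return new
        alpha = new
    raise ConvergenceError(
        f"Gamma shape inversion did not converge (s={s}, last alpha={alpha})"
    )


# ----------------------------------------------------------------------
# Bernoulli (discrete; used for conjugacy tests)
# ----------------------------------------------------------------------

class BernoulliFamily(ExponentialFamily):
    """Factorised Bernoulli on {0,1}^L with logit naturals."""

    name = "bernoulli"
    support = "{0,1}^L"

    def __init__(self, dim_z: int):
        self.dim_z = int(dim_z)
        self.dim_lambda = self.dim_z

    def _check_natural(self, lam):
        if not np.all(np.isfinite(lam)):
            raise DomainError("Bernoulli naturals must be finite")

    def _check_mean(self, mu):
        if np.any(mu <= 0.0) or np.any(mu >= 1.0):
            raise DomainError("Bernoulli means must lie in (0, 1)")

    def _log_partition(self, lam):
        return float(np.sum(np.logaddexp(0.0, lam)))

    def _natural_to_mean(self, lam):
        return special.expit(lam)

    def _mean_to_natural(self, mu):
        return special.logit(mu)

    def _sample(self, lam, n, rng):
        p = special.expit(lam)
        return (rng.uniform(size=(n, self.dim_z)) < p).astype(float)

    def _suff_stats(self, z):
        return np.atleast_2d(z)


# ----------------------------------------------------------------------
# public functional interface
# ----------------------------------------------------------------------

def log_partition(lam: NaturalParams) -> float:
    """A(lambda): the log-partition (cumulant) function."""
    return lam.family._log_partition(lam.values)


def natural_to_mean(lam: NaturalParams) -> MeanParams:
    """mu = grad A(lambda) = E[t(z)]."""
    return MeanParams(lam.family._natural_to_mean(lam.values), lam.family)


def mean_to_natural(mu: MeanParams) -> NaturalParams:
    """Inverse of :func:`natural_to_mean` on the open mean domain."""
    return NaturalParams(mu.family._mean_to_natural(mu.values), mu.family)


def sample(lam: NaturalParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. samples, shape ``(n, dim_z)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return lam.family._sample(lam.values, int(n), rng)


def kl_divergence(lam_q: NaturalParams, lam_p: NaturalParams) -> float:
    """KL(q || p) for two members of the same family.

    Uses the Bregman identity
    ``KL = (lambda_q - lambda_p) . mu_q - A(lambda_q) + A(lambda_p)``,
    in which the constant base measure cancels.
    """
    if lam_q.family != lam_p.family:
        raise FamilyMismatchError(
            f"cannot compare {lam_q.family!r} with {lam_p.family!r}")
    fam = lam_q.family
    mu_q = fam._natural_to_mean(lam_q.values)
    return float(
        (lam_q.values - lam_p.values) @ mu_q
        - fam._log_partition(lam_q.values)
        + fam._log_partition(lam_p.values)
    )


def entropy(lam: NaturalParams) -> float:
    """Differential (or discrete, for Bernoulli) entropy -E[log q]."""
    return lam.family._entropy(lam.values)


def log_density(lam: NaturalParams, z: np.ndarray) -> np.ndarray:
    """log q(z; lambda) for a batch of points, shape (n,)."""
    return lam.family._log_density(z, lam.values)
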