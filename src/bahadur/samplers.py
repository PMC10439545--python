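"""Sequential conditional samplers for order-2 multivariate Bernoulli vectors.

Both samplers draw the coordinates of X = (X_1, ..., X_m) one at a time, each
conditionally on the realized prefix.  Because the order-2 family is closed
under marginalization (restricting to the first n coordinates keeps the same
mu's and r's), the conditional success probability at step n has the closed
form

    P(X_n = 1 | x_1..x_{n-1}) = mu_n * (1 + S + z_n(1) t_n) / (1 + S),

where S = sum_{i<j<n} r_ij z_i z_j accumulates the realized pairwise terms,
t_n = sum_{i<n} r_in z_i couples variable n to the prefix, and
z_n(1) = sqrt((1-mu_n)/mu_n) is the standardized value of a success.

:func:`rb_unstr` maintains t_n from the realized z-history against an
arbitrary correlation matrix (O(m^2) per draw); :func:`rb_dplr` exploits a
diagonal-plus-low-rank structure R = D + U U^T by carrying the c-vector
w = sum_{i<n} z_i U_i, so t_n = U_n . w and each step costs O(c).

When the requested (mu, R) pair is not a valid probability distribution the
conditional probabilities eventually leave [0, 1]; the samplers then fail
transparently with :class:`InvalidDistributionError` naming the step, the
offending value, and the sample row, rather than silently renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .order2 import DPLR, FullCorrelation, Order2Spec, standardize

__all__ = [
    "InvalidDistributionError",
    "OpCounter",
    "conditional_success_prob",
    "prefix_conditional_prob",
    "rb_unstr",
    "rb_dplr",
]

#: conditional probabilities within this distance of [0, 1] are clamped;
#: anything further out raises InvalidDistributionError
CLAMP_TOL = 1e-9

#: |1 + S| below this aborts: the prefix has ~zero probability, which is
#: unreachable when the spec is a valid distribution
PREFIX_MASS_TOL = 1e-12

#: counted scalar operations per step that do not depend on the coupling
#: computation: probability formula (5), uniform comparison (1), realized-z
#: selection (1), S update (2)
_BASE_OPS_PER_STEP = 9


class InvalidDistributionError(ValueError):
    """The target (mu, R) is not a valid probability distribution.

    Raised by the samplers as soon as a conditional probability leaves
    [0, 1] (beyond clamping tolerance) or a prefix acquires ~zero mass.
    Carries the 0-based step index, the offending value, and the sample row.
    """

    def __init__(self, message: str, *, step: int | None = None,
                 value: float | None = None, sample_index: int | None = None):
        super().__init__(message)
        self.step = step
        self.value = value
        self.sample_index = sample_index


@dataclass
class OpCounter:
    """Accumulates the number of scalar arithmetic operations performed
    in the samplers' inner loops (deterministic work instrumentation)."""

    total: int = 0

    def add(self, n: int) -> None:
        self.total += int(n)


def _z_values(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z1 = np.sqrt((1.0 - mu) / mu)
    z0 = -np.sqrt(mu / (1.0 - mu))
    return z0, z1


def conditional_success_prob(mu_n, t_n, S, *, clamp_tol: float = CLAMP_TOL,
                             step: int | None = None):
    """P(X_n = 1 | prefix) given the coupling t_n and accumulator S.

    Vectorized over t_n / S.  Values within ``clamp_tol`` of [0, 1] are
    clamped to the boundary; beyond that an :class:`InvalidDistributionError`
    is raised identifying the step and worst offending value.
    """
    mu_n = float(mu_n)
    if not 0.0 < mu_n < 1.0:
        raise ValueError("mu_n must lie strictly in (0, 1)")
    t_n = np.asarray(t_n, dtype=float)
    S = np.asarray(S, dtype=float)
    denom = 1.0 + S
    bad_mass = np.abs(denom) < PREFIX_MASS_TOL
    if np.any(bad_mass):
        idx = int(np.argmax(bad_mass))
        raise InvalidDistributionError(
            f"prefix probability ~0 at step {step}: 1 + S = {denom.flat[idx]:.3e}",
            step=step, value=float(denom.flat[idx]), sample_index=idx,
        )
    z1 = np.sqrt((1.0 - mu_n) / mu_n)
    p = mu_n * (denom + z1 * t_n) / denom
    lo, hi = p.min(), p.max()
    if lo < -clamp_tol or hi > 1.0 + clamp_tol:
        offender = lo if lo < -clamp_tol else hi
        idx = int(np.argmin(p) if lo < -clamp_tol else np.argmax(p))
        raise InvalidDistributionError(
            f"conditional success probability {offender:.6g} outside [0, 1] "
            f"at step {step}: the target moments do not define a valid "
            f"probability distribution",
            step=step, value=float(offender), sample_index=idx,
        )
    return np.clip(p, 0.0, 1.0)


def prefix_conditional_prob(spec: Order2Spec, prefix) -> float:
    """P(X_{n+1} = 1 | X_1..X_n = prefix) for an explicit realized prefix.

    Routes through the same accumulator algebra as the samplers (the DPLR
    path if the spec is DPLR-structured), so tests can compare it against
    ratios of enumerated marginals.
    """
    prefix = np.asarray(prefix)
    n = prefix.shape[0]
    if n >= spec.m:
        raise ValueError("prefix must be shorter than m")
    mu = spec.mu
    if n == 0:
        return float(mu[0])
    z = standardize(prefix, mu[:n])
    if isinstance(spec.structure, DPLR):
        U = spec.structure.U
        w = z @ U[:n]                      # c-vector accumulator
        # S = sum_{i<j<=n} r_ij z_i z_j with r_ij = U_i . U_j off-diagonal
        S = 0.5 * (w @ w - np.einsum("i,ic,ic->", z * z, U[:n], U[:n]))
        t = float(U[n] @ w)
    else:
        R = spec.structure.R
        S = 0.5 * float(z @ R[:n, :n] @ z - z @ z)
        t = float(R[:n, n] @ z)
    return float(conditional_success_prob(mu[n], t, S, step=n))


def _draw_uniforms(rng: np.random.Generator, n_samples: int, m: int) -> np.ndarray:
    # One uniform variate per variable per sample, consumed column-by-column
    # in index order.  rb_unstr and rb_dplr share this discipline so that a
    # common seed yields identical streams (bit-identical output whenever the
    # conditional probabilities agree, which they do to ~1e-15).
    return rng.random((n_samples, m))


def rb_unstr(spec: Order2Spec, n_samples: int, rng: np.random.Generator,
             *, ops: OpCounter | None = None, return_probs: bool = False):
    """Sample i.i.d. order-2 MVB vectors under an arbitrary correlation matrix.

    O(m^2) work per draw: step n recomputes the coupling t_n = sum_{i<n}
    r_in z_i from the realized z-history.

    Parameters
    ----------
    spec : Order2Spec
        Any structure; a DPLR structure is expanded to its full matrix.
    n_samples : int
        Number of independent draws (rows of the output).
    rng : numpy.random.Generator
        Source of randomness; one uniform is consumed per entry.
    ops : OpCounter, optional
        If given, accumulates the scalar arithmetic-operation count.
    return_probs : bool
        Also return the (n_samples, m) matrix of conditional success
        probabilities realized along each sampling path.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    m = spec.m
    mu = spec.mu
    R = spec.correlation_matrix()
    z0, z1 = _z_values(mu)
    U_rand = _draw_uniforms(rng, n_samples, m)
    X = np.empty((n_samples, m), dtype=np.uint8)
    Z = np.empty((n_samples, m), dtype=float)
    S = np.zeros(n_samples)
    P = np.empty((n_samples, m), dtype=float) if return_probs else None
    for n in range(m):
        t = Z[:, :n] @ R[:n, n] if n else np.zeros(n_samples)
        p = conditional_success_prob(mu[n], t, S, step=n)
        x = U_rand[:, n] < p
        z = np.where(x, z1[n], z0[n])
        S += z * t
        X[:, n] = x
        Z[:, n] = z
        if P is not None:
            P[:, n] = p
        if ops is not None:
            ops.add(n_samples * (2 * n + _BASE_OPS_PER_STEP))
    if return_probs:
        return X, P
    return X


def rb_dplr(mu, U, n_samples: int, rng: np.random.Generator,
            *, ops: OpCounter | None = None, return_probs: bool = False):
    """Sample i.i.d. order-2 MVB vectors under R = D + U U^T in O(mc) per draw.

    ``U`` is the m x c low-rank factor (a 1-d array is treated as one
    column); the diagonal is implied by the unit-diagonal constraint
    d_k = 1 - sum_c U_kc^2, which must be nonnegative.  The sampling
    distribution is identical to :func:`rb_unstr` on the expanded matrix
    with r_ij = sum_c U_ic U_jc (i != j).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    structure = DPLR.from_factor(U)          # validates row norms <= 1
    spec = Order2Spec(mu, structure)         # validates mu
    Ufac = structure.U
    m, c = Ufac.shape
    z0, z1 = _z_values(mu)
    U_rand = _draw_uniforms(rng, n_samples, m)
    X = np.empty((n_samples, m), dtype=np.uint8)
    S = np.zeros(n_samples)
    w = np.zeros((n_samples, c))
    P = np.empty((n_samples, m), dtype=float) if return_probs else None
    for n in range(m):
        t = w @ Ufac[n]
        p = conditional_success_prob(mu[n], t, S, step=n)
        x = U_rand[:, n] < p
        z = np.where(x, z1[n], z0[n])
        S += z * t
        w += z[:, None] * Ufac[n]
        X[:, n] = x
        if P is not None:
            P[:, n] = p
        if ops is not None:
            ops.add(n_samples * (4 * c + _BASE_OPS_PER_STEP))
    if return_probs:
        return X, P
    return X
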