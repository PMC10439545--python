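"""Random valid order-2 specifications for validation experiments.

The feasible region of the order-2 truncation (the set of (mu, R) that yield
a true probability distribution) has no known closed-form characterization,
so these generators propose a random correlation structure and shrink it
toward independence until exhaustive enumeration certifies validity.
Deterministic given the generator state; intended for tests and the
acceptance experiments, where specs must be valid by construction.
"""

from __future__ import annotations

import numpy as np

from .order2 import Order2Spec, is_valid_order2

__all__ = ["random_valid_full_spec", "random_valid_dplr_spec"]

DEFAULT_MU_RANGE = (0.05, 0.5)


def _random_correlation(m: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((m, m + 2))
    C = A @ A.T
    s = np.sqrt(np.diag(C))
    return C / np.outer(s, s)


def random_valid_full_spec(m: int, rng: np.random.Generator,
                           mu_range=DEFAULT_MU_RANGE,
                           strength: float = 0.6) -> Order2Spec:
    """Random full-matrix spec, shrunk toward the identity until valid."""
    mu = rng.uniform(*mu_range, m)
    R0 = _random_correlation(m, rng)
    lam = strength
    eye = np.eye(m)
    while lam > 1e-4:
        spec = Order2Spec.from_correlation(mu, lam * R0 + (1.0 - lam) * eye)
        if is_valid_order2(spec):
            return spec
        lam *= 0.7
    return Order2Spec.from_correlation(mu, eye)


def random_valid_dplr_spec(m: int, c: int, rng: np.random.Generator,
                           mu_range=DEFAULT_MU_RANGE,
                           strength: float = 0.6) -> Order2Spec:
    """Random DPLR spec (m x c factor), shrunk toward zero until valid."""
    mu = rng.uniform(*mu_range, m)
    U0 = rng.standard_normal((m, c))
    norms = np.sqrt((U0 * U0).sum(axis=1))
    U0 = U0 / np.maximum(norms, 1.0)[:, None]   # row norms <= 1
    lam = strength
    while lam > 1e-4:
        spec = Order2Spec.from_factor(mu, lam * U0)
        if is_valid_order2(spec):
            return spec
        lam *= 0.7
    return Order2Spec.from_factor(mu, np.zeros((m, c)))
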