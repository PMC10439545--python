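"""Order-2 Bahadur representation of the multivariate Bernoulli distribution.

An m-dimensional multivariate Bernoulli (MVB) distribution factors as the
independence pmf times a polynomial correction in the standardized variables
``z_i = (x_i - mu_i) / sqrt(mu_i (1 - mu_i))``:

    p(x) = prod_i mu_i^{x_i} (1-mu_i)^{1-x_i} * f(x),
    f(x) = 1 + sum_{i<j} r_ij z_i z_j + (higher-order mixed moments).

The *order-2* family sets all mixed moments of order >= 3 to zero, so the
distribution is fully parameterized by the marginal means ``mu`` and the
pairwise correlations ``r_ij``.  Truncation has a price: for some (mu, R)
the resulting signed measure is not a probability distribution (it assigns
negative mass to some outcomes).  This module represents the family exactly,
evaluates it pointwise, enumerates it exhaustively for small m (the
brute-force oracle used throughout the test suite), and checks validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FullCorrelation",
    "DPLR",
    "Order2Spec",
    "PmfTable",
    "standardize",
    "pmf_order2",
    "enumerate_pmf",
    "is_valid_order2",
    "ValidityResult",
]

#: probabilities within this distance below zero are treated as zero
#: (boundary-valid specifications such as r_ij = 1 must not be rejected)
VALIDITY_TOL = 1e-12

#: hard cap on exhaustive 2^m enumeration
DEFAULT_ENUMERATION_CAP = 20

_UNIT_DIAG_TOL = 1e-9


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_mu(mu: np.ndarray) -> None:
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("marginal means mu must lie strictly in (0, 1)")


@dataclass(frozen=True)
class FullCorrelation:
    """Arbitrary symmetric unit-diagonal correlation matrix R."""

    R: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be a square matrix")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=_UNIT_DIAG_TOL):
            raise ValueError("R must have unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-12):
            raise ValueError("correlations must satisfy |r_ij| <= 1")
        object.__setattr__(self, "R", R)

    @property
    def m(self) -> int:
        return self.R.shape[0]

    def matrix(self) -> np.ndarray:
        return self.R


@dataclass(frozen=True)
class DPLR:
    """Diagonal-plus-low-rank correlation structure R = D + U U^T.

    ``U`` is m x c with c << m and ``d_k = 1 - sum_c U_kc^2 >= 0`` so the
    implied matrix has unit diagonal; off-diagonal r_ij = sum_c U_ic U_jc.
    The diagonal is stored explicitly and validated (rather than recomputed)
    so that construction errors surface immediately.
    """

    d: np.ndarray
    U: np.ndarray

    def __post_init__(self):
        U = np.asarray(self.U, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        if U.ndim != 2:
            raise ValueError("U must be an m x c matrix")
        d = _as_1d(self.d, "d")
        if d.shape[0] != U.shape[0]:
            raise ValueError("d and U must agree on m")
        if np.any(d < -_UNIT_DIAG_TOL):
            raise ValueError("diagonal entries d_k must be nonnegative")
        if np.any(np.abs(d + (U * U).sum(axis=1) - 1.0) > _UNIT_DIAG_TOL):
            raise ValueError("unit-diagonal constraint d_k + sum_c U_kc^2 = 1 violated")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "U", U)

    @classmethod
    def from_factor(cls, U) -> "DPLR":
        """Build the structure from U alone, with d = 1 - row norms."""
        U = np.asarray(U, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        sq = (U * U).sum(axis=1)
        if np.any(sq > 1.0 + _UNIT_DIAG_TOL):
            raise ValueError("rows of U must satisfy sum_c U_kc^2 <= 1")
        return cls(d=1.0 - sq, U=U)

    @property
    def m(self) -> int:
        return self.U.shape[0]

    @property
    def c(self) -> int:
        return self.U.shape[1]

    def matrix(self) -> np.ndarray:
        R = self.U @ self.U.T
        np.fill_diagonal(R, 1.0)
        return R


@dataclass(frozen=True)
class Order2Spec:
    """Complete parameterization of an order-2 MVB: means + pairwise structure."""

    mu: np.ndarray
    structure: FullCorrelation | DPLR

    def __post_init__(self):
        mu = _as_1d(self.mu, "mu")
        _check_mu(mu)
        if mu.shape[0] != self.structure.m:
            raise ValueError(
                f"mu has length {mu.shape[0]} but structure is {self.structure.m}-dimensional"
            )
        object.__setattr__(self, "mu", mu)

    @classmethod
    def from_correlation(cls, mu, R) -> "Order2Spec":
        return cls(mu=np.asarray(mu, dtype=float), structure=FullCorrelation(np.asarray(R, dtype=float)))

    @classmethod
    def from_factor(cls, mu, U) -> "Order2Spec":
        return cls(mu=np.asarray(mu, dtype=float), structure=DPLR.from_factor(U))

    @property
    def m(self) -> int:
        return self.mu.shape[0]

    def correlation_matrix(self) -> np.ndarray:
        return self.structure.matrix()

    def restrict(self, k: int) -> "Order2Spec":
        """Spec of the first k coordinates (order-2 marginals are closed)."""
        if not 0 < k <= self.m:
            raise ValueError("k must be in 1..m")
        if isinstance(self.structure, DPLR):
            return Order2Spec(self.mu[:k], DPLR(self.structure.d[:k], self.structure.U[:k]))
        return Order2Spec(self.mu[:k], FullCorrelation(self.structure.R[:k, :k]))


def standardize(x, mu) -> np.ndarray:
    """Standardized Bernoulli values z_i = (x_i - mu_i)/sqrt(mu_i(1-mu_i)).

    Under X_i ~ Bernoulli(mu_i), z_i has mean 0 and variance 1.  Accepts
    scalars or arrays (broadcast); x entries must be 0/1.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie strictly in (0, 1)")
    if not np.all((x == 0.0) | (x == 1.0)):
        raise ValueError("x entries must be binary (0 or 1)")
    return (x - mu) / np.sqrt(mu * (1.0 - mu))


def _outcomes(m: int) -> np.ndarray:
    """All 2^m binary outcomes in lexicographic order, row 0 = all zeros."""
    idx = np.arange(2**m)
    return ((idx[:, None] >> np.arange(m - 1, -1, -1)) & 1).astype(np.uint8)


def _order2_factor(Z: np.ndarray, R: np.ndarray) -> np.ndarray:
    # f(x) = 1 + sum_{i<j} r_ij z_i z_j ; R has unit diagonal
    quad = np.einsum("ki,ij,kj->k", Z, R, Z)
    return 1.0 + 0.5 * (quad - (Z * Z).sum(axis=1))


def pmf_order2(spec: Order2Spec, x) -> float:
    """Order-2 pmf at outcome x; may be negative for invalid specs.

    No clamping is applied: validity is a separate concern
    (:func:`is_valid_order2`).
    """
    x = np.asarray(x)
    if x.shape != (spec.m,):
        raise ValueError(f"x has shape {x.shape}, expected ({spec.m},)")
    z = standardize(x, spec.mu)
    p1 = float(np.prod(np.where(x == 1, spec.mu, 1.0 - spec.mu)))
    R = spec.correlation_matrix()
    f = float(_order2_factor(z[None, :], R)[0])
    return p1 * f


@dataclass
class PmfTable:
    """Exhaustive pmf over all 2^m outcomes (lexicographic order).

    The probabilities always sum to one, valid spec or not, because every
    cross-term integrates to zero under the independence measure.  Entries
    may be negative when the spec is not a valid distribution.
    """

    spec: Order2Spec
    outcomes: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)

    @property
    def m(self) -> int:
        return self.spec.m

    def means(self) -> np.ndarray:
        return self.probabilities @ self.outcomes

    def correlations(self) -> np.ndarray:
        Z = standardize(self.outcomes, self.spec.mu)
        return (Z * self.probabilities[:, None]).T @ Z

    def marginalize_last(self) -> "PmfTable":
        """Sum out the last coordinate; returns the table on the first m-1."""
        if self.m < 2:
            raise ValueError("cannot marginalize a univariate table")
        p = self.probabilities.reshape(-1, 2).sum(axis=1)
        sub = self.spec.restrict(self.m - 1)
        return PmfTable(spec=sub, outcomes=_outcomes(self.m - 1), probabilities=p)

    def min_outcome(self) -> tuple[np.ndarray, float]:
        k = int(np.argmin(self.probabilities))
        return self.outcomes[k].copy(), float(self.probabilities[k])

    def to_frame(self) -> pd.DataFrame:
        bits = ["".join(map(str, row)) for row in self.outcomes]
        return pd.DataFrame({"outcome": bits, "probability": self.probabilities})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def enumerate_pmf(spec: Order2Spec, max_m: int = DEFAULT_ENUMERATION_CAP) -> PmfTable:
    """Brute-force table of the order-2 pmf over all 2^m outcomes."""
    if spec.m > max_m:
        raise ValueError(
            f"refusing to enumerate 2^{spec.m} outcomes (cap is m = {max_m})"
        )
    X = _outcomes(spec.m)
    Z = standardize(X, spec.mu)
    logp1 = X @ np.log(spec.mu) + (1 - X) @ np.log1p(-spec.mu)
    p1 = np.exp(logp1)
    probs = p1 * _order2_factor(Z, spec.correlation_matrix())
    return PmfTable(spec=spec, outcomes=X, probabilities=probs)


@dataclass(frozen=True)
class ValidityResult:
    valid: bool
    witness: np.ndarray
    min_probability: float

    def __bool__(self) -> bool:  # allow `if is_valid_order2(spec): ...`
        return self.valid


def is_valid_order2(
    spec: Order2Spec,
    max_m: int = DEFAULT_ENUMERATION_CAP,
    tol: float = VALIDITY_TOL,
) -> ValidityResult:
    """Exhaustive validity check: is the order-2 truncation a true pmf?

    Valid iff the minimum outcome probability is >= -tol; the witness is the
    argmin outcome.  Only available under the enumeration cap — for larger m
    invalidity is detected lazily by the samplers, which raise as soon as a
    conditional probability leaves [0, 1].
    """
    table = enumerate_pmf(spec, max_m=max_m)
    witness, pmin = table.min_outcome()
    return ValidityResult(valid=pmin >= -tol, witness=witness, min_probability=pmin)
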