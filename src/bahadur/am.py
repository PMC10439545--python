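"""Equilibrium parameter calculus for primary-phenotypic assortative mating.

Model: an additive trait with panmictic heritability h2_0 (and, on the
conventional scaling, panmictic genetic variance sigma2_g0 = h2_0), mates
paired so that their phenotypes correlate at r.  Iterated over generations,
assortment builds positive, sign-consistent correlations among all causal
variants genome-wide and inflates the genetic variance until a fixed point
is reached.  Following Nagylaki's classical analysis, the equilibrium
heritability solves the quadratic r x^2 - a x + h2_0 a = 0 with
a = (1 - h2_0)^{-1}:

    h2_inf = (1 / 2r) * (a - sqrt(a^2 - 4 r h2_0 a)),

and the equilibrium cross-mate genetic correlation and genetic variance are
rg_inf = r * h2_inf and sigma2_g_inf = sigma2_g0 / (1 - rg_inf).  The
environmental variance is held at its panmictic value 1 - h2_0 (assortment
reshapes genetic, not environmental, variance), so
sigma2_y_inf = sigma2_g_inf + (1 - h2_0) and h2_inf = sigma2_g_inf /
sigma2_y_inf holds identically.

The induced correlation among causal haploid variants is rank-one plus
diagonal, R = D + phi phi^T.  With beta_k the *standardized* haploid effect
(the trait increment per standard deviation of variant k, sum beta_k^2 =
sigma2_g0) the per-variant loading solves the self-consistency condition
phi_k = sqrt(r) cov(z_k, y) / sigma_y_inf under Gaussian assortment and free
recombination, whose closed form is

    phi_k = u_k / (C + sqrt(C^2 + u_k^2)),
    u_k = 2 beta_k sqrt(r) / sigma_y_inf,     C = 1 - rg_inf,

with D_kk = 1 - phi_k^2.  This form is numerically stable (no cancellation
as beta_k -> 0), odd in beta_k (variants with opposite effect signs
correlate negatively), and always satisfies |phi_k| < 1, so the
unit-diagonal constraint of the DPLR structure is automatically satisfiable.
See docs/methods.md for the derivation and for its empirical validation
against forward-time simulation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["AMParameters", "h2_eq", "rg_eq", "vg_eq", "am_covariance_structure"]


def _check_h2_r(h2_0: float, r: float) -> None:
    if not 0.0 <= h2_0 < 1.0:
        raise ValueError("h2_0 must lie in [0, 1)")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")


def h2_eq(h2_0: float, r: float) -> float:
    """Equilibrium heritability under assortative mating.

    Returns the smaller root of r x^2 - a x + h2_0 a = 0, a = 1/(1 - h2_0);
    the r -> 0 limit is h2_0 (handled by an explicit branch).
    """
    _check_h2_r(h2_0, r)
    if r == 0.0 or h2_0 == 0.0:
        return float(h2_0)
    a = 1.0 / (1.0 - h2_0)
    disc = a * a - 4.0 * r * h2_0 * a
    if disc < 0.0:
        raise ValueError(
            f"no real equilibrium heritability for h2_0={h2_0}, r={r} "
            f"(negative discriminant {disc:.3e})"
        )
    # rationalized form of (a - sqrt(disc)) / (2 r): avoids the subtractive
    # cancellation that degrades the textbook root near h2_0 -> 1
    return float(2.0 * h2_0 * a / (a + np.sqrt(disc)))


def rg_eq(h2_0: float, r: float) -> float:
    """Equilibrium cross-mate genetic correlation rg_inf = r * h2_inf."""
    return float(r * h2_eq(h2_0, r))


def vg_eq(h2_0: float, r: float, sigma2_g0: float | None = None) -> float:
    """Equilibrium genetic variance sigma2_g0 / (1 - rg_inf).

    ``sigma2_g0`` defaults to h2_0 (unit panmictic phenotypic variance).
    """
    if sigma2_g0 is None:
        sigma2_g0 = h2_0
    if sigma2_g0 < 0.0:
        raise ValueError("sigma2_g0 must be nonnegative")
    rg = rg_eq(h2_0, r)
    if rg >= 1.0:
        raise ValueError(f"equilibrium genetic variance diverges (rg_inf = {rg})")
    return float(sigma2_g0 / (1.0 - rg))


@dataclass(frozen=True)
class AMParameters:
    """Panmictic inputs and the derived equilibrium quantities."""

    h2_0: float
    r: float
    sigma2_g0: float
    h2_inf: float
    rg_inf: float
    sigma2_g_inf: float
    sigma2_e: float
    sigma2_y_inf: float

    @classmethod
    def from_panmictic(cls, h2_0: float, r: float,
                       sigma2_g0: float | None = None) -> "AMParameters":
        _check_h2_r(h2_0, r)
        if sigma2_g0 is None:
            sigma2_g0 = h2_0
        h2i = h2_eq(h2_0, r)
        rgi = r * h2i
        vgi = sigma2_g0 / (1.0 - rgi)
        ve = 1.0 - h2_0
        return cls(h2_0=float(h2_0), r=float(r), sigma2_g0=float(sigma2_g0),
                   h2_inf=h2i, rg_inf=rgi, sigma2_g_inf=vgi,
                   sigma2_e=ve, sigma2_y_inf=vgi + ve)

    def as_dict(self) -> dict:
        return asdict(self)


def am_covariance_structure(mu, beta, h2_0: float, r: float):
    """DPLR correlation structure (phi, d) of causal haploid variants at
    assortative-mating equilibrium.

    Parameters
    ----------
    mu : array_like
        Allele frequencies of the m haploid causal variants, each in (0, 1).
    beta : array_like
        Standardized haploid effects (trait units per SD of the variant).
    h2_0, r : float
        Panmictic heritability and cross-mate phenotype correlation.

    Returns
    -------
    phi : ndarray
        Rank-one factor; cor(x_j, x_k) = phi_j phi_k for j != k.
    d : ndarray
        Diagonal entries d_k = 1 - phi_k^2.

    Notes
    -----
    beta_k = 0 and r = 0 yield phi_k = 0 exactly through the same stable
    expression u / (C + sqrt(C^2 + u^2)) — no 0/0 is ever formed.  Since
    C > 0 whenever rg_inf < 1, |phi_k| < 1 always holds, so the domain
    error for phi_k^2 > 1 is purely defensive.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if mu.shape != beta.shape:
        raise ValueError("mu and beta must have the same length")
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    params = AMParameters.from_panmictic(h2_0, r)
    C = 1.0 - params.rg_inf
    if C <= 0.0:
        raise ValueError("equilibrium is degenerate: rg_inf >= 1")
    u = 2.0 * beta * np.sqrt(r) / np.sqrt(params.sigma2_y_inf)
    phi = u / (C + np.sqrt(C * C + u * u))
    if np.any(phi * phi > 1.0):
        raise ValueError("phi_k^2 > 1: no valid unit-diagonal DPLR structure")
    return phi, 1.0 - phi * phi
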