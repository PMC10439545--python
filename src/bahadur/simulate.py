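"""End-to-end genotype/phenotype simulation at assortative-mating equilibrium.

One individual = one m-dimensional multivariate-Bernoulli draw covering both
gametes: haploid variants (2j-1, 2j) (1-based; adjacent columns) form
diploid locus j, and the AM-induced correlation — within and between loci,
within and between gametes — is captured by the same rank-one phi phi^T
structure.  Individuals are mutually independent draws (a sample of
unrelated individuals at equilibrium), so no forward-time iteration, mate
pairing, or meiosis is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .am import AMParameters, am_covariance_structure
from .samplers import rb_dplr

__all__ = [
    "GeneticArchitecture",
    "SimulationResult",
    "sample_allele_frequencies",
    "sample_effects",
    "am_simulate",
    "realized_h2",
]

DEFAULT_MAF_RANGE = (0.05, 0.5)


def sample_allele_frequencies(m_loci: int, maf_low: float = DEFAULT_MAF_RANGE[0],
                              maf_high: float = DEFAULT_MAF_RANGE[1],
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-locus allele frequencies ~ Uniform(maf_low, maf_high), duplicated
    to the two haploid variants of each diploid locus (length 2 * m_loci)."""
    if rng is None:
        rng = np.random.default_rng()
    if m_loci < 1:
        raise ValueError("m_loci must be positive")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    per_locus = rng.uniform(maf_low, maf_high, m_loci)
    return np.repeat(per_locus, 2)


def sample_effects(m: int, sigma2_g0: float,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Standardized haploid effects: one N(0,1) draw per diploid locus,
    duplicated within the pair, rescaled so sum_k beta_k^2 = sigma2_g0."""
    if rng is None:
        rng = np.random.default_rng()
    if m < 2 or m % 2:
        raise ValueError("m must be a positive even number of haploid variants")
    if sigma2_g0 <= 0.0:
        raise ValueError("sigma2_g0 must be positive")
    raw = np.repeat(rng.standard_normal(m // 2), 2)
    return raw * np.sqrt(sigma2_g0 / (raw @ raw))


@dataclass(frozen=True)
class GeneticArchitecture:
    """Haploid causal architecture with its equilibrium DPLR structure.

    ``beta`` are standardized haploid effects; ``beta_allelic`` the same
    effects on the raw 0/1 allele scale (beta / sqrt(mu (1-mu))), returned
    so both conventions are explicit.  ``pairing[j] = (2j, 2j+1)`` (0-based)
    maps diploid locus j to its haploid columns.
    """

    mu: np.ndarray
    beta: np.ndarray
    phi: np.ndarray = field(repr=False)
    d: np.ndarray = field(repr=False)
    params: AMParameters

    def __post_init__(self):
        m = self.mu.shape[0]
        if m % 2 or self.beta.shape[0] != m:
            raise ValueError("mu and beta must share an even length")
        if not (np.all(self.mu[::2] == self.mu[1::2])
                and np.all(self.beta[::2] == self.beta[1::2])):
            raise ValueError("mu and beta must be identical within diploid pairs")

    @property
    def m(self) -> int:
        return self.mu.shape[0]

    @property
    def n_loci(self) -> int:
        return self.m // 2

    @property
    def pairing(self) -> np.ndarray:
        return np.arange(self.m).reshape(-1, 2)

    @property
    def beta_allelic(self) -> np.ndarray:
        return self.beta / np.sqrt(self.mu * (1.0 - self.mu))

    @classmethod
    def generate(cls, m: int, h2_0: float, r: float, rng: np.random.Generator,
                 maf_range=DEFAULT_MAF_RANGE) -> "GeneticArchitecture":
        params = AMParameters.from_panmictic(h2_0, r)
        mu = sample_allele_frequencies(m // 2, *maf_range, rng=rng)
        beta = sample_effects(m, params.sigma2_g0, rng=rng)
        phi, d = am_covariance_structure(mu, beta, h2_0, r)
        return cls(mu=mu, beta=beta, phi=phi, d=d, params=params)


@dataclass(frozen=True)
class SimulationResult:
    """Haplotypes, genotypes, genetic values, phenotypes, and provenance."""

    haplotypes: np.ndarray = field(repr=False)
    genotypes: np.ndarray = field(repr=False)
    g: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    architecture: GeneticArchitecture
    seed: int | None

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def params(self) -> AMParameters:
        return self.architecture.params


def am_simulate(n: int, m: int, h2_0: float, r: float,
                seed: int | np.random.SeedSequence | None = None,
                maf_range=DEFAULT_MAF_RANGE) -> SimulationResult:
    """Simulate n unrelated individuals at assortative-mating equilibrium.

    Parameters
    ----------
    n : int
        Number of individuals (independent MVB draws).
    m : int
        Number of haploid causal variants (even; m/2 diploid loci).
    h2_0, r : float
        Panmictic heritability and cross-mate phenotype correlation.
    seed : int or numpy.random.SeedSequence, optional
        Single source seed; component substreams (frequencies, effects,
        haplotypes, environmental noise) are derived deterministically.
    maf_range : (float, float)
        Uniform support of the per-locus allele frequencies.

    Notes
    -----
    Haplotypes are drawn by :func:`bahadur.samplers.rb_dplr` with the
    rank-one factor U = phi; genetic values are g_i = sum_k beta_k z_ik with
    z the standardization of the haplotypes against mu; phenotypes add
    independent N(0, 1 - h2_0) environmental noise.
    """
    if m < 2 or m % 2:
        raise ValueError("m must be a positive even number of haploid variants")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_arch, ss_hap, ss_env = ss.spawn(3)
    arch = GeneticArchitecture.generate(m, h2_0, r, np.random.default_rng(ss_arch),
                                        maf_range=maf_range)
    haplotypes = rb_dplr(arch.mu, arch.phi[:, None], n, np.random.default_rng(ss_hap))
    z = (haplotypes - arch.mu) / np.sqrt(arch.mu * (1.0 - arch.mu))
    g = z @ arch.beta
    e = np.random.default_rng(ss_env).normal(0.0, np.sqrt(1.0 - h2_0), n)
    genotypes = (haplotypes[:, ::2] + haplotypes[:, 1::2]).astype(np.int8)
    return SimulationResult(
        haplotypes=haplotypes, genotypes=genotypes, g=g, y=g + e,
        architecture=arch,
        seed=seed if isinstance(seed, (int, type(None))) else None,
    )


def realized_h2(g, y) -> float:
    """Sample variance of genetic values over sample variance of phenotypes."""
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.shape != y.shape or g.ndim != 1 or g.shape[0] < 2:
        raise ValueError("g and y must be equal-length vectors with n >= 2")
    vy = y.var(ddof=1)
    if vy == 0.0:
        raise ValueError("phenotypic variance is zero")
    return float(g.var(ddof=1) / vy)
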