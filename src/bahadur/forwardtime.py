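"""Minimal forward-time assortative-mating simulator (independent oracle).

Starts from a panmictic population (independent Bernoulli gametes), then
iterates: phenotype assignment with fresh environmental noise, assortative
mate pairing targeting a cross-mate phenotype correlation r, and meiosis
with free recombination (loci unlinked), two offspring per pair so the
population size stays constant.  Used to validate that the direct
equilibrium sampler (:func:`bahadur.simulate.am_simulate`) lands on the same
stationary state the generational process converges to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import DEFAULT_MAF_RANGE, sample_allele_frequencies, sample_effects

__all__ = ["Population", "assortative_pairing", "meiosis", "run_forward"]


@dataclass
class Population:
    """n individuals x 2 gametes x L unlinked diploid loci, plus the shared
    architecture (per-locus frequencies and standardized haploid effects)."""

    haplotypes: np.ndarray = field(repr=False)   # (n, 2, L) binary
    mu: np.ndarray                               # (L,) per-locus frequencies
    beta: np.ndarray                             # (L,) standardized haploid effect
    generation: int = 0

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def genetic_values(self) -> np.ndarray:
        z = (self.haplotypes - self.mu) / np.sqrt(self.mu * (1.0 - self.mu))
        return np.einsum("ngl,l->n", z, self.beta)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


def assortative_pairing(phenotypes, r: float, rng: np.random.Generator) -> np.ndarray:
    """Partition indices into mate pairs with cross-mate correlation ~ r.

    Gaussian-copula rank matching: individuals are split at random into two
    pools; a bivariate normal sample with correlation r is drawn, and the
    phenotype ranks of each pool are matched to the ranks of the
    corresponding Gaussian margin.  The realized product-moment correlation
    is r in expectation, up to a small rank-coupling attenuation.

    Returns an (n/2, 2) array of index pairs.
    """
    y = np.asarray(phenotypes, dtype=float)
    n = y.shape[0]
    if n % 2:
        raise ValueError("need an even number of individuals to pair")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    perm = rng.permutation(n)
    pool_a, pool_b = perm[: n // 2], perm[n // 2:]
    x1 = rng.standard_normal(n // 2)
    x2 = r * x1 + np.sqrt(1.0 - r * r) * rng.standard_normal(n // 2)
    # position i of the pairing receives the pool member whose phenotype rank
    # equals the rank of the i-th Gaussian coordinate
    a = pool_a[np.argsort(y[pool_a])][np.argsort(np.argsort(x1))]
    b = pool_b[np.argsort(y[pool_b])][np.argsort(np.argsort(x2))]
    return np.column_stack([a, b])


def meiosis(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a 2 x L parent: at each locus the transmitted allele
    is chosen from the two parental haplotypes with probability 1/2
    independently (free recombination)."""
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 2:
        raise ValueError("parent must be a 2 x L haplotype array")
    L = parent.shape[1]
    choice = rng.integers(0, 2, L)
    return parent[choice, np.arange(L)]


def _gametes(haplotypes: np.ndarray, parent_idx: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    # vectorized meiosis for a batch of parents -> (k, L) gametes
    k = parent_idx.shape[0]
    L = haplotypes.shape[2]
    choice = rng.integers(0, 2, (k, L))
    return haplotypes[parent_idx[:, None], choice, np.arange(L)[None, :]]


def founder_population(n: int, n_loci: int, h2_0: float,
                       rng: np.random.Generator,
                       maf_range=DEFAULT_MAF_RANGE) -> Population:
    """Panmictic founders: independent Bernoulli(mu) gametes."""
    mu = sample_allele_frequencies(n_loci, *maf_range, rng=rng)[::2]
    beta = sample_effects(2 * n_loci, h2_0, rng=rng)[::2]
    hap = (rng.random((n, 2, n_loci)) < mu).astype(np.int8)
    return Population(haplotypes=hap, mu=mu, beta=beta, generation=0)


def run_forward(n: int, n_loci: int, h2_0: float, r: float, generations: int,
                rng: np.random.Generator | int | None = None,
                maf_range=DEFAULT_MAF_RANGE) -> pd.DataFrame:
    """Iterate assortative mating for ``generations`` generations.

    Returns a per-generation trajectory (generation 0 = panmictic founders)
    with realized heritability, genetic/phenotypic variances, cross-mate
    phenotype and genetic-value correlations of the pairs formed in that
    generation, and the mean absolute allele-frequency change from the
    founders.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if n % 2:
        raise ValueError("population size must be even")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pop = founder_population(n, n_loci, h2_0, rng, maf_range=maf_range)
    freq0 = pop.allele_frequencies()
    sigma_e = np.sqrt(1.0 - h2_0)
    rows = []
    for gen in range(generations + 1):
        g = pop.genetic_values()
        y = g + rng.normal(0.0, sigma_e, n)
        pairs = assortative_pairing(y, r, rng)
        rows.append({
            "generation": gen,
            "h2": g.var(ddof=1) / y.var(ddof=1),
            "var_g": g.var(ddof=1),
            "var_y": y.var(ddof=1),
            "cross_mate_r_pheno": float(np.corrcoef(y[pairs[:, 0]], y[pairs[:, 1]])[0, 1]),
            "cross_mate_r_g": float(np.corrcoef(g[pairs[:, 0]], g[pairs[:, 1]])[0, 1]),
            "mean_abs_freq_change": float(np.abs(pop.allele_frequencies() - freq0).mean()),
        })
        if gen == generations:
            break
        moms = np.repeat(pairs[:, 0], 2)
        dads = np.repeat(pairs[:, 1], 2)
        hap = np.stack([_gametes(pop.haplotypes, moms, rng),
                        _gametes(pop.haplotypes, dads, rng)], axis=1)
        pop = Population(haplotypes=hap, mu=pop.mu, beta=pop.beta,
                         generation=gen + 1)
    return pd.DataFrame(rows)
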