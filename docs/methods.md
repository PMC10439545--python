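# Methods

## The order-2 multivariate Bernoulli family

For X ∈ {0,1}^m with marginal means μ ∈ (0,1)^m, write
z_i = (x_i − μ_i)/√(μ_i(1−μ_i)). Any MVB pmf factors as the independence
pmf times 1 + Σ_{i<j} r_{ij} z_i z_j + Σ_{i<j<k} r_{ijk} z_i z_j z_k + …,
where the r's are the mixed moments of the standardized variables. The
order-2 family truncates everything above the pairwise terms, leaving the
means and the correlation matrix R as the complete parameterization. Three
consequences drive the whole design:

1. **Normalization is unconditional.** Every cross-term integrates to zero
   under the independence measure, so the truncated "pmf" sums to one even
   when it is not a valid distribution (some outcome probabilities may be
   negative). Validity is a property to *check*, not assume.
2. **Moments are exact.** Whenever the truncation is valid, its means and
   pairwise correlations are exactly μ and R — there is no approximation
   error in the targeted moments.
3. **Marginal closure.** Restricting to the first n coordinates stays in
   the family with the same μ's and r's. This is what makes sequential
   conditional sampling exact: at step n the conditional success
   probability has the closed form μ_n(1 + S + z_n(1)t_n)/(1 + S) with
   S the accumulated pairwise sum over the realized prefix and t_n the
   coupling of variable n to the prefix.

`enumerate_pmf` materializes all 2^m outcomes (capped at m = 20) and is the
brute-force oracle for everything else: validity checking, conditional
probability ratios, and empirical total-variation comparisons.

## Samplers

Both samplers draw coordinates in natural index order (any order gives the
same joint law by the chain rule; fixing it makes runs reproducible), and
consume exactly one uniform variate per variable per sample, column by
column. Because the unstructured and DPLR recursions compute algebraically
identical conditional probabilities, a shared seed makes their outputs
bit-identical in practice (probabilities agree to ~1e−15; a draw could only
differ if a uniform fell inside that sliver).

- `rb_unstr`: t_n = Σ_{i<n} r_{in} z_i from the realized z history —
  O(m²) per draw, arbitrary R.
- `rb_dplr`: for R = D + UUᵀ (unit diagonal, so D is implied by U),
  carry w = Σ_{i<n} z_i U_i; then t_n = U_n·w and the update is
  w ← w + z_n U_n, S ← S + z_n t_n — O(mc) per draw.

The z value entering the accumulators is computed from the *realized* draw,
which is what makes the product of realized conditional probabilities equal
the joint pmf exactly (tested to 1e−10).

Numerical guards: conditional probabilities within 1e−9 of [0,1] are
clamped to the boundary (boundary-valid targets such as r_ij = 1 live
there); anything further out raises `InvalidDistributionError` carrying the
step index, the offending value and the sample row — the sampler never
renormalizes silently. If |1 + S| < 1e−12 the prefix has essentially zero
probability (unreachable for valid targets) and the sampler aborts the same
way. Enumerated validity uses a −1e−12 floor on the minimum outcome
probability for the same boundary reason.

Work accounting: the samplers optionally count the scalar arithmetic
operations of their inner loops (coupling dot products, accumulator
updates, and a fixed per-step overhead). This gives a hardware-independent
scaling measurement: doubling m doubles the count for `rb_dplr` at fixed c
and quadruples it for `rb_unstr` (up to the O(m) lower-order term).

## Assortative-mating equilibrium

Primary-phenotypic assortment on an additive trait: panmictic heritability
h²₀, panmictic genetic variance σ²_g,0 (= h²₀ on the unit-phenotypic-variance
scaling), cross-mate phenotype correlation r. The equilibrium heritability
is the smaller root of r x² − a x + h²₀ a = 0 with a = (1−h²₀)⁻¹; we
evaluate it in the rationalized form 2h²₀a/(a + √(a² − 4rh²₀a)) to avoid
subtractive cancellation as h²₀ → 1 (fixed-point residuals stay below
1e−12 across the whole parameter grid). Then r_g,∞ = r·h²_∞ and
σ²_g,∞ = σ²_g,0/(1 − r_g,∞). The environmental variance is held at its
panmictic value 1 − h²₀ — assortment reshapes genetic, not environmental,
variance — which makes h²_∞ = σ²_g,∞/σ²_y,∞ an identity.

**The variant-level structure.** Let β_k be the standardized haploid effect
(trait change per SD of variant k; Σβ² = σ²_g,0) and ω_k = cov(z_k, y) at
equilibrium. Under Gaussian assortment, the covariance between any variable
A in one mate and B in the other factorizes as r·cov(A,y)cov(B,y)/σ²_y.
With unlinked loci, the generation recursions for within-gamete and
cross-gamete covariances share a single fixed point in which *every* pair
of distinct haploid variants in an individual has correlation φ_jφ_k with

    φ_k = √r · ω_k / σ_y,∞,      ω_k = β_k(1 − φ_k²) + φ_k (βᵀφ).

Substituting the equilibrium aggregate βᵀφ = √r σ²_g,∞/σ_y,∞ = r_g,∞·σ_y,∞/√r
turns this into a per-variant quadratic whose stable solution is

    φ_k = u_k / (C + √(C² + u_k²)),   u_k = 2β_k√r/σ_y,∞,   C = 1 − r_g,∞.

This expression is odd in β_k (opposite-sign effects correlate negatively —
the sign-consistency of AM-induced dependence), has no cancellation or 0/0
anywhere (β_k → 0 and r → 0 give φ_k = 0 exactly through the same formula,
with φ_k/β_k → √r/(σ_y,∞C) finite), and satisfies |φ_k| < 1 identically, so
the unit-diagonal DPLR constraint d_k = 1 − φ_k² ≥ 0 can never fail. Note
that under the standardized-effect convention the allele frequency drops
out of φ entirely; a per-allele-effect convention reintroduces √(μ(1−μ))
but describes the same structure. We validated this derivation — rather
than fixing the convention by assumption — with the variance-closure test:
βᵀRβ must equal σ²_g,∞ up to the O(Σβ²φ²) term that vanishes in the
infinitesimal (many small effects) limit, and the realized heritability of
direct equilibrium draws must match both the closed form and independent
forward-time simulation. Both hold (see `tests/test_acceptance.py`); the
alternative scalings we considered fail the closure by constant factors.

## The end-to-end simulator

`am_simulate(n, m, h2_0, r, seed)` treats one individual as one
m-dimensional MVB draw covering both gametes: haploid variants (2j−1, 2j)
form diploid locus j (adjacency is an arbitrary but recorded convention),
so within-individual maternal×paternal covariance is captured by the same
φφᵀ structure, and individuals are independent draws — a cohort of
unrelated individuals at equilibrium.

Generator choices, fixed once:

- Allele frequencies: per-locus Uniform(0.05, 0.5), duplicated within the
  pair — a flat MAF spectrum over the range where common-variant
  architectures live. Configurable via `maf_range`.
- Effects: one N(0,1) per diploid locus, duplicated, rescaled so
  Σβ² = σ²_g,0 exactly (a Gaussian architecture; the equilibrium calculus
  is agnostic to this choice).
- Environmental noise: N(0, 1 − h²₀), independent of genotype; phenotype
  y = g + e with no intercept.
- Seeding: one user seed; `SeedSequence` children for the architecture,
  the haplotype draws, and the noise, so runs are bit-reproducible while
  sampling stays vectorized across individuals.

Defaults (`n=8000`, `m=2000` haploid variants at the CLI) correspond to a
cohort scale at which the realized heritability of a single replicate sits
within ~0.02 of h²_∞.

What the generator does **not** emulate: local LD (loci are unlinked at
panmixis; combining AM structure with reference-haplotype LD is out of
scope), rare-variant spectra, non-additive effects, sex-specific or
multi-trait assortment, and disequilibrium (pre-equilibrium) AM dynamics.
Passing tests therefore certify the sampler and the equilibrium calculus,
not realism of any particular trait architecture.

## Forward-time oracle

`run_forward` is deliberately minimal: discrete generations, constant
population size, two offspring per mate pair, mating pools formed by random
halving (the model is sex-symmetric), free recombination in meiosis, fresh
environmental noise each generation. Pairing uses Gaussian-copula rank
matching: split into two pools, draw bivariate normals with correlation r,
and match phenotype ranks to Gaussian ranks within each pool. This attains
cross-mate phenotype correlation r in expectation (a small rank-coupling
attenuation, well under the Monte-Carlo noise of the experiments, is the
price of not modeling an explicit preference mechanism). Trajectories track
h², Var(g), cross-mate phenotype/genetic correlations, and allele-frequency
drift.

The consistency experiment runs both arms at h²₀ = r = 0.5 with 500
haploid variants, 2000 individuals and 20 replicates per arm — sizes chosen
so the two-sample comparison has sub-1% standard errors while the whole
experiment stays in the tens of seconds — and compares direct-draw h²
against forward-time h² averaged over generations 16–20 (the plateau) with
a Welch t-test, plus a 3-standard-error check of the direct arm against the
closed form 2 − √2.

## Known limitations and numerical caveats

- The feasible region of the order-2 truncation is not characterized; the
  package *detects* infeasibility (exhaustively for m ≤ 20, lazily via the
  samplers otherwise) rather than predicting it. Strong per-variant
  effects (small m with large h²₀ and r) can push the implied rank-one
  structure outside the family — the sampler then fails loudly, by design.
- Total-variation comparisons against the enumeration oracle are
  noise-floor-limited: at 200,000 draws the expected TV of *exact*
  sampling already reaches ≈0.01 at m = 7–8 (it scales like
  Π(√μ_i + √(1−μ_i)) / √n_draws), so per-spec TV bounds are asserted for
  m ≤ 6 and the mean across specs is bounded for the full range.
- The closed-form equilibrium identities hold exactly only in the
  infinitesimal limit; at finite m the implied genetic variance is
  σ²_g,0 + (βᵀφ)² − Σβ²φ², i.e. below σ²_g,∞ by O(Σβ²φ²) (≈0.002 in
  heritability units at m = 500, h²₀ = r = 0.5). Both simulation arms
  carry the same deviation, which is why they are compared against each
  other as well as against the closed form.
- The Welch-comparison arm of the validation is a hypothesis test at
  α = 0.05 and is stochastic by construction; it is run at fixed seeds.
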