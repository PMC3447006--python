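# Methods

This note documents the statistical and genetic methods implemented in
`ploidysel`, the conventions chosen where the underlying experimental
protocol admits more than one reading, and the quantitative behaviour of
the realized-heritability estimator under the simulated design.

## 1. Trait model

Phenotype of individual *i* in generation *t*:

```
z_i = mu_ploidy + e_t + (A_i - Abar_0) + eps_i,   eps_i ~ N(0, sigma_E^2)
```

- `mu_ploidy` — ploidy-group baseline (days to first flower).
- `e_t` — generation-wide environmental block shared by all lines grown in
  the same season (defaults `0, −3.7, +3.5, +1.1, −6.0` days). Blocks
  cancel exactly in the control-corrected response.
- `A_i` — additive genetic value over `n_loci` unlinked biallelic loci.
  With the default *ploidy-standardized* dosage scale,
  `A_i = (2/ploidy) * Σ_l d_il * a_l` where `d_il` is the focal-allele
  dosage. Genome doubling (AB → AABB) therefore leaves `A` unchanged at
  the moment of synthesis, and ploidy mean differences are carried by the
  baseline alone.
- Sterility is an independent Bernoulli draw (defaults 0.35 diploid, 0.28
  neotetraploid, 0.05 tetraploid); sterile plants are excluded from all
  summaries and from selection.

At Hardy–Weinberg proportions the additive variance is
`sigma_A^2 = (2/ploidy)^2 * ploidy * Σ_l p_l q_l a_l^2`.
`GeneticArchitecture.from_heritability` solves the equal-effect `a` and
`sigma_E` so that `sigma_A^2 / sigma_P^2` equals the requested
heritability and the phenotypic CV matches the requested percentage. The
focal allele has a negative (earliness) effect, so downward selection on
flowering time raises its frequency.

## 2. Meiosis

Diploid gametes draw 1 of 2 alleles per locus (binomial). Tetrasomic
gametes draw 2 of 4 alleles without replacement — hypergeometric in the
dosage — modelling random chromosome segregation. Double reduction is
supported: with probability `alpha ≤ 1/6` per locus the gamete instead
carries two copies of one uniformly chosen parental allele. The unit tests
check the simulated gamete distributions against exhaustive enumeration.

## 3. Breeding design

Counts per ploidy group (`DesignConfig` presets):

| | diploid | tetraploid | neotetraploid |
|---|---|---|---|
| base families × plants | 113 × 2 | 105 × 2 | 29 × 2 |
| round-one selection | top 48 split into 2 lines of 24 | same | single group of 20 |
| partners per parent | 3 | 3 | 4 (round one), then 3 |
| seed-family pairs | 36 | 36 | 40 created, 35 sampled |
| rounds of selection | 4 | 4 | 4 |
| per-round cohort | 36 fam × 4 seeds, 10 % mortality | same | same |
| final generation | 15 fam × 2 | same | same |

Diploid and tetraploid bases are maternal half-sib families (each family
shares a latent Hardy–Weinberg dam; pollen gametes are independent),
matching field-collected seed from an outcrossing species. The
neotetraploid base descends from 55 synthesized parents, crossed into 29
reciprocal pairs (three parents serve twice), so its families are full
sibs and the synthesis parents appear in the pedigree.

Selection takes the earliest-flowering fertile plants with **at most one
plant per maternal family**; when siblings co-rank in the selection group,
only the earliest is kept and the next-ranked plant fills the slot.
Control lines draw parents at random under the same restriction. Crossing
pairs every selected parent with exactly `k` non-relative partners
(no shared parent, no shared maternal family) — a k-regular graph found by
random stub matching with an exact `networkx.k_factor` fallback. One
orientation of each reciprocal pair is grown, chosen at random.

## 4. Response estimators

For a selected line with per-generation fertile-cohort means `x_t` and
selected-parent means `s_t`, against a control line with means `c_t`:

- selection differential `S_t = x_t − s_t` (positive toward earliness),
- divergence `D_t = c_t − x_t` (`D_0 = 0` by shared-base construction),
- response `R_t = D_t − D_{t−1}`,
- realized heritability `b_T = R_c / S_c` with `R_c = Σ R_t`,
  `S_c = Σ S_t` (optionally a through-origin regression of `R_c` on
  `S_c`).

Confidence limits use the measurement-error approximation

```
Var(b_T) = 2 * sigma_P^2 * (1/M + 1/N) / S_c^2
```

with Student-*t* critical values on `N − 1` degrees of freedom, where `N`
and `M` are harmonic means of per-generation grown and selected counts and
`sigma_P^2` is the base cohort's phenotypic variance. This form models the
sampling error of the line means and parent groups only; it deliberately
excludes genetic drift, so it understates the replicate-to-replicate
spread of `b_T` (the test suite reports the ratio, roughly 3–4× under the
default designs). The per-line divergence statistic at the final
generation is the control mean minus the average of the two selected-line
means, with standard error propagated from per-line `sd/√n`.

## 5. Inbreeding

Wright's path-counting method:

```
F_X = Σ_A Σ_paths (1/2)^(n1 + n2 + 1) * (1 + F_A)
```

summing over common ancestors `A` and pairs of ancestral paths from the
two parents that share no interior individual. Transmission is treated as
disomic for every ploidy — tetraploids are scored with the same path rules
as diploids — which is the convention used when such experiments report
pedigree F values; a tetrasomic coefficient (which would depend on double
reduction) is out of scope. The implementation is validated against an
exact recursive-kinship computation and a Monte-Carlo gene-dropping
oracle. Simulated four-generation lines of 24 parents accumulate mean F of
roughly 0.01–0.05 by the final generation.

## 6. Coefficient of variation

For a Normal sample of size *n*, `T = √n · mean / sd` follows a
noncentral *t* distribution with `n − 1` degrees of freedom and
noncentrality `√n / (CV/100)`. The confidence interval for the CV inverts
this pivot in the noncentrality parameter (vectorized bracketed bisection
on the noncentral-*t* CDF, tolerance 1e−8). The interval is asymmetric —
wider above — for finite *n*; Monte-Carlo coverage at n = 50 is 95 % ± 1 %
over 10⁴ simulations. 2C DNA content is estimated as the
sample/standard fluorescence peak ratio times the standard's known content
(0.87 pg default).

## 7. Behaviour of `b_T` under the full design

The estimator is unbiased where theory says it should be: in simulated
round one (mass selection from an unstructured-in-LD base), the genetic
superiority of the selected parents and the realized response both equal
`h² · S` within Monte-Carlo error. Over four rounds of the full protocol,
the grand mean of `b_T` settles at ≈ 0.80–0.83 × the base heritability
(200 replicates each):

| design | base h² | mean b_T | SD across replicates |
|---|---|---|---|
| diploid | 0.40 | 0.333 | 0.104 |
| tetraploid | 0.31 | 0.255 | 0.080 |
| neotetraploid | 0.55 | 0.438 | 0.115 |

Decomposition (diploid): per-round response-to-differential ratios start
at 0.40 in round one and fall to ≈ 0.30 in rounds two to four, matching
the genetic superiority of the selected parents measured directly in the
simulator. Two mechanisms, both intrinsic to the protocol:

1. **Bulmer effect.** Truncation selection at proportion ≈ 0.18 induces
   negative gametic-phase disequilibrium; the standard recursion predicts
   equilibrium cohort heritability ≈ 0.355 for base 0.40. Inbreeding
   (mean F up to ~0.05) and selection-driven allele-frequency change trim
   a few percent more.
2. **Family-restricted selection.** With 24 parents drawn one-per-family
   from at most 36 surviving full-sib families, the between-family
   component of selection is nearly exhausted and the remainder acts
   within families, where only the segregation (half the additive)
   variance is available. This lowers the parental genetic superiority
   per unit of phenotypic differential below the Bulmer-only expectation.

A `b_T` measured by this protocol therefore estimates an *effective*
heritability of the design, biased downward by a factor ≈ 0.8 relative to
the base-population parameter. Comparisons *between* ploidy groups are
essentially unaffected, because the attenuation factor is common to the
three designs.
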