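"""Forward simulator of a multi-line truncation-selection experiment.

The simulator reproduces the structure of a divergence-selection breeding
design on flowering time run in parallel on three kinds of material: diploids,
extant autotetraploids, and newly synthesized (colchicine-doubled)
neotetraploids.  Each experiment comprises a base population, two selected
lines and one randomly-mated control line, advanced for four generations by
truncation selection on days to first flower, reciprocal crossing of each
selected parent to ``k`` non-relatives, and random choice of one orientation
per reciprocal seed-family pair.

The trait model is additive and polygenic: ``n_loci`` unlinked biallelic loci
with per-locus allele effects, a ploidy-level baseline mean, a shared
generation-wide environmental block, and i.i.d. Gaussian environmental noise.
Tetraploid meiosis follows random chromosome segregation (a gamete receives 2
of the 4 alleles at each locus), optionally with double reduction: with
probability ``alpha`` both gamete alleles are copies of a single parental
allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    CrossingDesignError,
    MatingError,
    SelectionError,
    SimulationError,
)
from .pedigree import UNKNOWN_PARENT, Pedigree, PedigreeRecord
from .response import GenerationSummary

# Defaults describing the study conditions: flowering-time means of the three
# base cohorts (days), base coefficients of variation (percent), sterility
# fractions, and the shared generation-to-generation environmental swings
# (days, relative to the base generation) seen in the control lines.
BASE_MEAN_DAYS = {"diploid": 44.2, "neotetraploid": 47.1, "tetraploid": 50.3}
BASE_CV_PERCENT = {"diploid": 7.9, "neotetraploid": 6.4, "tetraploid": 12.3}
STERILITY_RATE = {"diploid": 0.35, "neotetraploid": 0.28, "tetraploid": 0.05}
GENERATION_ENV_DAYS = (0.0, -3.7, 3.5, 1.1, -6.0)

MAX_DOUBLE_REDUCTION = 1.0 / 6.0


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# genetic architecture
# ---------------------------------------------------------------------------


@dataclass
class GeneticArchitecture:
    """Trait architecture and noise model for one simulated population.

    ``allele_effects[l]`` is the phenotypic effect (days) of one copy of the
    focal allele at locus ``l``; the reference allele has effect 0.  With the
    default ``dosage_scale='ploidy_standardized'`` the genetic value is
    ``(2/ploidy) * sum(dosage * effects)``, so doubling a genome leaves a
    genotype's value unchanged at the moment of synthesis and ploidy mean
    differences are carried entirely by ``ploidy_baseline``.  The ``'raw'``
    mode sums effects over all allele copies instead.
    """

    n_loci: int
    allele_effects: np.ndarray
    founder_allele_freq: np.ndarray
    env_sd: float
    ploidy_baseline: float
    sterility_rate: float = 0.0
    dosage_scale: str = "ploidy_standardized"
    double_reduction: float = 0.0
    generation_env_effects: Sequence[float] = GENERATION_ENV_DAYS
    variance_inflation: Sequence[float] | None = None

    def __post_init__(self) -> None:
        self.allele_effects = np.asarray(self.allele_effects, dtype=float)
        self.founder_allele_freq = np.asarray(
            self.founder_allele_freq, dtype=float
        )
        if self.allele_effects.shape != (self.n_loci,):
            raise ValueError("allele_effects must have length n_loci")
        if self.founder_allele_freq.shape != (self.n_loci,):
            raise ValueError("founder_allele_freq must have length n_loci")
        if self.env_sd < 0:
            raise ValueError("env_sd must be non-negative")
        if not 0.0 <= self.double_reduction <= MAX_DOUBLE_REDUCTION:
            raise ValueError(
                f"double_reduction must lie in [0, {MAX_DOUBLE_REDUCTION:.4f}]"
            )
        if not 0.0 <= self.sterility_rate < 1.0:
            raise ValueError("sterility_rate must lie in [0, 1)")
        if self.dosage_scale not in ("ploidy_standardized", "raw"):
            raise ValueError("dosage_scale must be 'ploidy_standardized' or 'raw'")

    @classmethod
    def from_heritability(
        cls,
        h2: float,
        ploidy: int,
        mean_days: float,
        cv_percent: float,
        sterility_rate: float = 0.0,
        n_loci: int = 100,
        founder_freq: float = 0.5,
        double_reduction: float = 0.0,
        generation_env_effects: Sequence[float] = GENERATION_ENV_DAYS,
    ) -> "GeneticArchitecture":
        """Equal-effect architecture hitting a target base-population
        narrow-sense heritability and phenotypic CV.

        The per-allele effect is solved from the Hardy-Weinberg additive
        variance at the founder frequency, ``sigma2_A = (4/ploidy) *
        sum(p*q*a^2)`` under the ploidy-standardized dosage scale; the
        environmental standard deviation absorbs the rest of
        ``sigma2_P = (cv/100 * mean)^2``.  The focal allele is the *early*
        allele (negative effect), so selection for early flowering drives it
        upward in frequency.
        """
        if not 0.0 <= h2 < 1.0:
            raise ValueError("h2 must lie in [0, 1)")
        sigma2_p = (cv_percent / 100.0 * mean_days) ** 2
        sigma2_a = h2 * sigma2_p
        p = founder_freq
        if sigma2_a > 0:
            a = math.sqrt(sigma2_a * ploidy / (4.0 * n_loci * p * (1.0 - p)))
        else:
            a = 0.0
        return cls(
            n_loci=n_loci,
            allele_effects=np.full(n_loci, -a),
            founder_allele_freq=np.full(n_loci, p),
            env_sd=math.sqrt(sigma2_p - sigma2_a),
            ploidy_baseline=mean_days,
            sterility_rate=sterility_rate,
            double_reduction=double_reduction,
            generation_env_effects=tuple(generation_env_effects),
        )

    def dosage_factor(self, ploidy: int) -> float:
        return 2.0 / ploidy if self.dosage_scale == "ploidy_standardized" else 1.0

    def additive_variance(self, ploidy: int) -> float:
        """Hardy-Weinberg additive genetic variance at the founder allele
        frequencies for the given ploidy."""
        p = self.founder_allele_freq
        return float(
            self.dosage_factor(ploidy) ** 2
            * ploidy
            * np.sum(p * (1.0 - p) * self.allele_effects**2)
        )

    def heritability(self, ploidy: int) -> float:
        va = self.additive_variance(ploidy)
        return va / (va + self.env_sd**2)

    def mean_genetic_value(self, ploidy: int) -> float:
        """Population-mean genetic value at the founder frequencies; genetic
        values enter phenotypes as deviations from this mean so that the
        base-population mean equals ``ploidy_baseline``."""
        return float(
            self.dosage_factor(ploidy)
            * ploidy
            * np.sum(self.founder_allele_freq * self.allele_effects)
        )

    def generation_env(self, generation: int) -> float:
        effects = self.generation_env_effects
        return float(effects[generation]) if generation < len(effects) else 0.0

    def env_sd_at(self, generation: int) -> float:
        if self.variance_inflation is None:
            return self.env_sd
        mult = (
            self.variance_inflation[generation]
            if generation < len(self.variance_inflation)
            else 1.0
        )
        return self.env_sd * math.sqrt(mult)


# ---------------------------------------------------------------------------
# genotypes, gametes, crosses
# ---------------------------------------------------------------------------


@dataclass
class Genotype:
    """Per-locus allele multiset for a biallelic trait, stored as the count
    (dosage) of the focal allele; the multiset cardinality at every locus is
    the ploidy."""

    dosage: np.ndarray
    ploidy: int

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int64)
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.dosage.min(initial=0) < 0 or self.dosage.max(initial=0) > self.ploidy:
            raise ValueError("dosage out of range for ploidy")

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[0]


def draw_founder_genotype(
    arch: GeneticArchitecture, ploidy: int, rng, size: int | None = None
) -> np.ndarray:
    """Dosage draws at Hardy-Weinberg proportions (independent allele copies
    at the founder frequencies).  Returns shape ``(size, n_loci)`` or
    ``(n_loci,)``."""
    rng = _as_rng(rng)
    p = arch.founder_allele_freq
    shape = (size, arch.n_loci) if size is not None else arch.n_loci
    return rng.binomial(ploidy, p, size=shape)


def synthesize_neotetraploid(g: Genotype) -> Genotype:
    """Colchicine-style whole genome doubling: every allele's copy number is
    exactly doubled (AB -> AABB), deterministically."""
    if g.ploidy != 2:
        raise MatingError("can only double a diploid genotype")
    return Genotype(dosage=2 * g.dosage, ploidy=4)


def gamete_dosage(
    dosage: np.ndarray, ploidy: int, alpha: float, rng, size: int | None = None
) -> np.ndarray:
    """Dosage of the focal allele in gametes of a parent with the given
    per-locus dosage.

    Diploids segregate 1 of 2 alleles (Mendelian).  Tetraploids draw 2 of 4
    alleles without replacement (random chromosome segregation); with
    probability ``alpha`` per locus, the gamete instead carries two copies of
    one uniformly chosen parental allele (double reduction).
    """
    rng = _as_rng(rng)
    if not 0.0 <= alpha <= MAX_DOUBLE_REDUCTION:
        raise ValueError(
            f"double-reduction rate must lie in [0, {MAX_DOUBLE_REDUCTION:.4f}]"
        )
    n_loci = dosage.shape[-1]
    shape = (size, n_loci) if size is not None else (n_loci,)
    if ploidy == 2:
        if alpha != 0.0:
            raise ValueError("double reduction is undefined for diploids")
        return rng.binomial(1, dosage / 2.0, size=shape)
    if ploidy != 4:
        raise ValueError("ploidy must be 2 or 4")
    gam = rng.hypergeometric(dosage, 4 - dosage, 2, size=shape)
    if alpha > 0.0:
        dr = rng.random(shape) < alpha
        if dr.any():
            doubled = 2 * rng.binomial(1, np.broadcast_to(dosage / 4.0, shape))
            gam = np.where(dr, doubled, gam)
    return gam


def make_gamete(g: Genotype, alpha: float, rng) -> np.ndarray:
    """One gamete (per-locus focal-allele count among ``ploidy/2`` alleles)."""
    return gamete_dosage(g.dosage, g.ploidy, alpha, rng)


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class SimIndividual:
    id: str
    dam_id: str
    sire_id: str
    maternal_family: str
    line: str
    generation: int
    ploidy: int
    fertile: bool
    genotype: Genotype
    breeding_value: float
    phenotype: float

    def to_pedigree_record(self, generation_offset: int = 0) -> PedigreeRecord:
        return PedigreeRecord(
            id=self.id,
            dam_id=self.dam_id,
            sire_id=self.sire_id,
            maternal_family=self.maternal_family,
            line=self.line,
            generation=self.generation + generation_offset,
            ploidy=self.ploidy,
            fertile=self.fertile,
        )


def cross(
    dam: SimIndividual, sire: SimIndividual, rng, alpha: float = 0.0
) -> Genotype:
    """Offspring genotype: union of one gamete from each parent."""
    if dam.id == sire.id:
        raise MatingError(f"selfing attempt for {dam.id!r}")
    if dam.ploidy != sire.ploidy:
        raise MatingError(
            f"ploidy mismatch: {dam.id!r} ({dam.ploidy}x) x "
            f"{sire.id!r} ({sire.ploidy}x)"
        )
    rng = _as_rng(rng)
    g1 = make_gamete(dam.genotype, alpha, rng)
    g2 = make_gamete(sire.genotype, alpha, rng)
    return Genotype(dosage=g1 + g2, ploidy=dam.ploidy)


def assign_phenotype(
    ind: SimIndividual, arch: GeneticArchitecture, generation: int, rng
) -> float:
    """Realize the phenotype (days to first flower) and fertility of one
    individual in place, and return the phenotype.

    phenotype = ploidy baseline + generation block + centered genetic value
    + Normal(0, env_sd); sterility is an independent Bernoulli draw.
    """
    rng = _as_rng(rng)
    factor = arch.dosage_factor(ind.ploidy)
    bv = float(
        factor * np.dot(ind.genotype.dosage, arch.allele_effects)
        - arch.mean_genetic_value(ind.ploidy)
    )
    ind.breeding_value = bv
    ind.phenotype = (
        arch.ploidy_baseline
        + arch.generation_env(generation)
        + bv
        + rng.normal(0.0, arch.env_sd_at(generation))
    )
    ind.fertile = bool(rng.random() >= arch.sterility_rate)
    return ind.phenotype


# ---------------------------------------------------------------------------
# design configuration
# ---------------------------------------------------------------------------


@dataclass
class DesignConfig:
    """Counts and rules of one ploidy group's selection design.

    The class methods encode the three study designs: base-population sizes,
    numbers selected, partners per parent, the neotetraploid first-round
    special case (a single selected line of 20, four partners each, 40
    reciprocal pairs created of which 35 are sampled to found each daughter
    line), and the small final common-garden generation (15 families of 2).
    """

    ploidy: int
    neo: bool
    line_prefix: str
    n_base_families: int
    n_per_family: int = 2
    n_selected: int = 24
    partners_per_parent: int = 3
    n_generations: int = 4
    n_offspring_per_family: int = 4
    final_families: int = 15
    final_offspring_per_family: int = 2
    mortality: float = 0.1
    base_mortality: float = 0.005
    round_one_pool: int = 48
    neo_round_one_selected: int = 20
    neo_round_one_partners: int = 4
    neo_pairs_kept: int = 35
    neo_founder_parents: int = 55
    founder_mode: str = "hwe"  # "hwe" or "doubled_diploid" (neo founders)
    maternal_family_structure: str = "half_sib"  # or "full_sib"
    relative_avoid_depth: int = 1
    crossing_retries: int = 2000

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.neo and self.ploidy != 4:
            raise ValueError("neotetraploid designs have ploidy 4")
        if self.partners_per_parent < 1:
            raise ValueError("partners_per_parent must be >= 1")
        if self.founder_mode not in ("hwe", "doubled_diploid"):
            raise ValueError("founder_mode must be 'hwe' or 'doubled_diploid'")

    @property
    def selected_lines(self) -> tuple[str, str]:
        return (f"{self.line_prefix}1", f"{self.line_prefix}2")

    @property
    def control_line(self) -> str:
        return f"{self.line_prefix}C"

    @property
    def lines(self) -> tuple[str, ...]:
        return self.selected_lines + (self.control_line,)

    @classmethod
    def diploid(cls, **overrides) -> "DesignConfig":
        return cls(
            ploidy=2, neo=False, line_prefix="D", n_base_families=113, **overrides
        )

    @classmethod
    def tetraploid(cls, **overrides) -> "DesignConfig":
        return cls(
            ploidy=4, neo=False, line_prefix="T", n_base_families=105, **overrides
        )

    @classmethod
    def neotetraploid(cls, **overrides) -> "DesignConfig":
        return cls(
            ploidy=4, neo=True, line_prefix="N", n_base_families=29, **overrides
        )


def default_architecture(
    design: DesignConfig, h2: float, **kwargs
) -> GeneticArchitecture:
    """Architecture matching the design's base cohort: published base mean,
    base CV, and sterility rate for the corresponding ploidy group."""
    kind = (
        "diploid"
        if design.ploidy == 2
        else ("neotetraploid" if design.neo else "tetraploid")
    )
    return GeneticArchitecture.from_heritability(
        h2=h2,
        ploidy=design.ploidy,
        mean_days=kwargs.pop("mean_days", BASE_MEAN_DAYS[kind]),
        cv_percent=kwargs.pop("cv_percent", BASE_CV_PERCENT[kind]),
        sterility_rate=kwargs.pop("sterility_rate", STERILITY_RATE[kind]),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# base populations
# ---------------------------------------------------------------------------


def found_base_population(
    arch: GeneticArchitecture,
    n_families: int,
    n_per_family: int,
    ploidy: int,
    rng_seed,
    *,
    line: str = "BASE",
    structure: str = "half_sib",
) -> tuple[list[SimIndividual], Pedigree]:
    """Field-collected base population: ``n_families`` maternal families of
    ``n_per_family`` seedlings each.

    Individuals are founders in the pedigree (parents unrecorded) but carry
    genuine family genetic structure: each family shares a latent
    Hardy-Weinberg dam, and each member receives one maternal gamete plus an
    independent Hardy-Weinberg pollen gamete (maternal half-sibs, matching a
    highly outcrossing species) or, with ``structure='full_sib'``, a gamete
    from a single latent sire.  Marginal genotype frequencies remain at
    Hardy-Weinberg proportions.
    """
    if n_families < 1 or n_per_family < 1:
        raise ValueError("need at least one family with one member")
    if structure not in ("half_sib", "full_sib"):
        raise ValueError("structure must be 'half_sib' or 'full_sib'")
    rng = _as_rng(rng_seed)
    ped = Pedigree()
    cohort: list[SimIndividual] = []
    half = ploidy // 2
    p = arch.founder_allele_freq
    alpha = arch.double_reduction if ploidy == 4 else 0.0
    counter = 0
    for fam in range(n_families):
        fam_label = f"{line}.f{fam:03d}"
        dam_dosage = draw_founder_genotype(arch, ploidy, rng)
        maternal = gamete_dosage(dam_dosage, ploidy, alpha, rng, size=n_per_family)
        if structure == "full_sib":
            sire_dosage = draw_founder_genotype(arch, ploidy, rng)
            paternal = gamete_dosage(
                sire_dosage, ploidy, alpha, rng, size=n_per_family
            )
        else:
            paternal = rng.binomial(half, p, size=(n_per_family, arch.n_loci))
        for j in range(n_per_family):
            counter += 1
            ind = SimIndividual(
                id=f"{line}.{counter:04d}",
                dam_id=UNKNOWN_PARENT,
                sire_id=UNKNOWN_PARENT,
                maternal_family=fam_label,
                line=line,
                generation=0,
                ploidy=ploidy,
                fertile=True,
                genotype=Genotype(maternal[j] + paternal[j], ploidy),
                breeding_value=0.0,
                phenotype=0.0,
            )
            assign_phenotype(ind, arch, 0, rng)
            cohort.append(ind)
            ped.add(ind.to_pedigree_record())
    return cohort, ped


def found_neotetraploid_base(
    arch: GeneticArchitecture,
    design: DesignConfig,
    rng,
) -> tuple[list[SimIndividual], Pedigree, int]:
    """Synthesized-neotetraploid base: a small pool of genome-doubled parents
    reciprocally crossed into seed-family pairs, two offspring per pair.

    Returns the base cohort, the pedigree (which records the synthesis
    parents, so base relatedness is visible to inbreeding calculations), and
    the pedigree generation offset (the base sits one pedigree generation
    below its recorded parents).
    """
    rng = _as_rng(rng)
    ped = Pedigree()
    n_parents = design.neo_founder_parents
    parents: list[SimIndividual] = []
    for i in range(n_parents):
        if design.founder_mode == "doubled_diploid":
            diploid = Genotype(draw_founder_genotype(arch, 2, rng), 2)
            genotype = synthesize_neotetraploid(diploid)
        else:
            genotype = Genotype(draw_founder_genotype(arch, 4, rng), 4)
        ind = SimIndividual(
            id=f"SYN.{i:03d}",
            dam_id=UNKNOWN_PARENT,
            sire_id=UNKNOWN_PARENT,
            maternal_family=f"SYN.f{i:03d}",
            line="SYNTH",
            generation=0,
            ploidy=4,
            fertile=True,
            genotype=genotype,
            breeding_value=0.0,
            phenotype=float("nan"),
        )
        parents.append(ind)
        ped.add(ind.to_pedigree_record())
    # reciprocal pairs; a few parents serve in two pairs when pairs outnumber
    # parent couples (55 parents -> 29 pairs reuses 3 parents)
    order = list(rng.permutation(n_parents))
    pairs: list[tuple[SimIndividual, SimIndividual]] = []
    while len(pairs) < design.n_base_families and len(order) >= 2:
        a = order.pop()
        b = order.pop()
        pairs.append((parents[a], parents[b]))
    idx = 0
    while len(pairs) < design.n_base_families:
        a = parents[int(rng.integers(n_parents))]
        b = parents[idx % n_parents]
        idx += 1
        if a.id != b.id:
            pairs.append((a, b))
    cohort: list[SimIndividual] = []
    counter = 0
    for fam, (a, b) in enumerate(pairs):
        fam_label = f"BASE.f{fam:03d}"
        for j in range(design.n_per_family):
            counter += 1
            dam, sire = (a, b) if rng.random() < 0.5 else (b, a)
            genotype = Genotype(
                make_gamete(dam.genotype, arch.double_reduction, rng)
                + make_gamete(sire.genotype, arch.double_reduction, rng),
                4,
            )
            ind = SimIndividual(
                id=f"BASE.{counter:04d}",
                dam_id=dam.id,
                sire_id=sire.id,
                maternal_family=fam_label,
                line="BASE",
                generation=0,
                ploidy=4,
                fertile=True,
                genotype=genotype,
                breeding_value=0.0,
                phenotype=0.0,
            )
            assign_phenotype(ind, arch, 0, rng)
            cohort.append(ind)
            # the base sits one pedigree generation below the synthesis
            # parents; experiment generations stay 0-based
            ped.add(ind.to_pedigree_record(generation_offset=1))
    return cohort, ped, 1


# ---------------------------------------------------------------------------
# selection and crossing
# ---------------------------------------------------------------------------


def _ranked_fertile(cohort: Sequence[SimIndividual], rng) -> list[SimIndividual]:
    fertile = [ind for ind in cohort if ind.fertile]
    keys = rng.random(len(fertile))  # seeded tie-break on equal phenotypes
    return [
        ind
        for _, _, ind in sorted(
            zip((i.phenotype for i in fertile), keys, fertile),
            key=lambda t: (t[0], t[1]),
        )
    ]


def truncation_select(
    cohort: Sequence[SimIndividual],
    m: int,
    rng,
    restrict_families: bool = True,
) -> list[SimIndividual]:
    """The ``m`` earliest-flowering fertile plants, at most one per maternal
    family: when siblings co-rank in the selection group only the earliest is
    kept and the next-ranked plant takes the freed slot."""
    rng = _as_rng(rng)
    ranked = _ranked_fertile(cohort, rng)
    if restrict_families:
        chosen: list[SimIndividual] = []
        used: set[str] = set()
        for ind in ranked:
            if ind.maternal_family in used:
                continue
            chosen.append(ind)
            used.add(ind.maternal_family)
            if len(chosen) == m:
                return chosen
        raise SelectionError(
            f"needed {m} plants from distinct families, found {len(chosen)}"
        )
    if len(ranked) < m:
        raise SelectionError(f"needed {m} fertile plants, found {len(ranked)}")
    return ranked[:m]


def random_select(
    cohort: Sequence[SimIndividual],
    m: int,
    rng,
    restrict_families: bool = True,
) -> list[SimIndividual]:
    """Control-line parent draw: ``m`` random fertile plants, with the same
    one-per-family restriction as truncation selection."""
    rng = _as_rng(rng)
    fertile = [ind for ind in cohort if ind.fertile]
    order = list(rng.permutation(len(fertile)))
    chosen: list[SimIndividual] = []
    used: set[str] = set()
    for i in order:
        ind = fertile[i]
        if restrict_families and ind.maternal_family in used:
            continue
        chosen.append(ind)
        used.add(ind.maternal_family)
        if len(chosen) == m:
            return chosen
    raise SelectionError(
        f"needed {m} fertile plants from distinct families, found {len(chosen)}"
    )


def split_round_one(
    cohort: Sequence[SimIndividual],
    pool_size: int,
    per_line: int,
    rng,
) -> tuple[list[SimIndividual], list[SimIndividual]]:
    """First selection round of a two-line design: the first ``pool_size``
    fertile plants to flower are split into two selected lines, maternal
    siblings going to different lines."""
    rng = _as_rng(rng)
    ranked = _ranked_fertile(cohort, rng)
    counts: dict[str, int] = {}
    pool: list[SimIndividual] = []
    for ind in ranked:
        if counts.get(ind.maternal_family, 0) >= 2:
            continue
        pool.append(ind)
        counts[ind.maternal_family] = counts.get(ind.maternal_family, 0) + 1
        if len(pool) == pool_size:
            break
    if len(pool) < pool_size:
        raise SelectionError(
            f"needed {pool_size} fertile plants for the round-one pool, "
            f"found {len(pool)}"
        )
    by_family: dict[str, list[SimIndividual]] = {}
    for ind in pool:
        by_family.setdefault(ind.maternal_family, []).append(ind)
    line_a: list[SimIndividual] = []
    line_b: list[SimIndividual] = []
    singles: list[SimIndividual] = []
    for members in by_family.values():
        if len(members) == 2:
            first, second = (
                members if rng.random() < 0.5 else [members[1], members[0]]
            )
            line_a.append(first)
            line_b.append(second)
        else:
            singles.append(members[0])
    order = list(rng.permutation(len(singles)))
    for i in order:
        if len(line_a) < per_line:
            line_a.append(singles[i])
        elif len(line_b) < per_line:
            line_b.append(singles[i])
        else:
            break
    if len(line_a) != per_line or len(line_b) != per_line:
        raise SelectionError("could not split the round-one pool evenly")
    return line_a, line_b


@dataclass(frozen=True)
class ReciprocalPair:
    """One reciprocal cross: two seed families with the same parents in
    opposite dam/sire roles."""

    a: str
    b: str


def crossing_design(
    selected: Sequence[SimIndividual],
    k: int,
    ped: Pedigree,
    rng,
    *,
    max_depth: int | None = None,
    retries: int | None = None,
) -> list[ReciprocalPair]:
    """Reciprocal crossing plan: every selected parent mates with exactly
    ``k`` distinct non-relative partners within the line, giving
    ``len(selected) * k / 2`` reciprocal seed-family pairs.

    Relatedness is screened with :meth:`Pedigree.are_relatives` down to
    ``max_depth`` meioses (default 1: parents and shared parents), plus a
    shared-maternal-family check that also covers founders with unrecorded
    parents.  The k-regular pairing is found by repeated random stub
    matching; an exception is raised if no valid design appears within the
    retry budget.
    """
    rng = _as_rng(rng)
    m = len(selected)
    if m * k % 2 != 0:
        raise CrossingDesignError("selected count times partners must be even")
    if k >= m:
        raise CrossingDesignError("each parent needs k distinct partners")
    depth = 1 if max_depth is None else max_depth
    budget = 2000 if retries is None else retries
    forbidden: set[frozenset[int]] = set()
    for i in range(m):
        for j in range(i + 1, m):
            a, b = selected[i], selected[j]
            if a.maternal_family == b.maternal_family or ped.are_relatives(
                a.id, b.id, max_depth=depth
            ):
                forbidden.add(frozenset((i, j)))
    stubs = np.repeat(np.arange(m), k)
    for _ in range(budget):
        perm = rng.permutation(stubs)
        edges = set()
        ok = True
        for i in range(0, len(perm), 2):
            u, v = int(perm[i]), int(perm[i + 1])
            if u == v:
                ok = False
                break
            e = frozenset((u, v))
            if e in edges or e in forbidden:
                ok = False
                break
            edges.add(e)
        if ok:
            pairs = sorted(tuple(sorted(e)) for e in edges)
            return [
                ReciprocalPair(selected[u].id, selected[v].id) for u, v in pairs
            ]
    # random stub matching struggles when forbidden edges cluster; fall back
    # to an exact k-factor search on the eligibility graph
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(range(m))
    graph.add_edges_from(
        (i, j)
        for i in range(m)
        for j in range(i + 1, m)
        if frozenset((i, j)) not in forbidden
    )
    try:
        factor = nx.k_factor(graph, k)
    except nx.NetworkXUnfeasible as exc:
        raise CrossingDesignError(
            f"no {k}-regular non-relative design exists for {m} parents"
        ) from exc
    pairs = sorted(tuple(sorted(e)) for e in factor.edges())
    return [ReciprocalPair(selected[u].id, selected[v].id) for u, v in pairs]


def advance_generation(
    pairs: Sequence[ReciprocalPair],
    parents: dict[str, SimIndividual],
    n_offspring: int,
    mortality: float,
    arch: GeneticArchitecture,
    ped: Pedigree,
    rng,
    *,
    line: str,
    generation: int,
    generation_offset: int = 0,
) -> list[SimIndividual]:
    """Produce the next cohort: one orientation of each reciprocal pair is
    chosen at random to be the seed family, ``n_offspring`` seeds are sown
    per family, and each offspring survives an independent Bernoulli
    mortality draw.  Survivors are phenotyped, screened for sterility, and
    appended to the pedigree."""
    if not pairs:
        raise SimulationError("no seed-family pairs to advance")
    rng = _as_rng(rng)
    cohort: list[SimIndividual] = []
    counter = 0
    for fam_idx, pair in enumerate(pairs):
        dam, sire = (
            (parents[pair.a], parents[pair.b])
            if rng.random() < 0.5
            else (parents[pair.b], parents[pair.a])
        )
        n_live = int(np.sum(rng.random(n_offspring) >= mortality))
        if n_live == 0:
            continue
        alpha = arch.double_reduction if dam.ploidy == 4 else 0.0
        maternal = gamete_dosage(dam.genotype.dosage, dam.ploidy, alpha, rng, n_live)
        paternal = gamete_dosage(sire.genotype.dosage, sire.ploidy, alpha, rng, n_live)
        dosages = maternal + paternal
        factor = arch.dosage_factor(dam.ploidy)
        bvs = factor * dosages @ arch.allele_effects - arch.mean_genetic_value(
            dam.ploidy
        )
        noise = rng.normal(0.0, arch.env_sd_at(generation), size=n_live)
        sterile = rng.random(n_live) < arch.sterility_rate
        fam_label = f"{line}.g{generation}.f{fam_idx:02d}"
        base_val = arch.ploidy_baseline + arch.generation_env(generation)
        for j in range(n_live):
            counter += 1
            ind = SimIndividual(
                id=f"{line}.g{generation}.{counter:03d}",
                dam_id=dam.id,
                sire_id=sire.id,
                maternal_family=fam_label,
                line=line,
                generation=generation,
                ploidy=dam.ploidy,
                fertile=not bool(sterile[j]),
                genotype=Genotype(dosages[j], dam.ploidy),
                breeding_value=float(bvs[j]),
                phenotype=float(base_val + bvs[j] + noise[j]),
            )
            cohort.append(ind)
            ped.add(ind.to_pedigree_record(generation_offset))
    return cohort


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentRecord:
    """Everything one simulated experiment produced: cohorts per line and
    generation, parent selections, the pedigree, per-generation summaries,
    and a stage-by-stage count ledger (families, plants grown, fertile
    plants, parents crossed, seed-family pairs created)."""

    design: DesignConfig
    seed: int
    pedigree: Pedigree
    cohorts: dict[str, dict[int, list[SimIndividual]]]
    selections: dict[tuple[str, int], list[str]]
    summaries: list[GenerationSummary]
    counts: list[dict]
    generation_offset: int = 0

    def line_summaries(self, line: str) -> list[GenerationSummary]:
        return sorted(
            (s for s in self.summaries if s.line == line),
            key=lambda s: s.generation,
        )

    def mean_inbreeding(
        self, line: str, generation: int, fertile_only: bool = True
    ) -> float:
        return self.pedigree.mean_line_inbreeding(
            line, generation + self.generation_offset, fertile_only
        )

    def phenotype_rows(self):
        for line, by_gen in self.cohorts.items():
            for gen in sorted(by_gen):
                for ind in by_gen[gen]:
                    yield ind

    def phenotype_frame(self):
        import pandas as pd

        rows = [
            {
                "id": ind.id,
                "dam": ind.dam_id,
                "sire": ind.sire_id,
                "maternal_family": ind.maternal_family,
                "line": ind.line,
                "generation": ind.generation + self.generation_offset,
                "ploidy": ind.ploidy,
                "fertile": int(ind.fertile),
                "phenotype_days": round(ind.phenotype, 6),
                "breeding_value": round(ind.breeding_value, 6),
            }
            for ind in self.phenotype_rows()
        ]
        return pd.DataFrame(rows)

    def write_phenotypes(self, path) -> None:
        self.phenotype_frame().to_csv(path, index=False)


def _line_rng(seed: int, line_code: int, generation: int) -> np.random.Generator:
    # one named stream per line per generation, stable under config edits
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(line_code), int(generation)])
    )


def _summarize(
    line: str,
    generation: int,
    cohort: Sequence[SimIndividual],
    selected: Sequence[SimIndividual],
) -> GenerationSummary:
    fertile = [i.phenotype for i in cohort if i.fertile]
    sel = [i.phenotype for i in selected]
    return GenerationSummary(
        line=line,
        generation=generation,
        n_grown=len(cohort),
        n_selected=len(sel),
        mean_fertile=float(np.mean(fertile)),
        sd_fertile=float(np.std(fertile, ddof=1)) if len(fertile) > 1 else 0.0,
        mean_selected=float(np.mean(sel)) if sel else float("nan"),
    )


def run_experiment(
    design: DesignConfig, arch: GeneticArchitecture, seed: int
) -> ExperimentRecord:
    """Simulate one complete selection experiment for one ploidy group.

    Deterministic given ``seed``.  Produces the base population, the
    first-round line founding (with the neotetraploid special case), and
    ``n_generations`` rounds of truncation selection (random parent draws in
    the control line), reciprocal crossing, and family-limited reproduction,
    with the final generation reared at reduced family counts.
    """
    seed = int(seed)
    base_rng = _line_rng(seed, 0, 0)
    sel1_name, sel2_name = design.selected_lines
    ctrl_name = design.control_line
    line_codes = {sel1_name: 1, sel2_name: 2, ctrl_name: 3}

    if design.neo:
        base, ped, offset = found_neotetraploid_base(arch, design, base_rng)
    else:
        base, ped = found_base_population(
            arch,
            design.n_base_families,
            design.n_per_family,
            design.ploidy,
            base_rng,
            structure=design.maternal_family_structure,
        )
        offset = 0
    # base mortality (a handful of deaths between sowing and scoring)
    if design.base_mortality > 0:
        alive = base_rng.random(len(base)) >= design.base_mortality
        base = [ind for ind, a in zip(base, alive) if a]

    cohorts: dict[str, dict[int, list[SimIndividual]]] = {"BASE": {0: base}}
    selections: dict[tuple[str, int], list[str]] = {}
    summaries: list[GenerationSummary] = []
    counts: list[dict] = []
    n_fertile_base = sum(1 for i in base if i.fertile)
    counts.append(
        {
            "line": "BASE",
            "stage": "base",
            "maternal_families": len({i.maternal_family for i in base}),
            "individuals": len(base),
            "fertile_individuals": n_fertile_base,
        }
    )

    def do_round(
        line: str,
        round_idx: int,
        cohort: list[SimIndividual],
        parent_group: list[SimIndividual],
        k: int,
        pairs_subset: int | None,
        n_offspring: int,
    ) -> list[SimIndividual]:
        rng = _line_rng(seed, line_codes[line], round_idx)
        pairs = crossing_design(
            parent_group,
            k,
            ped,
            rng,
            max_depth=design.relative_avoid_depth,
            retries=design.crossing_retries,
        )
        created = len(pairs)
        if pairs_subset is not None and pairs_subset < len(pairs):
            keep = rng.choice(len(pairs), size=pairs_subset, replace=False)
            pairs = [pairs[i] for i in sorted(keep)]
        parents = {p.id: p for p in parent_group}
        nxt = advance_generation(
            pairs,
            parents,
            n_offspring,
            design.mortality,
            arch,
            ped,
            rng,
            line=line,
            generation=round_idx,
            generation_offset=offset,
        )
        selections[(line, round_idx)] = [p.id for p in parent_group]
        counts.append(
            {
                "line": line,
                "stage": f"selection_{round_idx}",
                "individuals_in_crosses": len(parent_group),
                "seed_family_pairs_created": created,
            }
        )
        counts.append(
            {
                "line": line,
                "stage": f"generation_{round_idx}",
                "maternal_families": len({i.maternal_family for i in nxt}),
                "individuals": len(nxt),
                "fertile_individuals": sum(1 for i in nxt if i.fertile),
            }
        )
        return nxt

    # ---- round one: found the lines from the shared base ----
    r1_rng = _line_rng(seed, 9, 0)
    fertile_base = [i for i in base if i.fertile]
    if design.neo:
        sel_parents = truncation_select(
            fertile_base, design.neo_round_one_selected, r1_rng
        )
        ctrl_parents = random_select(
            fertile_base, design.neo_round_one_selected, r1_rng
        )
        for line in (sel1_name, sel2_name):
            summaries.append(_summarize(line, 0, base, sel_parents))
            cohorts.setdefault(line, {})[1] = do_round(
                line,
                1,
                base,
                sel_parents,
                design.neo_round_one_partners,
                design.neo_pairs_kept,
                design.n_offspring_per_family,
            )
        summaries.append(_summarize(ctrl_name, 0, base, ctrl_parents))
        cohorts.setdefault(ctrl_name, {})[1] = do_round(
            ctrl_name,
            1,
            base,
            ctrl_parents,
            design.neo_round_one_partners,
            design.neo_pairs_kept,
            design.n_offspring_per_family,
        )
    else:
        line1_parents, line2_parents = split_round_one(
            base, design.round_one_pool, design.n_selected, r1_rng
        )
        ctrl_parents = random_select(fertile_base, design.n_selected, r1_rng)
        for line, group in (
            (sel1_name, line1_parents),
            (sel2_name, line2_parents),
            (ctrl_name, ctrl_parents),
        ):
            summaries.append(_summarize(line, 0, base, group))
            cohorts.setdefault(line, {})[1] = do_round(
                line,
                1,
                base,
                group,
                design.partners_per_parent,
                None,
                design.n_offspring_per_family,
            )

    # ---- subsequent rounds ----
    for rnd in range(2, design.n_generations + 1):
        final = rnd == design.n_generations
        for line in (sel1_name, sel2_name, ctrl_name):
            cohort = cohorts[line][rnd - 1]
            rng = _line_rng(seed, line_codes[line] + 4, rnd)
            if line == ctrl_name:
                group = random_select(cohort, design.n_selected, rng)
            else:
                group = truncation_select(cohort, design.n_selected, rng)
            summaries.append(_summarize(line, rnd - 1, cohort, group))
            cohorts[line][rnd] = do_round(
                line,
                rnd,
                cohort,
                group,
                design.partners_per_parent,
                design.final_families if final else None,
                design.final_offspring_per_family
                if final
                else design.n_offspring_per_family,
            )

    # final-generation summaries (no further selection)
    for line in (sel1_name, sel2_name, ctrl_name):
        summaries.append(
            _summarize(line, design.n_generations, cohorts[line][design.n_generations], [])
        )

    return ExperimentRecord(
        design=design,
        seed=seed,
        pedigree=ped,
        cohorts=cohorts,
        selections=selections,
        summaries=summaries,
        counts=counts,
        generation_offset=offset,
    )
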