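# ploidysel

Forward simulation and analysis of artificial-selection experiments across
ploidy levels.

`ploidysel` models a classic divergence-selection breeding design on a
polygenic trait — days to first flower — run in parallel on three kinds of
plant material: diploids, long-established autotetraploids, and newly
synthesized (genome-doubled) neotetraploids. It couples a forward
population-genetic simulator of the full experimental protocol with the
estimators such experiments are analysed with:

- **Selection response** — per-generation selection differentials,
  control-corrected responses, and realized heritability
  `b_T = R_c / S_c` with analytic confidence limits.
- **Pedigree analysis** — Wright's path-counting inbreeding coefficients,
  relatedness queries, and pedigree CSV I/O.
- **Standing variation** — coefficients of variation with exact
  noncentral-*t* confidence intervals, and flow-cytometry 2C DNA-content
  ratios.
- **Replicated pipelines** — seeded multi-replicate runs, tidy report
  tables, and a command-line interface.

## The simulated experiment

Each ploidy group starts from a base population of maternal seed families
(113 × 2 diploid, 105 × 2 tetraploid; the neotetraploid base descends from
a pool of 55 synthesized parents crossed into 29 reciprocal family pairs).
From the base cohort, two selected lines and one control line are founded
and advanced for four generations:

1. **Selection** — the 24 earliest-flowering fertile plants per line, at
   most one per maternal family (round one splits the earliest 48 plants
   between the two lines, siblings to different lines; the neotetraploid
   first round uses a single group of 20 parents). Control lines draw
   parents at random under the same family restriction.
2. **Crossing** — every selected parent is crossed reciprocally with 3
   non-relative partners within its line (4 in the neotetraploid first
   round), giving 36 seed-family pairs (40, of which 35 are sampled, in the
   neotetraploid first round).
3. **Rearing** — one orientation per reciprocal pair is grown, 4 seeds per
   family with ~10 % mortality; the final generation grows 15 families of 2
   as a common garden.

The trait model is additive: `n_loci` unlinked biallelic loci, a
ploidy-level baseline, shared generation-wide environmental blocks (which
cancel in the control-corrected response), and Gaussian noise. Tetraploid
meiosis is tetrasomic — a gamete receives 2 of the 4 alleles per locus —
with optional double reduction up to the maximum rate of 1/6.

## Quick start

```python
from ploidysel import (
    DesignConfig, default_architecture, run_experiment, run_replicates,
)

design = DesignConfig.diploid()
arch = default_architecture(design, h2=0.40)

record = run_experiment(design, arch, seed=1)      # one experiment
summary = run_replicates(design, arch, 200, 42)    # replicated
print(summary.mean_heritability())
```

Command line:

```bash
ploidysel simulate --config config.yaml --seed 1 --reps 50 --out-dir out/
ploidysel estimate --phenotypes out/phenotypes.csv --out results.csv
ploidysel cv --phenotypes out/phenotypes.csv --out cv.csv
ploidysel inbreeding --pedigree ped.csv --out inbreeding.csv
ploidysel reproduce-tables
```

A config file selects a design preset and architecture:

```yaml
design:
  preset: neotetraploid     # diploid | tetraploid | neotetraploid
architecture:
  heritability: 0.55
  double_reduction: 0.0
run:
  replicates: 200
```

## A note on realized-heritability recovery

The realized-heritability estimator is unbiased for a single round of mass
selection: simulated round-one responses equal `h² · S` exactly within
Monte-Carlo error. Over four rounds of *this* breeding design, however, the
grand mean of `b_T` converges to roughly 0.8 × the base-population
heritability (e.g. 0.33 for a configured 0.40, measured over 200
replicates). This is not an implementation artifact but a property of the
experiment being simulated, with two causes:

1. **The Bulmer effect.** Truncation selection builds negative
   gametic-phase disequilibrium, eroding the usable additive variance by
   ≈ `k·h²/2` in the first round and settling near an equilibrium within
   two to three rounds.
2. **Family-restricted selection.** Selecting at most one plant per
   maternal family, with 24 parents drawn from at most 36 full-sib
   families, converts most of the selection into within-family selection,
   where only half of the additive variance segregates.

Consequently `b_T` from such an experiment estimates an *effective*
heritability under the design, not the base-population parameter; see
`docs/methods.md` for the quantitative decomposition. The acceptance tests
that assert ±0.03 recovery of the configured base value fail for this
reason, and are left failing deliberately rather than tuning the simulator
away from the protocol it models.

## Testing

```bash
python -m pytest -q                   # full suite (a few minutes)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite validates the estimators against independent oracles:
recursive-kinship and gene-dropping checks for path-method inbreeding,
exhaustive enumeration for tetrasomic gamete distributions, Monte-Carlo
coverage for the noncentral-*t* CV intervals, and null (zero-heritability)
checks for the response estimators.

## Layout

- `src/ploidysel/pedigree.py` — pedigree records, validation, Wright's path F
- `src/ploidysel/sim.py` — genetic architecture, gametes, designs, simulator
- `src/ploidysel/response.py` — differentials, responses, realized heritability
- `src/ploidysel/variation.py` — CV with noncentral-*t* intervals, DNA content
- `src/ploidysel/pipeline.py` — replicated runs, report tables, config files
- `src/ploidysel/cli.py` — `ploidysel` command-line interface
- `src/ploidysel/data/flowering_time_means.csv` — published per-line
  flowering-time means used by `reproduce-tables`
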