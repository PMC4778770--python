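# commnull

Null-model tests for species co-occurrence and trait-based limiting
similarity on presence–absence community matrices, with the simulation
machinery to measure the tests' own type I and type II error rates across
matrix sizes.

Community ecologists use two families of randomization tests to look for
fingerprints of competition in species × site incidence tables: *negative
co-occurrence* tests (do species segregate across sites more than chance?)
and *limiting similarity* tests (are the functional traits of co-occurring
species more evenly spread than chance?).  Both are applied to matrices
ranging from a handful of species and plots to thousands, yet their error
rates are only guaranteed in comfortable regimes.  `commnull` implements the
standard versions of both tests and a sweep framework that quantifies, by
simulation, where they can be trusted — how small a matrix is too small, and
when the popular abundance-weighted trait randomization starts rejecting
noise.

## The models

- **C-Score / fixed–fixed independent swap.**  For species *i*, *j* with
  incidences *rᵢ*, *rⱼ* sharing *S* sites, CUᵢⱼ = (rᵢ − S)(rⱼ − S) counts
  their 2×2 checkerboard sub-matrices; the C-Score is the mean CUᵢⱼ over all
  m(m−1)/2 pairs.  Null matrices preserve all row and column sums via trial
  swaps of random checkerboard sub-matrices (30,000 per randomization by
  default, 5,000 randomizations).
- **NN / SDNN under AITS or AWTS.**  Per site, each species' distance to its
  nearest trait neighbour is computed; the site mean (NN) and sample sd
  (SDNN) are averaged over sites holding ≥ 2 species.  AITS permutes traits
  among species uniformly; AWTS deals trait values out in rank order to
  abundance-weighted recipients, imposing a trait–abundance association.
- **Three significance criteria.**  Inclusive p (nulls tied with the
  observed count toward rejection), exclusive p (strict exceedance — a valid
  permutation p-value), and SES = (Obs − Mean)/Std with |SES| > 1.96.
  The inclusive/exclusive contrast matters precisely when constrained
  randomizations of small matrices keep reproducing the observed
  configuration.
- **Power analysis by signal injection.**  Maximal co-occurrence signal via
  10,000 Fisher–Yates row-shuffle hill-climbing iterations; maximal trait
  signal via 100,000 permutation iterations on matrices passing a pairwise
  hypergeometric co-occurrence screen.

See `docs/methods.md` for assumptions, parameter defaults and their
rationale, and known limitations.

## Worked example

```python
import numpy as np
from commnull import CooccurrenceNullModel, generate_matrix, generate_traits

rng = np.random.default_rng(42)
matrix = generate_matrix(12, 15, rng=rng)   # 12 species x 15 sites, log-normal incidence
traits = generate_traits(12, rng=rng)       # uniform (0, 100], 2 decimals

result = CooccurrenceNullModel(matrix, n_randomizations=1000, n_swaps=5000).fit(seed=1)
print(result.summary())
```

```
        C-Score / independent swap null model test
==========================================================
statistic                                          c_score
observed                                          7.363636
randomizations                                        1000
null mean                                         7.169742
null sd                                           0.167606
SES                                                 1.1568
----------------------------------------------------------
tail proportions                 upper               lower
  ties included                 0.1310              0.8820
  ties excluded                 0.1180              0.8690
----------------------------------------------------------
calls at alpha=0.05, tails=two:
  inclusive                                not significant
  exclusive                                not significant
  ses                                      not significant
==========================================================
```

The observed C-Score (7.36) sits 1.16 null standard deviations above the
mean of 1,000 margin-preserving randomizations; 11.8% of null matrices were
strictly more segregated, so none of the three criteria calls this random
community significant — the correct answer, since it was generated without
any species interactions.  `TraitNullModel(matrix, traits, metric="nn",
scheme="aits").fit(seed=2)` works the same way for limiting similarity.

Error-rate sweeps run through `GridSpec`:

```python
from commnull import GridSpec, run_type1_cell

spec = GridSpec(species_levels=(10,), site_levels=(10,), replicates=200,
                models=("cooc",), n_randomizations=500, n_swaps=5000)
summaries, records = run_type1_cell(10, 10, spec, rng=np.random.default_rng(0))
```

Each summary row carries the rejection proportion with an exact binomial 95%
interval plus diagnostics (mean null sd, SES-outlier share, tie rate).  A
`commnull` command-line tool wraps fixture generation (`generate`), testing
user CSVs (`test-matrix`, with warnings for < 10 species and for AWTS beyond
35 sites), YAML-configured sweeps (`type1`, `type2`) and TSV aggregation
(`report`); sweep outputs include a manifest (config, seeds, version) that
reproduces every cell byte-for-byte.

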