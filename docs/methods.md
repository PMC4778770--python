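# Methods

`commnull` implements randomization tests for two community-assembly
hypotheses on binary species × site matrices — negative co-occurrence
(species segregation) and trait-based limiting similarity (trait divergence /
even spacing) — together with the simulation machinery needed to measure the
tests' own type I and type II error rates across matrix sizes.

## Test statistics

**C-Score.** For species *i*, *j* with incidences *rᵢ*, *rⱼ* sharing *S*
sites, the checkerboard-unit count is CUᵢⱼ = (rᵢ − S)(rⱼ − S); the C-Score
is the mean of CUᵢⱼ over all m(m−1)/2 species pairs.  Its smallest possible
increment (the *granule size*) is 1/(m(m−1)/2), so small matrices have
coarse, tie-prone null distributions.

**NN and SDNN.**  Per site, each present species' nearest-neighbour distance
is the smallest |tᵢ − tⱼ| to another present species' trait value; the site
NN is the mean and the site SDNN the sample (n−1) standard deviation of
those distances.  (The population-sd convention differs only by the factor
√((k−1)/k) per site; the sample convention is used throughout.)  Community
NN/SDNN are means over sites with ≥ 2 species; sites with fewer species
carry no spacing information and are excluded, and a community with no such
site has undefined metrics.  Tied trait values are legal and give zero
distances.

## Randomizations

**Fixed–fixed independent swap.**  Each null matrix restarts from the focal
matrix and applies `n_swaps` *trial* swaps: draw two distinct rows and two
distinct columns uniformly; if the induced 2×2 sub-matrix is a checkerboard,
exchange its diagonal.  Row and column sums are preserved exactly.  Counting
attempts (with self-loops on failures) makes the chain's transition matrix
symmetric and its stationary distribution uniform over the fixed-margin
space; we verified this against exhaustive enumeration of small margin
classes.  Counting only *successful* swaps — a natural misreading of
"30,000 swaps" — turns the chain into the degree-biased jump process whose
stationary mass is proportional to a matrix's checkerboard count, which we
measured to inflate the 10×10 exclusive-criterion error rate from ~0.07 to
~0.22.  The default is 30,000 trial swaps and 5,000 randomizations; the desk
profile uses 5,000 and 500.

**AITS.**  Abundance-independent trait shuffling: a uniform permutation of
the trait values among species, the exact group-action null for traits that
are exchangeable across species.

**AWTS.**  Abundance-weighted trait shuffling.  No standard formulation
exists, so the algorithm is a design choice: trait values are dealt out in
rank order (largest first), each going to a species drawn with probability
proportional to its occurrence count from the species not yet assigned.
Repeated shuffles therefore maintain a stable trait–abundance association —
the scheme's null hypothesis — while preserving the trait multiset exactly
and collapsing to a uniform permutation when occurrence counts are equal.
Because the imposed association does not condition on the observed
assignment, the null distribution can sit away from the observed statistic
for communities whose traits are *not* clustered by abundance; this is the
mechanism behind the elevated false-positive rates of the AWTS tests on
random communities (about 20% at 10 species × 75 sites under the default
generator), and it is why AWTS should be reserved for systems where traits
really are structured by abundance.  We also evaluated a variant in which
recipients are visited in decreasing abundance order and draw donors
proportionally to the donors' abundance: its null permutations are biased
*toward* the observed assignment, which makes the test conservative
everywhere, and it is not offered.

## Significance criteria

Given N null values and the observed statistic, three criteria are computed:

- **inclusive** — null values tied with the observed count as evidence of
  extremeness: a tail is significant when the share of nulls *strictly*
  beyond the observed is < α (equivalently, the observed is ≥ (1−α)·N of
  the nulls).  When a constrained randomization often reproduces the focal
  configuration (small matrices, coarse granularity), ties accumulate at the
  observed value and the inclusive call over-rejects — the repeated-matrix
  pathology.
- **exclusive** — ties count against rejection: a tail is significant when
  the share of nulls at-or-beyond the observed is < α.  This is a valid
  permutation p-value, so each tail rejects at most α·100% of the time for
  exchangeable data.
- **SES** — (observed − null mean)/null sd, significant beyond |1.96|
  two-tailed or a signed 1.645 one-tailed.  A zero null sd leaves SES
  undefined (counted non-significant, flagged); |SES| ≥ 20 keeps the value
  but sets the outlier flag, and such outliers are dropped from SES
  correlation diagnostics.

The observed statistic is never appended to the null sample; the
inclusive/exclusive pair already expresses the discreteness that the append
convention papers over.

**Tail conventions.**  Type I sweeps test the co-occurrence model two-tailed
(segregation and aggregation are both departures), each tail at α = 0.05 —
hence the ~10% inclusive rate on well-behaved matrices.  Trait models are
tested one-tailed in the limiting-similarity direction by default (NN upper,
SDNN lower; `GridSpec(trait_tails="two")` restores two-tailed calls): the
exclusive criterion then keeps its false-positive rate below α at every
matrix size, which is the behaviour the error-rate literature reports for
these tests.  Type II sweeps are one-tailed in the direction of the injected
signal.

## Synthetic communities

Species incidences are drawn from a log-normal distribution, rounded half-up
and rejection-sampled into [1, n] (rejection rather than clamping, so no
probability spike at the bounds); occurrences are placed uniformly among
sites; while any site is empty, a random species row is re-placed.  Traits
are uniform on (0, 100] truncated (not rounded) to two decimals, so at most
10,000 distinct values exist and ties are possible.

Defaults: `log_mean = ln(0.5·n)`, `log_sd = 1.0` — median occupancy half the
sites, right-skewed, matrix fill ≈ 0.45.  Two facts constrain this choice:

1. *Coverage feasibility.*  The empty-site repair can only terminate when
   total incidence comfortably exceeds the site count, which rules out any
   site-independent ("absolute") log-normal: parameters sparse enough to be
   realistic at 10 sites leave 75-site matrices uncoverable.
2. *Calibration of the co-occurrence test.*  Matrices built by independent
   uniform row placement are uniform draws from their row/column-margin
   class, but matrices that went through the repair loop are not.  When
   repair is frequent the fixed–fixed test loses calibration even though the
   data are pure noise (we measured exclusive-criterion error rising from
   ~0.07 to ~0.15 at 10×10 with a sparser default).  At the chosen default,
   repair triggers on ~1–2% of ≥10-species matrices and the measured error
   rates are nominal.  The repair-induced conditioning affects only the
   co-occurrence test; trait tests condition on the matrix and are immune.

What the generator does *not* emulate: spatial or environmental structure,
species interactions, abundance data (matrices are binary), or trait
distributions other than uniform.  Passing error-rate tests on these
communities therefore says the procedures are calibrated for unstructured
data of realistic shape — not that they are robust to every real-world
matrix-generating process.

## Signal injection (power analysis)

Co-occurrence signal: hill-climb the C-Score for 10,000 iterations; each
iteration re-places every species' occurrences uniformly among sites
(Fisher–Yates row shuffles: row totals kept, column totals free) and keeps
the arrangement when the C-Score improves.  Empty sites left by the winning
arrangement are dropped (a zero column cannot hold a checkerboard).  The
fraction of placement space that 10,000 iterations explore shrinks with
matrix size, so the injected signal — and with it detection power — weakens
as sites grow; raising the budget restores power and is a config knob.

Trait signal: only matrices with no significantly negatively co-occurring
pair receive trait structure (pairwise hypergeometric screen, P(shared ≤ S)
< 0.05; failing matrices are discarded and regenerated so cell counts stay
exact).  The trait vector is then hill-climbed for 100,000 iterations with
fresh uniform permutations, maximizing NN or minimizing SDNN.  With
full-permutation proposals, restarting from the best-so-far or the original
vector is distributionally identical (a uniform permutation of any fixed
arrangement is uniform); a single-swap hill climber is available via
`proposal="swap"`.

## Error sweeps

`GridSpec` fixes the grid (species levels, site levels, replicate and
randomization counts, models, α).  `GridSpec.full_study()` holds the full
error-rate study grid (22 species levels × 21 site levels) at 10,000
replicates × 5,000 randomizations — a cluster-sized job.  The shipped desk profile (200 replicates, 500
randomizations, 5,000 trial swaps) runs a cell in seconds to minutes on one
CPU; every rejection proportion is reported with an exact Clopper–Pearson
95% interval so scaled-down runs can be compared honestly against
full-scale expectations.  Problem sizes in the acceptance script (200–500 replicates per
cell) were chosen on the same basis.

Per-cell seeds are spawned from the master seed with numpy's `SeedSequence`
in (species, sites[, model]) order, so cells reproduce bit-exactly and could
be executed in any order.  Within a type I cell all requested models test
the same generated matrix/trait pair, which is what pairs SES values across
models for the correlation diagnostics.  Matrices on which NN/SDNN are
undefined (every site a singleton) are discarded and regenerated for trait
runs; SES-undefined results count as non-significant but are tallied in
`ses_outlier_proportion`; the mean share of null values tied with the
observed is reported as `tie_rate`.

Diagnostics: `trait_abundance_chisq` (goodness-of-fit of per-trait-value
occurrence totals before vs after a shuffle, df = m−1, duplicate values
matched neutrally), `null_breadth` (mean null sd per cell; it shrinks with
site count as site-level values average out), and `ses_correlation`
(Pearson r between paired SES series after dropping |SES| ≥ 20).

## Numerical and degenerate-input choices

- Null sd and SES use the sample (n−1) standard deviation.
- Rejection thresholds use strict `p < α`.
- A matrix admitting no checkerboard is returned unchanged by the swap with
  a logged warning; an all-tied null is a legal (degenerate) distribution.
- The repair loop and incidence redraws are capped (defaults 10⁶ and 10⁵)
  and raise a degenerate-input error naming the offending dimensions.
- Compiled kernels use an inline xorshift64* generator seeded per call from
  a numpy `Generator`, so every result is reproducible from one master seed.

## Known limitations

- An AWTS inflation that *grows* with site count (near-nominal at few
  sites) is what site-dependent abundance skew would produce; under a
  site-scaled incidence family the abundance-share skew is constant in n,
  so the AWTS inflation here is roughly flat in site count instead.
  Incidence skew increasing with n conflicts with coverage feasibility
  (point 1 above).
- Detection of maximized co-occurrence signal at 15 species × 50 sites
  measures ~0.38–0.44 at these settings; the level is sensitive to the
  incidence distribution through both the achievable maximal C-Score and
  the null spread, so it should be read as indicative, not universal.
- Extremely elongated grids (e.g. 3 species × 150 sites) are infeasible for
  the repair-based generator and fail loudly rather than silently biasing.
- The sweeps run serially; per-cell entry points (`run_type1_cell`,
  `run_type2_cell`) and the deterministic seed-splitting rule are the
  intended hooks for external parallelisation.
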