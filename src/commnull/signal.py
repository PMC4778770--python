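"""Signal injection for power (type II error) estimation.

Co-occurrence signal is injected by hill-climbing the C-Score: every
iteration re-places each species' occurrences uniformly among sites with a
Fisher-Yates shuffle (row totals kept, column totals free) and keeps the
arrangement whenever the C-Score improves.  Trait (limiting-similarity)
signal is injected the same way on the trait vector, maximizing NN or
minimizing SDNN over uniform permutations.  Trait structure is only added to
matrices with no significantly negatively co-occurring species pair, screened
with a pairwise hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _kernels
from .core import as_rng, child_seed
from .matrix import CommunityMatrix, TraitVector, align_traits
from .traits import METRICS, community_trait_metrics

DEFAULT_CSCORE_ITERATIONS = 10_000
DEFAULT_TRAIT_ITERATIONS = 100_000
DEFAULT_SCREEN_ALPHA = 0.05


@dataclass(frozen=True)
class MaximizationResult:
    """Outcome of a keep-if-better randomized search."""

    best_object: object  # CommunityMatrix or TraitVector
    best_score: float
    iterations: int
    improvements: int


def maximize_cscore(matrix: CommunityMatrix,
                    n_iterations: int = DEFAULT_CSCORE_ITERATIONS,
                    rng=None, drop_empty_sites: bool = True) -> MaximizationResult:
    """Search ``n_iterations`` Fisher-Yates row shuffles for a maximal C-Score.

    The search never returns a score below the input matrix's own C-Score.
    A winning shuffle may leave sites empty; those sites are dropped from the
    returned matrix (shrinking it), since a zero column can never hold a
    checkerboard and the downstream swap test runs on the altered matrix.
    """
    if matrix.n_species < 2:
        raise ValueError("C-Score maximization requires at least two species")
    if n_iterations < 0:
        raise ValueError("n_iterations must be non-negative")
    rng = as_rng(rng)
    best, best_score, improvements = _kernels.fy_maximize_kernel(
        matrix.occupancy.copy(), n_iterations, child_seed(rng))
    assert np.array_equal(best.sum(axis=1), matrix.row_sums)
    sites = matrix.sites
    if drop_empty_sites:
        keep = best.sum(axis=0) > 0
        best = best[:, keep]
        sites = tuple(s for s, k in zip(sites, keep) if k)
    out = CommunityMatrix(best, species=matrix.species, sites=sites)
    return MaximizationResult(out, float(best_score), n_iterations, int(improvements))


def negative_pair_screen(matrix: CommunityMatrix,
                         alpha: float = DEFAULT_SCREEN_ALPHA) -> bool:
    """True when no species pair co-occurs significantly less than chance.

    For incidences r1, r2 in n sites sharing S sites, the shared-site count
    under independent placement is hypergeometric; the pair is significantly
    negative when P(shared <= S) < alpha.
    """
    if matrix.n_species < 2:
        raise ValueError("pair screen requires at least two species")
    occ = matrix.occupancy.astype(np.int64)
    n = matrix.n_sites
    r = matrix.row_sums
    shared = occ @ occ.T
    iu, ju = np.triu_indices(matrix.n_species, k=1)
    p_low = stats.hypergeom.cdf(shared[iu, ju], n, r[iu], r[ju])
    return bool((p_low >= alpha).all())


def maximize_trait_structure(matrix: CommunityMatrix, traits: TraitVector,
                             metric: str = "nn",
                             n_iterations: int = DEFAULT_TRAIT_ITERATIONS,
                             rng=None, proposal: str = "permutation") -> MaximizationResult:
    """Search trait permutations maximizing NN (or minimizing SDNN).

    ``proposal="permutation"`` draws a fresh uniform permutation of the trait
    multiset each iteration (so restarting from the best-so-far or from the
    original vector is distributionally identical); ``proposal="swap"`` is a
    single-transposition hill climber on the best-so-far assignment.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if proposal not in ("permutation", "swap"):
        raise ValueError("proposal must be 'permutation' or 'swap'")
    if n_iterations < 0:
        raise ValueError("n_iterations must be non-negative")
    rng = as_rng(rng)
    traits = align_traits(matrix, traits)

    from .traits import _site_members  # local import to avoid cycle at module load

    members, offsets = _site_members(matrix)
    buf = np.empty(matrix.n_species, dtype=np.float64)
    which = METRICS.index(metric)
    sign = 1.0 if metric == "nn" else -1.0  # maximize NN, minimize SDNN

    best_vals = traits.values.copy()
    nn, sdnn, defined = _kernels.nn_metric_kernel(members, offsets, best_vals, buf)
    if defined == 0:
        raise ValueError("every site holds fewer than two species")
    best_score = sign * (nn, sdnn)[which]

    improvements = 0
    work = best_vals.copy()
    for _ in range(n_iterations):
        if proposal == "permutation":
            work = rng.permutation(traits.values)
        else:
            work[:] = best_vals
            i, j = rng.choice(matrix.n_species, size=2, replace=False)
            work[i], work[j] = work[j], work[i]
        vals = _kernels.nn_metric_kernel(members, offsets, work, buf)
        score = sign * vals[which]
        if score > best_score:
            best_score = score
            best_vals = work.copy()
            improvements += 1

    return MaximizationResult(traits.with_values(best_vals), float(sign * best_score),
                              n_iterations, improvements)
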