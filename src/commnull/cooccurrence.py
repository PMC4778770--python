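"""C-Score statistic and the fixed-fixed independent swap null model.

The C-Score of a presence-absence matrix is the mean, over unordered species
pairs, of the checkerboard-unit count CU_ij = (r_i - S)(r_j - S), where r_i
and r_j are the species' incidences and S the number of sites they share; it
rises with species segregation.  Its null distribution is built by the
independent swap algorithm: each null matrix restarts from the focal matrix
and applies a fixed number of successful diagonal exchanges of random 2x2
checkerboard sub-matrices, preserving all row and column sums exactly.

``n_swaps`` counts *attempted* (trial) swaps.  Failed attempts leave the
matrix unchanged, which makes the chain's transition matrix symmetric and its
stationary distribution uniform over the fixed-margin space; counting only
successful swaps would instead sample matrices in proportion to their
checkerboard count and visibly inflate type I error rates (verified against
exhaustive enumeration of small margin classes).
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernels
from .core import NullDistribution, as_rng, child_seed
from .matrix import CommunityMatrix

logger = logging.getLogger(__name__)

#: Trial swaps per randomization (follows the 30,000-swap mixing guidance).
DEFAULT_N_SWAPS = 30_000
#: Randomizations per null distribution.
DEFAULT_N_RANDOMIZATIONS = 5_000


def c_score(matrix: CommunityMatrix) -> float:
    """Mean number of 2x2 checkerboard sub-matrices per species pair."""
    if matrix.n_species < 2:
        raise ValueError("C-Score requires at least two species")
    return float(_kernels.c_score_kernel(matrix.occupancy))


def granularity(m: int) -> float:
    """Smallest possible C-Score increment: 1 / (number of species pairs)."""
    if m < 2:
        raise ValueError("granularity requires at least two species")
    return 1.0 / (m * (m - 1) / 2.0)


def independent_swap_randomize(matrix: CommunityMatrix, n_swaps: int = DEFAULT_N_SWAPS,
                               rng=None) -> CommunityMatrix:
    """One fixed-fixed randomization: ``n_swaps`` trial checkerboard swaps.

    A matrix admitting no swap at all (e.g. all ones) is returned unchanged
    with a logged warning.
    """
    if n_swaps < 1:
        raise ValueError("n_swaps must be positive")
    if matrix.n_species < 2 or matrix.n_sites < 2:
        raise ValueError("swap randomization needs at least a 2x2 matrix")
    rng = as_rng(rng)
    occ = matrix.occupancy.copy()
    got = _kernels.swap_chain_kernel(occ, n_swaps, child_seed(rng))
    if got == 0:
        logger.warning("no successful swap in %d attempts on a %dx%d matrix; "
                       "returning it unchanged", n_swaps, matrix.n_species,
                       matrix.n_sites)
    out = CommunityMatrix(occ, species=matrix.species, sites=matrix.sites)
    assert np.array_equal(out.row_sums, matrix.row_sums)
    assert np.array_equal(out.col_sums, matrix.col_sums)
    return out


def cscore_null(matrix: CommunityMatrix,
                n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
                n_swaps: int = DEFAULT_N_SWAPS, rng=None) -> NullDistribution:
    """C-Score null distribution, each randomization restarting from ``matrix``."""
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be positive")
    rng = as_rng(rng)
    observed = c_score(matrix)
    nulls, zero_success, violations = _kernels.cscore_null_kernel(
        matrix.occupancy.copy(), n_randomizations, n_swaps, child_seed(rng))
    if violations:
        raise AssertionError("swap chain violated fixed margins")  # pragma: no cover
    if zero_success == n_randomizations:
        logger.warning("no randomization achieved a single successful swap; "
                       "the matrix admits no checkerboard exchange")
    return NullDistribution(observed, nulls, statistic_name="c_score")
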