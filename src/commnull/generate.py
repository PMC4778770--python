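"""Synthetic community generator: random incidence matrices and trait vectors.

Species incidences (number of occupied sites) are drawn from a log-normal
distribution, rounded to the nearest integer and rejection-sampled into
[1, n_sites]; occurrences are then placed uniformly at random among sites.
Empty sites are repaired by re-placing randomly chosen species until every
site holds at least one species.  Traits are uniform on (0, 100], truncated
(not rounded) to two decimal places.

The log-normal's parameters are a modelling choice.  The default scales the
median incidence with the number of sites (median occupancy = half the
sites, sigma = 1 on the log scale), giving right-skewed "few common, many
rare" incidence patterns while keeping the empty-site repair a rare event.
Rarity of repair matters statistically, not just computationally: repaired
matrices are no longer uniform draws from their row/column-margin class, and
when repair is frequent the fixed-fixed co-occurrence test loses its
calibration (its exclusive-criterion error rate is only guaranteed for
margin-uniform communities).  A fixed, site-independent parameterization is
available by passing an explicit :class:`IncidenceParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DegenerateMatrixError, as_rng
from .matrix import CommunityMatrix, TraitVector

#: Default median species occupancy as a fraction of the site count.
DEFAULT_OCCUPANCY_FRACTION = 0.5
#: Default log-scale standard deviation of the incidence distribution.
DEFAULT_LOG_SD = 1.0


@dataclass(frozen=True)
class IncidenceParams:
    """Natural-log-scale parameters of the species incidence distribution."""

    log_mean: float
    log_sd: float

    def __post_init__(self):
        if not self.log_sd > 0:
            raise ValueError("log_sd must be positive")

    @classmethod
    def default_for(cls, n_sites: int) -> "IncidenceParams":
        return cls(log_mean=math.log(DEFAULT_OCCUPANCY_FRACTION * n_sites),
                   log_sd=DEFAULT_LOG_SD)


def sample_incidence(n_sites: int, params: IncidenceParams | None = None,
                     rng=None, max_redraws: int = 100_000) -> int:
    """Draw one species incidence in [1, n_sites].

    A log-normal draw is rounded half-up to the nearest integer and redrawn
    until it lands in [1, n_sites]; zero incidences are thereby discarded
    (rejection, not clamping, so no probability spike at the bounds).
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    params = params or IncidenceParams.default_for(n_sites)
    rng = as_rng(rng)
    for _ in range(max_redraws):
        draw = rng.lognormal(mean=params.log_mean, sigma=params.log_sd)
        k = int(math.floor(draw + 0.5))  # round half-up
        if 1 <= k <= n_sites:
            return k
    raise DegenerateMatrixError(
        f"no valid incidence in [1, {n_sites}] after {max_redraws} draws "
        f"(log_mean={params.log_mean}, log_sd={params.log_sd})"
    )


def _place_row(n_sites: int, incidence: int, rng: np.random.Generator) -> np.ndarray:
    row = np.zeros(n_sites, dtype=np.uint8)
    row[rng.choice(n_sites, size=incidence, replace=False)] = 1
    return row


def generate_matrix(m: int, n: int, params: IncidenceParams | None = None,
                    rng=None, max_repair_iterations: int = 1_000_000) -> CommunityMatrix:
    """Generate a random m-species x n-site presence-absence matrix.

    Each species' incidence is sampled independently and its occurrences are
    scattered uniformly among sites.  While any site is empty, a species row
    is chosen at random and its occurrences re-placed; the loop is capped so
    infeasible dimensions fail loudly instead of spinning.  An incidence
    vector whose total is below the site count can never cover every site,
    so such vectors are redrawn before placement.
    """
    if m < 1 or n < 1:
        raise ValueError(f"matrix dimensions must be positive, got m={m}, n={n}")
    params = params or IncidenceParams.default_for(n)
    rng = as_rng(rng)

    for _ in range(max_repair_iterations):
        incidences = np.array([sample_incidence(n, params, rng) for _ in range(m)])
        if incidences.sum() >= n:
            break
    else:
        raise DegenerateMatrixError(
            f"could not draw a feasible incidence vector for m={m}, n={n}"
        )

    occ = np.vstack([_place_row(n, r, rng) for r in incidences])

    repairs = 0
    while not occ.any(axis=0).all():
        if repairs >= max_repair_iterations:
            raise DegenerateMatrixError(
                f"empty-site repair exceeded {max_repair_iterations} iterations "
                f"for m={m}, n={n}"
            )
        i = int(rng.integers(m))
        occ[i] = _place_row(n, incidences[i], rng)
        repairs += 1

    return CommunityMatrix(occ)


def generate_traits(m: int, rng=None) -> TraitVector:
    """Draw m trait values uniformly on (0, 100], truncated to two decimals.

    Truncation maps 3.456 -> 3.45.  Draws that truncate to 0.00 are redrawn
    so every value stays strictly positive.  Values are stored as k/100, so
    ties are possible (at most 10,000 distinct values).
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    rng = as_rng(rng)
    hundredths = np.empty(m, dtype=np.int64)
    for i in range(m):
        k = 0
        while k == 0:
            k = int(math.floor(rng.uniform(0.0, 100.0) * 100.0))
        hundredths[i] = k
    return TraitVector(hundredths / 100.0)
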