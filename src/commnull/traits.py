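"""Trait-based limiting-similarity metrics and trait-shuffling null models.

Metrics: per site, each present species' nearest-neighbour trait distance is
the smallest absolute trait difference to any other species at that site.
NN is the site mean of these distances averaged over sites, SDNN the site
sample standard deviation averaged over sites.  Sites with fewer than two
species carry no information about trait spacing and are excluded.

Randomizations: AITS permutes trait values among species uniformly; AWTS
biases the permutation so that abundant species tend to receive trait values
originally borne by abundant species, approximately preserving the
trait-abundance relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import NullDistribution, UndefinedMetricError, as_rng
from .matrix import CommunityMatrix, TraitVector, align_traits

DEFAULT_N_RANDOMIZATIONS = 5_000

METRICS = ("nn", "sdnn")
SCHEMES = ("aits", "awts")


@dataclass(frozen=True)
class SiteTraitStats:
    """Nearest-neighbour trait statistics of one site."""

    site_id: str
    species_in_site: int
    nn_mean: float | None
    nn_sd: float | None


def _site_members(matrix: CommunityMatrix):
    """CSR (members, offsets) listing species present at each site."""
    occ = matrix.occupancy
    members = []
    offsets = np.zeros(matrix.n_sites + 1, dtype=np.int64)
    for s in range(matrix.n_sites):
        present = np.flatnonzero(occ[:, s])
        members.append(present)
        offsets[s + 1] = offsets[s] + present.size
    return np.concatenate(members).astype(np.int64), offsets


def _nn_distances(values: np.ndarray) -> np.ndarray:
    order = np.sort(values)
    gaps = np.diff(order)
    dists = np.empty(order.size)
    dists[0] = gaps[0]
    dists[-1] = gaps[-1]
    if order.size > 2:
        dists[1:-1] = np.minimum(gaps[:-1], gaps[1:])
    return dists


def site_nn_stats(matrix: CommunityMatrix, traits: TraitVector, site: int) -> SiteTraitStats:
    """Nearest-neighbour stats for one site; undefined below two species."""
    if not 0 <= site < matrix.n_sites:
        raise IndexError(f"site index {site} out of range")
    traits = align_traits(matrix, traits)
    present = np.flatnonzero(matrix.occupancy[:, site])
    if present.size < 2:
        return SiteTraitStats(matrix.sites[site], int(present.size), None, None)
    dists = _nn_distances(traits.values[present])
    return SiteTraitStats(matrix.sites[site], int(present.size),
                          float(dists.mean()), float(np.std(dists, ddof=1)))


def community_trait_metrics(matrix: CommunityMatrix, traits: TraitVector) -> tuple[float, float]:
    """(NN, SDNN): site-level nearest-neighbour stats averaged over sites."""
    traits = align_traits(matrix, traits)
    members, offsets = _site_members(matrix)
    buf = np.empty(matrix.n_species, dtype=np.float64)
    nn, sdnn, defined = _kernels.nn_metric_kernel(members, offsets, traits.values, buf)
    if defined == 0:
        raise UndefinedMetricError("every site holds fewer than two species")
    return float(nn), float(sdnn)


def aits_shuffle(traits: TraitVector, rng=None) -> TraitVector:
    """Abundance-independent trait shuffle: a uniform permutation of values."""
    if len(traits) < 2:
        raise ValueError("shuffling requires at least two species")
    rng = as_rng(rng)
    return traits.with_values(rng.permutation(traits.values))


def awts_shuffle(traits: TraitVector, occurrences, rng=None) -> TraitVector:
    """Abundance-weighted trait shuffle.

    The trait values are dealt out in rank order (largest first); each value
    goes to a species drawn, with probability proportional to its occurrence
    count, from the species not yet assigned a value.  Abundant species
    therefore tend to receive values from the same end of the trait ranking,
    so repeated shuffles maintain a stable trait-abundance association - the
    randomization's null hypothesis - while the trait multiset is preserved
    exactly.  With equal occurrence counts every draw is uniform and the
    scheme collapses to ``aits_shuffle``.

    Because the imposed association does not condition on which species bore
    which value in the observed data, the null distribution it generates can
    sit away from the observed statistic; this is the mechanism behind the
    elevated false-positive rates of abundance-weighted trait tests on
    communities whose traits are not actually clustered by abundance.
    """
    occurrences = np.asarray(occurrences, dtype=np.float64)
    if occurrences.size != len(traits):
        raise ValueError("occurrences must align with the trait vector")
    if (occurrences < 1).any():
        raise ValueError("all occurrence counts must be >= 1")
    rng = as_rng(rng)
    values = np.sort(traits.values)[::-1]
    m = values.size
    remaining = np.arange(m)
    out = np.empty(m)
    for v in values:
        w = occurrences[remaining]
        cum = np.cumsum(w)
        pick = np.searchsorted(cum, rng.uniform(0.0, cum[-1]), side="right")
        pick = min(pick, remaining.size - 1)
        out[remaining[pick]] = v
        remaining = np.delete(remaining, pick)
    return traits.with_values(out)


def trait_null_distribution(matrix: CommunityMatrix, traits: TraitVector,
                            metric: str = "nn", scheme: str = "aits",
                            n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
                            rng=None) -> NullDistribution:
    """Null distribution of NN or SDNN under trait shuffling (matrix fixed)."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be positive")
    rng = as_rng(rng)
    traits = align_traits(matrix, traits)
    members, offsets = _site_members(matrix)
    buf = np.empty(matrix.n_species, dtype=np.float64)
    which = METRICS.index(metric)

    nn, sdnn, defined = _kernels.nn_metric_kernel(members, offsets, traits.values, buf)
    if defined == 0:
        raise UndefinedMetricError("every site holds fewer than two species")
    observed = (nn, sdnn)[which]

    occurrences = matrix.row_sums
    sorted_multiset = np.sort(traits.values)
    nulls = np.empty(n_randomizations)
    for t in range(n_randomizations):
        if scheme == "aits":
            shuffled = rng.permutation(traits.values)
        else:
            shuffled = awts_shuffle(traits, occurrences, rng).values
        assert np.array_equal(np.sort(shuffled), sorted_multiset)
        vals = _kernels.nn_metric_kernel(members, offsets, shuffled, buf)
        nulls[t] = vals[which]
    return NullDistribution(float(observed), nulls, statistic_name=metric)
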