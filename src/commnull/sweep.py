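"""Type I / type II error-rate sweeps over species x site grids.

A grid cell fixes the matrix dimensions; each replicate generates a fresh
random community (and trait vector), runs the requested null models, and the
cell reports per-criterion rejection proportions with exact binomial 95%
intervals plus diagnostics (mean null-distribution sd, SES-outlier share,
tie rate).  For type I runs the matrices are pure noise, so the rejection
proportion estimates the false-positive rate; for type II runs the matrices
carry maximal injected signal, so it estimates detection (power), and the
type II error is its complement.

Replication, randomization and swap counts are configuration: the full study
grid (10,000 replicates x 5,000 randomizations per cell over hundreds of
cells) is a cluster job, while :meth:`GridSpec.desk` holds a single-machine
profile (200 replicates, 500 randomizations, 5,000 swaps) whose binomial
intervals are wide but honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cooccurrence import cscore_null
from .core import as_rng
from .generate import IncidenceParams, generate_matrix, generate_traits
from .matrix import CommunityMatrix, TraitVector
from .significance import CRITERIA, classify
from .signal import maximize_cscore, maximize_trait_structure, negative_pair_screen
from .traits import trait_null_distribution

MODELS = ("cooc", "aits_nn", "aits_sdnn", "awts_nn", "awts_sdnn")

#: Species and site levels of the full type I study grid.
FULL_TYPE1_SPECIES = tuple(range(3, 21)) + (25, 30, 35, 50)
FULL_TYPE1_SITES = tuple(range(3, 16)) + (20, 25, 30, 35, 50, 75, 100, 150)
FULL_TYPE2_SPECIES = (5, 10, 15, 20, 25, 30, 35)
FULL_TYPE2_SITES_COOC = tuple(range(3, 16)) + (20, 25, 30, 35, 50)
FULL_TYPE2_SITES_TRAIT = FULL_TYPE2_SITES_COOC + (75, 100, 150, 200)


def _model_parts(model: str) -> tuple[str, str]:
    """(scheme, metric) of a trait model label; cooc handled by callers."""
    scheme, metric = model.split("_", 1)
    return scheme, metric


@dataclass(frozen=True)
class GridSpec:
    """Configuration of an error-rate sweep."""

    species_levels: tuple = (10,)
    site_levels: tuple = (10,)
    replicates: int = 200
    models: tuple = MODELS
    n_randomizations: int = 500
    n_swaps: int = 5_000
    alpha: float = 0.05
    cscore_iterations: int = 10_000
    trait_iterations: int = 100_000
    screen_alpha: float = 0.05
    max_screen_attempts: int = 1_000
    incidence_params: IncidenceParams | None = None  # None = site-scaled default
    #: Type I tail convention for trait models: "directional" tests only the
    #: limiting-similarity tail (high NN / low SDNN), "two" tests both tails.
    #: The co-occurrence test is always two-tailed for type I runs.
    trait_tails: str = "directional"

    def __post_init__(self):
        if min(self.species_levels) < 3 or min(self.site_levels) < 3:
            raise ValueError("species and site levels must all be >= 3")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.trait_tails not in ("directional", "two"):
            raise ValueError("trait_tails must be 'directional' or 'two'")

    @classmethod
    def desk(cls, **overrides) -> "GridSpec":
        """Single-machine profile: reduced replication, same procedures."""
        return cls(**overrides)

    @classmethod
    def full_study(cls, kind: str = "type1", **overrides) -> "GridSpec":
        """The full published-scale grid (a cluster-sized computation)."""
        base = dict(replicates=10_000, n_randomizations=5_000, n_swaps=30_000)
        if kind == "type1":
            base.update(species_levels=FULL_TYPE1_SPECIES, site_levels=FULL_TYPE1_SITES)
        elif kind == "type2":
            base.update(species_levels=FULL_TYPE2_SPECIES,
                        site_levels=FULL_TYPE2_SITES_TRAIT)
        else:
            raise ValueError("kind must be 'type1' or 'type2'")
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class GridCellSummary:
    """Per (species, sites, model, criterion) rejection summary."""

    species: int
    sites: int
    model: str
    metric: str
    criterion: str
    rejections: int
    replicates: int
    rejection_proportion: float
    ci_low: float
    ci_high: float
    mean_null_sd: float
    ses_outlier_proportion: float
    tie_rate: float


def binomial_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval for k successes in n trials."""
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def _fit_null(matrix: CommunityMatrix, traits: TraitVector | None, model: str,
              spec: GridSpec, rng):
    if model == "cooc":
        return cscore_null(matrix, spec.n_randomizations, spec.n_swaps, rng=rng)
    scheme, metric = _model_parts(model)
    return trait_null_distribution(matrix, traits, metric=metric, scheme=scheme,
                                   n_randomizations=spec.n_randomizations, rng=rng)


def _generate_testable(m: int, n: int, spec: GridSpec, needs_traits: bool,
                       rng, max_attempts: int = 1_000) -> CommunityMatrix:
    """Generate a matrix; when trait metrics are needed, require a site with
    two or more species (NN/SDNN are undefined on all-singleton-site
    communities, so such draws are discarded and regenerated)."""
    for _ in range(max_attempts):
        matrix = generate_matrix(m, n, spec.incidence_params, rng)
        if not needs_traits or (matrix.col_sums >= 2).any():
            return matrix
    raise RuntimeError(f"no matrix with a >=2-species site in {max_attempts} "
                       f"attempts at {m}x{n}")


def _metric_of(model: str) -> str:
    return "c_score" if model == "cooc" else _model_parts(model)[1]


def _summarize(records: pd.DataFrame, replicates: int) -> list[GridCellSummary]:
    out = []
    for (m, n, model), group in records.groupby(["species", "sites", "model"],
                                                sort=False):
        for criterion in CRITERIA:
            k = int(group[f"significant_{criterion}"].sum())
            ntests = len(group)
            lo, hi = binomial_interval(k, ntests)
            out.append(GridCellSummary(
                species=int(m), sites=int(n), model=model, metric=_metric_of(model),
                criterion=criterion, rejections=k, replicates=ntests,
                rejection_proportion=k / ntests, ci_low=lo, ci_high=hi,
                mean_null_sd=float(group["null_sd"].mean()),
                ses_outlier_proportion=float(group["ses_outlier"].mean()),
                tie_rate=float(group["tie_fraction"].mean()),
            ))
    return out


def _type1_tails(model: str, spec: GridSpec) -> str:
    """Tail convention of a type I test.

    Co-occurrence is tested two-tailed (segregation and aggregation are both
    departures from randomness).  Trait tests default to the one-tailed
    limiting-similarity direction - divergence for NN, evenness (low) for
    SDNN - the convention under which the exclusive criterion keeps its
    false-positive rate below alpha at every matrix size.
    """
    if model == "cooc" or spec.trait_tails == "two":
        return "two"
    return "one_upper" if _model_parts(model)[1] == "nn" else "one_lower"


def run_type1_cell(m: int, n: int, spec: GridSpec, rng=None,
                   models: Sequence[str] | None = None
                   ) -> tuple[list[GridCellSummary], pd.DataFrame]:
    """Type I cell: random matrices tested at ``spec.alpha``.

    All requested models test the *same* generated matrix/trait pair per
    replicate, so SES values are paired across models for the correlation
    diagnostics.  Returns (summaries, per-replicate records).
    """
    rng = as_rng(rng)
    models = tuple(models or spec.models)
    needs_traits = any(model != "cooc" for model in models)
    rows = []
    for rep in range(spec.replicates):
        matrix = _generate_testable(m, n, spec, needs_traits, rng)
        tv = generate_traits(m, rng) if needs_traits else None
        for model in models:
            dist = _fit_null(matrix, tv, model, spec, rng)
            res = classify(dist, alpha=spec.alpha, tails=_type1_tails(model, spec))
            row = {"species": m, "sites": n, "model": model, "replicate": rep,
                   "observed": dist.observed, "null_mean": dist.null_mean,
                   "null_sd": dist.null_sd, "tie_fraction": dist.tie_fraction,
                   "ses": res.ses, "ses_outlier": res.ses_outlier}
            for criterion in CRITERIA:
                row[f"significant_{criterion}"] = res.significant[criterion]
            rows.append(row)
    records = pd.DataFrame(rows)
    return _summarize(records, spec.replicates), records


def run_type2_cell(m: int, n: int, spec: GridSpec, model: str, rng=None
                   ) -> tuple[list[GridCellSummary], pd.DataFrame]:
    """Type II cell: signal-maximized matrices, one-tailed tests.

    The rejection proportion here is the detection rate (power); the type II
    error rate is one minus it.  Trait models only receive matrices passing
    the negative-pair screen; failing matrices are discarded and regenerated.
    """
    rng = as_rng(rng)
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    rows = []
    for rep in range(spec.replicates):
        if model == "cooc":
            matrix = generate_matrix(m, n, spec.incidence_params, rng)
            result = maximize_cscore(matrix, spec.cscore_iterations, rng)
            dist = cscore_null(result.best_object, spec.n_randomizations,
                               spec.n_swaps, rng=rng)
            tails = "one_upper"
        else:
            scheme, metric = _model_parts(model)
            for _ in range(spec.max_screen_attempts):
                matrix = _generate_testable(m, n, spec, True, rng)
                if negative_pair_screen(matrix, spec.screen_alpha):
                    break
            else:
                raise RuntimeError(
                    f"no matrix passed the negative-pair screen in "
                    f"{spec.max_screen_attempts} attempts at {m}x{n}")
            tv = generate_traits(m, rng)
            result = maximize_trait_structure(matrix, tv, metric=metric,
                                              n_iterations=spec.trait_iterations,
                                              rng=rng)
            dist = trait_null_distribution(matrix, result.best_object, metric=metric,
                                           scheme=scheme,
                                           n_randomizations=spec.n_randomizations,
                                           rng=rng)
            tails = "one_upper" if metric == "nn" else "one_lower"
        res = classify(dist, alpha=spec.alpha, tails=tails)
        row = {"species": m, "sites": n, "model": model, "replicate": rep,
               "observed": dist.observed, "null_mean": dist.null_mean,
               "null_sd": dist.null_sd, "tie_fraction": dist.tie_fraction,
               "ses": res.ses, "ses_outlier": res.ses_outlier,
               "improvements": result.improvements}
        for criterion in CRITERIA:
            row[f"significant_{criterion}"] = res.significant[criterion]
        rows.append(row)
    records = pd.DataFrame(rows)
    return _summarize(records, spec.replicates), records


def run_grid(spec: GridSpec, kind: str = "type1", seed=None, site_levels=None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every cell of the grid with per-cell seeds split from ``seed``.

    Cell seeds are spawned from a master SeedSequence in (species, sites,
    model) order, so results are reproducible and independent of execution
    order.  Returns (summary table, per-replicate records).
    """
    if kind not in ("type1", "type2"):
        raise ValueError("kind must be 'type1' or 'type2'")
    master = np.random.SeedSequence(seed)
    sites = tuple(site_levels or spec.site_levels)
    cells = [(m, n) for m in spec.species_levels for n in sites]
    summaries: list[GridCellSummary] = []
    records = []
    if kind == "type1":
        children = master.spawn(len(cells))
        for (m, n), child in zip(cells, children):
            cell_summaries, cell_records = run_type1_cell(
                m, n, spec, rng=np.random.default_rng(child))
            summaries.extend(cell_summaries)
            records.append(cell_records)
    else:
        jobs = [(m, n, model) for (m, n) in cells for model in spec.models]
        children = master.spawn(len(jobs))
        for (m, n, model), child in zip(jobs, children):
            cell_summaries, cell_records = run_type2_cell(
                m, n, spec, model, rng=np.random.default_rng(child))
            summaries.extend(cell_summaries)
            records.append(cell_records)
    return summaries_frame(summaries), pd.concat(records, ignore_index=True)


SUMMARY_COLUMNS = ["species", "sites", "model", "metric", "criterion",
                   "rejections", "replicates", "rejection_proportion",
                   "ci_low", "ci_high", "mean_null_sd",
                   "ses_outlier_proportion", "tie_rate"]


def summaries_frame(summaries: Iterable[GridCellSummary]) -> pd.DataFrame:
    frame = pd.DataFrame([s.__dict__ for s in summaries], columns=SUMMARY_COLUMNS)
    return frame[SUMMARY_COLUMNS]


def export_grid(summaries, path) -> None:
    """Long-format TSV, one row per (species, sites, model, criterion)."""
    frame = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    if frame.empty:
        raise ValueError("nothing to export")
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# supplementary diagnostics


def trait_abundance_chisq(traits_before: TraitVector, traits_after: TraitVector,
                          occurrences) -> tuple[float, int]:
    """Goodness-of-fit chi-square of trait abundance before vs after a shuffle.

    Each trait value's abundance is the occurrence count of the species
    bearing it: the expected count is the original bearer's occurrences, the
    observed count the post-shuffle bearer's.  df = m - 1.  Duplicate trait
    values are matched greedily in order.
    """
    occ = np.asarray(occurrences, dtype=float)
    before, after = traits_before.values, traits_after.values
    if not (before.size == after.size == occ.size):
        raise ValueError("trait vectors and occurrences must align")
    if (occ < 1).any():
        raise ValueError("occurrence counts must be >= 1")
    if not np.array_equal(np.sort(before), np.sort(after)):
        raise ValueError("trait multisets differ; not a shuffle of the same values")
    pools: dict[float, list[float]] = {}
    for j, value in enumerate(after):
        pools.setdefault(value, []).append(occ[j])
    chi2 = 0.0
    for k, value in enumerate(before):
        expected = occ[k]
        pool = pools[value]
        # prefer an exact abundance match so tied trait values pair neutrally
        observed = pool.pop(pool.index(expected)) if expected in pool else pool.pop()
        chi2 += (observed - expected) ** 2 / expected
    return float(chi2), before.size - 1


def ses_correlation(ses_x, ses_y, outlier_bound: float = 20.0) -> tuple[float, float]:
    """Pearson r (and p) between paired SES series, dropping |SES| >= 20 pairs."""
    x = np.asarray(ses_x, dtype=float)
    y = np.asarray(ses_y, dtype=float)
    if x.size != y.size:
        raise ValueError("SES series must be paired")
    keep = (np.abs(x) < outlier_bound) & (np.abs(y) < outlier_bound)
    keep &= np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable SES pairs; correlation undefined")
    r, p = stats.pearsonr(x[keep], y[keep])
    return float(r), float(p)


def null_breadth(records: pd.DataFrame) -> pd.DataFrame:
    """Mean null-distribution sd per (species, sites, model) cell."""
    return (records.groupby(["species", "sites", "model"], sort=False)["null_sd"]
            .mean().reset_index(name="mean_null_sd"))
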