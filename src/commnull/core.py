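"""Shared containers, errors and RNG plumbing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateMatrixError(RuntimeError):
    """Raised when a matrix with no empty rows/columns cannot be produced."""


class UndefinedMetricError(ValueError):
    """Raised when a community metric is undefined (e.g. no site holds two species)."""


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (None, int, SeedSequence or Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit seed for a compiled kernel from a Generator stream."""
    return int(rng.integers(0, 2**31 - 1))


@dataclass(frozen=True)
class NullDistribution:
    """An observed statistic together with its randomization distribution.

    Attributes
    ----------
    observed : float
        Value of the test statistic on the focal (un-randomized) data.
    null_values : ndarray
        Statistic recomputed on each of N randomized data sets.
    statistic_name : str
        Label such as ``"c_score"``, ``"nn"`` or ``"sdnn"``.
    """

    observed: float
    null_values: np.ndarray
    statistic_name: str = "statistic"

    def __post_init__(self):
        vals = np.asarray(self.null_values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("null_values must be a non-empty 1-d sequence")
        object.__setattr__(self, "null_values", vals)

    @property
    def n_randomizations(self) -> int:
        return int(self.null_values.size)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        """Sample (n-1) standard deviation of the null values."""
        if self.null_values.size < 2:
            return 0.0
        return float(np.std(self.null_values, ddof=1))

    @property
    def tie_fraction(self) -> float:
        """Fraction of null values exactly equal to the observed statistic."""
        return float(np.mean(self.null_values == self.observed))

    def to_tsv(self, path) -> None:
        """Single-column TSV export (header = statistic name) for audit."""
        header = f"{self.statistic_name}\tobserved={self.observed!r}"
        np.savetxt(path, self.null_values, fmt="%.17g", header=header, comments="# ")
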