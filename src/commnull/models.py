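"""Model objects tying a null-model test together, statsmodels style.

A model is constructed from data (a community matrix, plus traits for the
limiting-similarity tests) and configuration; ``fit(seed)`` runs the
randomization and returns a :class:`NullModelResults` carrying the observed
statistic, the null distribution, SES, the four tail proportions and
significance calls, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cooccurrence, traits as traits_mod
from .core import NullDistribution
from .matrix import CommunityMatrix, TraitVector, align_traits
from .significance import SignificanceResult, classify, ses_value, tail_proportions


@dataclass(frozen=True)
class NullModelResults:
    """Fitted null-model test: observed statistic vs randomization distribution."""

    model_name: str
    distribution: NullDistribution

    @property
    def observed(self) -> float:
        return self.distribution.observed

    @property
    def null_mean(self) -> float:
        return self.distribution.null_mean

    @property
    def null_sd(self) -> float:
        return self.distribution.null_sd

    @property
    def n_randomizations(self) -> int:
        return self.distribution.n_randomizations

    @property
    def ses(self) -> float:
        return ses_value(self.distribution)[0]

    @property
    def ses_outlier(self) -> bool:
        return ses_value(self.distribution)[1]

    @property
    def pvalues(self):
        return tail_proportions(self.distribution)

    def significance(self, alpha: float = 0.05, tails: str = "two") -> SignificanceResult:
        return classify(self.distribution, alpha=alpha, tails=tails)

    def summary(self, alpha: float = 0.05, tails: str = "two") -> str:
        res = self.significance(alpha=alpha, tails=tails)
        p = self.pvalues
        lines = [
            f"{self.model_name} null model test".center(58),
            "=" * 58,
            f"{'statistic':<28}{self.distribution.statistic_name:>30}",
            f"{'observed':<28}{self.observed:>30.6f}",
            f"{'randomizations':<28}{self.n_randomizations:>30d}",
            f"{'null mean':<28}{self.null_mean:>30.6f}",
            f"{'null sd':<28}{self.null_sd:>30.6f}",
            f"{'SES':<28}{self.ses:>30.4f}" + ("  [outlier]" if self.ses_outlier else ""),
            "-" * 58,
            f"{'tail proportions':<18}{'upper':>20}{'lower':>20}",
            f"{'  ties included':<18}{p.inclusive_upper:>20.4f}{p.inclusive_lower:>20.4f}",
            f"{'  ties excluded':<18}{p.exclusive_upper:>20.4f}{p.exclusive_lower:>20.4f}",
            "-" * 58,
            f"calls at alpha={alpha:g}, tails={tails}:",
        ]
        for criterion in ("inclusive", "exclusive", "ses"):
            verdict = "significant" if res.significant[criterion] else "not significant"
            lines.append(f"{'  ' + criterion:<28}{verdict:>30}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_frame(self, alpha: float = 0.05, tails: str = "two") -> pd.DataFrame:
        row = {"model": self.model_name,
               "statistic": self.distribution.statistic_name,
               "observed": self.observed,
               "null_mean": self.null_mean,
               "null_sd": self.null_sd,
               "n_randomizations": self.n_randomizations}
        row.update(self.significance(alpha=alpha, tails=tails).to_row())
        return pd.DataFrame([row])


class CooccurrenceNullModel:
    """C-Score + fixed-fixed independent swap co-occurrence test."""

    def __init__(self, matrix: CommunityMatrix,
                 n_randomizations: int = cooccurrence.DEFAULT_N_RANDOMIZATIONS,
                 n_swaps: int = cooccurrence.DEFAULT_N_SWAPS):
        self.matrix = matrix
        self.n_randomizations = n_randomizations
        self.n_swaps = n_swaps

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CooccurrenceNullModel":
        return cls(CommunityMatrix.from_csv(path), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "CooccurrenceNullModel":
        return cls(CommunityMatrix.from_frame(frame), **kwargs)

    def fit(self, seed=None) -> NullModelResults:
        dist = cooccurrence.cscore_null(self.matrix, self.n_randomizations,
                                        self.n_swaps, rng=seed)
        return NullModelResults("C-Score / independent swap", dist)


class TraitNullModel:
    """NN or SDNN limiting-similarity test under AITS or AWTS shuffling."""

    def __init__(self, matrix: CommunityMatrix, traits: TraitVector,
                 metric: str = "nn", scheme: str = "aits",
                 n_randomizations: int = traits_mod.DEFAULT_N_RANDOMIZATIONS):
        self.matrix = matrix
        self.traits = align_traits(matrix, traits)
        self.metric = metric
        self.scheme = scheme
        self.n_randomizations = n_randomizations

    @classmethod
    def from_csv(cls, matrix_path, traits_path, **kwargs) -> "TraitNullModel":
        return cls(CommunityMatrix.from_csv(matrix_path),
                   TraitVector.from_csv(traits_path), **kwargs)

    def fit(self, seed=None) -> NullModelResults:
        dist = traits_mod.trait_null_distribution(
            self.matrix, self.traits, metric=self.metric, scheme=self.scheme,
            n_randomizations=self.n_randomizations, rng=seed)
        name = f"{self.metric.upper()} / {self.scheme.upper()}"
        return NullModelResults(name, dist)
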