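"""Significance calls from a randomization null distribution.

Three criteria are supported:

``inclusive``
    Null values tied with the observed statistic count as evidence of
    extremeness: a tail is significant when the proportion of null values
    *strictly* beyond the observed is below alpha (equivalently, when the
    observed is >= at least (1 - alpha) of the null values for the upper
    tail).  When a randomization frequently reproduces the focal data - the
    repeated-matrix problem of small, tightly constrained matrices - ties
    pile up at the observed value and the inclusive call rejects too often.

``exclusive``
    Ties count against rejection: a tail is significant when the proportion
    of null values at-or-beyond the observed is below alpha.  This is a
    valid permutation p-value (per-tail rejection probability <= alpha under
    the null for exchangeable data), hence the more conservative call.

``ses``
    Standardized effect size (observed - null mean) / null sd; |SES| > 1.96
    is significant two-tailed, |SES| > 1.645 one-tailed in the tested
    direction.  A zero null sd leaves the SES undefined (flagged as an
    outlier, called non-significant); |SES| >= 20 keeps the value but sets
    the outlier flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import NullDistribution

CRITERIA = ("inclusive", "exclusive", "ses")
TAILS = ("two", "one_upper", "one_lower")

SES_TWO_TAILED = 1.96
SES_ONE_TAILED = 1.645
SES_OUTLIER_BOUND = 20.0


@dataclass(frozen=True)
class TailProportions:
    """The four tail proportions of an observed value in its null distribution."""

    inclusive_upper: float  # share of null values >= observed
    inclusive_lower: float  # share of null values <= observed
    exclusive_upper: float  # share of null values >  observed
    exclusive_lower: float  # share of null values <  observed


@dataclass(frozen=True)
class SignificanceResult:
    p_inclusive_upper: float
    p_inclusive_lower: float
    p_exclusive_upper: float
    p_exclusive_lower: float
    ses: float  # nan when the null sd is zero
    ses_outlier: bool
    significant: dict = field(default_factory=dict)
    alpha: float = 0.05
    tails: str = "two"

    @property
    def ses_defined(self) -> bool:
        return not np.isnan(self.ses)

    def to_row(self) -> dict:
        """Flat mapping for one TSV row."""
        row = {
            "p_inclusive_upper": self.p_inclusive_upper,
            "p_inclusive_lower": self.p_inclusive_lower,
            "p_exclusive_upper": self.p_exclusive_upper,
            "p_exclusive_lower": self.p_exclusive_lower,
            "ses": self.ses,
            "ses_outlier": self.ses_outlier,
            "alpha": self.alpha,
            "tails": self.tails,
        }
        for criterion in CRITERIA:
            row[f"significant_{criterion}"] = self.significant[criterion]
        return row


def tail_proportions(dist: NullDistribution) -> TailProportions:
    """Tail proportions of the observed value; the observed is never appended."""
    null = dist.null_values
    n = null.size
    obs = dist.observed
    return TailProportions(
        inclusive_upper=float(np.count_nonzero(null >= obs)) / n,
        inclusive_lower=float(np.count_nonzero(null <= obs)) / n,
        exclusive_upper=float(np.count_nonzero(null > obs)) / n,
        exclusive_lower=float(np.count_nonzero(null < obs)) / n,
    )


def ses_value(dist: NullDistribution) -> tuple[float, bool]:
    """SES = (observed - null mean) / null sd, with the outlier flag.

    Returns (nan, True) when the null sd is zero, (ses, True) when
    |SES| >= 20, and (ses, False) otherwise.
    """
    sd = dist.null_sd
    if sd == 0.0:
        return float("nan"), True
    ses = (dist.observed - dist.null_mean) / sd
    return float(ses), bool(abs(ses) >= SES_OUTLIER_BOUND)


def classify(dist: NullDistribution, alpha: float = 0.05,
             tails: str = "two") -> SignificanceResult:
    """Significance of an observed statistic under all three criteria.

    Two-tailed calls test each tail at ``alpha``; one-tailed calls test only
    the stated direction.  Tie handling is the whole difference between the
    p-value criteria: the inclusive call uses the strict-exceedance
    proportions (ties at the observed support rejection), the exclusive call
    uses the tie-including proportions (ties block rejection), so per tail
    the inclusive call always rejects at least as often as the exclusive.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if tails not in TAILS:
        raise ValueError(f"tails must be one of {TAILS}, got {tails!r}")
    p = tail_proportions(dist)
    ses, outlier = ses_value(dist)

    inc_upper = p.exclusive_upper < alpha  # ties count toward the observed
    inc_lower = p.exclusive_lower < alpha
    exc_upper = p.inclusive_upper < alpha  # ties count toward the null
    exc_lower = p.inclusive_lower < alpha

    if tails == "two":
        significant = {
            "inclusive": inc_upper or inc_lower,
            "exclusive": exc_upper or exc_lower,
            "ses": (not np.isnan(ses)) and abs(ses) > SES_TWO_TAILED,
        }
    elif tails == "one_upper":
        significant = {
            "inclusive": inc_upper,
            "exclusive": exc_upper,
            "ses": (not np.isnan(ses)) and ses > SES_ONE_TAILED,
        }
    else:
        significant = {
            "inclusive": inc_lower,
            "exclusive": exc_lower,
            "ses": (not np.isnan(ses)) and ses < -SES_ONE_TAILED,
        }

    return SignificanceResult(
        p_inclusive_upper=p.inclusive_upper,
        p_inclusive_lower=p.inclusive_lower,
        p_exclusive_upper=p.exclusive_upper,
        p_exclusive_lower=p.exclusive_lower,
        ses=ses,
        ses_outlier=outlier,
        significant=significant,
        alpha=alpha,
        tails=tails,
    )
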