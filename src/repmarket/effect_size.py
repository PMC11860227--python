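"""Standardization of summary test statistics to Cohen's d.

Replication projects compare heterogeneous designs (two-sample and
one-sample t-tests, z-tests, 1-df chi-square and F tests) on a common
scale.  This module converts a test statistic plus its design (sample
sizes, degrees of freedom) into a standardized mean difference with a
standard error, applies the sign convention under which the original
study's effect is always positive, and builds normal-approximation
confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

from scipy.stats import norm

__all__ = [
    "TestSummary",
    "EffectSize",
    "UnsupportedFamilyError",
    "InvalidSummaryError",
    "cohens_d_from_stat",
    "apply_sign_convention",
    "effect_ci",
    "relative_effect_size",
    "FAMILIES",
    "T_FAMILIES",
]

#: Supported test families.
FAMILIES = ("two_sample_t", "one_sample_t", "z", "chi2_df1", "F_df1_num")

#: Families whose statistic reduces to a (possibly noncentral) t.
T_FAMILIES = ("two_sample_t", "one_sample_t", "F_df1_num")


class UnsupportedFamilyError(ValueError):
    """Raised for test families outside the supported set."""


class InvalidSummaryError(ValueError):
    """Raised when a summary violates its invariants."""


@dataclass(frozen=True)
class TestSummary:
    """One study's inferential result as reported in summary form.

    Parameters
    ----------
    study_id : str
        Identifier of the study.
    role : {'original', 'replication'}
    family : str
        One of :data:`FAMILIES`.
    statistic : float
        The reported test statistic.  chi2 and F statistics must be
        non-negative; t and z statistics may carry a sign.
    df : float, optional
        Degrees of freedom; required for t and F families.
    n1 : int
        First (or only) group size.
    n2 : int, optional
        Second group size; absent for one-sample designs.
    p_two_sided : float
        Two-sided p value in [0, 1].
    same_direction : bool, optional
        Replications only: whether the observed effect points in the
        original study's direction.
    """

    study_id: str
    role: str
    family: str
    statistic: float
    n1: int
    p_two_sided: float
    df: Optional[float] = None
    n2: Optional[int] = None
    same_direction: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.role not in ("original", "replication"):
            raise InvalidSummaryError(f"unknown role {self.role!r}")
        if self.family not in FAMILIES:
            raise UnsupportedFamilyError(
                f"unsupported test family {self.family!r}; expected one of {FAMILIES}"
            )
        if not math.isfinite(self.statistic):
            raise InvalidSummaryError("statistic must be finite")
        if self.family in ("chi2_df1", "F_df1_num") and self.statistic < 0:
            raise InvalidSummaryError(f"{self.family} statistic must be non-negative")
        if self.n1 < 2:
            raise InvalidSummaryError("n1 must be at least 2")
        if self.n2 is not None and self.n2 < 2:
            raise InvalidSummaryError("n2 must be at least 2 when present")
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise InvalidSummaryError("p_two_sided must lie in [0, 1]")
        if self.family in ("two_sample_t", "one_sample_t", "F_df1_num"):
            if self.df is None:
                raise InvalidSummaryError(f"df is required for family {self.family!r}")
            if self.df <= 0:
                raise InvalidSummaryError("df must be positive")

    @property
    def two_group(self) -> bool:
        return self.n2 is not None

    @property
    def n_total(self) -> int:
        return self.n1 + (self.n2 or 0)


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with its standard error.

    ``ci`` is an optional ``(lower, upper)`` pair at ``ci_level``.
    """

    d: float
    se: float
    n_total: int
    ci: Optional[Tuple[float, float]] = None
    ci_level: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise InvalidSummaryError("standard error must be positive")
        if self.ci is not None and not (self.ci[0] <= self.d <= self.ci[1]):
            raise InvalidSummaryError("confidence interval must contain d")


def _design_unit(n1: int, n2: Optional[int]) -> float:
    """sqrt of the variance multiplier mapping d to the test statistic scale."""
    if n2 is not None:
        return math.sqrt(1.0 / n1 + 1.0 / n2)
    return math.sqrt(1.0 / n1)


def d_standard_error(d: float, n1: int, n2: Optional[int] = None) -> float:
    """Large-sample standard error of Cohen's d.

    Two-group: sqrt((n1+n2)/(n1*n2) + d^2/(2*(n1+n2))).
    One-group: sqrt(1/n + d^2/(2*n)).
    """
    if n2 is not None:
        n = n1 + n2
        return math.sqrt(n / (n1 * n2) + d * d / (2.0 * n))
    return math.sqrt(1.0 / n1 + d * d / (2.0 * n1))


def cohens_d_from_stat(summary: TestSummary) -> EffectSize:
    """Convert a summary test statistic to Cohen's d with standard error.

    Conversions: two-sample t gives d = t*sqrt(1/n1 + 1/n2); one-sample
    (or paired) t gives d = t/sqrt(n); a z statistic uses the same design
    multiplier as the corresponding t; a 1-df chi-square is treated as
    z = sqrt(chi2) and a 1-numerator-df F as t = sqrt(F).  For the
    sign-less chi2/F families of a replication, the direction flag
    restores the sign relative to the original finding.
    """
    fam = summary.family
    unit = _design_unit(summary.n1, summary.n2)

    if fam in ("two_sample_t", "one_sample_t", "z"):
        stat = summary.statistic
    elif fam == "chi2_df1":
        stat = math.sqrt(summary.statistic)
    elif fam == "F_df1_num":
        stat = math.sqrt(summary.statistic)
    else:  # pragma: no cover - guarded in __post_init__
        raise UnsupportedFamilyError(fam)

    if fam in ("chi2_df1", "F_df1_num") and summary.same_direction is False:
        stat = -stat

    d = stat * unit
    se = d_standard_error(d, summary.n1, summary.n2)
    return EffectSize(d=d, se=se, n_total=summary.n_total)


def apply_sign_convention(
    d_original_raw: float, d_replication_raw: float, same_direction: bool
) -> Tuple[float, float]:
    """Orient a study pair so the original effect is positive.

    The original d is taken in absolute value; the replication d keeps a
    positive sign only if its effect pointed in the original's direction.
    """
    d_o = abs(d_original_raw)
    d_r = abs(d_replication_raw)
    if not same_direction:
        d_r = -d_r
    return d_o, d_r


def effect_ci(e: EffectSize, level: float = 0.95) -> Tuple[float, float]:
    """Normal-approximation confidence interval ``d +/- z * se``."""
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie strictly inside (0, 1)")
    z = norm.ppf(0.5 * (1.0 + level))
    return (e.d - z * e.se, e.d + z * e.se)


def with_ci(e: EffectSize, level: float = 0.95) -> EffectSize:
    """Return a copy of ``e`` carrying its CI at ``level``."""
    lo, hi = effect_ci(e, level)
    return replace(e, ci=(lo, hi), ci_level=level)


def relative_effect_size(d_r: float, d_o: float) -> float:
    """Replication effect divided by the original effect.

    Negative values indicate an opposite-direction replication.  The
    original effect must be strictly positive (guaranteed by the sign
    convention for any real original finding).
    """
    if d_o <= 0:
        raise ValueError("original effect size must be positive (apply the sign convention first)")
    return d_r / d_o
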