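"""Replication sample-size planning.

Replications are sized to have 90% power to detect two thirds of the
original study's standardized effect at the two-sided 5% level, with
the original sample size as a floor.  Power is computed on the
noncentral t distribution for t-based designs and the normal for
z-based designs; two-group designs assume balanced allocation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .effect_size import FAMILIES, T_FAMILIES, UnsupportedFamilyError
from .indicators import _two_sided_power

__all__ = ["DesignSpec", "replication_sample_size", "achieved_power"]


@dataclass(frozen=True)
class DesignSpec:
    """Design of the original study for power purposes.

    ``n_original`` is expressed in the units of ``allocation``: per
    group for two-group designs, the single group for one-sample
    designs.
    """

    family: str
    n_original: int
    two_group: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UnsupportedFamilyError(self.family)
        if self.n_original < 2:
            raise ValueError("n_original must be at least 2")


def achieved_power(
    n: int, d: float, design: DesignSpec, alpha: float = 0.05
) -> float:
    """Power of the design's two-sided test at per-group size ``n`` and
    true standardized effect ``d``."""
    if design.two_group:
        m = math.sqrt(n / 2.0)
        df = 2 * n - 2
    else:
        m = math.sqrt(n)
        df = n - 1
    return _two_sided_power(d, design.family, m, df, alpha)


def replication_sample_size(
    d_original: float,
    design: DesignSpec,
    power: float = 0.90,
    fraction: float = 2.0 / 3.0,
    alpha: float = 0.05,
) -> int:
    """Smallest per-group n reaching ``power`` against ``fraction * d_O``.

    Returns ``max(computed n, n_original)`` — the replication is never
    smaller than the original study.
    """
    if d_original <= 0:
        raise ValueError("original effect size must be positive")
    target = fraction * d_original

    # normal-approximation warm start, then exact integer search
    za = norm.ppf(1.0 - alpha / 2.0)
    zb = norm.ppf(power)
    groups = 2.0 if design.two_group else 1.0
    n = max(2, math.ceil(groups * (za + zb) ** 2 / target**2))

    while achieved_power(n, target, design, alpha) < power:
        n += 1
    while n > 2 and achieved_power(n - 1, target, design, alpha) >= power:
        n -= 1
    return max(n, design.n_original)
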