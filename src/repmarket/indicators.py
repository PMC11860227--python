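"""Per-study-pair replication indicator battery.

Given an original finding and its close replication (both standardized
to Cohen's d), this module computes:

* the statistical-significance criterion (p < 0.05, same direction);
* the small-telescopes verdict against d33, the effect the original
  design had 33% power to detect;
* the one-sided default Bayes factor BF_+0 (truncated Cauchy(0, 0.707)
  prior on the standardized effect) and the replication Bayes factor
  BF_R0 (prior replaced by the original study's posterior);
* Jeffreys evidence categories for Bayes factors;
* the fixed-effect (inverse-variance) meta-analytic effect combining
  original and replication;
* the 95% prediction interval for the replication effect and the
  two-sample z-test of a difference between the two effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import integrate, optimize
from scipy.stats import cauchy, nct, norm, t as t_dist

from .effect_size import (
    EffectSize,
    TestSummary,
    T_FAMILIES,
    apply_sign_convention,
    cohens_d_from_stat,
    effect_ci,
    relative_effect_size,
)

__all__ = [
    "StudyPair",
    "IndicatorReport",
    "IndicatorError",
    "BFIntegrationError",
    "significance_criterion",
    "small_telescope",
    "default_bf_plus0",
    "replication_bf_r0",
    "jeffreys_category",
    "fixed_effect_meta",
    "prediction_interval",
    "indicator_battery",
]

#: Scale of the default Cauchy prior on the standardized effect.
DEFAULT_PRIOR_SCALE = 0.707


class IndicatorError(RuntimeError):
    """An indicator computation failed; carries the indicator name."""


class BFIntegrationError(IndicatorError):
    """Numerical integration for a Bayes factor did not converge."""


@dataclass(frozen=True)
class StudyPair:
    """An original study and its replication, standardized and oriented."""

    original: TestSummary
    replication: TestSummary
    d_original: EffectSize
    d_replication: EffectSize

    def __post_init__(self) -> None:
        if self.d_original.d < 0:
            raise ValueError("original effect must be non-negative under the sign convention")

    @classmethod
    def from_summaries(cls, original: TestSummary, replication: TestSummary) -> "StudyPair":
        """Standardize both members and apply the sign convention."""
        if replication.same_direction is None:
            raise ValueError("replication summary must carry the same_direction flag")
        e_o = cohens_d_from_stat(original)
        e_r = cohens_d_from_stat(replication)
        d_o, d_r = apply_sign_convention(e_o.d, e_r.d, replication.same_direction)
        return cls(
            original=original,
            replication=replication,
            d_original=EffectSize(d=d_o, se=e_o.se, n_total=e_o.n_total),
            d_replication=EffectSize(d=d_r, se=e_r.se, n_total=e_r.n_total),
        )


@dataclass(frozen=True)
class IndicatorReport:
    """All indicator outcomes for one original/replication pair."""

    study_id: str
    sig_replicated: bool
    relative_es: float
    d33: float
    small_telescope_pass: bool
    bf_plus0: float
    bf_r0: float
    jeffreys_plus0: str
    jeffreys_r0: str
    meta_d: float
    meta_se: float
    meta_p: float
    meta_sig_05: bool
    meta_sig_005: bool
    pi_low: float
    pi_high: float
    z_diff: float
    p_diff: float
    pi_pass: bool

    def __post_init__(self) -> None:
        if self.bf_plus0 <= 0 or self.bf_r0 <= 0:
            raise ValueError("Bayes factors must be positive")
        if not self.pi_low < self.pi_high:
            raise ValueError("prediction interval must be a proper interval")
        if self.meta_sig_005 and not self.meta_sig_05:
            raise ValueError("significance at 0.005 implies significance at 0.05")


# ---------------------------------------------------------------------------
# significance criterion


def significance_criterion(pair: StudyPair) -> bool:
    """True iff the replication is significant (two-sided p < 0.05) in the
    original's direction."""
    rep = pair.replication
    return bool(rep.p_two_sided < 0.05 and rep.same_direction)


# ---------------------------------------------------------------------------
# small telescopes


def _ncp_multiplier(summary: TestSummary) -> float:
    """Factor mapping a standardized effect to the statistic's noncentrality."""
    if summary.two_group:
        return math.sqrt(summary.n1 * summary.n2 / (summary.n1 + summary.n2))
    return math.sqrt(summary.n1)


def _two_sided_power(
    d: float, family: str, m: float, df: Optional[float], alpha: float
) -> float:
    """Rejection probability of the two-sided test at standardized effect d."""
    lam = d * m
    if family in T_FAMILIES:
        crit = t_dist.ppf(1.0 - alpha / 2.0, df)
        # the far tail underflows to NaN inside scipy's nct for large ncp
        hi = nct.sf(crit, df, lam)
        lo = nct.cdf(-crit, df, lam)
        hi = 1.0 if (math.isnan(hi) and lam > crit) else (0.0 if math.isnan(hi) else hi)
        lo = 0.0 if math.isnan(lo) else lo
        return hi + lo
    crit = norm.ppf(1.0 - alpha / 2.0)
    return norm.sf(crit - lam) + norm.cdf(-crit - lam)


def d33(original: TestSummary, power: float = 1.0 / 3.0, alpha: float = 0.05) -> float:
    """Effect size the original design had ``power`` power to detect.

    Solved by bisection on the noncentral distribution of the original's
    family (noncentral t for t-based designs, normal for z-based).
    """
    m = _ncp_multiplier(original)
    df = original.df
    fam = original.family

    def gap(d: float) -> float:
        return _two_sided_power(d, fam, m, df, alpha) - power

    lo, hi = 1e-6, 10.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise IndicatorError("small_telescope: power equation has no root in [1e-6, 10]")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12))


def small_telescope(
    pair: StudyPair, alpha: float = 0.05, power: float = 1.0 / 3.0
) -> Tuple[float, bool]:
    """Small-telescopes verdict: ``(d33, pass)``.

    The replication fails iff the upper bound of its 90% CI lies below
    d33, i.e. the replication effect is significantly smaller than the
    'small effect' in a one-sided test at the 5% level.
    """
    d_small = d33(pair.original, power=power, alpha=alpha)
    _, upper = effect_ci(pair.d_replication, level=1.0 - 2.0 * alpha)
    return d_small, bool(upper >= d_small)


# ---------------------------------------------------------------------------
# Bayes factors


def _signed_statistic(summary: TestSummary) -> float:
    """Statistic on the t/z scale, oriented in the original's direction."""
    stat = summary.statistic
    if summary.family == "chi2_df1":
        stat = math.sqrt(stat)
    elif summary.family == "F_df1_num":
        stat = math.sqrt(stat)
    if summary.role == "replication":
        stat = abs(stat)
        if summary.same_direction is False:
            stat = -stat
    else:
        stat = abs(stat)
    return stat


_MIX_GRIDS: dict = {}


def _chi_mixture_grid(df: float, n_w: int = 1201) -> Tuple[np.ndarray, np.ndarray]:
    """Quadrature grid over W = chi2_df / df with its log-density."""
    from scipy.stats import gamma

    key = (df, n_w)
    if key not in _MIX_GRIDS:
        a, scale = df / 2.0, 2.0 / df
        w = np.linspace(
            gamma.ppf(1e-14, a, scale=scale), gamma.ppf(1.0 - 1e-14, a, scale=scale), n_w
        )
        _MIX_GRIDS[key] = (w, gamma.logpdf(w, a, scale=scale))
    return _MIX_GRIDS[key]


def _nct_pdf_mixture(x: float, df: float, ncp: np.ndarray) -> np.ndarray:
    """Noncentral-t pdf through its scale-mixture representation.

    t = (Z + ncp) / sqrt(W) with W = chi2_df / df, so the density is
    E_W[ phi(x * sqrt(W) - ncp) * sqrt(W) ], evaluated in log space on a
    fixed quadrature grid.  Stable for any df and noncentrality, unlike
    scipy's boost backend which overflows in the far tails.
    """
    from scipy.special import logsumexp

    w, logfw = _chi_mixture_grid(df)
    sw = np.sqrt(w)
    z = x * sw[None, :] - ncp[:, None]
    logint = -0.5 * z * z - 0.5 * math.log(2.0 * math.pi) + 0.5 * np.log(w) + logfw
    return np.exp(logsumexp(logint, axis=1) + math.log(w[1] - w[0]))


def _nct_pdf_safe(x: float, df: float, ncp: np.ndarray) -> np.ndarray:
    """Noncentral-t pdf, robust over the whole noncentrality range.

    Uses scipy's exact evaluation where it succeeds and the log-space
    mixture quadrature where boost overflows or returns NaN.
    """
    arr = np.atleast_1d(np.asarray(ncp, dtype=float))
    out = np.zeros_like(arr)
    near = np.abs(arr - x) < 38.0  # beyond: density < 1e-250
    if near.any():
        sub = arr[near]
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = np.asarray(nct.pdf(x, df, sub), dtype=float)
            bad = ~np.isfinite(vals)
            if bad.any():
                vals[bad] = _nct_pdf_mixture(x, df, sub[bad])
        except (OverflowError, FloatingPointError):
            vals = _nct_pdf_mixture(x, df, sub)
        out[near] = vals
    return out if np.ndim(ncp) else float(out[0])


def _likelihood(summary: TestSummary) -> Tuple[Callable[[np.ndarray], np.ndarray], float, float]:
    """Return ``(L, L0, mode)``: the likelihood of the observed statistic
    as a function of the standardized effect, its value under the null,
    and the effect value where it peaks.

    t-based designs use the exact noncentral-t likelihood; z-based
    designs use a normal likelihood on the z scale.
    """
    m = _ncp_multiplier(summary)
    obs = _signed_statistic(summary)
    if summary.family in T_FAMILIES:
        df = summary.df

        def lik(delta):
            return _nct_pdf_safe(obs, df, np.asarray(delta) * m)

        return lik, float(t_dist.pdf(obs, df)), obs / m

    def lik(delta):
        return norm.pdf(obs - np.asarray(delta) * m)

    return lik, float(norm.pdf(obs)), obs / m


def default_bf_plus0(
    rep: TestSummary, prior_scale: float = DEFAULT_PRIOR_SCALE, rtol: float = 1e-6
) -> float:
    """One-sided default Bayes factor BF_+0 for a replication result.

    Evidence for a positive standardized effect under a Cauchy(0,
    ``prior_scale``) prior truncated to the original's direction,
    against the point null, evaluated by adaptive quadrature.
    """
    lik, l0, mode = _likelihood(rep)
    m = _ncp_multiplier(rep)

    def integrand(delta):
        return float(2.0 * cauchy.pdf(delta, scale=prior_scale) * lik(delta))

    # likelihood support: a ~1/m-wide bump near the point estimate
    hi = max(10.0 * prior_scale, abs(mode) + 45.0 / m)
    pts = [p for p in (max(mode, 0.0), max(mode - 10.0 / m, 0.0), mode + 10.0 / m) if 0.0 < p < hi]
    num, err = integrate.quad(
        integrand, 0.0, hi, points=sorted(set(pts)) or None,
        epsrel=rtol, epsabs=0.0, limit=400,
    )
    if not math.isfinite(num) or num <= 0.0 or (err > 0 and err / num > 100 * rtol):
        raise BFIntegrationError(
            f"default_bf_plus0: quadrature failed (value {num!r}, abs err {err!r})"
        )
    return num / l0


def _posterior_grid(
    original: TestSummary, prior_scale: float, n_grid: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Grid and normalized posterior density of the effect given the original.

    Posterior ~ truncated Cauchy prior x original likelihood, normalized
    numerically on a grid spanning ten prior scales beyond the original
    point estimate.
    """
    e_o = cohens_d_from_stat(original)
    upper = max(10.0 * prior_scale, abs(e_o.d) + 10.0 * e_o.se)
    grid = np.linspace(0.0, upper, n_grid)
    lik, _, _ = _likelihood(original)
    density = 2.0 * cauchy.pdf(grid, scale=prior_scale) * lik(grid)
    area = integrate.simpson(density, x=grid)
    if not math.isfinite(area) or area <= 0.0:
        raise BFIntegrationError("replication_bf_r0: original posterior is degenerate")
    return grid, density / area


def replication_bf_r0(
    pair: StudyPair,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    n_grid: int = 4097,
) -> float:
    """Replication Bayes factor BF_R0.

    Same construction as BF_+0 but with the truncated-Cauchy prior
    replaced by the posterior of the effect given the original data —
    the replication's evidence on top of the original's.
    """
    grid, posterior = _posterior_grid(pair.original, prior_scale, n_grid)
    lik_r, l0_r, _ = _likelihood(pair.replication)
    num = integrate.simpson(posterior * lik_r(grid), x=grid)
    if not math.isfinite(num) or num < 0.0:
        raise BFIntegrationError("replication_bf_r0: marginal likelihood integration failed")
    return num / l0_r


_JEFFREYS_EDGES = (1 / 100, 1 / 30, 1 / 10, 1 / 3, 1.0, 3.0, 10.0, 30.0, 100.0)
_JEFFREYS_LABELS = (
    "extreme evidence for H0",
    "very strong evidence for H0",
    "strong evidence for H0",
    "moderate evidence for H0",
    "anecdotal evidence for H0",
    "anecdotal evidence for H1",
    "moderate evidence for H1",
    "strong evidence for H1",
    "very strong evidence for H1",
    "extreme evidence for H1",
)


def jeffreys_category(bf: float) -> str:
    """Jeffreys evidence category for a Bayes factor.

    Symmetric ladder on thresholds 1/100, 1/30, 1/10, 1/3, 1, 3, 10,
    30, 100 from extreme support for the null to extreme support for
    the alternative.  A Bayes factor of exactly 1 sits on the
    no-preference boundary and is reported as 'no evidence'.
    """
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    if bf == 1.0:
        return "no evidence"
    for edge, label in zip(_JEFFREYS_EDGES, _JEFFREYS_LABELS):
        if bf < edge:
            return label
    return _JEFFREYS_LABELS[-1]


# ---------------------------------------------------------------------------
# meta-analysis and prediction intervals


def fixed_effect_meta(pair: StudyPair) -> Tuple[float, float, float, bool, bool]:
    """Fixed-effect (inverse-variance) meta-analysis of the pair.

    Returns ``(meta_d, meta_se, meta_p, sig_05, sig_005)`` where the p
    value comes from a two-sided z-test of the pooled effect.
    """
    w_o = 1.0 / pair.d_original.se ** 2
    w_r = 1.0 / pair.d_replication.se ** 2
    meta_d = (w_o * pair.d_original.d + w_r * pair.d_replication.d) / (w_o + w_r)
    meta_se = 1.0 / math.sqrt(w_o + w_r)
    z = meta_d / meta_se
    p = 2.0 * norm.sf(abs(z))
    return meta_d, meta_se, p, bool(p < 0.05), bool(p < 0.005)


def prediction_interval(
    pair: StudyPair, level: float = 0.95
) -> Tuple[float, float, float, float, bool]:
    """Prediction interval for the replication effect around the original.

    Returns ``(pi_low, pi_high, z_diff, p_diff, pass)``.  The interval
    is ``d_O +/- z * sqrt(se_O^2 + se_R^2)``; a replication inside it
    does not differ from the original at the ``1 - level`` significance
    level (two-sample z-test).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    s = math.hypot(pair.d_original.se, pair.d_replication.se)
    zq = norm.ppf(0.5 * (1.0 + level))
    lo = pair.d_original.d - zq * s
    hi = pair.d_original.d + zq * s
    z_diff = (pair.d_replication.d - pair.d_original.d) / s
    p_diff = 2.0 * norm.sf(abs(z_diff))
    ok = bool(lo <= pair.d_replication.d <= hi)
    return lo, hi, z_diff, p_diff, ok


# ---------------------------------------------------------------------------
# battery


def indicator_battery(pair: StudyPair) -> IndicatorReport:
    """Compute the full indicator battery for one pair.

    Any member failure is re-raised as :class:`IndicatorError` with the
    indicator's name attached.
    """

    def run(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except IndicatorError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise IndicatorError(f"{name}: {exc}") from exc

    sig = run("significance_criterion", significance_criterion, pair)
    rel = run(
        "relative_effect_size",
        relative_effect_size,
        pair.d_replication.d,
        pair.d_original.d,
    )
    d_small, st_pass = run("small_telescope", small_telescope, pair)
    bf10 = run("default_bf_plus0", default_bf_plus0, pair.replication)
    bfr0 = run("replication_bf_r0", replication_bf_r0, pair)
    meta_d, meta_se, meta_p, sig05, sig005 = run("fixed_effect_meta", fixed_effect_meta, pair)
    pi_lo, pi_hi, z_diff, p_diff, pi_ok = run("prediction_interval", prediction_interval, pair)

    return IndicatorReport(
        study_id=pair.replication.study_id,
        sig_replicated=sig,
        relative_es=rel,
        d33=d_small,
        small_telescope_pass=st_pass,
        bf_plus0=bf10,
        bf_r0=bfr0,
        jeffreys_plus0=jeffreys_category(bf10),
        jeffreys_r0=jeffreys_category(bfr0),
        meta_d=meta_d,
        meta_se=meta_se,
        meta_p=meta_p,
        meta_sig_05=sig05,
        meta_sig_005=sig005,
        pi_low=pi_lo,
        pi_high=pi_hi,
        z_diff=z_diff,
        p_diff=p_diff,
        pi_pass=pi_ok,
    )
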