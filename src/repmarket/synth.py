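"""Synthetic study populations, forecasters and trading sessions.

Emulates the statistical structure of a decision-market replication
study with no human data: a pool of published findings that are all
significant at p < 0.05 (a publication filter that inflates observed
effects, especially for true nulls), a mixture of genuine and null
effects yielding an overall replication rate near one half,
replications powered at 90% against two thirds of the observed original
effect (hence roughly 3.5x larger samples), and forecasters whose
beliefs are informative about replication outcomes.

Every stochastic operation takes an explicit seed or generator, so a
full synthetic experiment is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import nct, t as t_dist

from .effect_size import TestSummary, cohens_d_from_stat
from .market import MarketState, TokenLedger, trade_to_belief
from .power import DesignSpec, replication_sample_size

__all__ = [
    "GeneratorConfig",
    "SyntheticStudy",
    "generate_study_population",
    "simulate_replication",
    "simulate_forecasters",
    "simulate_trading",
]

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is mandatory for stochastic operations")
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-population and market conditions for a synthetic experiment.

    Defaults mirror the emulated study: 41 candidate findings, 162
    forecasters trading LMSR markets with liquidity 100 and a 100-token
    endowment, original two-sample designs averaging about 292
    participants in total, a roughly even mixture of null and genuine
    effects, and replications powered at 90% against 2/3 of the
    observed original effect.
    """

    n_studies: int = 41
    null_fraction: float = 0.5
    effect_scale: float = 0.5  # half-normal scale of true effects, Cohen's d
    mean_n_per_group: float = 146.0
    n_sigma: float = 0.5  # lognormal shape of per-group sizes
    min_n_per_group: int = 20
    publication_filter: bool = True
    max_filter_attempts: int = 100_000
    alpha: float = 0.05
    # replication sizing
    power: float = 0.90
    fraction: float = 2.0 / 3.0
    # forecasters: partial information about the latent success odds plus
    # shared and idiosyncratic misperception, on the log-odds scale
    n_forecasters: int = 162
    belief_attenuation: float = 0.2  # fraction of the latent log-odds seen
    belief_noise: float = 2.0  # per-forecaster log-odds noise
    study_noise: float = 1.5  # shared per-study log-odds misperception
    # market
    b: float = 100.0
    endowment: float = 100.0
    max_passes: int = 8
    price_tol: float = 1e-4
    k_top: int = 12
    k_bottom: int = 12
    n_random: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.null_fraction <= 1.0):
            raise ValueError("null_fraction must lie in [0, 1]")
        if self.n_studies < 1:
            raise ValueError("n_studies must be positive")
        if self.effect_scale < 0 or self.belief_noise < 0 or self.study_noise < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class SyntheticStudy:
    """A simulated published finding and its latent ground truth.

    ``true_d`` is expressed in the original's published frame (positive
    when the genuine effect points in the published direction).
    """

    study_id: str
    true_d: float
    is_null: bool
    n_per_group: int
    original: TestSummary
    planned_n_r: int  # per group
    latent_replication_probability: float

    def __post_init__(self) -> None:
        if self.is_null != (self.true_d == 0.0):
            raise ValueError("true_d must be zero exactly for null studies")


def _draw_t_two_sample(rng: np.random.Generator, ncp: float, df: int) -> float:
    """A noncentral-t draw: (Z + ncp) / sqrt(chi2_df / df)."""
    z = rng.standard_normal() + ncp
    chi2 = rng.chisquare(df)
    return z / math.sqrt(chi2 / df)


def _latent_success_probability(true_d: float, n_r: int, alpha: float) -> float:
    """P(replication significant in the original's direction), analytically.

    Two-sample design with per-group n_r: the same-direction clause
    keeps only the upper rejection region (in the original's frame).
    """
    df = 2 * n_r - 2
    crit = t_dist.ppf(1.0 - alpha / 2.0, df)
    ncp = true_d * math.sqrt(n_r / 2.0)
    p = nct.sf(crit, df, ncp)
    if math.isnan(p):  # scipy's nct far tail underflows for large ncp
        p = 1.0 if ncp > crit else 0.0
    return float(p)


def generate_study_population(
    config: GeneratorConfig, seed: RngLike
) -> List[SyntheticStudy]:
    """Draw a pool of published original findings.

    Each study is a balanced two-sample design.  True effects are zero
    with probability ``null_fraction`` and half-normal otherwise.  With
    the publication filter on, each original result is resampled until
    significant at ``alpha``, reproducing the inflation of published
    effect sizes; the observed direction then defines the 'positive'
    direction for the replication.  The replication sample size and the
    latent probability of a successful replication are computed at
    generation time.
    """
    rng = _rng(seed)
    studies: List[SyntheticStudy] = []
    width = len(str(config.n_studies))
    for i in range(config.n_studies):
        is_null = bool(rng.random() < config.null_fraction)
        true_d = 0.0 if is_null else float(abs(rng.normal(0.0, config.effect_scale)))

        mu = math.log(config.mean_n_per_group) - config.n_sigma**2 / 2.0
        n = max(config.min_n_per_group, int(round(rng.lognormal(mu, config.n_sigma))))
        df = 2 * n - 2
        ncp = true_d * math.sqrt(n / 2.0)

        for attempt in range(config.max_filter_attempts):
            t = _draw_t_two_sample(rng, ncp, df)
            p = 2.0 * t_dist.sf(abs(t), df)
            if not config.publication_filter or p < config.alpha:
                break
        else:
            raise RuntimeError(
                f"publication filter did not accept a draw in "
                f"{config.max_filter_attempts} attempts"
            )

        observed_sign = 1.0 if t >= 0 else -1.0
        original = TestSummary(
            study_id=f"S{i + 1:0{width}d}",
            role="original",
            family="two_sample_t",
            statistic=abs(t),  # the observed direction defines 'positive'
            df=df,
            n1=n,
            n2=n,
            p_two_sided=min(p, 1.0),
        )
        d_o = cohens_d_from_stat(original).d
        n_r = replication_sample_size(
            d_o,
            DesignSpec(family="two_sample_t", n_original=n, two_group=True),
            power=config.power,
            fraction=config.fraction,
            alpha=config.alpha,
        )
        # express the true effect in the original's published frame: negative
        # if the (rare) significant original pointed opposite the true effect
        true_d_frame = observed_sign * true_d
        latent = _latent_success_probability(true_d_frame, n_r, config.alpha)
        studies.append(
            SyntheticStudy(
                study_id=original.study_id,
                true_d=true_d_frame,
                is_null=is_null,
                n_per_group=n,
                original=original,
                planned_n_r=n_r,
                latent_replication_probability=latent,
            )
        )
    return studies


def simulate_replication(
    study: SyntheticStudy, n_r: Optional[int] = None, seed: RngLike = None,
    alpha: float = 0.05,
) -> TestSummary:
    """Draw a replication result for one study.

    The replication statistic comes from the design's sampling
    distribution at the study's true effect, independent of the
    original; the direction flag compares it to the original's observed
    direction.
    """
    rng = _rng(seed)
    n = int(n_r if n_r is not None else study.planned_n_r)
    if n < 2:
        raise ValueError("replication group size must be at least 2")
    df = 2 * n - 2
    ncp = study.true_d * math.sqrt(n / 2.0)
    t = _draw_t_two_sample(rng, ncp, df)
    p = 2.0 * t_dist.sf(abs(t), df)
    return TestSummary(
        study_id=study.study_id,
        role="replication",
        family="two_sample_t",
        statistic=abs(t),
        df=df,
        n1=n,
        n2=n,
        p_two_sided=min(p, 1.0),
        same_direction=bool(t >= 0),  # original frame: its observed effect is +
    )


def simulate_forecasters(
    studies: Sequence[SyntheticStudy], config: GeneratorConfig, seed: RngLike
) -> Tuple[pd.DataFrame, pd.Series]:
    """Simulate per-forecaster replication beliefs.

    Forecasters observe a fraction ``belief_attenuation`` of the
    study's latent success log-odds (partial information shrinks
    forecasts toward indifference), distorted by a shared per-study
    misperception (``study_noise``) and an idiosyncratic per-forecaster
    term (``belief_noise``); beliefs are the logistic of the result,
    clipped to (0.01, 0.99).  With attenuation 1 and both noise scales
    0, the mean belief equals the latent probability exactly.  Returns
    the forecaster-by-study belief matrix and the per-study mean.
    """
    rng = _rng(seed)
    ids = [s.study_id for s in studies]
    latent = np.array(
        [min(max(s.latent_replication_probability, 1e-3), 1.0 - 1e-3) for s in studies]
    )
    logodds = config.belief_attenuation * np.log(latent / (1.0 - latent))
    shared = rng.normal(0.0, config.study_noise, size=len(studies))
    noise = rng.normal(
        0.0, config.belief_noise, size=(config.n_forecasters, len(studies))
    )
    beliefs = 1.0 / (1.0 + np.exp(-(logodds[None, :] + shared[None, :] + noise)))
    beliefs = np.clip(beliefs, 0.01, 0.99)
    frame = pd.DataFrame(
        beliefs,
        index=[f"trader{j + 1:03d}" for j in range(config.n_forecasters)],
        columns=ids,
    )
    return frame, frame.mean(axis=0)


def simulate_trading(
    beliefs: pd.DataFrame,
    config: GeneratorConfig,
    seed: RngLike,
    return_ledgers: bool = False,
):
    """Run a budget-constrained LMSR trading session.

    Traders act in seeded random order, one asset at a time, repeatedly
    until no pass moves any price by more than ``price_tol`` (or
    ``max_passes`` is reached).  Returns the trade log (one row per
    transaction) and the final price per study.
    """
    rng = _rng(seed)
    study_ids = list(beliefs.columns)
    traders = list(beliefs.index)
    states: Dict[str, MarketState] = {
        sid: MarketState(b=config.b) for sid in study_ids
    }
    ledgers: Dict[str, TokenLedger] = {
        tr: TokenLedger(endowment=config.endowment) for tr in traders
    }
    records: List[dict] = []
    tick = 0
    for _ in range(config.max_passes):
        max_move = 0.0
        for tr in rng.permutation(traders):
            ledger = ledgers[tr]
            for sid in rng.permutation(study_ids):
                state = states[sid]
                before_s, before_bal = state.s, ledger.balance
                price_before = state.price
                new_state, ledger = trade_to_belief(
                    state, float(beliefs.at[tr, sid]), ledger, asset_id=sid
                )
                if new_state.s != before_s:
                    states[sid] = new_state
                    move = abs(new_state.price - price_before)
                    max_move = max(max_move, move)
                    records.append(
                        {
                            "tick": tick,
                            "trader_id": tr,
                            "study_id": sid,
                            "shares": new_state.s - before_s,
                            "tokens": before_bal - ledger.balance,
                            "price": new_state.price,
                        }
                    )
                    tick += 1
        if max_move < config.price_tol:
            break
    log = pd.DataFrame(
        records, columns=["tick", "trader_id", "study_id", "shares", "tokens", "price"]
    )
    prices = pd.Series({sid: states[sid].price for sid in study_ids}, name="final_price")
    if return_ledgers:
        return log, prices, ledgers
    return log, prices
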