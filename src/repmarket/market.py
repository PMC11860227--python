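"""Logarithmic market scoring rule (LMSR) decision market.

An automated market maker quotes, for each study, the probability that
its replication will succeed.  With net sales s and liquidity b the
instantaneous price is the logistic p = e^{s/b} / (e^{s/b} + 1); the
token cost of a finite trade is the difference of the cost function
C(s) = b * ln(1 + e^{s/b}), so costs are path independent and the
market maker's worst-case loss per asset is b * ln 2.

The decision rule replicates the k_top highest-priced and k_bottom
lowest-priced studies plus n_random studies drawn from the middle.
Settlement pays one token per correct share in the deterministic tiers
and (middle-set size / n_random) tokens per correct share in the random
tier, which makes the ex-ante expected payout per correct share equal
across tiers and keeps truthful trading optimal.

Short positions are collateralized at the one-token face value: opening
a short share costs (1 - price) tokens, and a correct short (the study
fails to replicate) pays the tier payout, mirroring long positions on
the complementary outcome.  Budgets can therefore never go negative and
no separate margin rule is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "MarketState",
    "TokenLedger",
    "SelectionOutcome",
    "lmsr_price",
    "lmsr_cost",
    "trade_cost",
    "buy_with_tokens",
    "trade_to_belief",
    "select_studies",
    "settle_market",
]

_PRICE_EPS = 1e-12


def lmsr_price(s: float, b: float) -> float:
    """Instantaneous LMSR price e^{s/b} / (e^{s/b} + 1).

    Strictly inside (0, 1): the logistic saturates smoothly and is
    clipped away from the exact endpoints for extreme positions.
    """
    if b <= 0:
        raise ValueError("liquidity parameter b must be positive")
    return float(np.clip(expit(s / b), _PRICE_EPS, 1.0 - _PRICE_EPS))


def lmsr_cost(s: float, b: float) -> float:
    """LMSR cost function C(s) = b * ln(1 + e^{s/b})."""
    if b <= 0:
        raise ValueError("liquidity parameter b must be positive")
    return float(b * np.logaddexp(0.0, s / b))


def trade_cost(s_from: float, s_to: float, b: float) -> float:
    """Token cost of moving net sales from ``s_from`` to ``s_to``.

    Positive when buying (s increases); the derivative at s equals the
    instantaneous price, and the cost is additive over sub-trades.
    """
    return lmsr_cost(s_to, b) - lmsr_cost(s_from, b)


def _position_for_cost(s: float, tokens: float, b: float) -> float:
    """Net sales s' with ``trade_cost(s, s', b) == tokens`` (closed form).

    Inverts C: e^{s'/b} = e^{(C(s)+tokens)/b} - 1.
    """
    x = (lmsr_cost(s, b) + tokens) / b
    if x > 30.0:  # expm1 overflow region; log(e^x - 1) == x to double precision
        return b * x
    if x <= 0:
        raise ValueError("cost target below the market maker's minimum")
    return float(b * np.log(np.expm1(x)))


@dataclass(frozen=True)
class MarketState:
    """Per-asset market-maker state: net sales, liquidity, price path."""

    b: float
    s: float = 0.0
    price_history: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("liquidity parameter b must be positive")

    @property
    def price(self) -> float:
        return lmsr_price(self.s, self.b)


@dataclass
class TokenLedger:
    """One trader's token balance and per-asset holdings (negative = short)."""

    endowment: float = 100.0
    balance: Optional[float] = None
    holdings: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.balance is None:
            self.balance = self.endowment

    def position(self, asset_id: str) -> float:
        return self.holdings.get(asset_id, 0.0)


def buy_with_tokens(state: MarketState, tokens: float) -> Tuple[float, MarketState]:
    """Spend ``tokens`` buying shares; returns ``(shares, new_state)``.

    The new position solves trade_cost(s, s', b) = tokens exactly via
    the closed-form inverse of the cost function.  Selling is the
    inverse operation (negative share change returns tokens) and is
    exposed through :func:`trade_to_belief`.
    """
    if tokens < 0:
        raise ValueError("token amount must be non-negative")
    if tokens == 0:
        return 0.0, state
    s_new = _position_for_cost(state.s, tokens, state.b)
    new_state = replace(
        state, s=s_new, price_history=state.price_history + (lmsr_price(s_new, state.b),)
    )
    return s_new - state.s, new_state


def _trader_spend(delta: float, s: float, b: float, h: float, face: float) -> float:
    """Tokens the trader pays for a share change ``delta`` from holdings ``h``.

    LMSR cost plus collateral posted on (released from) the short side.
    """
    short_before = max(-h, 0.0)
    short_after = max(-(h + delta), 0.0)
    return trade_cost(s, s + delta, b) + face * (short_after - short_before)


def trade_to_belief(
    state: MarketState,
    belief: float,
    ledger: TokenLedger,
    asset_id: str = "asset",
    face: float = 1.0,
) -> Tuple[MarketState, TokenLedger]:
    """Trade toward ``belief`` until the price matches it or the budget binds.

    A risk-neutral trader maximizing expected settlement tokens buys
    while price < belief and shorts while price > belief; the optimal
    stopping point is price = belief.  The trader's balance covers the
    LMSR cost of longs and the (1 - price) collateral of shorts, so the
    constraint set is exactly balance >= 0.
    """
    if not (0.0 < belief < 1.0):
        raise ValueError("belief must lie strictly inside (0, 1)")
    s, b = state.s, state.b
    h = ledger.position(asset_id)
    target = b * float(logit(belief))
    delta_target = target - s
    if delta_target == 0.0:
        return state, ledger

    spend_full = _trader_spend(delta_target, s, b, h, face)
    if spend_full <= ledger.balance:
        delta = delta_target
        spend = spend_full
    else:
        # budget binds in the monotone-increasing region of the spend curve
        if delta_target > 0:
            lo = max(0.0, -h)
        else:
            lo = min(0.0, -h)
        f = lambda d: _trader_spend(d, s, b, h, face) - ledger.balance
        if f(lo) >= 0:
            delta = lo
        else:
            lo_, hi_ = sorted((lo, delta_target))
            delta = optimize.brentq(f, lo_, hi_, xtol=1e-12)
        spend = _trader_spend(delta, s, b, h, face)
    if delta == 0.0:
        return state, ledger

    new_state = replace(
        state,
        s=s + delta,
        price_history=state.price_history + (lmsr_price(s + delta, b),),
    )
    ledger.balance -= spend
    ledger.holdings[asset_id] = h + delta
    return new_state, ledger


@dataclass(frozen=True)
class SelectionOutcome:
    """Studies chosen for replication and the per-tier payout per share."""

    top_ids: Tuple[str, ...]
    bottom_ids: Tuple[str, ...]
    random_ids: Tuple[str, ...]
    unselected_ids: Tuple[str, ...]
    payout_per_share: Mapping[str, float]

    def tier_of(self, study_id: str) -> str:
        if study_id in self.top_ids:
            return "top"
        if study_id in self.bottom_ids:
            return "bottom"
        if study_id in self.random_ids:
            return "random"
        return "unselected"

    @property
    def selected_ids(self) -> Tuple[str, ...]:
        return self.top_ids + self.bottom_ids + self.random_ids


def select_studies(
    final_prices: Mapping[str, float],
    k_top: int = 12,
    k_bottom: int = 12,
    n_random: int = 2,
    seed: Union[int, np.random.Generator, None] = None,
) -> SelectionOutcome:
    """Apply the top/bottom/random decision rule to the final prices.

    Ties at tier boundaries break by price and then lexicographic study
    id, so the outcome is deterministic given prices and seed.  The
    random tier is drawn uniformly without replacement from the studies
    in neither extreme tier; its payout per share is scaled to (middle
    size / n_random) times the deterministic tiers' one token, making
    the ex-ante expected payout per correct share identical across
    tiers.
    """
    ids = sorted(final_prices)
    need = k_top + k_bottom + n_random
    if len(ids) < need:
        raise ValueError(f"need at least {need} studies, got {len(ids)}")

    by_price_desc = sorted(ids, key=lambda i: (-final_prices[i], i))
    top = tuple(by_price_desc[:k_top])
    rest = [i for i in ids if i not in top]
    by_price_asc = sorted(rest, key=lambda i: (final_prices[i], i))
    bottom = tuple(by_price_asc[:k_bottom])
    middle = sorted(i for i in rest if i not in bottom)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    random_ids = tuple(sorted(rng.choice(middle, size=n_random, replace=False).tolist()))
    unselected = tuple(i for i in middle if i not in random_ids)

    scaled = len(middle) / n_random
    return SelectionOutcome(
        top_ids=top,
        bottom_ids=bottom,
        random_ids=random_ids,
        unselected_ids=unselected,
        payout_per_share={"top": 1.0, "bottom": 1.0, "random": scaled, "unselected": 0.0},
    )


def settle_market(
    ledgers: Mapping[str, TokenLedger],
    selection: SelectionOutcome,
    outcomes: Mapping[str, bool],
) -> Dict[str, float]:
    """Settle all positions; returns tokens paid out per trader.

    A long share is correct if the study replicated; a short share is
    correct if it failed.  Correct shares pay the tier payout;
    unselected holdings pay nothing.
    """
    missing = [i for i in selection.selected_ids if i not in outcomes]
    if missing:
        raise ValueError(f"missing replication outcome for selected studies: {missing}")

    payouts: Dict[str, float] = {}
    for trader, ledger in ledgers.items():
        total = 0.0
        for asset_id, h in ledger.holdings.items():
            if h == 0.0:
                continue
            tier = selection.tier_of(asset_id)
            rate = selection.payout_per_share[tier]
            if rate == 0.0:
                continue
            success = outcomes[asset_id]
            if h > 0 and success:
                total += rate * h
            elif h < 0 and not success:
                total += rate * (-h)
        payouts[trader] = total
    return payouts
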