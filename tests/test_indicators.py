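"""Replication indicator battery: verdicts, Bayes factors, meta-analysis,
prediction intervals, with independent numerical oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize
from scipy.stats import norm, t as t_dist

from conftest import make_pair, two_sample_summary
from repmarket.indicators import (
    IndicatorError,
    d33,
    default_bf_plus0,
    fixed_effect_meta,
    indicator_battery,
    jeffreys_category,
    prediction_interval,
    replication_bf_r0,
    significance_criterion,
    small_telescope,
    _likelihood,
)


# ---------------------------------------------------------------------------
# significance criterion


class TestSignificance:
    def test_significant_same_direction(self):
        assert significance_criterion(make_pair(t_r=3.0, same_direction=True))

    def test_direction_clause(self):
        assert not significance_criterion(make_pair(t_r=3.0, same_direction=False))

    def test_nonsignificant(self):
        assert not significance_criterion(make_pair(t_r=1.0, same_direction=True))


# ---------------------------------------------------------------------------
# small telescopes


class TestSmallTelescope:
    def test_d33_against_normal_oracle(self):
        """d33 for a 50-per-group design near the normal-approximation root."""
        # oracle: lambda solving Phi(lam-1.96)+Phi(-lam-1.96)=1/3, then /sqrt(n/2)
        lam = optimize.brentq(
            lambda l: norm.cdf(l - 1.959964) + norm.cdf(-l - 1.959964) - 1 / 3, 0, 10
        )
        oracle = lam * math.sqrt(2 / 50)
        got = d33(two_sample_summary(n=50))
        assert got == pytest.approx(oracle, abs=0.01)  # noncentral-t refinement
        assert got == pytest.approx(0.3087, abs=5e-4)  # frozen noncentral value

    def test_d33_power_is_one_third(self):
        from repmarket.indicators import _two_sided_power, _ncp_multiplier

        orig = two_sample_summary(n=50)
        val = d33(orig)
        p = _two_sided_power(val, orig.family, _ncp_multiplier(orig), orig.df, 0.05)
        assert p == pytest.approx(1 / 3, abs=1e-8)

    def test_pass_when_ci_above_small_effect(self):
        # replication CI well above any plausible d33
        pair = make_pair(t_o=3.0, n_o=50, t_r=12.0, n_r=350)
        d_small, ok = small_telescope(pair)
        assert ok

    def test_fail_when_ci_below_small_effect(self):
        pair = make_pair(t_o=3.0, n_o=50, t_r=0.0, n_r=2000)
        d_small, ok = small_telescope(pair)
        lo, hi = pair.d_replication.d, pair.d_replication.d  # centred at 0
        assert not ok
        assert d_small > 0


# ---------------------------------------------------------------------------
# Bayes factors


def bf_plus0_oracle(rep):
    """Independent quadrature: substitute u = CDF of the half-Cauchy prior.

    delta = 0.707 * tan(pi u / 2) maps (0,1) to (0,inf) and makes the
    prior density drop out, so BF = int_0^1 L(delta(u)) du / L(0).
    """
    lik, l0, _ = _likelihood(rep)
    u = np.linspace(1e-9, 1 - 1e-9, 20001)
    delta = 0.707 * np.tan(math.pi * u / 2.0)
    vals = lik(delta)
    return integrate.simpson(vals, x=u) / l0


class TestDefaultBF:
    def test_null_statistic_supports_null(self):
        rep = two_sample_summary(role="replication", t=0.0, n=100, same_direction=True)
        bf = default_bf_plus0(rep)
        assert bf < 1

    def test_frozen_regression_value(self):
        """Oracle-computed BF for t = 0, n = 100 per group."""
        rep = two_sample_summary(role="replication", t=0.0, n=100, same_direction=True)
        assert default_bf_plus0(rep) == pytest.approx(0.15386, abs=2e-4)

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.5, 4.0])
    def test_matches_independent_quadrature(self, t):
        rep = two_sample_summary(role="replication", t=t, n=100, same_direction=True)
        assert default_bf_plus0(rep) == pytest.approx(bf_plus0_oracle(rep), rel=1e-4)

    def test_monotone_in_statistic(self):
        bfs = [
            default_bf_plus0(
                two_sample_summary(role="replication", t=t, n=100, same_direction=True)
            )
            for t in (0.0, 1.0, 2.0, 3.0, 4.0, 6.0)
        ]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))
        assert bfs[-1] > 10

    def test_opposite_direction_shrinks_evidence(self):
        same = two_sample_summary(role="replication", t=2.0, n=100, same_direction=True)
        opp = two_sample_summary(role="replication", t=2.0, n=100, same_direction=False)
        assert default_bf_plus0(opp) < default_bf_plus0(same)


def bf_r0_oracle(pair, n_u=8001):
    """Two-stage nested quadrature in the prior-CDF variable.

    Posterior given the original is prior x likelihood normalized; in
    the u variable both integrals are over (0,1) with the prior flat.
    """
    lik_o, _, _ = _likelihood(pair.original)
    lik_r, l0_r, _ = _likelihood(pair.replication)
    u = np.linspace(1e-9, 1 - 1e-9, n_u)
    delta = 0.707 * np.tan(math.pi * u / 2.0)
    w = lik_o(delta)
    num = integrate.simpson(w * lik_r(delta), x=u)
    den = integrate.simpson(w, x=u)
    return (num / den) / l0_r


class TestReplicationBF:
    def test_null_replication_after_strong_original(self):
        pair = make_pair(t_o=4.0, n_o=100, t_r=0.0, n_r=350)
        assert replication_bf_r0(pair) < 1

    def test_confirming_replication_adds_evidence(self):
        pair = make_pair(t_o=3.0, n_o=100, t_r=5.0, n_r=350)
        assert replication_bf_r0(pair) > 1

    @pytest.mark.parametrize(
        "t_o,n_o,t_r,n_r,same",
        [
            (2.5, 60, 1.0, 200, True),
            (3.5, 120, 3.0, 400, True),
            (2.1, 40, 0.5, 150, False),
            (4.0, 200, 2.0, 700, True),
            (2.8, 80, 2.8, 80, True),
        ],
    )
    def test_matches_nested_quadrature_oracle(self, t_o, n_o, t_r, n_r, same):
        pair = make_pair(t_o=t_o, n_o=n_o, t_r=t_r, n_r=n_r, same_direction=same)
        assert replication_bf_r0(pair) == pytest.approx(bf_r0_oracle(pair), rel=2e-3)

    def test_grid_refinement_stable(self):
        pair = make_pair(t_o=3.0, n_o=100, t_r=2.0, n_r=350)
        a = replication_bf_r0(pair, n_grid=4097)
        b = replication_bf_r0(pair, n_grid=8193)
        assert abs(a - b) < 1e-4


class TestJeffreys:
    @pytest.mark.parametrize(
        "bf,expect",
        [
            (15.0, "strong evidence for H1"),
            (0.05, "strong evidence for H0"),
            (1.0, "no evidence"),
            (200.0, "extreme evidence for H1"),
            (1 / 200, "extreme evidence for H0"),
            (2.0, "anecdotal evidence for H1"),
            (0.5, "anecdotal evidence for H0"),
        ],
    )
    def test_ladder(self, bf, expect):
        assert jeffreys_category(bf) == expect

    def test_invalid(self):
        with pytest.raises(ValueError):
            jeffreys_category(0.0)


# ---------------------------------------------------------------------------
# meta-analysis and prediction interval


class TestMeta:
    def test_equal_weights_average(self):
        pair = make_pair(t_o=2.0, n_o=100, t_r=2.0, n_r=100)
        meta_d, meta_se, _, _, _ = fixed_effect_meta(pair)
        avg = (pair.d_original.d + pair.d_replication.d) / 2
        assert meta_d == pytest.approx(avg, rel=1e-6)

    def test_against_gls_oracle(self, rng):
        """Inverse-variance pooling equals generalized least squares."""
        for _ in range(20):
            t_o = rng.uniform(2.0, 5.0)
            t_r = rng.uniform(-1.0, 5.0)
            n_o = int(rng.integers(20, 300))
            n_r = int(rng.integers(20, 900))
            pair = make_pair(t_o=t_o, n_o=n_o, t_r=t_r, n_r=n_r,
                             same_direction=bool(t_r >= 0))
            meta_d, meta_se, _, _, _ = fixed_effect_meta(pair)
            y = np.array([pair.d_original.d, pair.d_replication.d])
            sig = np.diag([pair.d_original.se**2, pair.d_replication.se**2])
            x = np.ones((2, 1))
            w = np.linalg.inv(sig)
            cov = np.linalg.inv(x.T @ w @ x)
            beta = cov @ x.T @ w @ y
            assert meta_d == pytest.approx(float(beta[0]), abs=1e-12)
            assert meta_se == pytest.approx(float(np.sqrt(cov[0, 0])), abs=1e-12)

    def test_significance_ordering(self):
        pair = make_pair(t_o=5.0, n_o=100, t_r=5.0, n_r=350)
        *_, sig05, sig005 = fixed_effect_meta(pair)
        assert sig05 and sig005


class TestPredictionInterval:
    def test_identical_replication_passes(self):
        pair = make_pair(t_o=3.0, n_o=100, t_r=3.0 * math.sqrt(3.5), n_r=350)
        # choose t_r so that d_R == d_O exactly: d = t*sqrt(2/n)
        t_r = pair.d_original.d / math.sqrt(2 / 350)
        pair = make_pair(t_o=3.0, n_o=100, t_r=t_r, n_r=350)
        lo, hi, z, p, ok = prediction_interval(pair)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert ok

    def test_pass_iff_p_above_alpha(self, rng):
        """Interval membership is equivalent to the z-test at 1 - level."""
        for _ in range(1000):
            t_o = rng.uniform(2.0, 6.0)
            t_r = rng.uniform(-3.0, 6.0)
            pair = make_pair(
                t_o=t_o, n_o=int(rng.integers(20, 200)),
                t_r=t_r, n_r=int(rng.integers(20, 600)),
                same_direction=bool(t_r >= 0),
            )
            lo, hi, z, p, ok = prediction_interval(pair)
            assert ok == (p >= 0.05 - 1e-12)


# ---------------------------------------------------------------------------
# battery


class TestBattery:
    def test_null_pair_verdicts(self):
        pair = make_pair(t_o=3.0, n_o=100, t_r=0.0, n_r=350)
        rep = indicator_battery(pair)
        assert not rep.sig_replicated
        assert rep.bf_plus0 < 1
        assert rep.bf_r0 < 1

    def test_strong_pair_verdicts(self):
        pair = make_pair(t_o=4.0, n_o=100, t_r=8.0, n_r=350)
        rep = indicator_battery(pair)
        assert rep.sig_replicated
        assert rep.small_telescope_pass
        assert rep.meta_sig_05 and rep.meta_sig_005
        assert rep.bf_plus0 > 1

    def test_invariants_on_random_pairs(self, rng):
        for _ in range(30):
            t_o = rng.uniform(2.0, 5.0)
            t_r = rng.uniform(0.0, 6.0)
            same = bool(rng.random() < 0.8)
            pair = make_pair(
                t_o=t_o, n_o=int(rng.integers(20, 200)),
                t_r=t_r, n_r=int(rng.integers(20, 600)), same_direction=same,
            )
            rep = indicator_battery(pair)
            assert rep.bf_plus0 > 0 and rep.bf_r0 > 0
            assert rep.pi_low < rep.pi_high
            assert rep.meta_sig_05 or not rep.meta_sig_005
            assert rep.pi_pass == (rep.p_diff >= 0.05 - 1e-12)

    def test_preregistered_indicators_agree_more_than_pi(self, rng):
        """Significance, small-telescopes, BF and meta verdicts rank-correlate
        strongly with each other and less with the prediction interval."""
        from repmarket.evaluation import kendall_tau_b

        cols = {k: [] for k in ("sig", "st", "bf", "meta", "pi")}
        for _ in range(60):
            t_o = rng.uniform(2.0, 4.5)
            t_r = rng.uniform(-1.0, 5.0)
            pair = make_pair(
                t_o=t_o, n_o=int(rng.integers(30, 200)),
                t_r=abs(t_r), n_r=int(rng.integers(60, 600)),
                same_direction=bool(t_r >= 0),
            )
            rep = indicator_battery(pair)
            cols["sig"].append(rep.sig_replicated)
            cols["st"].append(rep.small_telescope_pass)
            cols["bf"].append(rep.bf_plus0 > 1)
            cols["meta"].append(rep.meta_sig_05)
            cols["pi"].append(rep.pi_pass)
        tau_prereg = kendall_tau_b(cols["sig"], cols["bf"])
        tau_pi = kendall_tau_b(cols["sig"], cols["pi"])
        assert tau_prereg > tau_pi
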