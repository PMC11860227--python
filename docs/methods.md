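# Methods

This note documents the models, numerical choices and design decisions
behind the package, and what the synthetic-data generator does and does
not emulate.

## Effect-size standardization

All inferential results are reduced to Cohen's *d*.  For a balanced or
unbalanced two-sample t statistic, d = t·√(1/n₁ + 1/n₂); for a one-sample
or paired t, d = t/√n; a z statistic uses the same design multiplier as
the corresponding t; a χ² with 1 df is treated as z = √χ², and an F with 1
numerator df as t = √F, with the replication's direction flag restoring the
lost sign.  Standard errors use the large-sample expressions
√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))) (two-group) and √(1/n + d²/(2n))
(one-group).  Designs that do not reduce to these families (multi-df F,
interaction contrasts) are rejected rather than approximated.

Under the orientation convention the original effect is always positive
and the replication effect keeps a positive sign only when it points in
the original's direction; relative effect sizes d_R/d_O can therefore be
negative.

Confidence intervals on *d* use the normal approximation d ± z·se rather
than noncentral-t inversion.  In the regime this package targets the
replication samples are large (hundreds per group), where the two
constructions agree to the third decimal; a Monte-Carlo coverage test in
the suite bounds the approximation error.  Hedges' small-sample correction
is deliberately out of scope for the same reason.

## Replication indicators

**Significance criterion.**  Two-sided p < 0.05 (strict inequality) *and*
an effect in the original's direction.  On true nulls this fires at α/2,
not α, because the direction clause discards one rejection region.

**Small telescopes.**  d33 solves power(d; original design, two-sided
α = 0.05) = 1/3 by bisection on [10⁻⁶, 10] (power tolerance 10⁻⁸), using
the noncentral-t for t-based designs and the normal for z-based designs.
A replication fails if the upper bound of its 90% normal CI falls below
d33 — the one-sided 5% test expressed through the interval.

**Bayes factors.**  BF₊₀ is the marginal likelihood of the replication
statistic under a Cauchy(0, 0.707) prior on δ truncated to δ > 0 (the
original's direction), divided by the likelihood at δ = 0.  The likelihood
is the exact noncentral-t density when df is available and a normal
density on the z scale otherwise.  The integral is evaluated by adaptive
quadrature (relative tolerance 10⁻⁶) over a finite interval that provably
contains all numerically representable mass, with break points at the
likelihood bump; non-convergence raises an error rather than falling back
silently.  BF_R0 replaces the prior with the posterior of δ given the
original data, obtained by normalizing prior × original likelihood on a
uniform grid spanning at least ten prior scales (4097 points; doubling the
grid changes BF_R0 by < 10⁻⁴, which the suite asserts).  Both are checked
against independent quadrature oracles that integrate in the prior-CDF
variable, a substitution that removes the prior density from the integrand
entirely.

scipy's noncentral-t density (boost) overflows when the noncentrality is
far from the observation or df is large.  The package substitutes a
log-space evaluation of the scale-mixture representation
E_W[φ(x√W − δm)·√W], W ~ χ²_df/df, on a 1201-point Gamma-quantile grid,
used only where the exact routine fails; in the overlap region the two
agree to ~10⁻⁵ relative for df ≥ 20.

**Meta-analysis.**  Fixed-effect inverse-variance pooling of the pair,
with a two-sided z-test and flags at 0.05 and 0.005.  Random-effects
pooling is meaningless for two studies and is out of scope.

**Prediction interval.**  d_O ± z·√(se_O² + se_R²) at level 0.95; passing
the interval is algebraically equivalent to the two-sample z-test of a
difference being non-significant at 1 − level, which the suite checks by
enumeration on random pairs.

**Jeffreys categories** use the symmetric ladder at 1/100, 1/30, 1/10,
1/3, 1, 3, 10, 30, 100; a Bayes factor of exactly 1 is labelled "no
evidence".

## Power planning

The replication sample size is the smallest per-group n whose two-sided
test at α = 0.05 has ≥ 90% power against ⅔·d_O, computed on the
noncentral-t (normal for z designs) with a normal-approximation warm start
and exact integer search, then floored at the original sample size.
Two-group designs assume balanced allocation; how unbalanced or
within-subject originals should be powered (the repeated-measures
correlation) is left to the caller, who can pass a one-group design
instead.

## Decision market

The LMSR cost function C(s) = b·ln(1 + e^{s/b}) is evaluated with
`logaddexp`; prices are the logistic of s/b, clipped away from exactly 0
and 1.  Buying with a fixed token budget inverts C in closed form
(s' = b·ln(e^{(C(s)+tokens)/b} − 1), switching to the asymptotic identity
above the overflow point), so the stated 10⁻¹⁰-token tolerance is met
exactly.  Cost additivity (path independence) and the b·ln 2 worst-case
maker loss per asset are asserted property-style in the suite.

**Short positions** are collateralized at the one-token face value: going
short one share costs (1 − price) tokens, and a correct short (the study
fails) pays the tier payout at settlement, exactly mirroring a long
position on the complementary outcome.  This makes the budget constraint
simply balance ≥ 0 — no separate margin rule, and worst-case settlement
liability is prepaid by construction.  A trader moving the price to their
belief therefore maximizes expected settled tokens whether long or short,
which the suite verifies by grid optimization.

**Selection** takes the k_top highest and k_bottom lowest final prices
with ties broken by price then lexicographic study id (the mechanism must
be deterministic given prices and seed), then draws n_random studies
uniformly from the middle.  The random tier pays (middle size /
n_random) per correct share, so the ex-ante expected payout per correct
share equals the deterministic tiers' one token for every configuration —
asserted exactly, not numerically.

**Trading protocol.**  A live platform is asynchronous; the simulator
instead lets traders act in seeded random order, one asset at a time, in
repeated passes until no price moves by more than 10⁻⁴ (or a pass cap is
hit).  Budgets bind, so final prices are a budget-constrained equilibrium
rather than exact belief averages.

## Evaluation statistics

Clopper–Pearson intervals come from beta quantiles (exact tail
inversion).  Fisher's two-sided p uses the probability-mass criterion (sum
of conditionally no-more-probable tables).  Boschloo's unconditional test
fixes the row totals, orders tables by their Fisher p (one-sided Fisher p
for the one-sided test; probability-mass two-sided Fisher p for the
two-sided test) and takes the supremum of the binomial-product tail over a
1000-point grid in the nuisance success probability; several two-sided
conventions exist, and this one — rather than doubling the one-sided p —
is the package's default because it is the direct unconditional analogue
of the two-sided Fisher test it sharpens.  The Wilcoxon signed-rank test
drops zero differences, midranks ties, applies the tie-corrected normal
variance and no continuity correction.  Correlation CIs (Pearson and
point-biserial) use the Fisher z-transform.  Kendall's τ_b and the
remaining standard statistics are delegated to scipy, with brute-force
enumeration oracles in the suite.

## Synthetic-data generator

The generator emulates the *structure* of a decision-market replication
study, not any particular set of findings:

- **Study pool** (default 41): balanced two-sample designs with per-group
  sizes lognormal around a mean of 146 (mean total ≈ 292, shape 0.5,
  floor 20).  True effects are 0 with probability 0.5 and half-normal
  (scale 0.5, so mean ≈ 0.4 s.d.) otherwise — a mixture chosen to put the
  end-to-end replication rate in the neighbourhood of one half.
- **Publication filter**: each original result is resampled until
  p < 0.05 (rejection sampling, capped at 10⁵ draws).  Conditioning on
  significance inflates observed effects — severely for nulls, mildly for
  genuine effects — which is exactly the mechanism behind published
  effect-size inflation.  The observed direction defines the pair's
  "positive" direction.
- **Replication sizing** uses the power rule above on the *observed*
  (inflated) original d, reproducing the several-fold scale-up of
  replication samples.
- **Latent replication probability** is computed analytically from the
  true effect, the planned replication size and α via the noncentral-t
  tail, not by nested simulation.
- **Forecasters** (default 162) observe a fraction (0.2) of the latent
  success log-odds — partial information that shrinks beliefs toward
  indifference — plus a shared per-study misperception (s.d. 1.5) and an
  idiosyncratic term (s.d. 2.0) on the log-odds scale, clipped to
  (0.01, 0.99).  These three defaults were calibrated once so that the
  simulated market reproduces the forecast-informativeness regime of real
  replication markets: mean beliefs spanning roughly 0.1–0.9, a
  point-biserial correlation with outcomes around 0.5, and a Brier score
  around 0.19.  With attenuation 1 and zero noise the mean belief equals
  the latent probability exactly, which anchors the construction.

What the generator does **not** emulate: heterogeneous test families (all
synthetic originals are two-sample t), unbalanced or within-subject
designs, questionable research practices beyond the significance filter,
correlated forecaster expertise, strategic or manipulative trading, and
time-varying true effects.  Passing tests therefore show that the
mechanism and the indicator battery behave correctly under a clean,
calibrated sampling model — not that real studies satisfy that model.

## Problem sizes and determinism

The default experiment (41 studies, 162 forecasters, ≈ 1000 trades,
26 replications with full indicator batteries) runs in a few seconds; the
test suite uses this size directly and pools several seeds where a
property is statistical, with Monte-Carlo tolerances stated as multiples
of the binomial standard error.  One global seed is expanded into
per-stage substreams (population, forecasters, trading, random tier,
replications) so stages can be rerun in isolation; every stochastic
entry point requires an explicit seed, and reruns are bit-identical.
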