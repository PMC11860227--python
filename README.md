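# repmarket

Decision-market study selection and replication assessment, as a tested,
reusable Python pipeline.

## The problem

Large-scale replication projects are expensive, so which published findings
should be replicated first?  One principled mechanism is a **decision
market**: forecasters trade on the probability that each candidate finding
will replicate, and the final market prices themselves determine which
studies are put to the test (for example the 12 highest- and 12
lowest-priced studies out of a pool of 41, plus 2 drawn at random from the
middle so that every study retains a strictly positive selection
probability — the ingredient that keeps truthful trading optimal).

Once the chosen replications are run, "did it replicate?" has no single
answer.  This package computes the full battery of indicators used in
systematic replication projects, on a common Cohen's *d* scale, together
with the statistics needed to evaluate the forecasts themselves.

## What is implemented

**Market mechanism.**  A logarithmic market scoring rule (LMSR) automated
market maker with cost function C(s) = b·ln(1 + e^{s/b}), instantaneous
price p = e^{s/b}/(e^{s/b} + 1), liquidity b = 100 and 100-token trader
endowments.  Budget-constrained trading toward a belief, the
top-12/bottom-12/random-2 selection rule, and settlement paying 1 token per
correct share in the deterministic tiers and (middle-set size / number
drawn) = 17/2 = 8.5 tokens in the random tier, which equalizes the ex-ante
expected payout per correct share across tiers.

**Effect-size standardization.**  Conversion of t, z, 1-df χ² and
1-numerator-df F statistics to Cohen's *d* with standard errors, under the
sign convention that the original effect is always positive.

**Replication indicators**, per original/replication pair:

- *statistical significance*: two-sided p < 0.05 in the original's direction;
- *relative effect size*: d_R / d_O;
- *small telescopes*: is d_R significantly below d33, the effect the
  original design had 33% power to detect;
- *default Bayes factor* BF₊₀ with a Cauchy(0, 0.707) prior truncated to
  the original's direction, and the *replication Bayes factor* BF_R0 using
  the original study's posterior as the prior, both with Jeffreys evidence
  categories;
- *fixed-effect meta-analysis* of the pair with 0.05 and 0.005 thresholds;
- *95% prediction interval* d_O ± 1.96·√(se_O² + se_R²) and the two-sample
  z-test of a difference between the effects.

**Power planning.**  Replication sample sizes with 90% power to detect 2/3
of the original effect at the two-sided 5% level (noncentral-t), floored at
the original sample size.

**Evaluation statistics.**  Clopper–Pearson exact binomial intervals,
Fisher's exact test and Boschloo's exact unconditional test for tier
comparisons, point-biserial and Pearson correlations with Fisher-z
intervals, Kendall's τ_b, Brier and absolute forecast scores, and the
Wilcoxon signed-rank test for effect-size shrinkage.

**Synthetic data.**  A generator emulating the statistical structure of
such a study: 41 findings that are all significant at p < 0.05 (a
publication filter that inflates observed effects), a mixture of null and
genuine effects giving a replication rate near one half, replications a few
times larger than the originals, and 162 forecasters whose beliefs are
informative but noisy, so the whole mechanism can be exercised end to end
with no human data.

## Worked example

```python
from repmarket import GeneratorConfig, run_experiment

report = run_experiment(GeneratorConfig(), seed=2)
agg = report.aggregates
rate = agg["replication_rate"]
print(f"selected: {len(report.selection.selected_ids)} of {len(report.final_prices)} studies")
print(f"replication rate: {rate['k']}/{rate['n']} = {100*rate['rate']:.1f}% "
      f"(95% CI {100*rate['ci'][0]:.1f}%, {100*rate['ci'][1]:.1f}%)")
print(f"relative effect size (ratio of means): {100*agg['relative_es_ratio_of_means']:.1f}%")
print(f"point-biserial(prices, outcomes): r = {agg['point_biserial_market']['r']:.3f}")
print(f"market Brier score: {agg['market_scores']['mean_brier']:.3f}")
print(f"Fisher p (top vs bottom tier): {agg['fisher_p']:.3f}")
```

prints

```
selected: 26 of 41 studies
replication rate: 14/26 = 53.8% (95% CI 33.4%, 73.4%)
relative effect size (ratio of means): 67.6%
point-biserial(prices, outcomes): r = 0.727
market Brier score: 0.124
Fisher p (top vs bottom tier): 0.003
```

The 26 selected studies are the 12 top-priced, 12 bottom-priced and 2
random draws from the remaining 17.  The replication rate counts the pairs
passing the significance criterion, with its exact binomial interval; the
relative effect size is the mean replication *d* over the mean original
*d*; the point-biserial correlation measures how informative the final
market prices were about the outcomes; and the Fisher p compares the
top-tier and bottom-tier replication rates.  Results vary across seeds —
each run is one realization of a 26-replication experiment.

A command-line interface exposes the same pipeline stage by stage
(`repmarket simulate | market | select | indicators | evaluate | run`),
reading and writing delimited-text tables so any stage can be swapped for
real data — `repmarket indicators --studies table.csv --out ind.csv`
computes the full battery for user-supplied summary statistics.

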