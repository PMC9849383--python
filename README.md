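# perfpot

Potential estimation from longitudinal performance data on a lower-is-better
scale (race points, where the smaller the score, the better the result).

Coaches and federation staff face a recurring question: given a young
athlete's results so far, what is their *potential* — the curve their
performance is likely to follow with age, with honest uncertainty — and what
*type* of progression are they on? `perfpot` answers both from nothing more
than (individual, age, score) records:

1. **Hierarchical Bayesian curve fit.** The age-performance relationship is
   a sum of two exponential laws, U-shaped for minimized scores,

       p(t) = a·e^(−b·t) + c·e^(d·t),

   with an additive random part per individual around each fixed parameter:
   `p_i(t) = (a+a_i)e^{−(b+b_i)t} + (c+c_i)e^{(d+d_i)t}`. The posterior is
   drawn with a No-U-Turn sampler (4 chains × 200 retained draws by
   default), giving every individual 800 parameter quadruplets. The curve's
   peak has the closed form `t* = ln(ab/cd)/(b+d)`.
2. **Potential curves with estimate intervals.** The per-age median and
   quantile envelope of each individual's 800 curves, in raw years and
   points, plus peak age/score summaries (median ± half-interval). The
   envelope quantifies uncertainty about *potential*, not about single race
   results.
3. **Progression typologies and membership.** Individuals (represented by
   their median quadruplets) are clustered with Gaussian mixtures across the
   fourteen volume/shape/orientation covariance parameterizations; the model
   is selected by a slope-density overlap score (mean over ages 10–20 and
   cluster pairs of ∫min(f′_i, f′_j); lower = more distinct progression
   types). Each individual then gets mean membership probabilities with
   intervals, propagated through their posterior draws.

Training data are filtered to the best (minimum) score per individual per
age year, which neutralizes counter-performances, and standardized (scores
also shifted strictly positive) before fitting.

No real federation data ship with the package; a synthetic-cohort generator
with known ground truth (including a four-typology preset with highly
unequal cluster sizes) stands in for it everywhere, so every stage is
testable offline.

## Worked example

```python
import perfpot
from perfpot import SamplerConfig

# synthetic cohort of 80 skiers with four progression typologies
spec = perfpot.four_typology_preset(n_individuals=80, seed=1)
records, truth = perfpot.generate(spec)

# best result per age year, then standardize; here we reuse the generator's
# transform so fitted parameters are directly comparable to the truth
# (with real data you would call perfpot.fit_standardization(best))
best = perfpot.best_per_age(records)
std = truth.standardization
table = perfpot.standardize(best, std)

# hierarchical Bayesian fit (reduced draws for the example)
ens = perfpot.fit_hierarchical(table, config=SamplerConfig(chains=2, draws=100, warmup=200, seed=1))
print(perfpot.summarize_fixed(ens).round(4))
print("R2 hierarchical:", round(perfpot.r_squared(ens, table), 3))
print("R2 pooled OLS:  ", round(perfpot.r_squared(perfpot.ols_prefit(table), table), 3))

# population potential peak in raw units
pk = perfpot.peak_summary(ens.fixed, std)
print(f"peak age {pk['peak_age']:.2f} ± {pk['peak_age_half_interval']:.2f} years, "
      f"peak score {pk['peak_score']:.2f} ± {pk['peak_score_half_interval']:.2f} points")

# typologies and membership for one individual
med = perfpot.median_params(ens)
model, scores = perfpot.select_model(
    perfpot.fit_mixture_family(med, seed=1), med, std)
print("selected:", model.parameterization, "K =", model.n_components,
      "overlap =", round(model.overlap, 3))
prof = perfpot.profile(model, ens.individual_draws(ens.individual_ids[0]))
print("membership of", ens.individual_ids[0], prof.mean.round(2))
```

Output:

```
             Estimate  Est.Error    Q2.5   Q97.5
a_Intercept    0.5075     0.0153  0.4775  0.5397
b_Intercept    2.2535     0.0413  2.1672  2.3283
c_Intercept    0.8406     0.0113  0.8153  0.8597
d_Intercept    0.1895     0.0068  0.1743  0.2017
R2 hierarchical: 1.0
R2 pooled OLS:   0.691
peak age 21.21 ± 0.18 years, peak score 140.26 ± 0.98 points
selected: EII K = 4 overlap = 0.076
membership of ind0000 [1. 0. 0. 0.]
```

Read: the population fixed effects land close to the generative center
(a=0.5206, b=2.3245, c=0.8706, d=0.1826 — shifted slightly because a
quarter of the cohort comes from the minority typologies); the hierarchical
fit explains essentially all score variance while the pooled curve without
random effects explains about two thirds; the population peaks near age 21
at ~140 points on this synthetic scale; model selection recovers the four
generative typologies (cluster sizes 56/10/8/6 — one dominant average
cluster, three rare ones); and the first individual belongs to the dominant
cluster with near certainty.

The same pipeline is scriptable from the shell:

```
perfpot -v run-all --seed 1 --n-individuals 80 --out my_run
```

which writes every stage artifact (records, training table, posterior
draws, curves, cluster model, membership table) plus a JSON run report
under `my_run/`.

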