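# Methods

`perfpot` estimates the performance *potential* of individuals from
longitudinal score data on a lower-is-better scale (race points: the smaller
the score, the better the result). It has three stages: a Bayesian
hierarchical fit of a double-exponential age-performance curve, ensemble
summaries of the fitted curves (potential curves with estimate intervals and
peak summaries), and clustering of individual curve parameters into
progression typologies with probabilistic membership.

## The curve model

The population age-performance relationship is a sum of two exponential
laws — one for the progression phase, one for the decline phase — adjusted
for minimized scores so the curve is U-shaped:

    p(t) = a·e^(−b·t) + c·e^(d·t),        a, b, c, d > 0,

with `t` the standardized age. The interior minimum (the performance peak,
since lower is better) has the closed form

    t* = ln(a·b / (c·d)) / (b + d),

which we use exactly; a grid-search minimizer exists only as a test oracle.
The classical maximized-score orientation `a·(1−e^{−bt}) + c·(1−e^{dt})` is
also implemented; the two differ by an affine reflection and share `t*`.

Each individual *i* gets an additive random part around every fixed
parameter: `p_i(t) = (a+a_i)·e^{−(b+b_i)t} + (c+c_i)·e^{(d+d_i)t}`. All four
effective parameters must stay positive for the U shape to survive, so the
model is parameterized on the log scale: `log θ_ip ~ Normal(φ_p, σ_p²)`
independently per parameter, which enforces positivity for every retained
posterior draw by construction. The additive offsets reported downstream are
`θ_ip − exp(φ_p)`.

## Preprocessing

Raw data are long-format records (individual, decimal age, score). A single
atypically bad result — a counter-performance — should not define a season,
so the model trains on the best (minimum) score per individual per integer
age year (ties: first record wins). Ages outside [10, 25] years are dropped
by default (configurable). Scores are centered, reduced, and shifted by
`−min + 10⁻³` so all training values are strictly positive; ages are
centered and reduced. The transform is global (one spec per data set), kept
as a JSON sidecar, and strictly monotone, so "best per age" is preserved on
either scale.

## Bayesian fit

* **Likelihood**: Gaussian residuals on the standardized score scale.
* **Priors**: `φ_p ~ Normal(log(OLS prefit), 1.0)` where the prefit is a
  pooled nonlinear least-squares fit (log-scale parameters, multistart
  Levenberg–Marquardt); `σ_p` and the residual scale get half-Normal(1.0)
  priors. Random effects are independent across parameters (no
  cross-parameter covariance is modelled).
* **Sampler**: an in-package No-U-Turn Sampler — multinomial sampling over
  the doubling trajectory tree, dual-averaging step-size adaptation (target
  acceptance 0.9), diagonal metric estimated over expanding warmup windows,
  divergence flagged above an energy error of 1000, maximum tree depth 10.
  The log posterior and its analytic gradient are evaluated in a single
  fused pass over the records.
* **Parameterization**: mixed. The data identify each individual's `a`, `b`,
  `c` strongly (the decline term dominates young-age scores), so those use
  centered coordinates (`log θ_ip` sampled directly); the growth rate `d` is
  weakly identified per individual and its centered form develops a funnel
  in (φ_d, σ_d) — measured as a curvature blow-up near the mode — so `d`
  uses the non-centered offset coordinate. This combination was the only
  one of the three (all-centered, all-non-centered, mixed) with clean R-hat
  and calibrated credible intervals in recovery simulations.
* **Defaults**: 4 chains × 200 retained draws after 500 warmup iterations,
  so every individual ends with 800 parameter quadruplets. Warmup is
  separate from the retained count: adaptation draws are never retained.
  Runs are exactly reproducible from (data, config, seed); chains get
  independent seed streams spawned from the master seed.
* **Diagnostics**: split R-hat and effective sample size per fixed parameter
  (flagged above 1.05), divergence fraction (warned above 2%).

Goodness of fit is summarized by `R² = 1 − SS_res/SS_tot` on the training
table, computed both for the hierarchical fit (each record predicted from
its own individual's posterior-median quadruplet) and for the pooled
fixed-only least-squares curve. On heterogeneous cohorts the hierarchical
R² exceeds the pooled R² — the population curve cannot capture individual
level differences. The adjusted variant penalizes by the number of fitted
parameters (4 per curve by default).

## Potential curves and peaks

Every retained quadruplet defines one curve; evaluating the ensemble on a
0.1-year age grid and destandardizing gives raw-unit curves. The potential
curve is the per-age median with a quantile envelope — central 95%
(0.025, 0.975) for the population, central 90% (0.05, 0.95) for individual
curves by default, both configurable. The envelope is an *estimate
interval*: uncertainty about the potential curve itself, not a prediction
interval for single results. Peaks are computed draw-wise via the closed
form and summarized as median ± half-width of the central 95% interval
(posterior-SD reporting is selectable). Draws without an interior peak are
excluded and counted; more than half excluded is an error.

## Clustering into progression typologies

Individuals are represented by the component-wise median of their retained
quadruplets and clustered with finite Gaussian mixtures fitted by EM
(k-means++ initialization, 10 restarts, relative tolerance 10⁻⁸, at most
500 iterations, 10⁻⁶ diagonal covariance regularization). The covariance
family is the full volume/shape/orientation decomposition
`Σ_k = λ_k D_k A_k D_kᵀ` — fourteen parameterizations from spherical-equal
(EII) to fully variable (VVV). Constrained M-steps follow the standard
closed forms; the two shared-orientation models (EVE, VVE) use a
majorize-minimize update for the common orientation (each step an
orthogonal Procrustes solve, so the EM objective still ascends; a few
alternations per M-step suffice — a generalized EM).

**Model selection.** Progression is about *slopes*, so candidate mixtures
are compared by a slope-density overlap score: for each raw scoring age
t ∈ {10, …, 20} and each cluster pair (i < j), the overlap coefficient
∫ min(f′_i, f′_j) of Gaussian kernel densities of the members' curve
derivatives at t (derivatives in raw points per year, chain rule through
the age standardization; Silverman bandwidth with a floor of 10⁻⁶ of the
slope scale; trapezoid integration on a grid extending 5 bandwidths past
the pooled support). The score is the mean over all (age, pair) terms —
dividing by the term count `11·K(K−1)/2` rather than a bare constant keeps
scores in [0, 1] and comparable across different K. Lower is better:
distinct typologies progress differently.

The number of clusters is fixed once by BIC across all candidates
(BIC is reported for information throughout), and the overlap score then
selects *between* the fourteen parameterizations at that K; ties break
toward fewer free parameters, then smaller K. A raw argmin of the overlap
score across K was rejected as degenerate in both directions: merging two
slope-similar clusters lowers the mean pairwise overlap, and so does
splitting a continuum (the two halves of one Gaussian have nearly disjoint
slope densities) — in simulation the raw argmin drifted to K=3 or K=8 on a
four-typology cohort depending on sample size. The same drift appears if
each parameterization brings its *own* BIC-best K: a misspecified
spherical model fragments the data into many slope-separated shards and
wins. With one likelihood-determined K, the slope-separation score does
what it is for — arbitrating covariance geometry.

Candidates whose EM collapses (vanishing weight, singular covariance) or
that produce clusters with fewer than two members are discarded with a log
entry. Unequal cluster sizes are expected and preserved.

## Membership with uncertainty

For each individual, every retained quadruplet is pushed through the
selected mixture's posterior component probabilities; the mean over draws
is the membership profile (a simplex), and per-cluster central quantile
intervals (default 95%) propagate curve-fit uncertainty into the typology
assignment. Relabeling mixture components permutes profiles exactly; as
the draw spread shrinks to zero the profile collapses to the
responsibilities of the median quadruplet.

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes, with known
ground truth. Individual log-quadruplets are drawn around a population
center (default: the documented population estimate a=0.5206, b=2.3245,
c=0.8706, d=0.1826 on the standardized scale) with per-parameter log-scale
random-effect SDs (default 0.1), or from a mixture of typology components.
Each individual is observed at every integer age in [10, 25], several
results per age (default 3), as curve value + Gaussian residual (default
SD 0.1, standardized scale) + one-sided counter-performance noise: with
probability 0.3 an exponential worse-score shift (scale 0.5). Exponential
variates are always drawn so the noise stream is identical across
counter-performance settings at a fixed seed. Scores are destandardized
with a fixed plausible transform (age 17.5 ± 4.6 years; score scale chosen
so the population peak lands near 141 points at about age 21) purely to
exercise raw-unit handling.

The four-typology preset defines one dominant "average" component (weight
0.76) and three rare ones (0.08 each): better-young-level/low-progression
(smaller a, b), lower-young-level/strong-progression (larger a, b), and
overall-lower-performance (larger c). Components are tight on the log
scale (SD 0.03) so their slope densities are well separated — a cohort on
which typology recovery has an unambiguous right answer.

What the generator does **not** emulate: points-calculation rules, race
penalties, field-strength dynamics, season structure, injuries, or
dropout. Passing recovery tests therefore shows the machinery is correct
under the model's own assumptions, not that real race data satisfy them.

## Study sizes and numerical choices in the shipped checks

* Parameter recovery: 20 cohorts of 60 individuals, one result per age,
  counter-performance off (the regime where best-per-age values are
  unbiased curve samples — with several results per age the per-age minimum
  is biased low by construction, for real data exactly as for synthetic
  data, and a coverage statement about the generative truth would be
  ill-posed), 2 chains × 250 draws after 250 warmup (enough retained draws
  that the Monte-Carlo error of the interval endpoints is small against the
  interval width). Every fixed parameter
  must sit in its central 95% interval in ≥ 18 of 20 replicates; the
  population peak age must be recovered within 0.3 years in every
  replicate.
* Recovery and the acceptance script condition on the generator's
  standardization; refitting the transform from data would shift the curve
  family by an additive constant and make the truth inexpressible in the
  refit scale. The CLI pipeline, by contrast, always fits its own
  standardization from the input records.
* The typology-recovery and membership-coherence checks run the clustering
  stage on the generator's true quadruplets of a 400-individual cohort
  (the clustering input contract is "a table of quadruplets"; using truth
  isolates the clustering stage from posterior noise). The acceptance
  script instead runs the full pipeline — posterior medians in, membership
  from real posterior draws — on a 150-individual cohort at the default
  4 × 200 draws.
* Overlap-score validation uses exact Normal densities against the closed
  form 2·Φ(−δ/2σ) (tolerance 10⁻³) and Monte-Carlo importance estimates
  (3 standard errors) on random Gaussian pairs.

## Known limitations

* The random-effect scales of the growth term (c, d) are weakly identified
  per individual: when the true between-individual variance is zero, their
  posterior upper bounds are limited by per-individual measurement
  uncertainty (≈ 0.8 × residual scale for d) rather than shrinking
  indefinitely with cohort size. The decline-term scales (a, b) do shrink
  below a tenth of the residual scale in the same regime.
* Credible-interval coverage for d is the tightest of the four parameters
  in recovery simulations (~90% at nominal 95% with short chains); longer
  chains improve it. R-hat above 1.05 on any fixed parameter is flagged in
  the diagnostics and should be taken seriously before interpreting
  intervals.
* The overlap score compares *fitted* cluster slope densities; it cannot
  detect that a typology exists if the mixture never proposes it (K range
  and the ≥ 5 individuals-per-component floor bound what is proposed).
* Residuals are modelled as homoscedastic on the standardized scale;
  real race points are typically right-skewed with age-dependent spread.
  The best-per-age filter absorbs much, not all, of that skew.
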