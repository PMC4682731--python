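# Methods

`sabnet` implements a stochastic actor-based (actor-oriented) model for
the joint evolution of a directed friendship network and an ordinal
behavior ("drinking") observed in panel waves, together with a
method-of-moments estimator, descriptive statistics, a nested
model-series driver, and a synthetic school-panel generator.

## The co-evolution model

Between consecutive observation waves, change is modeled as a
continuous-time sequence of micro-steps on a period normalized to unit
length.  Waiting times are exponential with total intensity
`n_active * (lambda_net + lambda_beh)`, where the rate parameters
`lambda` give the expected number of change opportunities per active
actor per period and per dependent variable.  At each event one active
actor is drawn uniformly and one dependent variable proportional to the
rates:

* **Network opportunity.** The actor chooses among toggling the tie to
  each other active actor or leaving the network unchanged, with
  probabilities proportional to `exp(gain)`; the no-change alternative
  has gain 0.  The gain of toggling `x_ij` is the change in the actor's
  network objective function, a weighted sum of effect statistics
  (Table below).
* **Behavior opportunity.** The actor chooses among the feasible moves
  {-1, 0, +1} on the 1..6 ordinal scale, with probabilities
  proportional to `exp(gain)` of the behavior objective function — the
  ordinal-logistic-like influence model.

Only one tie or one behavior level changes per micro-step.  Under all
parameters zero, a network opportunity toggles with probability
`(n-1)/n` (n-1 candidate toggles plus no change), giving expected
toggles per actor per period of `rate * (n-1)/n`; this closed form is
verified by the simulator tests.

### Effect statistics

Network (selection) effects for actor *i* with covariate *v* (centered
at a configurable mean except where noted):

| name | statistic |
|---|---|
| outdegree | Σ_j x_ij |
| reciprocity | Σ_j x_ij x_ji |
| transitive triplets | Σ_jh x_ij x_jh x_ih |
| 3-cycles | Σ_jh x_ij x_jh x_hi |
| indegree popularity (sqrt) | Σ_j x_ij sqrt(x_+j) |
| ego | v_i Σ_j x_ij |
| alter | Σ_j x_ij v_j |
| ego × alter | v_i Σ_j x_ij v_j |
| same | Σ_j x_ij I(v_i = v_j) (raw values) |

Behavior (influence) effects for the centered score *z*:

| name | statistic |
|---|---|
| linear / quadratic shape | z_i, z_i² |
| indegree / outdegree | z_i Σ_j x_ji, z_i Σ_j x_ij |
| average alter | z_i (Σ_j x_ij z_j) / (Σ_j x_ij), 0 for isolates |
| covariate | z_i v_i |

The average-alter statistic of an actor without outgoing ties is 0,
i.e. an isolate's behavior drifts only under the shape effects — the
no-information convention after centering.

### Roles: evaluation, creation, endowment

Every network effect carries a role.  *Evaluation* effects enter the
gain of every toggle; *creation* effects only when the toggle would
form a new tie; *endowment* effects only when it would dissolve an
existing one.  Splitting the ego × alter drinking term into a creation
and an endowment copy separates drinking-based selection into the
formation of new friendships versus the continuation of existing ones.

### Centering

Behavior and covariates enter ego/alter/interaction and influence
statistics centered at a grand mean computed from the observed data
(pooled over groups in multigroup estimation); the `same` effect
matches raw values.  Centering is configurable per model.

## Estimation: method of moments with Robbins–Monro

Parameters are chosen so that expected simulated statistics equal their
observed targets.  Per free parameter one target:

* **Rates** — the observed number of tie changes (behavior: summed
  absolute level changes) in the period, over cells/actors observed at
  both ends.
* **Evaluation effects** — the statistic summed over actors and periods,
  evaluated on the observed end-of-period state.
* **Creation effects** — the same statistic evaluated on the network of
  newly formed ties (absent at the period start, present at its end);
  **endowment effects** on the maintained ties (present at both).
  Identical end-state targets for the new/old split would leave the two
  parameters unidentified; the formation/maintenance decomposition of
  the target is what separates them.

Missing data: simulations start from the observed wave with missing
cells carried forward from the last observation (zero at the first
wave); behavior is imputed the same way (leading gaps backfilled).  All
targets are masked to the observed cells/actors at the period end, and
the identical mask is applied to simulated end states, so missingness
cannot bias the moment comparison.  Composition change gives joiners
empty tie rows at their join time and freezes leavers afterwards;
inactive actors contribute no statistics.

The fit has three phases:

1. **Derivative matrix.** `D = dE[S]/dtheta` by forward finite
   differences (step 0.4) with common random numbers, `n_phase1 = 30`
   replicates per column.
2. **Robbins–Monro.** `theta <- theta - a_t D^{-1}(S_sim - S_obs)` with
   gain `a_t = 0.2 / 2^subphase` over 4 subphases whose lengths grow by
   1.5× (30 iterations in the first); the subphase average of the
   iterates (Polyak) seeds the next subphase.  Steps are computed from
   an SVD of `D` with singular values floored at 1e-2 of the largest —
   `D` is itself a Monte-Carlo estimate, and unfloored small singular
   values turn its noise into unbounded steps along weakly identified
   directions.  Per-coordinate steps are clipped at 0.3, effect
   parameters at ±6, rates kept in [0.02, 40] on the log scale.
3. **Diagnostics.** At the final parameters, 500 simulations give the
   statistic covariance Σ and the convergence t-ratios
   `mean(S_sim - S_obs)/sd(S_sim)`; standard errors come from
   `D^{-1} Σ D^{-T}` with `D` re-estimated at the solution (inverse
   floored only against exact singularity, so uncertainty along flat
   directions is reported honestly).  A fit with
   `max |conv t| > 0.15` re-runs up to 3 times warm-started at the
   current solution; if a re-run remains far off (`> 0.5`) the next one
   restarts cold, since that pattern indicates a wrong root of the
   moment equations rather than slow polishing.  Persistent failure is
   flagged on the result, never silently accepted.

Initial values: rates from observed change counts, network outdegree
−1, other effects 0 — unless the supplied model carries nonzero
parameters, which are used as warm starts (so a fitted model can be
refit on fresh data from where it left off).

With roughly 300 micro-steps per simulated period this puts one fit of
a ~8-parameter model on a 60-actor two-wave panel at a few hundred
thousand simulated micro-steps, about 15–30 s on one core; the test
suite's Monte-Carlo studies choose replicate counts and phase sizes
around that operating point.

**Multigroup estimation** pools one parameter per shared effect across
groups (targets and simulated statistics summed over groups) while
rates stay per group and period.  The model-series driver reports this
pooled fit as the "Both" column next to the per-school fits and the
between-school comparison `t = (b1 - b2)/sqrt(se1² + se2²)`.

## The model series

`run_series` fits a nested ladder per behavior variable: selection only
(M1), influence only (M2), selection with the ego × alter term split
into new/old (M3), the joint model (M4), plus network-closure controls
(transitive triplets, 3-cycles, indegree popularity) and
indegree/outdegree influence (M5), plus covariate effects (M6).  The
"network closure" control set is fixed to the full structural battery
since nothing narrower is canonical.  Covariate sets are configurable;
the defaults use same-sex and same-race matching in selection and
sex/parental-drinking/availability main effects in the behavior model.
Significance stars use two-sided normal p-values at 0.05/0.01/0.001.

## Descriptives

Density and average degree are reported under two denominators — all
actors on the roster, and respondents only (actors with an observed
outgoing row) — because wave-level nonresponse makes the choice
material and conventions differ.  The dyad census partitions observed
unordered pairs into mutual/asymmetric/null; tie-change tables and the
Jaccard stability index `stable / (created + dissolved + stable)` use
only cells observed at both waves.  Moran's I at geodesic distances 1
and 2 defaults to directed forward ties with binary weights and *exact*
distance (not ≤); symmetrized and row-normalized variants are options,
since published usage is often ambiguous on this point.  The
friend-similarity index is `mean over ties of 1 - |z_i - z_j| / range`.

## Synthetic school panels

The generator emulates a multi-wave in-school friendship census:

* Covariates: sex (~49% female), grade 9–12, race from a ~93%-one-race
  or a heterogeneous preset, parent education/drinking, alcohol
  availability, per-wave smoking and off-list nomination counts, and a
  ~5% restricted-nomination subset.
* Wave 1: a dyad-independent logistic draw with same-sex, same-grade
  and drinking-similarity homophily, calibrated by bisection to a
  target mean degree (default 4).
* Waves 2+: forward simulation under a true model (defaults: outdegree
  −3.3, reciprocity 2.0, transitive triplets 0.25, same-sex 0.45,
  same-grade 0.55, drinking ego × alter 0.15, quadratic shape −0.25,
  average alter 0.4; network rate 4, behavior rate 1.2 per period).
  These values were fixed once so that complete panels land in the
  observed ranges for sparse school networks: average degree declining
  within ~1.5–6.5 across waves, adjacent-wave Jaccard ~0.15–0.45, and
  friend drinking-similarity ~0.45–0.85.
* Observation layer: the survey instrument's 5-male/5-female nomination
  cap (1+1 for the restricted subset) censors the lowest-valued ties
  from the observed panel only; wave-level nonresponse blanks whole
  outgoing rows (defaults 25%/5%/20%); joiners/leavers get presence
  intervals.  Ground truth (the uncensored complete panels and the true
  parameters) ships alongside.

What the generator does **not** emulate: degree heterogeneity beyond
what the structural effects induce, attribute-dependent nonresponse,
measurement error in self-reports, school-year seasonality, and
multiplex or off-roster relations (off-list counts are generated as a
covariate, not as ties).  Passing recovery tests on these panels
therefore demonstrates correctness of the machinery under the model's
own assumptions plus instrument-style censoring — not robustness to
every real-data pathology.

The two-wave recovery configuration (n = 60, outdegree −2.0,
reciprocity 1.5, ego × alter 0.15, average alter 0.3, quadratic −0.3,
rates 3.0/1.5, initial mean degree 7, no masking) keeps a small
negative quadratic shape in the truth: without any variance-stabilizing
shape the behavior process is non-stationary and the moment equations
acquire spurious roots, which is a property of the model class, not of
the estimator.

## Numerical conventions and degenerate inputs

* Behavior scores live on 1..6 (raw 1–7 intensity is top-coded at 6);
  steps outside the range are excluded from choice sets, never clamped
  after the fact.
* Jaccard stability of an all-zero change table and Moran's I of a
  constant attribute return NaN (undefined), not 0.
* The three-state adjacency code is {0 absent, 1 present, -1 missing};
  the diagonal is structurally zero.
* Centering means default to observed grand means; disabling centering
  reproduces raw-scale statistics exactly.
* Identical seeds give identical panels, simulations and fits; every
  RNG stream derives from a single integer seed via `SeedSequence`
  spawning keyed by (stage, group, period, replicate), so adding a
  group leaves other groups' draws unchanged.

## Known limitations

* Method-of-moments only; no maximum-likelihood or Bayesian estimation,
  no GWESP/balance effects, no endogenous rate effects, no conditional
  (change-count-conditioned) simulation.
* At desk scale (n ≈ 50–150, 2–3 waves) the behavior-influence block is
  weakly identified; standard errors are honest about this (they can be
  large), and misspecified models can legitimately fail to converge —
  the flag on the result is the intended signal.
* The nomination-cap censoring in the generator deliberately violates
  the fitted model class, mirroring the instrument; fits on heavily
  censored dense panels will show elevated convergence t-ratios for
  degree-linked effects.
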