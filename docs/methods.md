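# Methods

## Model and likelihood

`remkit` models an undirected relational event history among a fixed set
of N actors.  The risk set R(t) contains all N(N−1)/2 unordered pairs,
crossed with K event types when types are modelled (so N(N−1)/2 · K
candidates).  Candidate rates are log-linear in statistics,
log λ = Σ β_p x_p, and the hazard is piecewise constant between events.
Two consequences define the likelihood: waiting times are exponential in
the summed rate, and the event identity is multinomial in the relative
rates.  The full log-likelihood is therefore

    Σ_e [ β·x_obs(e) − Δt_e Σ_{R(t_e)} exp(β·x) ],

the per-event log-rate of the realized candidate minus the integrated
total hazard over the waiting interval.  The ordinal variant replaces the
integrated-hazard term by the log of the rate sum (a conditional-logit
choice likelihood) and discards the waiting times.  Any statistic that is
constant over the risk set at every event — baseline, weekend, group —
cancels from the ordinal likelihood and is not identified there;
`fit_rem` refuses such columns for ordinal fits with an explicit error
rather than silently returning an arbitrary value along the flat
direction.

Fitting is damped Newton with analytic gradient and Hessian, started at
β = 0, declared converged when the gradient max-norm falls below 1e-8
(at most 200 iterations; both objectives are concave, so step halving on
the Newton direction always makes progress).  Standard errors are the
square roots of the diagonal of the inverse observed information; Wald
p-values are two-sided with significance marked at 0.05 and no
multiple-testing correction.  BIC = −2·loglik + p·ln(M), where M counts
the *split* dyadic events, the unit the likelihood runs over.  A rank
check on the pooled Gram matrix rejects collinear designs before
optimization, naming the involved columns.

## Statistics

Exogenous: baseline (identically 1); category-pair indicators
(both-members-have-level, members-differ) for gender and age group; the
minimum and maximum of the pair's standardized trait scores; a weekend
indicator driven by a calendar (configurable start weekday, minute 0 of
day 0; weekend = Saturday/Sunday); a group indicator equal to 1 when the
currently observed event originates from a group interaction (constant
over the risk set, so it acts as a rate shift rather than a choice
covariate).

Endogenous: inertia Σ ln(d_e)/(|A_e|−1) over past events of the dyad
(with an unweighted per-event count available as a toggle), distinct
shared partners, and within-type variants restricted to past events of
the candidate's type.  Endogenous statistics are standardized over the
active risk set at each time point using the sample SD (ddof = 1); a
degenerate (constant) statistic maps to all zeros so early-history events
stay usable.  Interactions are elementwise products of two previously
defined columns — endogenous components enter already scaled, and the
product is not re-standardized.

Two implementations coexist on purpose: plain history-list functions used
as references in the test suite, and an incremental calculator (running
per-dyad inertia totals and 0/1 adjacency matrices whose product counts
shared partners) used by design assembly and the simulator.  The suite
asserts their agreement on random histories.

## Group splitting

A raw event with m ≥ 3 participants becomes all m(m−1)/2 dyadic events in
a seeded random order, the k-th placed at t + k/(M+1) — evenly spaced and
strictly inside (t, t+1), so induced times never collide with the next
integer minute.  Statistics for every constituent are evaluated at the
pre-spacing onset t on the history strictly before t; the whole group
enters the history afterwards, so a group never feeds back into its own
statistics and simultaneous raw events do not see each other.  Waiting
times use the spaced times (t_0 = 0).  Raw events sharing an onset minute
keep their input order where possible; after spacing, dyadic events are
stably sorted by time, which can interleave same-minute raw events — the
only case where raw order is not preserved exactly, and one the
likelihood is indifferent to.  Durations ≤ 1 minute are rejected (their
ln-weight would be non-positive).

## Moving window

Windows [start, start + L) slide in steps S ≤ L; events belong to a
window by their statistic-evaluation time.  Within a window, endogenous
statistics use only the window's own events and the first waiting time is
measured from the window start, keeping the per-window baseline
interpretable; a single full-span window therefore reproduces the global
fit exactly.  Windows below a minimum event count (default 100) are
skipped with a warning — small windows give unstable estimates.  A
weekend effect inside a moving-window model triggers a warning: day-scale
rate differences are already absorbed by the per-window baselines.  The
ordinal likelihood remains available for users who prefer to sidestep the
window-boundary waiting-time convention.

## Goodness of fit

For each original (pre-split) event, candidates are ranked by predicted
rate with ties broken by a seeded random permutation; the event is a hit
if its best-ranked constituent dyad falls in the top k = ceil(share·|R|)
(share 0.05 by default).  The ceiling guarantees a non-empty top set; the
random tie-break makes a rate-constant model hit at the share itself in
expectation on dyadic data.  The metric depends only on ranks, hence is
invariant to monotone transforms of the rates.  It is computed in-sample
by default; any design (e.g. held-out) can be passed instead.

## Simulator

Histories are drawn by competing exponential clocks: statistics → rates →
exponential waiting time on the summed rate → multinomial candidate draw,
iterated to the horizon.  The statistics come from the same incremental
calculator as estimation, by construction.  Durations are log-normal with
location ln 30 and spread ln(8)/1.96 (≈ 97.5% of draws at or below 240
min), clamped to [5, 1805] minutes.  Group events have no generative
mechanism inside the model: a configured group-size distribution promotes
the drawn dyad by adding uniformly sampled extra members, and a `group`
effect in the model's effect list is excluded from generative rates.  Rates are
re-evaluated at each event time, so a clock boundary (weekend onset)
takes effect at the first event after it — consistent with the
piecewise-constant hazard the estimator assumes.

The bundled synthetic cohort (`generate_connect_like`) has 126 actors
(101 female / 25 male, 103 young / 23 older), two settings, a 23-day
horizon, and true coefficients with moderate homophily and trait effects
and a −0.75 weekend effect.  The endogenous truth coefficients (inertia
0.04, shared partners 0.03) are deliberately smaller than typical fitted
values on real data: per-time-point standardized counts reach z ≈ √D
while history is concentrated on few dyads, so larger generative values
make the feedback loop self-exciting and blow the event volume up by an
order of magnitude.  The baseline −11.0 yields roughly 2,500–3,000 raw
events over 23 days.  What the generator does not emulate: integer-minute
reporting, diurnal (within-day) rhythm, actor availability gaps,
setting-dependent rates in the untyped preset, and any behavioral group
formation — so passing tests show the estimation machinery is correct
under the model, not that the model describes any particular real
population.

## Test problem sizes and numerical choices

Parameter-recovery checks use 12-actor cohorts (66 dyads) with truth
(−8 baseline, 0.3 inertia, 0.2 trait-minimum), 50 replicate histories of
250 and 500 events: at this size the per-replicate sampling error
comfortably dominates the O(1/M) finite-sample bias of the maximum
likelihood estimator, and the bias itself was verified to shrink as the
event count doubles.  Likelihood oracle checks enumerate choice
probabilities explicitly on risk sets of at most 10 entries and agree to
1e-10; analytic gradients match central finite differences to 1e-5;
the baseline-only optimizer reproduces the closed form ln(M/(R·T)) to
1e-8.  Hit-rate calibration uses 800 dyadic events on 20 actors and a
3-standard-error binomial band around the share.

Degenerate inputs: an empty active risk set raises; per-event scaling
needs at least two entries; constant or all-missing trait columns are
rejected before standardization (mean imputation happens first, matching
the documented preprocessing order); simultaneous events are allowed
(zero waiting times contribute nothing to the integrated hazard).

## Known limitations

Directed events and sender/receiver statistics (reciprocity, degree) are
out of scope, as are exponential memory decay of past events, sampled /
case-control risk-set approximations, Bayesian estimation, and formal
change-point detection on coefficient trajectories.  The full design
array is held in memory (blocks × risk set × effects); histories of a few
thousand events on a 7,875-dyad risk set fit comfortably, but much larger
problems would need a streaming design.
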