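# remkit

Relational event models (REMs) for continuous-time social interaction
data: who interacts with whom, and when.

Given an actor table (demographics, trait scores) and a timestamped event
list (participant sets, setting, duration), `remkit` estimates
continuous-time models of the interaction process, traces how the drivers
of interaction change over time with a moving-window refit, distinguishes
event types (settings), scores predictive fit with a top-share hit rate,
and simulates synthetic histories from a specified model.  It is aimed at
researchers working with fine-grained interaction logs — experience
sampling, proximity sensors, communication records.

## The model

A relational event history is a sequence of interactions among N actors.
At any time t, the risk set R(t) holds every candidate event — here all
N(N−1)/2 unordered pairs (s, r), optionally crossed with an event type c.
Each candidate carries a log-linear rate

    log λ(s, r, c, t) = Σ_p β_p · x_p(s, r, c, t)

where the statistics x_p are exogenous (gender/age-pair indicators, the
minimum or maximum trait score in the pair, a weekend indicator) or
endogenous functions of the past history:

- **inertia** — Σ over past (s,r) events of ln(d_e) / (|A_e| − 1), a
  duration-weighted, group-size-discounted volume of past interaction;
- **shared partners** — the number of third actors both s and r have
  interacted with, plus within-setting variants of both.

Endogenous statistics are standardized over the risk set at each time
point.  Under a piecewise-constant hazard, the waiting time to the next
event is Exponential(Σ_R λ) and the event identity is multinomial with
probabilities λ / Σ λ, giving the full log-likelihood

    Σ_e [ β·x_obs(e) − Δt_e · Σ_{R(t_e)} exp(β·x) ]

or, when only the event order is known, the ordinal (conditional-logit)
form.  Group interactions are decomposed into all constituent dyadic
events, evenly spaced inside one minute in seeded random order, with
statistics evaluated at the pre-spacing onset; a group indicator absorbs
the artificial rate inflation, and ln(n_dyadic / n_raw) subtracted from
its coefficient recovers the net group tendency.

## Worked example

Simulate a three-day synthetic cohort (126 actors), split the group
events, and refit:

```python
import remkit
from remkit import EffectSpec

actors, events = remkit.generate_connect_like(seed=7, t_max_days=3.0)
dyadic, report = remkit.split_group_events(events, seed=1)
risk_set = remkit.build_risk_set(actors)
specs = [
    EffectSpec("baseline", "baseline"),
    EffectSpec("extraversion.min", "trait_min", attribute="extraversion"),
    EffectSpec("inertia", "inertia"),
    EffectSpec("shared.partners", "shared_partners"),
    EffectSpec("group", "group"),
]
design = remkit.build_design(dyadic, risk_set, actors, specs)
fit = remkit.fit_rem(design, kind="full")
print(fit.summary().round(3).to_string(index=False))
gof = remkit.top_share_hit_rate(fit.beta, design, share=0.05, seed=2)
```

Output:

```
394 raw events -> 1240 dyadic events (log expansion 1.15)
          effect  estimate    se  p_value  significant
        baseline   -11.261 0.067    0.000         True
extraversion.min     0.149 0.033    0.000         True
         inertia    -0.007 0.031    0.824        False
 shared.partners    -0.014 0.030    0.643        False
           group     1.781 0.072    0.000         True
BIC 27029.3 over 1240 events
top-5% hit rate: 0.127
net group effect: 0.63
```

Reading the numbers: the baseline −11.26 means a reference dyad starts an
interaction at rate exp(−11.26) per minute — multiplied by the 7875 dyads
at risk, one event about every 16 minutes.  The positive
`extraversion.min` coefficient (exp(0.149) ≈ 1.16) says pairs whose least
extraverted member scores one standard deviation higher interact about
16% faster.  Three days of history are too short for the (deliberately
weak) endogenous effects of this truth to reach significance.  The group
coefficient 1.78 mostly reflects the mechanical rate inflation from
splitting (ln(1240/394) = 1.15); the remaining 0.63 is the real tendency
to interact in groups.  The hit rate says the observed dyad ranked in the
model's top 5% predictions for 12.7% of events.

The same workflow is scriptable from the shell: `remkit simulate`,
`remkit fit`, `remkit fit-windows`, `remkit gof`, `remkit stats`, each
driven by a YAML config (see `remkit --help`).

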