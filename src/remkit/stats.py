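"""Dynamic network statistics over the risk set.

Each statistic x_p(s, r[, c], t) is a vector over the candidate events in
the risk set, evaluated at the onset of each observed event using only the
history strictly before that onset.  Exogenous statistics (indicators,
trait extremes) depend only on actor attributes or the clock; endogenous
statistics (inertia, shared partners, and their within-type variants)
summarize the past event history and are standardized per time point so
they stay comparable as history accumulates.

Two implementations coexist deliberately:

* plain ``stat_*`` functions that recompute from an explicit history list
  -- simple, easy to audit, used directly in tests; and
* :class:`EffectCalculator`, an incremental engine holding running inertia
  totals and adjacency matrices -- used by :func:`build_design` and by the
  simulator, which must share one statistics implementation.

Agreement between the two paths is enforced by the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ActorTable,
    DesignArray,
    DyadicEvent,
    RiskSet,
    ValidationError,
    active_mask,
)

MINUTES_PER_DAY = 1440
WEEKEND_DAYS = frozenset({5, 6})  # Saturday, Sunday with Monday = 0

ENDOGENOUS_KINDS = frozenset(
    {"inertia", "shared_partners", "type_inertia", "type_shared_partners"}
)
KINDS = ENDOGENOUS_KINDS | {
    "baseline",
    "category_pair",
    "trait_min",
    "trait_max",
    "weekend",
    "group",
    "type_dummy",
    "interaction",
}


@dataclass(frozen=True)
class Calendar:
    """Maps minutes since observation onset to weekdays.

    ``start_weekday`` is the weekday of minute 0 (0 = Monday).  Day index
    of minute t is floor(t / 1440); weekend days are Saturday and Sunday.
    """

    start_weekday: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start_weekday <= 6:
            raise ValidationError("start_weekday must be in 0..6 (0 = Monday)")

    def weekday(self, t: float) -> int:
        if t < 0:
            raise ValidationError(f"negative time {t}")
        return (self.start_weekday + int(t // MINUTES_PER_DAY)) % 7

    def is_weekend(self, t: float) -> bool:
        return self.weekday(t) in WEEKEND_DAYS


@dataclass(frozen=True)
class EffectSpec:
    """Specification of one statistic (model term).

    ``kind`` selects the statistic; the remaining fields parameterize it:
    ``attribute`` names a categorical attribute or trait, ``mode``/``level``
    configure category-pair indicators, ``focal_type`` the type dummy, and
    ``components`` the two previously defined effects of an interaction
    term.  ``scaled`` toggles per-time-point standardization; endogenous
    kinds default to on, exogenous kinds to off.  ``weighting`` switches
    inertia between the duration/group-size weighted form (default) and a
    conventional unweighted event count.
    """

    name: str
    kind: str
    attribute: str | None = None
    mode: str | None = None
    level: str | None = None
    focal_type: str | None = None
    components: tuple[str, str] | None = None
    scaled: bool | None = None
    weighting: str = "duration"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "interaction" and (
            self.components is None or len(self.components) != 2
        ):
            raise ValidationError(
                f"interaction effect {self.name!r} must name exactly two components"
            )
        if self.weighting not in ("duration", "count"):
            raise ValidationError(f"unknown inertia weighting {self.weighting!r}")

    @property
    def is_scaled(self) -> bool:
        if self.scaled is not None:
            return self.scaled
        return self.kind in ENDOGENOUS_KINDS


# ---------------------------------------------------------------------------
# Reference (history-list) statistic implementations


def _event_weight(event: DyadicEvent, weighting: str = "duration") -> float:
    if weighting == "count":
        return 1.0
    return math.log(event.duration) / (event.group_size - 1)


def _in_window(event: DyadicEvent, t: float, window_start: float | None) -> bool:
    if event.t_stat >= t:
        return False
    return window_start is None or event.t_stat >= window_start


def stat_baseline(risk_set: RiskSet, t: float | None = None) -> np.ndarray:
    """The intercept statistic: identically 1 for every candidate event."""
    return np.ones(len(risk_set))


def stat_category_pair(
    risk_set: RiskSet,
    actors: ActorTable,
    attribute: str,
    mode: str,
    level: str | None = None,
) -> np.ndarray:
    """Indicator per dyad: both members share ``level`` (both_level) or the
    members differ on the attribute (mixed)."""
    if attribute not in actors.frame.columns:
        raise ValidationError(f"unknown attribute {attribute!r}")
    values = actors.frame[attribute].to_numpy()
    a = values[risk_set.dyads[:, 0]]
    b = values[risk_set.dyads[:, 1]]
    if mode == "both_level":
        if level is None or level not in set(values):
            raise ValidationError(f"level {level!r} not present in {attribute!r}")
        per_dyad = (a == level) & (b == level)
    elif mode == "mixed":
        per_dyad = a != b
    else:
        raise ValidationError(f"unknown category_pair mode {mode!r}")
    return per_dyad.astype(float)[risk_set.dyad_index]


def stat_trait_extreme(
    risk_set: RiskSet, actors: ActorTable, trait: str, mode: str
) -> np.ndarray:
    """Per dyad, the min or max of the two members' standardized trait scores."""
    scores = actors.trait_values(trait)
    a = scores[risk_set.dyads[:, 0]]
    b = scores[risk_set.dyads[:, 1]]
    if mode == "min":
        per_dyad = np.minimum(a, b)
    elif mode == "max":
        per_dyad = np.maximum(a, b)
    else:
        raise ValidationError(f"unknown trait_extreme mode {mode!r}")
    return per_dyad[risk_set.dyad_index]


def stat_weekend(t: float, calendar: Calendar) -> float:
    """1 iff minute t falls on a Saturday or Sunday (constant over the risk set)."""
    return float(calendar.is_weekend(t))


def stat_group(group_size: int) -> float:
    """1 iff the observed event is part of a group interaction (|A_e| > 2)."""
    return float(group_size > 2)


def stat_inertia(
    history: Iterable[DyadicEvent],
    risk_set: RiskSet,
    t: float,
    window_start: float | None = None,
    weighting: str = "duration",
) -> np.ndarray:
    """Duration- and group-size-weighted volume of past interaction per dyad.

    For dyad (s, r), the sum over its past events of ln(d_e) / (|A_e| - 1):
    longer interactions weigh more, large-group co-presence weighs less.
    With ``weighting='count'`` each past event contributes 1 instead.
    """
    per_dyad = np.zeros(risk_set.n_dyads)
    for event in history:
        if _in_window(event, t, window_start):
            idx = _dyad_idx(risk_set, event.actors)
            per_dyad[idx] += _event_weight(event, weighting)
    return per_dyad[risk_set.dyad_index]


def stat_shared_partners(
    history: Iterable[DyadicEvent],
    risk_set: RiskSet,
    t: float,
    window_start: float | None = None,
) -> np.ndarray:
    """Number of distinct third actors with whom both dyad members interacted."""
    partners: dict[str, set[str]] = {a: set() for a in risk_set.actor_ids}
    for event in history:
        if _in_window(event, t, window_start):
            a, b = event.actors
            partners[a].add(b)
            partners[b].add(a)
    ids = risk_set.actor_ids
    per_dyad = np.array(
        [
            len((partners[ids[i]] & partners[ids[j]]) - {ids[i], ids[j]})
            for i, j in risk_set.dyads
        ],
        dtype=float,
    )
    return per_dyad[risk_set.dyad_index]


def stat_type_dummy(risk_set: RiskSet, focal_type: str) -> np.ndarray:
    """Indicator that a candidate event is of the focal type."""
    if not risk_set.typed:
        raise ValidationError("type dummy requires a typed risk set")
    if focal_type not in risk_set.event_types:
        raise ValidationError(
            f"unknown event type {focal_type!r}; have {risk_set.event_types}"
        )
    k = risk_set.event_types.index(focal_type)
    return (risk_set.type_index == k).astype(float)


def stat_type_inertia(
    history: Iterable[DyadicEvent],
    risk_set: RiskSet,
    t: float,
    window_start: float | None = None,
    weighting: str = "duration",
) -> np.ndarray:
    """Within-type inertia: the weighted sum restricted to past events whose
    setting matches the candidate event's type."""
    if not risk_set.typed:
        raise ValidationError("type inertia requires a typed risk set")
    values = np.zeros((risk_set.n_dyads, risk_set.n_types))
    type_pos = {c: k for k, c in enumerate(risk_set.event_types)}
    for event in history:
        if _in_window(event, t, window_start):
            if event.setting not in type_pos:
                raise ValidationError(
                    f"event setting {event.setting!r} not among risk-set types"
                )
            idx = _dyad_idx(risk_set, event.actors)
            values[idx, type_pos[event.setting]] += _event_weight(event, weighting)
    return values[risk_set.dyad_index, risk_set.type_index]


def stat_type_shared_partners(
    history: Iterable[DyadicEvent],
    risk_set: RiskSet,
    t: float,
    window_start: float | None = None,
) -> np.ndarray:
    """Within-type shared partners: third actors connected to both members
    through past events of the candidate's type only."""
    if not risk_set.typed:
        raise ValidationError("type shared partners requires a typed risk set")
    partners: dict[tuple[str, str], set[str]] = {}
    for event in history:
        if _in_window(event, t, window_start):
            a, b = event.actors
            partners.setdefault((a, event.setting), set()).add(b)
            partners.setdefault((b, event.setting), set()).add(a)
    ids = risk_set.actor_ids
    types = risk_set.event_types
    out = np.empty(len(risk_set))
    for e in range(len(risk_set)):
        i, j = risk_set.dyads[risk_set.dyad_index[e]]
        c = types[risk_set.type_index[e]]
        pa = partners.get((ids[i], c), set())
        pb = partners.get((ids[j], c), set())
        out[e] = len((pa & pb) - {ids[i], ids[j]})
    return out


def scale_per_event(values: np.ndarray, active: np.ndarray | None = None) -> np.ndarray:
    """Standardize a statistic over the (active) risk-set entries at one event.

    Uses the sample SD (ddof=1).  A degenerate (constant) statistic maps to
    all zeros so that early-history events remain usable.  Inactive entries
    are zeroed.
    """
    values = np.asarray(values, dtype=float)
    if active is None:
        active = np.ones(len(values), dtype=bool)
    if active.sum() < 2:
        raise ValidationError("per-event scaling needs at least 2 risk-set entries")
    out = np.zeros_like(values)
    sub = values[active]
    sd = sub.std(ddof=1)
    if sd > 0:
        out[active] = (sub - sub.mean()) / sd
    return out


def stat_interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise product of two effect columns (not re-standardized)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"component length mismatch: {a.shape} vs {b.shape}")
    return a * b


def _dyad_idx(risk_set: RiskSet, actors_pair: tuple[str, str]) -> int:
    entry = risk_set.index_of(*actors_pair, risk_set.event_types[0] if risk_set.typed else None)
    return int(risk_set.dyad_index[entry])


# ---------------------------------------------------------------------------
# Incremental engine


def validate_specs(specs: Sequence[EffectSpec], risk_set: RiskSet) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("effect names must be unique")
    seen: set[str] = set()
    for spec in specs:
        if spec.kind == "interaction":
            for comp in spec.components:  # type: ignore[union-attr]
                if comp not in seen:
                    raise ValidationError(
                        f"interaction {spec.name!r} references undefined effect {comp!r}"
                    )
        if spec.kind.startswith("type_") and not risk_set.typed:
            raise ValidationError(f"effect {spec.name!r} requires a typed risk set")
        seen.add(spec.name)


class EffectCalculator:
    """Incrementally maintained statistics over a fixed risk set.

    ``compute(t, group_size)`` returns the (E, P) statistic matrix at time
    t given the history fed in so far; ``update(events)`` appends observed
    dyadic events to the history.  The split between the two calls is what
    guarantees the no-self-feedback rule: all dyadic events of one group
    interaction are computed against the same history, then added together.
    """

    def __init__(
        self,
        risk_set: RiskSet,
        actors: ActorTable,
        specs: Sequence[EffectSpec],
        calendar: Calendar | None = None,
        window_start: float | None = None,
    ) -> None:
        validate_specs(specs, risk_set)
        self.risk_set = risk_set
        self.actors = actors
        self.specs = list(specs)
        self.calendar = calendar or Calendar()
        self.window_start = window_start
        n, d = risk_set.n_actors, risk_set.n_dyads
        k = max(1, risk_set.n_types)
        self._inertia = np.zeros((d, k))  # per-type; summed for untyped inertia
        self._inertia_count = np.zeros((d, k))
        self._adj = np.zeros((n, n))  # 0/1, zero diagonal, untyped
        self._adj_typed = np.zeros((k, n, n))
        self._type_pos = {c: j for j, c in enumerate(risk_set.event_types)}
        self._static: dict[str, np.ndarray] = {}
        self._precompute_static()

    def _precompute_static(self) -> None:
        rs, actors = self.risk_set, self.actors
        for spec in self.specs:
            if spec.kind == "baseline":
                self._static[spec.name] = stat_baseline(rs)
            elif spec.kind == "category_pair":
                self._static[spec.name] = stat_category_pair(
                    rs, actors, spec.attribute, spec.mode, spec.level
                )
            elif spec.kind == "trait_min":
                self._static[spec.name] = stat_trait_extreme(rs, actors, spec.attribute, "min")
            elif spec.kind == "trait_max":
                self._static[spec.name] = stat_trait_extreme(rs, actors, spec.attribute, "max")
            elif spec.kind == "type_dummy":
                self._static[spec.name] = stat_type_dummy(rs, spec.focal_type)

    def _dyad_index_of(self, pair: tuple[str, str]) -> int:
        return _dyad_idx(self.risk_set, pair)

    def compute(
        self,
        t: float,
        group_size: int = 2,
        active: np.ndarray | None = None,
    ) -> np.ndarray:
        """Statistic matrix (E, P) at time t for an event of the given group size."""
        rs = self.risk_set
        e_count = len(rs)
        if active is None:
            active = np.ones(e_count, dtype=bool)
        columns: dict[str, np.ndarray] = {}
        out = np.empty((e_count, len(self.specs)))
        for p, spec in enumerate(self.specs):
            if spec.name in self._static:
                col = self._static[spec.name].copy()
            elif spec.kind == "weekend":
                col = np.full(e_count, stat_weekend(t, self.calendar))
            elif spec.kind == "group":
                col = np.full(e_count, stat_group(group_size))
            elif spec.kind == "inertia":
                store = self._inertia if spec.weighting == "duration" else self._inertia_count
                col = store.sum(axis=1)[rs.dyad_index]
            elif spec.kind == "type_inertia":
                store = self._inertia if spec.weighting == "duration" else self._inertia_count
                col = store[rs.dyad_index, rs.type_index]
            elif spec.kind == "shared_partners":
                counts = self._adj @ self._adj
                col = counts[rs.dyads[:, 0], rs.dyads[:, 1]][rs.dyad_index]
            elif spec.kind == "type_shared_partners":
                col = np.empty(e_count)
                for j in range(max(1, rs.n_types)):
                    counts = self._adj_typed[j] @ self._adj_typed[j]
                    sel = rs.type_index == j
                    dy = rs.dyad_index[sel]
                    col[sel] = counts[rs.dyads[dy, 0], rs.dyads[dy, 1]]
            elif spec.kind == "interaction":
                a, b = spec.components  # type: ignore[misc]
                col = stat_interaction(columns[a], columns[b])
            else:  # pragma: no cover - guarded by validate_specs
                raise ValidationError(f"unhandled effect kind {spec.kind!r}")
            if spec.is_scaled:
                col = scale_per_event(col, active)
            else:
                col = np.where(active, col, 0.0)
            columns[spec.name] = col
            out[:, p] = col
        return out

    def update(self, events: Iterable[DyadicEvent]) -> None:
        """Append observed dyadic events to the history state."""
        rs = self.risk_set
        for event in events:
            if self.window_start is not None and event.t_stat < self.window_start:
                continue
            d = self._dyad_index_of(event.actors)
            i, j = rs.dyads[d]
            w = _event_weight(event)
            if rs.typed:
                if event.setting not in self._type_pos:
                    raise ValidationError(
                        f"event setting {event.setting!r} not among risk-set types "
                        f"{rs.event_types}"
                    )
                k = self._type_pos[event.setting]
            else:
                k = 0
            self._inertia[d, k] += w
            self._inertia_count[d, k] += 1.0
            self._adj[i, j] = self._adj[j, i] = 1.0
            if rs.typed:
                self._adj_typed[k, i, j] = self._adj_typed[k, j, i] = 1.0


# ---------------------------------------------------------------------------
# Design assembly


def build_design(
    dyadic_events: Sequence[DyadicEvent],
    risk_set: RiskSet,
    actors: ActorTable,
    specs: Sequence[EffectSpec],
    calendar: Calendar | None = None,
    window_start: float | None = None,
) -> DesignArray:
    """Assemble the full design: statistics, observed indices, waiting times.

    Statistics for every dyadic event are evaluated at the pre-spacing
    onset of its originating raw event, on the history strictly before that
    onset; the events of one group therefore share a statistic block and
    enter the history only after the whole block is computed.  Waiting
    times use the spaced times, measured from ``window_start`` (default 0)
    for the first event.
    """
    if not dyadic_events:
        raise ValidationError("no events to build a design from")
    calc = EffectCalculator(risk_set, actors, specs, calendar, window_start)
    typed = risk_set.typed

    # One statistic block per raw event (group_id), in order of first
    # appearance in the time-sorted sequence.  A group enters the history
    # only once evaluation has moved strictly past its pre-spacing onset, so
    # simultaneous raw events do not see each other and a group never feeds
    # back into its own statistics.
    blocks: dict[int, list[DyadicEvent]] = {}
    first_seen: dict[int, int] = {}
    for i, event in enumerate(dyadic_events):
        blocks.setdefault(event.group_id, []).append(event)
        first_seen.setdefault(event.group_id, i)
    block_order = sorted(blocks, key=lambda gid: (blocks[gid][0].t_stat, first_seen[gid]))
    block_pos = {gid: g for g, gid in enumerate(block_order)}

    e_count = len(risk_set)
    X = np.empty((len(block_order), e_count, len(specs)))
    active = np.empty((len(block_order), e_count), dtype=bool)
    pending: list[list[DyadicEvent]] = []
    for g, gid in enumerate(block_order):
        block = blocks[gid]
        t_stat = block[0].t_stat
        while pending and pending[0][0].t_stat < t_stat:
            calc.update(pending.pop(0))
        mask = active_mask(risk_set, t_stat, actors)
        X[g] = calc.compute(t_stat, group_size=block[0].group_size, active=mask)
        active[g] = mask
        pending.append(block)

    event_block, obs_index, times, group_ids, group_sizes = [], [], [], [], []
    for event in dyadic_events:
        g = block_pos[event.group_id]
        idx = risk_set.index_of(*event.actors, event.setting if typed else None)
        if not active[g, idx]:
            raise ValidationError(
                f"observed dyad {event.actors} at t={event.time} is not in the "
                "active risk set"
            )
        event_block.append(g)
        obs_index.append(idx)
        times.append(event.time)
        group_ids.append(event.group_id)
        group_sizes.append(event.group_size)

    times_arr = np.asarray(times, dtype=float)
    origin = 0.0 if window_start is None else float(window_start)
    dt = np.diff(times_arr, prepend=origin)
    if (dt < 0).any():
        raise ValidationError("events are not sorted by (spaced) time")
    return DesignArray(
        X=X,
        active=active,
        event_block=np.asarray(event_block, dtype=np.int64),
        obs_index=np.asarray(obs_index, dtype=np.int64),
        dt=dt,
        times=times_arr,
        group_ids=np.asarray(group_ids, dtype=np.int64),
        group_sizes=np.asarray(group_sizes, dtype=np.int64),
        effect_names=tuple(s.name for s in specs),
        riskset_size=e_count,
    )
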