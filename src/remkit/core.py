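"""Core domain types for undirected relational event histories.

A relational event history is a time-ordered sequence of interactions
among a fixed set of actors.  This module holds the containers shared by
the rest of the package -- the actor table, raw and dyadic event records,
the risk set of candidate events, the assembled design array, and fit
results -- plus risk-set construction and availability filtering.

Events here are undirected: a candidate event is an unordered actor pair,
optionally crossed with an event type (the "setting" of the interaction).
The canonical dyad representation is ``(min(id), max(id))`` under
lexicographic ordering of actor ids, which gives deterministic indexing
into design arrays.  The entry abstraction (separate dyad and type index
arrays) would extend to directed pairs, but directed risk sets are not
implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when input data violate a documented contract."""


# ---------------------------------------------------------------------------
# Actors


@dataclass
class ActorTable:
    """Actors with categorical covariates and (standardized) trait scores.

    Parameters
    ----------
    frame
        One row per actor, indexed by actor id (sorted lexicographically at
        construction).  Expected columns: ``gender`` (male/female),
        ``age_group`` (young/older) and one numeric column per trait.
    traits
        Names of the trait columns.  After :func:`remkit.ingest.standardize_traits`
        these are z-scores over actors (mean 0, sample SD 1).
    availability
        Optional per-actor list of ``[start, end)`` minute intervals during
        which the actor may interact.  Actors without an entry are always
        available.
    """

    frame: pd.DataFrame
    traits: tuple[str, ...] = ()
    availability: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    n_imputed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate actor ids: {dupes}")
        self.frame = self.frame.sort_index()
        self.traits = tuple(self.traits)
        missing = [t for t in self.traits if t not in self.frame.columns]
        if missing:
            raise ValidationError(f"trait columns not present: {missing}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def n(self) -> int:
        return len(self.frame)

    def trait_values(self, trait: str) -> np.ndarray:
        if trait not in self.traits:
            raise ValidationError(f"unknown trait {trait!r}; have {self.traits}")
        return self.frame[trait].to_numpy(dtype=float)

    def is_available(self, actor: str, t: float) -> bool:
        intervals = self.availability.get(actor)
        if not intervals:
            return True
        return any(start <= t < end for start, end in intervals)

    def availability_vector(self, t: float) -> np.ndarray:
        """Boolean availability per actor, in id order."""
        if not self.availability:
            return np.ones(self.n, dtype=bool)
        return np.array([self.is_available(a, t) for a in self.ids], dtype=bool)


# ---------------------------------------------------------------------------
# Events


@dataclass(frozen=True)
class RawEvent:
    """An observed interaction: onset minute, participant set, setting, duration."""

    time: float
    participants: tuple[str, ...]
    setting: str | None = None
    duration: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(sorted(set(self.participants))))
        if len(self.participants) < 2:
            raise ValidationError(
                f"event at t={self.time} lists fewer than 2 participants"
            )
        if not self.duration > 1:
            raise ValidationError(
                f"event at t={self.time} has duration {self.duration} <= 1 min"
            )

    @property
    def group_size(self) -> int:
        return len(self.participants)


@dataclass(frozen=True)
class DyadicEvent:
    """One dyadic constituent of a (possibly group) interaction.

    ``time`` is the spaced onset used for waiting times; ``t_stat`` is the
    pre-spacing onset of the originating raw event at which statistics are
    evaluated.  All dyadic events of one raw event share ``group_id``,
    ``setting``, ``duration`` and ``group_size``.
    """

    time: float
    t_stat: float
    actors: tuple[str, str]
    setting: str | None
    duration: float
    group_size: int
    group_id: int

    def __post_init__(self) -> None:
        a, b = self.actors
        if a == b:
            raise ValidationError(f"self-pair {self.actors} at t={self.time}")
        if a > b:
            object.__setattr__(self, "actors", (b, a))


# ---------------------------------------------------------------------------
# Risk set


@dataclass
class RiskSet:
    """The set R(t) of candidate events: all unordered actor pairs, optionally
    crossed with event types.

    Entries are ordered lexicographically by (first actor id, second actor
    id, type), i.e. dyad-major with types in sorted order within a dyad.
    ``dyad_index`` and ``type_index`` map each entry to its dyad and type.
    """

    actor_ids: tuple[str, ...]
    event_types: tuple[str, ...] = ()
    directed: bool = False

    def __post_init__(self) -> None:
        if self.directed:
            raise NotImplementedError("directed risk sets are not supported")
        self.actor_ids = tuple(self.actor_ids)
        self.event_types = tuple(self.event_types)
        n = len(self.actor_ids)
        pairs = np.array(list(combinations(range(n), 2)), dtype=np.int64)
        self.dyads: np.ndarray = pairs  # (D, 2) indices into actor_ids
        k = max(1, len(self.event_types))
        d = len(pairs)
        self.dyad_index: np.ndarray = np.repeat(np.arange(d, dtype=np.int64), k)
        self.type_index: np.ndarray = np.tile(np.arange(k, dtype=np.int64), d)
        self._lookup: dict[tuple, int] = {}

    @property
    def n_actors(self) -> int:
        return len(self.actor_ids)

    @property
    def n_dyads(self) -> int:
        return len(self.dyads)

    @property
    def n_types(self) -> int:
        return len(self.event_types)

    @property
    def typed(self) -> bool:
        return bool(self.event_types)

    def __len__(self) -> int:
        return self.n_dyads * max(1, self.n_types)

    def entries(self) -> list[tuple]:
        """All candidate events as ``(a, b)`` or ``(a, b, type)`` tuples."""
        out = []
        for e in range(len(self)):
            i, j = self.dyads[self.dyad_index[e]]
            entry: tuple = (self.actor_ids[i], self.actor_ids[j])
            if self.typed:
                entry = entry + (self.event_types[self.type_index[e]],)
            out.append(entry)
        return out

    def index_of(self, a: str, b: str, event_type: str | None = None) -> int:
        """Entry index of the candidate event (a, b[, type])."""
        if not self._lookup:
            self._build_lookup()
        a, b = (a, b) if a < b else (b, a)
        key = (a, b, event_type) if self.typed else (a, b)
        try:
            return self._lookup[key]
        except KeyError:
            raise ValidationError(f"candidate event {key} not in risk set") from None

    def _build_lookup(self) -> None:
        ids = self.actor_ids
        types = self.event_types
        for e in range(len(self)):
            i, j = self.dyads[self.dyad_index[e]]
            if self.typed:
                self._lookup[(ids[i], ids[j], types[self.type_index[e]])] = e
            else:
                self._lookup[(ids[i], ids[j])] = e


def build_risk_set(
    actors: ActorTable, event_types: Sequence[str] = ()
) -> RiskSet:
    """All N(N-1)/2 unordered pairs, crossed with event types when given.

    The ordering is deterministic (lexicographic by actor id, then type),
    so repeated construction yields identical entry order.
    """
    if actors.n < 2:
        raise ValidationError(f"need at least 2 actors, got {actors.n}")
    return RiskSet(actor_ids=actors.ids, event_types=tuple(sorted(event_types)))


def active_mask(risk_set: RiskSet, t: float, actors: ActorTable) -> np.ndarray:
    """Boolean mask over risk-set entries whose both members are available at t."""
    if t < 0:
        raise ValidationError(f"negative time {t}")
    avail = actors.availability_vector(t)
    dyad_ok = avail[risk_set.dyads[:, 0]] & avail[risk_set.dyads[:, 1]]
    return dyad_ok[risk_set.dyad_index]


def active_risk_set(risk_set: RiskSet, t: float, actors: ActorTable) -> list[tuple]:
    """Candidate events at risk at time t (both members available).

    With no availability intervals this is the full risk set.  An empty
    result (all actors unavailable) is degenerate; callers should treat it
    as such.
    """
    mask = active_mask(risk_set, t, actors)
    entries = risk_set.entries()
    return [entry for entry, ok in zip(entries, mask) if ok]


# ---------------------------------------------------------------------------
# Design array and fit result


@dataclass
class DesignArray:
    """Per-event statistics over the risk set, plus waiting times.

    Dyadic events originating from one group interaction share their
    statistic values (statistics are evaluated at the pre-spacing onset of
    the raw event), so statistic matrices are stored once per raw event
    ("block") and each observed dyadic event points into its block.

    Attributes
    ----------
    X : ndarray, shape (G, E, P)
        Statistic matrix per block: G raw-event blocks, E risk-set entries,
        P effects.
    active : ndarray of bool, shape (G, E)
        Risk-set availability mask per block.
    event_block : ndarray of int, shape (M,)
        Block index of each observed dyadic event.
    obs_index : ndarray of int, shape (M,)
        Risk-set entry index of each observed dyadic event.
    dt : ndarray, shape (M,)
        Waiting time from the previous (spaced) event; the first event is
        measured from the time origin (0, or the window start).
    """

    X: np.ndarray
    active: np.ndarray
    event_block: np.ndarray
    obs_index: np.ndarray
    dt: np.ndarray
    times: np.ndarray
    group_ids: np.ndarray
    group_sizes: np.ndarray
    effect_names: tuple[str, ...]
    riskset_size: int

    def __post_init__(self) -> None:
        m = len(self.obs_index)
        if not (len(self.event_block) == len(self.dt) == len(self.times) == m):
            raise ValidationError("inconsistent design array lengths")
        if m == 0:
            raise ValidationError("empty design array")
        if (self.dt < 0).any():
            raise ValidationError("negative waiting time in design")
        if self.obs_index.min() < 0 or self.obs_index.max() >= self.X.shape[1]:
            raise ValidationError("observed-entry index out of range")

    @property
    def n_events(self) -> int:
        return len(self.obs_index)

    @property
    def n_effects(self) -> int:
        return self.X.shape[2]

    def x_observed(self) -> np.ndarray:
        """Statistic vectors of the observed events, shape (M, P)."""
        return self.X[self.event_block, self.obs_index, :]


@dataclass
class FitResult:
    """Maximum-likelihood estimates for a relational event model."""

    effect_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    bic: float
    n_events: int
    kind: str
    converged: bool
    n_iter: int
    grad_norm: float

    @property
    def n_params(self) -> int:
        return len(self.beta)

    def pvalues(self) -> np.ndarray:
        from scipy import stats as _st

        z = self.beta / self.se
        return 2 * _st.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        """Table-style summary: effect, estimate, SE, significance at 0.05."""
        p = self.pvalues()
        return pd.DataFrame(
            {
                "effect": list(self.effect_names),
                "estimate": self.beta,
                "se": self.se,
                "p_value": p,
                "significant": p < 0.05,
            }
        )
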