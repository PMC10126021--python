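"""Reading actor/event files and preprocessing.

Covers trait imputation and standardization, age dichotomization, and the
decomposition of group interactions into spaced dyadic events.

File dialects
-------------
Actor file: delimited text (comma or tab) with header ``id, gender, age``
followed by any number of numeric trait columns.

Event file, dyadic dialect: ``time, actor1, actor2, setting, duration``.
Event file, group dialect: ``time, members, setting, duration`` where
``members`` is a semicolon-joined list of actor ids.  The dialect is
auto-detected from the header.  Times are minutes since observation
onset; durations are minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import ActorTable, DyadicEvent, RawEvent, ValidationError

GENDER_LEVELS = ("female", "male")
YOUNG_MAX_AGE = 24  # "young" is age 24 or younger; 25+ is "older"


@dataclass
class PreprocessReport:
    """Bookkeeping of the group-splitting step."""

    n_raw_events: int
    n_dyadic_events: int
    expansion_log_factor: float
    n_imputed: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _read_delimited(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame


def read_actor_table(path) -> ActorTable:
    """Parse an actor file; dichotomize age into young (<= 24) / older (>= 25).

    Raises :class:`ValidationError` listing offending rows on duplicate ids,
    unknown gender levels, or non-numeric ages.
    """
    frame = _read_delimited(path)
    required = {"id", "gender", "age"}
    if not required.issubset(frame.columns):
        raise ValidationError(
            f"actor file must have columns {sorted(required)}, got {list(frame.columns)}"
        )
    ids = frame["id"].str.strip()
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate actor ids: {dupes}")

    gender = frame["gender"].str.strip().str.lower()
    bad = sorted(set(gender) - set(GENDER_LEVELS))
    if bad:
        rows = frame.index[gender.isin(bad)].tolist()
        raise ValidationError(f"unknown gender levels {bad} in rows {rows}")

    age = pd.to_numeric(frame["age"], errors="coerce")
    if age.isna().any():
        rows = frame.index[age.isna()].tolist()
        raise ValidationError(f"non-numeric age in rows {rows}")

    trait_cols = [c for c in frame.columns if c not in ("id", "gender", "age")]
    out = pd.DataFrame(index=pd.Index(ids, name="id"))
    out["gender"] = gender.to_numpy()
    out["age"] = age.to_numpy()
    out["age_group"] = np.where(age.to_numpy() <= YOUNG_MAX_AGE, "young", "older")
    for col in trait_cols:
        out[col] = pd.to_numeric(frame[col], errors="coerce").to_numpy()
    return ActorTable(frame=out, traits=tuple(trait_cols))


def standardize_traits(actors: ActorTable, traits: list[str] | None = None) -> ActorTable:
    """Mean-impute missing trait values, then z-score over actors.

    Imputation happens before standardization: missing entries are replaced
    by the mean over observed actors, then the column is centred and divided
    by its sample SD (ddof=1).  Imputation counts are recorded on the
    returned table (``n_imputed``).  A trait that is entirely missing or has
    zero SD carries no information and raises.
    """
    if traits is None:
        traits = list(actors.traits)
    frame = actors.frame.copy()
    n_imputed: dict[str, int] = dict(actors.n_imputed)
    for trait in traits:
        if trait not in frame.columns:
            raise ValidationError(f"trait column {trait!r} not found")
        values = frame[trait].astype(float)
        n_missing = int(values.isna().sum())
        if n_missing == len(values):
            raise ValidationError(f"trait {trait!r} has no observed values")
        values = values.fillna(values.mean())
        sd = values.std(ddof=1)
        if not sd > 0:
            raise ValidationError(f"trait {trait!r} has zero variance")
        frame[trait] = (values - values.mean()) / sd
        n_imputed[trait] = n_missing
    return ActorTable(
        frame=frame,
        traits=tuple(dict.fromkeys(list(actors.traits) + list(traits))),
        availability=actors.availability,
        n_imputed=n_imputed,
    )


def read_event_list(path, actors: ActorTable) -> list[RawEvent]:
    """Parse an event file (dyadic or group dialect), validate, sort by onset.

    Sorting is stable: simultaneous events keep their input-file order.
    """
    frame = _read_delimited(path)
    cols = list(frame.columns)
    if {"time", "actor1", "actor2", "duration"}.issubset(cols):
        members = frame["actor1"].str.strip() + ";" + frame["actor2"].str.strip()
    elif {"time", "members", "duration"}.issubset(cols):
        members = frame["members"].str.strip()
    else:
        raise ValidationError(
            "event file must have columns (time, actor1, actor2[, setting], duration)"
            f" or (time, members[, setting], duration); got {cols}"
        )
    times = pd.to_numeric(frame["time"], errors="coerce")
    durations = pd.to_numeric(frame["duration"], errors="coerce")
    settings = (
        frame["setting"].str.strip() if "setting" in cols else pd.Series([None] * len(frame))
    )

    known = set(actors.ids)
    events: list[RawEvent] = []
    errors: list[str] = []
    for row, (t, mem, setting, dur) in enumerate(
        zip(times, members, settings, durations)
    ):
        parts = tuple(p.strip() for p in mem.split(";") if p.strip())
        unknown = [p for p in parts if p not in known]
        if unknown:
            errors.append(f"row {row}: unknown actor ids {unknown}")
            continue
        if math.isnan(t) or t < 0:
            errors.append(f"row {row}: invalid time {t}")
            continue
        try:
            events.append(
                RawEvent(time=float(t), participants=parts, setting=setting, duration=float(dur))
            )
        except ValidationError as exc:
            errors.append(f"row {row}: {exc}")
    if errors:
        raise ValidationError("invalid event rows:\n" + "\n".join(errors))
    events.sort(key=lambda e: e.time)  # list.sort is stable
    return events


def split_group_events(
    events: list[RawEvent], seed: int | None
) -> tuple[list[DyadicEvent], PreprocessReport]:
    """Decompose group interactions into spaced dyadic events.

    A raw event with m participants yields all m(m-1)/2 dyadic events in a
    seeded random order; the k-th (k = 1..M) is placed at t + k/(M+1), so
    the induced times are evenly spaced strictly inside (t, t+1) and never
    collide with the next integer minute.  Purely dyadic events (m = 2)
    keep their onset unchanged.  Every dyadic event carries the pre-spacing
    onset ``t_stat`` at which statistics are to be evaluated; spacing only
    affects waiting times.

    The returned list is stably sorted by spaced time, so simultaneous raw
    events interleave deterministically.
    """
    if seed is None:
        raise ValidationError("split_group_events requires an explicit seed")
    rng = np.random.default_rng(seed)
    dyadic: list[DyadicEvent] = []
    for gid, event in enumerate(events):
        pairs = list(combinations(event.participants, 2))
        m = len(pairs)
        if m > 1:
            pairs = [pairs[i] for i in rng.permutation(m)]
        for k, pair in enumerate(pairs, start=1):
            time = event.time if m == 1 else event.time + k / (m + 1)
            dyadic.append(
                DyadicEvent(
                    time=time,
                    t_stat=event.time,
                    actors=pair,
                    setting=event.setting,
                    duration=event.duration,
                    group_size=event.group_size,
                    group_id=gid,
                )
            )
    dyadic.sort(key=lambda e: e.time)
    n_raw, n_dyadic = len(events), len(dyadic)
    factor = expansion_log_factor(n_raw, n_dyadic) if n_raw else 0.0
    report = PreprocessReport(
        n_raw_events=n_raw, n_dyadic_events=n_dyadic, expansion_log_factor=factor
    )
    return dyadic, report


def expansion_log_factor(n_raw: int, n_dyadic: int) -> float:
    """ln(n_dyadic / n_raw): the artificial log-rate increase from splitting."""
    if n_raw <= 0 or n_dyadic <= 0:
        raise ValidationError("event counts must be positive")
    if n_dyadic < n_raw:
        raise ValidationError("dyadic count cannot be smaller than raw count")
    return math.log(n_dyadic / n_raw)
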