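"""Moving-window estimation of time-varying coefficients.

A window of fixed length slides over the event sequence in fixed steps;
the model is refitted on the events inside each window, with endogenous
statistics restricted to the window's own history and waiting times
restarted at the window start.  The sequence of per-window fits traces how
each coefficient develops over the observation period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ActorTable, DyadicEvent, FitResult, RiskSet, ValidationError
from .estimate import fit_rem
from .gof import GofResult, top_share_hit_rate
from .stats import Calendar, EffectSpec, MINUTES_PER_DAY, build_design

DEFAULT_MIN_EVENTS = 100  # below this, per-window estimates are unstable


@dataclass(frozen=True)
class Window:
    """Half-open time slice [start, end) in minutes."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"degenerate window [{self.start}, {self.end})")

    @property
    def midpoint_day(self) -> float:
        return (self.start + self.end) / 2 / MINUTES_PER_DAY

    def contains(self, t_stat: float) -> bool:
        return self.start <= t_stat < self.end


@dataclass
class WindowTrajectory:
    """Per-window fits, GoF values and event counts, ordered by window start."""

    windows: list[Window]
    fits: list[FitResult]
    gofs: list[GofResult | None]
    n_events: list[int]
    skipped: list[Window] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (window, effect)."""
        rows = []
        for window, fit, gof, n in zip(self.windows, self.fits, self.gofs, self.n_events):
            for name, est, se in zip(fit.effect_names, fit.beta, fit.se):
                rows.append(
                    {
                        "window_start": window.start,
                        "window_end": window.end,
                        "midpoint_day": window.midpoint_day,
                        "effect": name,
                        "estimate": est,
                        "se": se,
                        "bic": fit.bic,
                        "gof": gof.hit_rate if gof is not None else np.nan,
                        "n_events": n,
                    }
                )
        return pd.DataFrame(rows)


def make_windows(
    t_start: float, t_end: float, length_minutes: float, step_minutes: float
) -> list[Window]:
    """Windows [t_start + k*step, t_start + k*step + length) with end <= t_end.

    If the requested length exceeds the observed span, a single full-span
    window is returned with a warning.
    """
    if length_minutes <= 0:
        raise ValidationError("window length must be positive")
    if not 0 < step_minutes <= length_minutes:
        raise ValidationError("step must be in (0, length]")
    span = t_end - t_start
    if length_minutes > span:
        warnings.warn(
            f"window length {length_minutes} exceeds span {span}; using one window",
            stacklevel=2,
        )
        return [Window(t_start, t_end)]
    count = int((span - length_minutes) // step_minutes) + 1
    return [
        Window(t_start + k * step_minutes, t_start + k * step_minutes + length_minutes)
        for k in range(count)
    ]


def fit_moving_window(
    dyadic_events: Sequence[DyadicEvent],
    risk_set: RiskSet,
    actors: ActorTable,
    specs: Sequence[EffectSpec],
    windows: Sequence[Window],
    kind: str = "full",
    calendar: Calendar | None = None,
    min_events: int = DEFAULT_MIN_EVENTS,
    gof_share: float | None = 0.05,
    gof_seed: int | None = None,
) -> WindowTrajectory:
    """Fit the model window by window and assemble coefficient trajectories.

    Events are assigned to a window by their statistic-evaluation time
    (pre-spacing onset).  Endogenous statistics within a window use only
    the window's own events, and the first waiting time is measured from
    the window start.  Windows with fewer than ``min_events`` events are
    skipped with a warning.  A weekend effect is redundant here -- weekday/
    weekend differences show up in the per-window baselines -- so its
    presence triggers a warning.
    """
    if any(spec.kind == "weekend" for spec in specs):
        warnings.warn(
            "a weekend effect in a moving-window model is redundant: day-level "
            "rate differences are absorbed by the per-window baseline",
            stacklevel=2,
        )
    kept: list[Window] = []
    fits: list[FitResult] = []
    gofs: list[GofResult | None] = []
    counts: list[int] = []
    skipped: list[Window] = []
    for window in windows:
        subset = [e for e in dyadic_events if window.contains(e.t_stat)]
        if len(subset) < min_events:
            warnings.warn(
                f"window [{window.start}, {window.end}) holds {len(subset)} events "
                f"(< {min_events}); skipped",
                stacklevel=2,
            )
            skipped.append(window)
            continue
        design = build_design(
            subset, risk_set, actors, specs, calendar, window_start=window.start
        )
        fit = fit_rem(design, kind=kind)
        gof = (
            top_share_hit_rate(fit.beta, design, share=gof_share, seed=gof_seed)
            if gof_share is not None
            else None
        )
        kept.append(window)
        fits.append(fit)
        gofs.append(gof)
        counts.append(len(subset))
    if not kept:
        raise ValidationError("all windows were skipped; nothing to fit")
    return WindowTrajectory(
        windows=kept, fits=fits, gofs=gofs, n_events=counts, skipped=skipped
    )
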