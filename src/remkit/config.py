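"""Run configuration: YAML parsing, effect-spec lists, run records.

A run config names the input files, the models (each an ordered effect
list), the likelihood kind, calendar start weekday, window settings, GoF
share and all seeds.  Seeds are mandatory for every stochastic step
(group-split ordering, GoF tie-breaks, simulation); a config without them
fails fast instead of defaulting silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ValidationError
from .stats import EffectSpec

CANONICAL_EFFECTS: dict[str, dict] = {
    "baseline": {"kind": "baseline"},
    "both.male": {"kind": "category_pair", "attribute": "gender", "mode": "both_level", "level": "male"},
    "mixed.gender": {"kind": "category_pair", "attribute": "gender", "mode": "mixed"},
    "both.older": {"kind": "category_pair", "attribute": "age_group", "mode": "both_level", "level": "older"},
    "mixed.age": {"kind": "category_pair", "attribute": "age_group", "mode": "mixed"},
    "extraversion.min": {"kind": "trait_min", "attribute": "extraversion"},
    "extraversion.max": {"kind": "trait_max", "attribute": "extraversion"},
    "agreeableness.min": {"kind": "trait_min", "attribute": "agreeableness"},
    "agreeableness.max": {"kind": "trait_max", "attribute": "agreeableness"},
    "inertia": {"kind": "inertia"},
    "shared.partners": {"kind": "shared_partners"},
    "weekend": {"kind": "weekend"},
    "group": {"kind": "group"},
    "study": {"kind": "type_dummy", "focal_type": "study"},
    "setting.inertia": {"kind": "type_inertia"},
    "setting.shared.partners": {"kind": "type_shared_partners"},
}


def parse_effect(entry) -> EffectSpec:
    """One effect from config: a canonical name, an ``a.x.b`` interaction
    name, or a mapping with explicit fields."""
    if isinstance(entry, str):
        if entry in CANONICAL_EFFECTS:
            return EffectSpec(name=entry, **CANONICAL_EFFECTS[entry])
        if ".x." in entry:
            a, b = entry.split(".x.", 1)
            return EffectSpec(name=entry, kind="interaction", components=(a, b))
        raise ValidationError(f"unknown canonical effect name {entry!r}")
    if isinstance(entry, dict):
        entry = dict(entry)
        name = entry.pop("name")
        kind = entry.pop("kind", None)
        if kind is None:
            base = dict(CANONICAL_EFFECTS.get(name, {}))
            if not base:
                raise ValidationError(f"effect {name!r} needs an explicit kind")
            kind = base.pop("kind")
            base.update(entry)
            entry = base
        if "components" in entry:
            entry["components"] = tuple(entry["components"])
        return EffectSpec(name=name, kind=kind, **entry)
    raise ValidationError(f"cannot parse effect entry {entry!r}")


def parse_effects(entries) -> list[EffectSpec]:
    specs = [parse_effect(e) for e in entries]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate effect names in model: {names}")
    return specs


@dataclass
class RunConfig:
    actors_path: Path | None
    events_path: Path | None
    output_dir: Path
    models: list[tuple[str, list[EffectSpec]]]
    likelihood: str = "full"
    start_weekday: int = 0
    event_types: tuple[str, ...] = ()
    window_length_days: float = 3.0
    window_step_days: float = 1.0
    min_window_events: int = 100
    gof_share: float = 0.05
    seeds: dict[str, int] = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def require_seed(self, name: str) -> int:
        if name not in self.seeds:
            raise ValidationError(
                f"config must set seeds.{name} (stochastic steps need explicit seeds)"
            )
        return int(self.seeds[name])

    def require_files(self) -> None:
        for label, path in (("actors", self.actors_path), ("events", self.events_path)):
            if path is None:
                raise ValidationError(f"config must set the {label} file path")
            if not Path(path).exists():
                raise ValidationError(f"{label} file not found: {path}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} is not a mapping")
    models = []
    for model in raw.get("models", []):
        models.append((model["name"], parse_effects(model["effects"])))
    window = raw.get("window", {})
    return RunConfig(
        actors_path=Path(raw["actors"]) if "actors" in raw else None,
        events_path=Path(raw["events"]) if "events" in raw else None,
        output_dir=Path(raw.get("output_dir", ".")),
        models=models,
        likelihood=raw.get("likelihood", "full"),
        start_weekday=int(raw.get("start_weekday", 0)),
        event_types=tuple(raw.get("event_types", [])),
        window_length_days=float(window.get("length_days", 3.0)),
        window_step_days=float(window.get("step_days", 1.0)),
        min_window_events=int(window.get("min_events", 100)),
        gof_share=float(raw.get("gof_share", 0.05)),
        seeds={k: int(v) for k, v in raw.get("seeds", {}).items()},
        simulate=raw.get("simulate", {}),
    )


def config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_run_record(path: Path, record: dict) -> None:
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
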