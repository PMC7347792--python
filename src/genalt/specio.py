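"""Reading and writing the structured text formats.

World/statement specs, learning-environment specs and population specs are
YAML-dialect structured text (plain JSON is a YAML subset, so both are
accepted by the same loader).  Parsing is strict: unknown keys raise.
Tabular output is CSV with ``#``-prefixed header comments carrying the
package version, the generating command and the seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .experiment import ParticipantProfile, make_population
from .learning import Environment
from .semantics import GenericStatement
from .worldmodel import Event, World, WorldError, make_world, union_events

__all__ = [
    "WorldSpec",
    "load_world_spec",
    "parse_world_spec",
    "load_environment_spec",
    "load_population_spec",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class WorldSpec:
    """A compiled world plus its named events and statements."""

    world: World
    events: dict[str, Event]
    statements: dict[str, GenericStatement]


def _load_structured(path) -> Mapping:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise WorldError(f"{path}: top level must be a mapping")
    return data


def _compile_event(world: World, spec, name: str) -> Event:
    """Event spec: mapping var -> value or value-list (conjunction of
    memberships), or a list of such mappings (their union)."""
    if isinstance(spec, list):
        return union_events([_compile_event(world, s, name) for s in spec])
    if not isinstance(spec, Mapping):
        raise WorldError(f"event {name!r}: expected mapping or list of mappings")
    e = world.full_event()
    for var, val in spec.items():
        part = (world.event_in(var, val) if isinstance(val, (list, tuple))
                else world.event_eq(var, val))
        e = e & part
    return Event(world, e.indices, name=name)


_STATEMENT_KEYS = {"group", "feature", "alt_features", "alt_groups",
                   "background_var", "group_partition"}


def parse_world_spec(data: Mapping) -> WorldSpec:
    world = make_world(data)
    events = {
        str(name): _compile_event(world, espec, str(name))
        for name, espec in (data.get("events") or {}).items()
    }

    def ev(name, where):
        if name not in events:
            raise WorldError(f"statement {where!r} references unknown event {name!r}")
        return events[name]

    statements = {}
    for sname, sspec in (data.get("statements") or {}).items():
        unknown = set(sspec) - _STATEMENT_KEYS
        if unknown:
            raise WorldError(f"statement {sname!r}: unknown keys {sorted(unknown)}")
        statements[str(sname)] = GenericStatement(
            group=ev(sspec["group"], sname),
            feature=ev(sspec["feature"], sname),
            alt_features=tuple(ev(n, sname) for n in sspec.get("alt_features", [])),
            alt_groups=tuple(ev(n, sname) for n in sspec.get("alt_groups", [])),
            background_var=sspec.get("background_var"),
            group_partition=tuple(ev(n, sname) for n in sspec.get("group_partition", [])),
            name=str(sname),
        )
    return WorldSpec(world=world, events=events, statements=statements)


def load_world_spec(path) -> WorldSpec:
    """Load a world (+ events + statements) spec file, JSON or YAML."""
    return parse_world_spec(_load_structured(path))


def load_environment_spec(path) -> Environment:
    """Learning-environment spec: list of cue configurations.

    Format: ``{"configurations": [{"cues": [...], "probability": p,
    "outcome_prob": q}, ...]}``.
    """
    data = _load_structured(path)
    unknown = set(data) - {"configurations"}
    if unknown:
        raise WorldError(f"unknown environment keys: {sorted(unknown)}")
    cfg, out = {}, {}
    for entry in data["configurations"]:
        extra = set(entry) - {"cues", "probability", "outcome_prob"}
        if extra:
            raise WorldError(f"unknown configuration keys: {sorted(extra)}")
        key = frozenset(map(str, entry["cues"]))
        cfg[key] = float(entry["probability"])
        out[key] = float(entry["outcome_prob"])
    return Environment(configurations=cfg, outcome_probs=out)


def load_population_spec(path) -> list[ParticipantProfile]:
    """Population spec: explicit participant list, or a sized strategy mix.

    Either ``{"participants": [{"id", "strategy", "noise_sd",
    "prior_alt_prob"?}, ...]}`` or ``{"n", "shares", "noise_sd", "seed"?,
    "prior_alt_prob"?}``.
    """
    data = _load_structured(path)
    if "participants" in data:
        unknown = set(data) - {"participants"}
        if unknown:
            raise WorldError(f"unknown population keys: {sorted(unknown)}")
        profiles = []
        for entry in data["participants"]:
            extra = set(entry) - {"id", "strategy", "noise_sd", "prior_alt_prob"}
            if extra:
                raise WorldError(f"unknown participant keys: {sorted(extra)}")
            profiles.append(ParticipantProfile(
                id=str(entry["id"]), strategy=entry["strategy"],
                noise_sd=float(entry.get("noise_sd", 0.0)),
                prior_alt_prob=entry.get("prior_alt_prob")))
        return profiles
    unknown = set(data) - {"n", "shares", "noise_sd", "seed", "prior_alt_prob"}
    if unknown:
        raise WorldError(f"unknown population keys: {sorted(unknown)}")
    return make_population(
        n=int(data["n"]), shares=dict(data["shares"]),
        noise_sd=float(data.get("noise_sd", 0.0)), seed=data.get("seed"),
        prior_alt_prob=float(data.get("prior_alt_prob", 0.15)))


def write_table(df: pd.DataFrame, path, command: str = "",
                seed: Optional[int] = None) -> None:
    """Write a CSV with a commented provenance header (version, command, seed)."""
    buf = io.StringIO()
    buf.write(f"# genalt {__version__}\n")
    if command:
        buf.write(f"# command: {command}\n")
    buf.write(f"# seed: {seed}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (or any plain CSV)."""
    return pd.read_csv(path, comment="#")
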