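"""Configuration loading and text-based snapshot persistence.

Snapshots are a JSON dialect chosen for diffability: schema-versioned, fully
lossless for all state fields (floats round-trip via Python's repr), and
human-inspectable.  Run configurations are TOML or JSON; unknown keys are
rejected and all validation problems are reported together.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

from .chemistry import ChemParams
from .driver import SimulationConfig, genotype_preset
from .mechanics import MechanicsParams
from .mesh import DivisionNoise, TissueMesh, validate_mesh

SNAPSHOT_SCHEMA = "auxindisk-snapshot-1"


class SnapshotError(RuntimeError):
    pass


class ConfigError(ValueError):
    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.problems))


# -- snapshots ----------------------------------------------------------------


def write_snapshot(mesh: TissueMesh, path, config_digest=None) -> None:
    doc = {
        "schema": SNAPSHOT_SCHEMA,
        "iteration": mesh.iteration,
        "config_digest": config_digest,
        "vertices": [[v.id, float(v.pos[0]), float(v.pos[1])]
                     for v in mesh.vertices.values()],
        "walls": [[w.id, w.v1, w.v2, w.rest_length, list(w.cells),
                   [[cid, p] for cid, p in w.pin.items()]]
                  for w in mesh.walls.values()],
        "cells": [[c.id, list(c.wall_ids), c.aux, c.cuc, c.delta_aux]
                  for c in mesh.cells.values()],
    }
    Path(path).write_text(json.dumps(doc, separators=(",", ":")) + "\n")


def read_snapshot(path, validate: bool = True) -> TissueMesh:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SnapshotError(f"{path}: not valid JSON: {exc}") from exc
    if doc.get("schema") != SNAPSHOT_SCHEMA:
        raise SnapshotError(
            f"{path}: schema {doc.get('schema')!r} != {SNAPSHOT_SCHEMA!r}")
    mesh = TissueMesh()
    mesh.iteration = int(doc.get("iteration", 0))
    for vid, x, y in doc["vertices"]:
        mesh.add_vertex((x, y), vid=vid)
    missing_pin = []
    for wid, v1, v2, rest, cells, pin in doc["walls"]:
        if rest is None:
            try:
                d = mesh.vertices[v2].pos - mesh.vertices[v1].pos
            except KeyError as exc:
                raise SnapshotError(f"{path}: wall {wid} endpoint missing") from exc
            rest = float((d[0] ** 2 + d[1] ** 2) ** 0.5)
        mesh.add_wall(v1, v2, rest, cells,
                      {} if pin is None else {cid: p for cid, p in pin},
                      wid=wid)
        if pin is None:
            missing_pin.append(wid)
    for cid, wids, aux, cuc, delta in doc["cells"]:
        mesh.add_cell(wids, cid=cid, aux=aux, cuc=cuc, delta_aux=delta)
    if missing_pin and len(missing_pin) == len(mesh.walls):
        from .chemistry import init_pin
        init_pin(mesh)
    if validate:
        problems = validate_mesh(mesh)
        if problems:
            raise SnapshotError(f"{path}: invalid mesh: "
                                + "; ".join(problems[:10]))
    from .mesh import update_areas
    update_areas(mesh)
    return mesh


# -- configuration ------------------------------------------------------------

_TOP_KEYS = {
    "genotype": str,
    "growth_rate": (int, float),
    "n_iterations": int,
    "seed": int,
    "snapshot_every": int,
    "division_area_thres": (int, float),
    "max_wall_len": (int, float),
    "frozen_noise": bool,
    "output_dir": str,
}
_SECTIONS = {
    "mechanics": MechanicsParams,
    "chemistry": ChemParams,
    "division_noise": DivisionNoise,
}


def load_config(path) -> SimulationConfig:
    """Load and fully resolve a run configuration (TOML or JSON).

    An empty file yields all defaults (WT, growth rate 0.8, 100 iterations).
    Unknown keys, type mismatches and out-of-range values are aggregated into
    a single ConfigError.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        data = {}
    elif path.suffix == ".toml":
        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    return config_from_dict(data)


def config_from_dict(data: dict) -> SimulationConfig:
    problems = []
    kwargs = {}
    for key, value in data.items():
        if key in _TOP_KEYS:
            want = _TOP_KEYS[key]
            if not isinstance(value, want) or isinstance(value, bool) != (want is bool):
                problems.append(f"{key}: expected {want}, got {value!r}")
            elif key != "output_dir":
                kwargs[key] = value
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            names = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - names
            if bad:
                problems.append(f"{key}: unknown keys {sorted(bad)}")
                continue
            try:
                kwargs[key] = cls(**value)
            except (TypeError, ValueError) as exc:
                problems.append(f"{key}: {exc}")
        else:
            problems.append(f"unknown key {key!r}")
    if "genotype" in kwargs:
        try:
            kwargs["genotype"] = genotype_preset(kwargs["genotype"])
        except ValueError as exc:
            problems.append(str(exc))
    if problems:
        raise ConfigError(problems)
    try:
        return SimulationConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError([str(exc)])


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["genotype"] = config.genotype.name
    return d


def config_digest(config: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
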