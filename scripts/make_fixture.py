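"""Regenerate the packaged default initial disk (73 cells, 348 walls).

The disk is produced by auxindisk.mesh.build_disk with a frozen seed and a
boundary subdivision tuned so the wall count is exact; positions are rounded
to 1e-6 µm so the file is stable.  Rest lengths and PIN are stored as null
and derived at load time (rest = current length, PIN apolar).
"""

import json
from pathlib import Path

import numpy as np

from auxindisk import build_disk, validate_mesh
from auxindisk.io import SNAPSHOT_SCHEMA

SEED = 2
RADIUS = 27.0
OUT = Path(__file__).resolve().parents[1] / "src/auxindisk/data/default_disk.json"


def main():
    mesh = build_disk(73, RADIUS, seed=SEED, total_walls=348)
    for v in mesh.vertices.values():
        v.pos = np.round(v.pos, 6)
    assert len(mesh.cells) == 73 and len(mesh.walls) == 348
    assert not validate_mesh(mesh)
    doc = {
        "schema": SNAPSHOT_SCHEMA,
        "iteration": 0,
        "config_digest": None,
        "vertices": [[v.id, float(v.pos[0]), float(v.pos[1])]
                     for v in sorted(mesh.vertices.values(), key=lambda v: v.id)],
        "walls": [[w.id, w.v1, w.v2, None, list(w.cells), None]
                  for w in sorted(mesh.walls.values(), key=lambda w: w.id)],
        "cells": [[c.id, list(c.wall_ids), 0.0, 0.0, 1.0]
                  for c in sorted(mesh.cells.values(), key=lambda c: c.id)],
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(doc, separators=(",", ":")) + "\n")
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
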