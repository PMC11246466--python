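import numpy as np
import pytest

from auxindisk.mesh import TissueMesh, update_areas


def mesh_from_polygons(polys) -> TissueMesh:
    """Build a TissueMesh from CCW vertex-coordinate loops.

    Vertices and walls shared between polygons (matched by rounded
    coordinates / vertex pairs) are created once, so adjacent polygons become
    neighbouring cells.
    """
    m = TissueMesh()
    vid_of = {}
    wall_of = {}
    for poly in polys:
        ids = []
        for p in poly:
            key = (round(float(p[0]), 9), round(float(p[1]), 9))
            if key not in vid_of:
                vid_of[key] = m.add_vertex(p)
            ids.append(vid_of[key])
        cid = m.add_cell([])
        wids = []
        for a, b in zip(ids, ids[1:] + ids[:1]):
            key = (min(a, b), max(a, b))
            if key not in wall_of:
                d = m.vertices[b].pos - m.vertices[a].pos
                wall_of[key] = m.add_wall(a, b, float(np.hypot(*d)), ())
            w = m.walls[wall_of[key]]
            if cid not in w.cells:
                w.cells = w.cells + (cid,)
            wids.append(wall_of[key])
        m.cells[cid].wall_ids = wids
    update_areas(m)
    return m


def rectangle_mesh(w=10.0, h=4.0) -> TissueMesh:
    return mesh_from_polygons([[(0, 0), (w, 0), (w, h), (0, h)]])


def three_cell_strip() -> TissueMesh:
    """Three unit-height cells in a row; interior interfaces have length 1."""
    return mesh_from_polygons([
        [(0, 0), (1, 0), (1, 1), (0, 1)],
        [(1, 0), (2, 0), (2, 1), (1, 1)],
        [(2, 0), (3, 0), (3, 1), (2, 1)],
    ])


def unequal_neighbor_mesh() -> TissueMesh:
    """Centre cell with interior interfaces of lengths 1 (A) and 2 (C)."""
    A = [(0, 0), (2, 0), (2, 1), (0, 1)]
    B = [(2, 0), (4, 0), (4, 3), (2, 3), (2, 1)]
    C = [(0, 1), (2, 1), (2, 3), (0, 3)]
    return mesh_from_polygons([A, B, C])


@pytest.fixture(scope="session")
def default_disk():
    from auxindisk import load_default_disk

    return load_default_disk()


@pytest.fixture()
def disk(default_disk):
    return default_disk.copy()
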