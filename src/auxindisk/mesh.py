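"""Polygonal tissue geometry and topology.

The simulated meristem is a planar mesh: vertices joined by straight wall
segments (the springs of the mechanical model), grouped into simple polygonal
cells.  Interior walls separate exactly two cells; boundary walls have exactly
one incident cell and form the outer rim of the disk on which turgor pressure
acts.  Cells carry the chemical state (auxin, CUC, the per-cell production
noise multiplier) and each wall segment carries a PIN allocation per incident
cell side.

Topological operations -- wall subdivision and cell division by the
minimal-wall-length rule -- conserve total tissue area and apportion wall
state (rest lengths, PIN) proportionally to the new segment lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """A polygon or wall is degenerate (self-intersecting, zero length...)."""


class MeshLoadError(RuntimeError):
    """The packaged initial-disk fixture is missing or corrupt."""


# Per-side PIN seeded on a freshly created division wall, before the daughter
# cells are renormalised to a unit PIN sum.
NEW_WALL_PIN = 1e-6


@dataclass
class Vertex:
    id: int
    pos: np.ndarray  # (2,) float64, µm


@dataclass
class WallSegment:
    id: int
    v1: int
    v2: int
    rest_length: float
    cells: tuple  # ids of the 1 (boundary) or 2 (interior) incident cells
    pin: dict = field(default_factory=dict)  # cell id -> PIN allocation >= 0


@dataclass
class Cell:
    id: int
    wall_ids: list  # ordered CCW loop of wall ids
    aux: float = 0.0
    cuc: float = 0.0
    delta_aux: float = 1.0
    area: float = 0.0  # cached; refreshed by cell_area / update_areas


@dataclass
class DivisionNoise:
    """Gaussian noise (SD, µm) applied by the minimal-wall-length division rule.

    cell_center_sd displaces the centroid the candidate planes pass through;
    cell_division_sd perturbs each candidate plane's chord-length score before
    the minimum is taken; wall_junction_sd displaces each junction point along
    its intersected wall (clamped inside the wall).
    """

    cell_division_sd: float = 2.0
    cell_center_sd: float = 2.0
    wall_junction_sd: float = 2.0


class TissueMesh:
    """Vertices, wall segments, and polygonal cells of the simulated disk."""

    def __init__(self):
        self.vertices: dict[int, Vertex] = {}
        self.walls: dict[int, WallSegment] = {}
        self.cells: dict[int, Cell] = {}
        self.iteration = 0
        self.warnings: list[str] = []
        self._next_vid = 0
        self._next_wid = 0
        self._next_cid = 0

    # -- construction helpers -------------------------------------------------

    def add_vertex(self, pos, vid=None) -> int:
        if vid is None:
            vid = self._next_vid
        self.vertices[vid] = Vertex(vid, np.asarray(pos, dtype=float).copy())
        self._next_vid = max(self._next_vid, vid + 1)
        return vid

    def add_wall(self, v1, v2, rest_length, cells, pin=None, wid=None) -> int:
        if wid is None:
            wid = self._next_wid
        self.walls[wid] = WallSegment(wid, v1, v2, float(rest_length),
                                      tuple(cells), dict(pin or {}))
        self._next_wid = max(self._next_wid, wid + 1)
        return wid

    def add_cell(self, wall_ids, cid=None, **state) -> int:
        if cid is None:
            cid = self._next_cid
        self.cells[cid] = Cell(cid, list(wall_ids), **state)
        self._next_cid = max(self._next_cid, cid + 1)
        return cid

    # -- basic queries --------------------------------------------------------

    def wall_length(self, wall) -> float:
        if isinstance(wall, int):
            wall = self.walls[wall]
        d = self.vertices[wall.v2].pos - self.vertices[wall.v1].pos
        return float(math.hypot(d[0], d[1]))

    def is_boundary(self, wall) -> bool:
        if isinstance(wall, int):
            wall = self.walls[wall]
        return len(wall.cells) == 1

    def copy(self) -> "TissueMesh":
        m = TissueMesh()
        for v in self.vertices.values():
            m.vertices[v.id] = Vertex(v.id, v.pos.copy())
        for w in self.walls.values():
            m.walls[w.id] = WallSegment(w.id, w.v1, w.v2, w.rest_length,
                                        w.cells, dict(w.pin))
        for c in self.cells.values():
            m.cells[c.id] = Cell(c.id, list(c.wall_ids), c.aux, c.cuc,
                                 c.delta_aux, c.area)
        m.iteration = self.iteration
        m.warnings = list(self.warnings)
        m._next_vid, m._next_wid, m._next_cid = (self._next_vid,
                                                 self._next_wid,
                                                 self._next_cid)
        return m

    def transform(self, rotation_deg=0.0, translation=(0.0, 0.0)) -> "TissueMesh":
        """Rigidly transformed copy (used for equivariance checks)."""
        th = math.radians(rotation_deg)
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        t = np.asarray(translation, dtype=float)
        m = self.copy()
        for v in m.vertices.values():
            v.pos = R @ v.pos + t
        return m


# -- cell loops and areas -----------------------------------------------------


def oriented_walls(mesh: TissueMesh, cell: Cell):
    """Return (ordered (wall_id, forward) pairs, ordered vertex-id loop).

    The loop vertex i is shared by walls i-1 and i; wall i runs from loop
    vertex i to loop vertex i+1.  ``forward`` is True when the cell traverses
    the wall from v1 to v2.
    """
    wids = cell.wall_ids
    n = len(wids)
    if n < 3:
        raise GeometryError(f"cell {cell.id} has fewer than 3 walls")
    loop = []
    oriented = []
    walls = mesh.walls
    prev = walls[wids[-1]]
    for i in range(n):
        cur = walls[wids[i]]
        # fast path: exactly one endpoint shared with the previous wall
        a1 = cur.v1 == prev.v1 or cur.v1 == prev.v2
        a2 = cur.v2 == prev.v1 or cur.v2 == prev.v2
        if a1 != a2:
            v = cur.v1 if a1 else cur.v2
            loop.append(v)
            oriented.append((cur.id, cur.v1 == v))
            prev = cur
            continue
        shared = {prev.v1, prev.v2} & {cur.v1, cur.v2}
        if len(shared) != 1:
            # ambiguous (two walls sharing both endpoints) or broken loop
            if not shared:
                raise GeometryError(
                    f"cell {cell.id}: walls {prev.id} and {cur.id} not adjacent")
            # two-vertex lens: disambiguate using the wall after `cur`
            nxt = mesh.walls[wids[(i + 1) % n]]
            nxt_shared = {nxt.v1, nxt.v2} & {cur.v1, cur.v2}
            shared = shared - nxt_shared or shared
        v = next(iter(shared))
        loop.append(v)
        oriented.append((cur.id, cur.v1 == v))
        prev = cur
    return oriented, loop


def cell_vertex_loop(mesh: TissueMesh, cell) -> list:
    if isinstance(cell, int):
        cell = mesh.cells[cell]
    return oriented_walls(mesh, cell)[1]


def _loop_positions(mesh, loop):
    return np.array([mesh.vertices[v].pos for v in loop])


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _polygon_centroid(pts: np.ndarray):
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cr = x * yn - xn * y
    a = 0.5 * cr.sum()
    if abs(a) < 1e-300:
        return pts.mean(axis=0)
    cx = ((x + xn) * cr).sum() / (6 * a)
    cy = ((y + yn) * cr).sum() / (6 * a)
    return np.array([cx, cy])


def _segments_intersect(p1, p2, p3, p4) -> bool:
    d1, d2 = p2 - p1, p4 - p3
    den = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(den) < 1e-14:
        return False
    r = p3 - p1
    t = (r[0] * d2[1] - r[1] * d2[0]) / den
    s = (r[0] * d1[1] - r[1] * d1[0]) / den
    eps = 1e-9
    return eps < t < 1 - eps and eps < s < 1 - eps


def _is_simple(pts: np.ndarray) -> bool:
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(pts[i], pts[(i + 1) % n],
                                   pts[j], pts[(j + 1) % n]):
                return False
    return True


def cell_area(cell, mesh: TissueMesh, check_simple=False) -> float:
    """Positive shoelace area (µm²) of the cell's ordered vertex loop."""
    if isinstance(cell, int):
        cell = mesh.cells[cell]
    pts = _loop_positions(mesh, cell_vertex_loop(mesh, cell))
    if check_simple and not _is_simple(pts):
        raise GeometryError(f"cell {cell.id} polygon is self-intersecting")
    a = _signed_area(pts)
    if a < 0:
        # normalise stored orientation to CCW
        cell.wall_ids.reverse()
        a = -a
    if a <= 0:
        raise GeometryError(f"cell {cell.id} has non-positive area")
    cell.area = a
    return a


def update_areas(mesh: TissueMesh) -> None:
    for c in mesh.cells.values():
        cell_area(c, mesh)


# -- wall subdivision ---------------------------------------------------------


def split_wall(mesh: TissueMesh, wall_id: int, points):
    """Split a wall at interior points (ordered from v1 towards v2).

    Rest length and each side's PIN are apportioned proportionally to the new
    sub-segment lengths.  Incident cells' ordered wall lists are updated in
    place.  Returns (new wall ids ordered v1->v2, new vertex ids).
    """
    w = mesh.walls[wall_id]
    p1 = mesh.vertices[w.v1].pos
    pts = [np.asarray(p, dtype=float) for p in points]
    if not pts:
        return [wall_id], []
    new_vids = [mesh.add_vertex(p) for p in pts]
    chain = [w.v1] + new_vids + [w.v2]
    seg_len = np.array([
        float(np.hypot(*(mesh.vertices[b].pos - mesh.vertices[a].pos)))
        for a, b in zip(chain[:-1], chain[1:])])
    total = seg_len.sum()
    if total <= 0:
        raise GeometryError(f"wall {wall_id}: zero total length on split")
    frac = seg_len / total
    new_wids = []
    for (a, b), f in zip(zip(chain[:-1], chain[1:]), frac):
        pin = {cid: p * f for cid, p in w.pin.items()}
        new_wids.append(mesh.add_wall(a, b, w.rest_length * f, w.cells, pin))
    del mesh.walls[wall_id]
    for cid in w.cells:
        cell = mesh.cells[cid]
        k = cell.wall_ids.index(wall_id)
        forward = _traverses_forward(mesh, cell, k, w)
        repl = new_wids if forward else list(reversed(new_wids))
        cell.wall_ids[k:k + 1] = repl
    return new_wids, new_vids


def _traverses_forward(mesh, cell, k, wall) -> bool:
    """Does `cell` traverse `wall` (at index k of its loop) from v1 to v2?"""
    n = len(cell.wall_ids)
    prev = mesh.walls[cell.wall_ids[(k - 1) % n]]
    nxt = mesh.walls[cell.wall_ids[(k + 1) % n]]
    prev_shared = {prev.v1, prev.v2} & {wall.v1, wall.v2}
    nxt_shared = {nxt.v1, nxt.v2} & {wall.v1, wall.v2}
    if prev_shared == {wall.v1} or nxt_shared == {wall.v2}:
        return True
    if prev_shared == {wall.v2} or nxt_shared == {wall.v1}:
        return False
    # fall back: walk the whole loop
    ordered, _ = oriented_walls(mesh, cell)
    return dict(ordered)[wall.id]


def split_long_walls(mesh: TissueMesh, max_len: float = 1.0) -> TissueMesh:
    """Replace every wall longer than max_len by ceil(len/max_len) equal parts."""
    for wid in list(mesh.walls):
        w = mesh.walls[wid]
        a = mesh.vertices[w.v1].pos
        b = mesh.vertices[w.v2].pos
        length = float(np.hypot(*(b - a)))
        n = math.ceil(length / max_len - 1e-12)
        if n <= 1:
            continue
        pts = [a + (b - a) * (i / n) for i in range(1, n)]
        split_wall(mesh, wid, pts)
    return mesh


# -- cell division ------------------------------------------------------------


def divide_cell(mesh: TissueMesh, cell, noise: DivisionNoise | None = None,
                rng=None) -> TissueMesh:
    """Divide a cell by the minimal-wall-length rule.

    Candidate division planes are 180 orientations at 1° spacing through the
    (noise-displaced) centroid; the plane whose chord through the polygon has
    the smallest (noise-perturbed) length wins.  Junction points are displaced
    along their walls by junction noise, clamped inside the wall.  Daughters
    inherit aux, cuc and delta_aux unchanged; split walls apportion PIN by
    length; the new wall gets an infinitesimal PIN on both sides and each
    daughter's PIN allocation is renormalised to sum 1.
    """
    if isinstance(cell, int):
        cell = mesh.cells[cell]
    noise = noise or DivisionNoise()
    rng = np.random.default_rng() if rng is None else rng

    _, loop = oriented_walls(mesh, cell)
    pts = _loop_positions(mesh, loop)
    if _signed_area(pts) < 0:
        cell.wall_ids.reverse()
        _, loop = oriented_walls(mesh, cell)
        pts = _loop_positions(mesh, loop)

    # noisy plane selection; fall back to the noiseless minimal chord when the
    # noisy one would produce a degenerate (sliver) daughter
    plan = _plan_division(mesh, cell, pts, noise, rng)
    if plan is None and (noise.cell_center_sd > 0 or noise.cell_division_sd > 0
                         or noise.wall_junction_sd > 0):
        plan = _plan_division(mesh, cell, pts, DivisionNoise(0.0, 0.0, 0.0), rng)
    if plan is None:
        mesh.warnings.append(f"division skipped: cell {cell.id} degenerate")
        return mesh
    (i1, s1, j1), (i2, s2, j2) = plan
    n = len(loop)

    ordered, _ = oriented_walls(mesh, cell)
    nv1, split1 = _split_loop_edge(mesh, ordered[i1], j1)
    ordered2, _ = oriented_walls(mesh, cell)
    # after the first split the loop gained one vertex at position i1,
    # shifting later edge indices by one
    i2b = i2 + 1 if (split1 and i2 > i1) else i2
    nv2, _ = _split_loop_edge(mesh, ordered2[i2b], j2)

    _, loop = oriented_walls(mesh, cell)
    k1, k2 = loop.index(nv1), loop.index(nv2)
    wids = cell.wall_ids
    m = len(wids)
    # wall i of the loop runs from loop vertex i to i+1
    arc_a = [wids[i % m] for i in range(k1, k1 + (k2 - k1) % m)]
    arc_b = [wids[i % m] for i in range(k2, k2 + (k1 - k2) % m)]
    if not arc_a or not arc_b:
        mesh.warnings.append(f"division skipped: cell {cell.id} empty arc")
        return mesh

    rest = float(np.hypot(*(j2 - j1)))
    if rest <= 0:
        mesh.warnings.append(f"division skipped: cell {cell.id} zero chord")
        return mesh

    state = dict(aux=cell.aux, cuc=cell.cuc, delta_aux=cell.delta_aux)
    ca = mesh.add_cell([], **state)
    cb = mesh.add_cell([], **state)
    nw = mesh.add_wall(nv1, nv2, rest, (ca, cb),
                       {ca: NEW_WALL_PIN, cb: NEW_WALL_PIN})
    # daughter A runs nv1 -> ... -> nv2 then back along the new wall
    mesh.cells[ca].wall_ids = arc_a + [nw]
    mesh.cells[cb].wall_ids = arc_b + [nw]
    for d, arc in ((ca, arc_a), (cb, arc_b)):
        for wid in arc:
            w = mesh.walls[wid]
            w.cells = tuple(d if c == cell.id else c for c in w.cells)
            if cell.id in w.pin:
                w.pin[d] = w.pin.pop(cell.id)
    del mesh.cells[cell.id]
    for d in (ca, cb):
        _renormalise_pin(mesh, mesh.cells[d])
        cell_area(mesh.cells[d], mesh)
    return mesh


def _plan_division(mesh, cell, pts, noise, rng, min_area_frac=0.2):
    """Pick a division chord; returns ((edge, s, point), (edge, s, point)).

    Returns None when no valid chord exists, when both junctions fall on the
    same wall, or when a prospective daughter would hold less than
    min_area_frac of the parent area (numerical degeneracy guard).
    """
    centroid = _polygon_centroid(pts)
    center = centroid
    if noise.cell_center_sd > 0:
        center = centroid + rng.normal(0.0, noise.cell_center_sd, 2)
        if not _point_in_polygon(center, pts):
            center = centroid
    sel = _min_length_chord(pts, center, noise.cell_division_sd, rng)
    if sel is None:
        return None
    (i1, s1), (i2, s2) = sel
    if i1 == i2:
        return None
    n = len(pts)
    edge_lens = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)
    if noise.wall_junction_sd > 0:
        s1 += rng.normal(0.0, noise.wall_junction_sd) / edge_lens[i1]
        s2 += rng.normal(0.0, noise.wall_junction_sd) / edge_lens[i2]
    s1 = min(max(s1, 0.05), 0.95)
    s2 = min(max(s2, 0.05), 0.95)
    j1 = pts[i1] + s1 * (pts[(i1 + 1) % n] - pts[i1])
    j2 = pts[i2] + s2 * (pts[(i2 + 1) % n] - pts[i2])
    # prospective daughter areas
    piece = [j1] + [pts[k % n] for k in range(i1 + 1, i1 + 1 + (i2 - i1) % n)] + [j2]
    a_piece = abs(_signed_area(np.array(piece)))
    a_total = abs(_signed_area(pts))
    if min(a_piece, a_total - a_piece) < min_area_frac * a_total:
        return None
    return (i1, s1, j1), (i2, s2, j2)


def _renormalise_pin(mesh, cell):
    total = sum(mesh.walls[w].pin.get(cell.id, 0.0) for w in cell.wall_ids)
    if total > 0:
        for w in cell.wall_ids:
            pin = mesh.walls[w].pin
            if cell.id in pin:
                pin[cell.id] /= total


def _split_loop_edge(mesh, oriented_entry, point, snap=0.1):
    """Split the wall behind one loop edge at `point`.

    Returns (vertex id, split happened).  A junction within `snap` µm of an
    existing endpoint reuses that endpoint instead of splitting, so divisions
    never create sliver segments much shorter than `snap`.
    """
    wid, _forward = oriented_entry
    w = mesh.walls[wid]
    for vid in (w.v1, w.v2):
        if np.hypot(*(mesh.vertices[vid].pos - point)) < snap:
            return vid, False
    _, new_vids = split_wall(mesh, wid, [point])
    return new_vids[0], True


def _point_in_polygon(p, pts) -> bool:
    x, y = p
    n = len(pts)
    inside = False
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xint:
                inside = not inside
    return inside


def _min_length_chord(pts, center, score_sd, rng, n_orient=180):
    """Minimal (noise-scored) chord through `center` across the polygon.

    Returns ((edge_index, fraction), (edge_index, fraction)) for the two
    junctions, or None if no valid chord exists.
    """
    a = pts
    e = np.roll(pts, -1, axis=0) - pts  # (m,2) edge vectors
    th = np.deg2rad(np.arange(n_orient, dtype=float))
    d = np.stack([np.cos(th), np.sin(th)], axis=1)  # (K,2)
    r = a - center  # (m,2)
    den = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (r[None, :, 0] * e[None, :, 1] - r[None, :, 1] * e[None, :, 0]) / den
        s = (r[None, :, 0] * d[:, None, 1] - r[None, :, 1] * d[:, None, 0]) / den
    valid = (np.abs(den) > 1e-12) & (s >= 0.0) & (s < 1.0) & np.isfinite(t)
    t_pos = np.where(valid & (t > 0), t, np.inf).min(axis=1)
    t_neg = np.where(valid & (t <= 0), t, -np.inf).max(axis=1)
    chord = t_pos - t_neg
    ok = np.isfinite(chord)
    if not ok.any():
        return None
    score = chord.copy()
    if score_sd > 0:
        score = score + rng.normal(0.0, score_sd, n_orient)
    score[~ok] = np.inf
    k = int(np.argmin(score))
    ip = int(np.where(valid[k] & (t[k] > 0), t[k], np.inf).argmin())
    im = int(np.where(valid[k] & (t[k] <= 0), t[k], -np.inf).argmax())
    return (ip, float(s[k, ip])), (im, float(s[k, im]))


# -- validation ---------------------------------------------------------------


def validate_mesh(mesh: TissueMesh, pin_normalised=False) -> list:
    """Check structural invariants; returns a list of violation strings."""
    out = []
    for v in mesh.vertices.values():
        if not np.all(np.isfinite(v.pos)):
            out.append(f"vertex {v.id}: non-finite position")
    for w in mesh.walls.values():
        for vid in (w.v1, w.v2):
            if vid not in mesh.vertices:
                out.append(f"wall {w.id}: missing endpoint {vid}")
        if not (w.rest_length > 0):
            out.append(f"wall {w.id}: non-positive rest length")
        if len(w.cells) not in (1, 2):
            out.append(f"wall {w.id}: {len(w.cells)} incident cells")
        for cid in w.cells:
            if cid not in mesh.cells:
                out.append(f"wall {w.id}: missing incident cell {cid}")
            elif w.id not in mesh.cells[cid].wall_ids:
                out.append(f"wall {w.id}: not listed by incident cell {cid}")
        for cid, p in w.pin.items():
            if cid not in w.cells:
                out.append(f"wall {w.id}: PIN for non-incident cell {cid}")
            if p < 0:
                out.append(f"wall {w.id}: negative PIN")
    for c in mesh.cells.values():
        for wid in c.wall_ids:
            if wid not in mesh.walls:
                out.append(f"cell {c.id}: missing wall {wid}")
                break
            if c.id not in mesh.walls[wid].cells:
                out.append(f"cell {c.id}: wall {wid} does not list it")
        else:
            endpoints_ok = all(
                mesh.walls[w].v1 in mesh.vertices
                and mesh.walls[w].v2 in mesh.vertices
                for w in c.wall_ids)
            if not endpoints_ok:
                out.append(f"cell {c.id}: wall endpoints missing")
                continue
            try:
                a = cell_area(c, mesh, check_simple=len(c.wall_ids) <= 40)
                if a <= 0:
                    out.append(f"cell {c.id}: non-positive area")
            except GeometryError as exc:
                out.append(f"cell {c.id}: {exc}")
        if not (c.aux >= 0 and c.cuc >= 0 and c.delta_aux >= 0):
            out.append(f"cell {c.id}: negative concentration or noise")
    V, E, C = len(mesh.vertices), len(mesh.walls), len(mesh.cells)
    if V - E + C != 1:
        out.append(f"Euler relation violated: V-E+C = {V - E + C} != 1")
    if pin_normalised:
        for c in mesh.cells.values():
            interior = [w for w in c.wall_ids
                        if w in mesh.walls and len(mesh.walls[w].cells) == 2]
            if not interior:
                continue
            total = sum(mesh.walls[w].pin.get(c.id, 0.0) for w in c.wall_ids
                        if w in mesh.walls)
            if abs(total - 1.0) > 1e-6:
                out.append(f"cell {c.id}: PIN sum {total} != 1")
    return out


# -- disk construction --------------------------------------------------------


def build_disk(target_cells: int, radius: float, seed: int,
               lloyd_iters: int = 6, boundary_spacing: float = 1.2,
               total_walls: int | None = None,
               min_wall_len: float = 0.25) -> TissueMesh:
    """Build a roughly round polygonal disk of about `target_cells` cells.

    Cells are a Lloyd-relaxed Voronoi tessellation of seed points in the disk
    (points mirrored across the rim keep all regions finite, so the rim is a
    polygon of near-tangent chords).  Boundary walls are subdivided to about
    `boundary_spacing` µm, or -- when `total_walls` is given -- so that the
    total wall count is exactly `total_walls`.
    """
    if target_cells < 1:
        raise ValueError("target_cells must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if target_cells == 1:
        return _single_cell_disk(radius)

    from scipy.spatial import Voronoi

    rng = np.random.default_rng(seed)
    r = radius * 0.92 * np.sqrt(rng.random(target_cells))
    th = rng.random(target_cells) * 2 * np.pi
    pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)

    def mirrored(p):
        d = np.hypot(p[:, 0], p[:, 1])
        d = np.maximum(d, 1e-9)
        scale = (2 * radius - d) / d
        return p * scale[:, None]

    vor = None
    for _ in range(lloyd_iters + 1):
        vor = Voronoi(np.vstack([pts, mirrored(pts)]))
        new_pts = []
        for i in range(target_cells):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or not region:
                new_pts.append(pts[i])
                continue
            new_pts.append(_polygon_centroid(vor.vertices[region]))
        pts = np.array(new_pts)

    mesh = TissueMesh()
    vid_of = {}
    wall_of = {}
    for i in range(target_cells):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise GeometryError("unbounded Voronoi region in disk build")
        poly = vor.vertices[region]
        if _signed_area(poly) < 0:
            region = region[::-1]
        wids = []
        for a, b in zip(region, region[1:] + region[:1]):
            for vv in (a, b):
                if vv not in vid_of:
                    vid_of[vv] = mesh.add_vertex(vor.vertices[vv])
            key = (min(a, b), max(a, b))
            if key not in wall_of:
                length = float(np.hypot(*(vor.vertices[b] - vor.vertices[a])))
                wall_of[key] = mesh.add_wall(vid_of[a], vid_of[b], length, ())
            wids.append(wall_of[key])
        cid = mesh.add_cell(wids)
        for wid in wids:
            w = mesh.walls[wid]
            w.cells = w.cells + (cid,)

    _collapse_short_walls(mesh, min_wall_len)
    _subdivide_boundary(mesh, boundary_spacing, total_walls)
    for w in mesh.walls.values():
        w.rest_length = mesh.wall_length(w)
    update_areas(mesh)
    problems = validate_mesh(mesh)
    if problems:
        raise GeometryError("disk build produced invalid mesh: "
                            + "; ".join(problems[:5]))
    return mesh


def _single_cell_disk(radius, n_sides=24) -> TissueMesh:
    mesh = TissueMesh()
    th = np.linspace(0, 2 * np.pi, n_sides, endpoint=False)
    vids = [mesh.add_vertex((radius * math.cos(t), radius * math.sin(t)))
            for t in th]
    cid = mesh.add_cell([])
    wids = []
    for a, b in zip(vids, vids[1:] + vids[:1]):
        length = mesh.wall_length(WallSegment(-1, a, b, 1.0, ()))
        wids.append(mesh.add_wall(a, b, length, (cid,)))
    mesh.cells[cid].wall_ids = wids
    update_areas(mesh)
    return mesh


def _collapse_short_walls(mesh, min_len):
    """Collapse near-degenerate construction edges onto their midpoint.

    Short Voronoi edges would become extremely stiff springs; collapsing one
    merges its endpoints (Euler relation preserved).  A collapse is skipped
    when an incident cell would drop below 4 walls.
    """
    changed = True
    while changed:
        changed = False
        for wid in sorted(mesh.walls, key=lambda w: mesh.wall_length(w)):
            w = mesh.walls.get(wid)
            if w is None or mesh.wall_length(w) >= min_len:
                continue
            if any(len(mesh.cells[c].wall_ids) <= 3 for c in w.cells):
                continue
            keep, drop = w.v1, w.v2
            mid = 0.5 * (mesh.vertices[keep].pos + mesh.vertices[drop].pos)
            mesh.vertices[keep].pos = mid
            del mesh.vertices[drop]
            del mesh.walls[wid]
            for other in mesh.walls.values():
                if other.v1 == drop:
                    other.v1 = keep
                if other.v2 == drop:
                    other.v2 = keep
            for cid in w.cells:
                mesh.cells[cid].wall_ids.remove(wid)
            changed = True
            break


def _subdivide_boundary(mesh, spacing, total_walls):
    bwalls = [w.id for w in mesh.walls.values() if len(w.cells) == 1]
    lengths = {wid: mesh.wall_length(wid) for wid in bwalls}
    if total_walls is None:
        pieces = {wid: max(1, math.ceil(lengths[wid] / spacing))
                  for wid in bwalls}
    else:
        extras = total_walls - len(mesh.walls)
        if extras < 0:
            raise ValueError(
                f"total_walls={total_walls} below current count {len(mesh.walls)}")
        pieces = {wid: 1 for wid in bwalls}
        # largest-remainder allocation proportional to boundary length
        tot = sum(lengths.values())
        quota = {wid: extras * lengths[wid] / tot for wid in bwalls}
        for wid in bwalls:
            pieces[wid] += int(quota[wid])
        left = extras - sum(p - 1 for p in pieces.values())
        order = sorted(bwalls, key=lambda w: quota[w] - int(quota[w]),
                       reverse=True)
        for wid in order[:left]:
            pieces[wid] += 1
    for wid in bwalls:
        n = pieces[wid]
        if n <= 1:
            continue
        w = mesh.walls[wid]
        a = mesh.vertices[w.v1].pos
        b = mesh.vertices[w.v2].pos
        split_wall(mesh, wid, [a + (b - a) * (i / n) for i in range(1, n)])


def load_default_disk() -> TissueMesh:
    """Load the packaged 73-cell / 348-wall initial disk.

    The returned mesh has aux = cuc = 0 everywhere, delta_aux = 1, rest
    lengths equal to current lengths, and apolar (length-proportional) PIN.
    """
    from importlib import resources

    from . import io as adio

    ref = resources.files("auxindisk").joinpath("data/default_disk.json")
    try:
        with resources.as_file(ref) as path:
            mesh = adio.read_snapshot(path)
    except FileNotFoundError as exc:
        raise MeshLoadError("packaged default disk fixture missing") from exc
    problems = validate_mesh(mesh)
    if problems:
        raise MeshLoadError("default disk fixture corrupt: "
                            + "; ".join(problems[:5]))
    return mesh
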