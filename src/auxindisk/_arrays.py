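"""Array-level view of a TissueMesh, rebuilt after topological changes.

Mechanics and chemistry are vectorised over these flat arrays; the driver's
"reinitialisation" stage amounts to discarding and recompiling this view.
State written into the arrays is scattered back to the mesh objects by the
``sync_*`` helpers.
"""

from __future__ import annotations

import numpy as np

from .mesh import TissueMesh, oriented_walls


class MeshArrays:
    def __init__(self, mesh: TissueMesh):
        self.mesh = mesh
        self.vids = list(mesh.vertices)
        self.vindex = {v: i for i, v in enumerate(self.vids)}
        self.pos = np.array([mesh.vertices[v].pos for v in self.vids],
                            dtype=float).reshape(-1, 2)

        self.wids = list(mesh.walls)
        self.windex = {w: i for i, w in enumerate(self.wids)}
        walls = [mesh.walls[w] for w in self.wids]
        self.wall_u = np.array([self.vindex[w.v1] for w in walls], dtype=np.intp)
        self.wall_v = np.array([self.vindex[w.v2] for w in walls], dtype=np.intp)
        self.wall_rest = np.array([w.rest_length for w in walls], dtype=float)

        self.cids = list(mesh.cells)
        self.cindex = {c: i for i, c in enumerate(self.cids)}
        self.n_cells = len(self.cids)
        self.aux = np.array([mesh.cells[c].aux for c in self.cids])
        self.cuc = np.array([mesh.cells[c].cuc for c in self.cids])
        self.delta = np.array([mesh.cells[c].delta_aux for c in self.cids])

        # cell vertex loops, flattened for reduceat-style accumulation
        flat, nxt, off = [], [], []
        for cid in self.cids:
            loop = oriented_walls(mesh, mesh.cells[cid])[1]
            idx = [self.vindex[v] for v in loop]
            off.append(len(flat))
            flat.extend(idx)
            nxt.extend(idx[1:] + idx[:1])
        self.loop_flat = np.array(flat, dtype=np.intp)
        self.loop_next = np.array(nxt, dtype=np.intp)
        self.loop_off = np.array(off, dtype=np.intp)

        # boundary walls (one incident cell) for turgor forces
        bmask = np.array([len(w.cells) == 1 for w in walls])
        self.bw = np.nonzero(bmask)[0]
        self.bw_cell = np.array(
            [self.cindex[walls[i].cells[0]] for i in self.bw], dtype=np.intp)

        # directed interface sides: one record per (interior wall, source cell)
        side_w, side_src, side_dst, side_pin = [], [], [], []
        pair_index: dict[tuple, int] = {}
        side_pair = []
        for wi, w in enumerate(walls):
            if len(w.cells) != 2:
                continue
            a, b = w.cells
            for src, dst in ((a, b), (b, a)):
                key = (src, dst)
                if key not in pair_index:
                    pair_index[key] = len(pair_index)
                side_w.append(wi)
                side_src.append(self.cindex[src])
                side_dst.append(self.cindex[dst])
                side_pair.append(pair_index[key])
                side_pin.append(w.pin.get(src, 0.0))
        self.side_wall = np.array(side_w, dtype=np.intp)
        self.side_src = np.array(side_src, dtype=np.intp)
        self.side_pair = np.array(side_pair, dtype=np.intp)
        self.side_pin = np.array(side_pin, dtype=float)
        self.n_pairs = len(pair_index)
        self.pair_src = np.zeros(self.n_pairs, dtype=np.intp)
        self.pair_dst = np.zeros(self.n_pairs, dtype=np.intp)
        for (src, dst), p in pair_index.items():
            self.pair_src[p] = self.cindex[src]
            self.pair_dst[p] = self.cindex[dst]
        self.pair_rev = np.array(
            [pair_index[(k[1], k[0])] for k in pair_index], dtype=np.intp)

    # -- geometry -------------------------------------------------------------

    def wall_lengths(self) -> np.ndarray:
        d = self.pos[self.wall_v] - self.pos[self.wall_u]
        return np.hypot(d[:, 0], d[:, 1])

    def areas(self) -> np.ndarray:
        p1 = self.pos[self.loop_flat]
        p2 = self.pos[self.loop_next]
        cr = p1[:, 0] * p2[:, 1] - p2[:, 0] * p1[:, 1]
        return 0.5 * np.add.reduceat(cr, self.loop_off)

    def centroids(self) -> np.ndarray:
        p1 = self.pos[self.loop_flat]
        p2 = self.pos[self.loop_next]
        cr = p1[:, 0] * p2[:, 1] - p2[:, 0] * p1[:, 1]
        a = 0.5 * np.add.reduceat(cr, self.loop_off)
        cx = np.add.reduceat((p1[:, 0] + p2[:, 0]) * cr, self.loop_off)
        cy = np.add.reduceat((p1[:, 1] + p2[:, 1]) * cr, self.loop_off)
        return np.stack([cx, cy], axis=1) / (6 * a)[:, None]

    def pair_pins(self) -> np.ndarray:
        return np.bincount(self.side_pair, weights=self.side_pin,
                           minlength=self.n_pairs)

    def pair_lengths(self) -> np.ndarray:
        seg_len = self.wall_lengths()[self.side_wall]
        return np.bincount(self.side_pair, weights=seg_len,
                           minlength=self.n_pairs)

    # -- scatter back to mesh objects ----------------------------------------

    def sync_positions(self) -> None:
        for i, vid in enumerate(self.vids):
            self.mesh.vertices[vid].pos = self.pos[i].copy()

    def sync_rest_lengths(self) -> None:
        for i, wid in enumerate(self.wids):
            self.mesh.walls[wid].rest_length = float(self.wall_rest[i])

    def sync_chem(self) -> None:
        for i, cid in enumerate(self.cids):
            c = self.mesh.cells[cid]
            c.aux = float(self.aux[i])
            c.cuc = float(self.cuc[i])
            c.delta_aux = float(self.delta[i])
        walls = self.mesh.walls
        for k in range(len(self.side_wall)):
            w = walls[self.wids[self.side_wall[k]]]
            w.pin[self.cids[self.side_src[k]]] = float(self.side_pin[k])

    def sync_areas(self) -> None:
        areas = self.areas()
        for i, cid in enumerate(self.cids):
            self.mesh.cells[cid].area = float(areas[i])


def compile_arrays(mesh: TissueMesh) -> MeshArrays:
    return MeshArrays(mesh)
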