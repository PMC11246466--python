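"""Turgor-driven mass-spring equilibration and rest-length growth.

Each wall segment is a linear spring whose tension is k times its strain
(current length / rest length - 1), so the force on a vertex v is

    F_v = sum_n k (||p_n - p_v|| / L_vn - 1) (p_n - p_v) / ||p_n - p_v||

over its spring neighbours n.  Uniform turgor pressure is applied as a
normal force on boundary walls only (it cancels on interior walls): each
boundary wall pushes P * length / 2 outward on each of its endpoints.

Relaxation integrates the overdamped dynamics with backward-Euler steps
(one Newton iteration per step, spring-only Jacobian, adaptive step size)
until the maximum residual force norm falls below tolerance.  Growth then
extends each spring's rest length by its relative stretch times the
extensibility g:  dL/dt = g (||p_n - p_v|| - L) / L.  The growth law is
applied literally, so compressed springs shrink their rest length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._arrays import MeshArrays, compile_arrays
from .mesh import TissueMesh


@dataclass
class MechanicsParams:
    k: float = 1.0          # spring stiffness (force per unit strain)
    P: float = 0.002        # turgor pressure (force per unit boundary length)
    relax_tol: float = 1e-4     # max residual force norm at convergence
    relax_max_steps: int = 200
    euler_dt: float = 0.1       # initial implicit step (grows adaptively)
    damping: float = 1.0        # mobility of the overdamped dynamics

    def __post_init__(self):
        for name in ("k", "P", "relax_tol", "euler_dt", "damping"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MechanicsParams.{name} must be positive")
        if self.relax_max_steps <= 0:
            raise ValueError("relax_max_steps must be positive")


@dataclass
class GrowthParams:
    g: float = 0.8          # extensibility (per iteration)
    dt_growth: float = 1.0  # growth step (iterations)

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("extensibility g must be >= 0")


# -- forces -------------------------------------------------------------------


def _spring_forces_arr(arrays: MeshArrays, k: float) -> np.ndarray:
    d = arrays.pos[arrays.wall_v] - arrays.pos[arrays.wall_u]
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r <= 0):
        bad = arrays.wids[int(np.argmin(r))]
        raise FloatingPointError(f"zero-length spring (wall {bad})")
    coef = k * (r / arrays.wall_rest - 1.0) / r
    f = coef[:, None] * d
    n = len(arrays.pos)
    F = np.zeros((n, 2))
    for c in (0, 1):
        F[:, c] = (np.bincount(arrays.wall_u, f[:, c], minlength=n)
                   - np.bincount(arrays.wall_v, f[:, c], minlength=n))
    return F


def _turgor_forces_arr(arrays: MeshArrays, P: float) -> np.ndarray:
    n = len(arrays.pos)
    F = np.zeros((n, 2))
    if len(arrays.bw) == 0 or P == 0:
        return F
    u = arrays.wall_u[arrays.bw]
    v = arrays.wall_v[arrays.bw]
    d = arrays.pos[v] - arrays.pos[u]
    normal = np.stack([d[:, 1], -d[:, 0]], axis=1)  # |normal| = wall length
    mid = 0.5 * (arrays.pos[u] + arrays.pos[v])
    cent = arrays.centroids()[arrays.bw_cell]
    sign = np.where(np.einsum("ij,ij->i", normal, mid - cent) >= 0, 1.0, -1.0)
    f = 0.5 * P * sign[:, None] * normal
    for c in (0, 1):
        F[:, c] = (np.bincount(u, f[:, c], minlength=n)
                   + np.bincount(v, f[:, c], minlength=n))
    return F


def spring_forces(mesh: TissueMesh, k: float = 1.0) -> dict:
    """Spring force on every vertex, as a {vertex id: (2,) array} mapping."""
    arrays = compile_arrays(mesh)
    F = _spring_forces_arr(arrays, k)
    return {vid: F[i].copy() for i, vid in enumerate(arrays.vids)}


def turgor_forces(mesh: TissueMesh, P: float) -> dict:
    """Outward turgor force on every vertex (zero off the boundary)."""
    arrays = compile_arrays(mesh)
    F = _turgor_forces_arr(arrays, P)
    return {vid: F[i].copy() for i, vid in enumerate(arrays.vids)}


# -- implicit relaxation ------------------------------------------------------


def _stiffness_pattern(arrays: MeshArrays):
    """COO row/col indices for the 4 2x2 blocks of every spring (cached)."""
    pat = getattr(arrays, "_mech_pattern", None)
    if pat is not None:
        return pat
    u, v = arrays.wall_u, arrays.wall_v
    blocks = [(u, u, 1.0), (v, v, 1.0), (u, v, -1.0), (v, u, -1.0)]
    rows, cols, signs = [], [], []
    for p, q, s in blocks:
        for dr in (0, 1):
            for dc in (0, 1):
                rows.append(2 * p + dr)
                cols.append(2 * q + dc)
                signs.append((s, dr, dc))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    arrays._mech_pattern = (rows, cols, signs)
    return arrays._mech_pattern


def _assemble(arrays: MeshArrays, k: float, damping_factor: float) -> sp.csc_matrix:
    """Regularised stiffness matrix K(x) + damping for one implicit step.

    K is the spring-force Jacobian with the transverse stiffness of
    compressed springs clamped at 0 (PSD projection), so the matrix is
    positive definite; the damping term is proportional to the local
    diagonal stiffness (Levenberg-style), which resolves soft modes far
    better than a uniform mass term.
    """
    rows, cols, signs = _stiffness_pattern(arrays)
    d = arrays.pos[arrays.wall_v] - arrays.pos[arrays.wall_u]
    r = np.hypot(d[:, 0], d[:, 1])
    dx, dy = d[:, 0] / r, d[:, 1] / r
    c1 = k / arrays.wall_rest                 # along the spring axis
    c2 = np.maximum(k * (r / arrays.wall_rest - 1.0) / r, 0.0)
    kxx = c1 * dx * dx + c2 * (1 - dx * dx)
    kyy = c1 * dy * dy + c2 * (1 - dy * dy)
    kxy = (c1 - c2) * dx * dy
    comp = {(0, 0): kxx, (0, 1): kxy, (1, 0): kxy, (1, 1): kyy}
    data = np.concatenate([s * comp[(dr, dc)] for s, dr, dc in signs])
    n = 2 * len(arrays.pos)
    A = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsc()
    diag = A.diagonal()
    A = A + sp.diags(damping_factor * np.maximum(diag, 1e-8) + 1e-10,
                     format="csc")
    return A


def _residual(arrays, params) -> tuple[np.ndarray, float]:
    F = _spring_forces_arr(arrays, params.k) + _turgor_forces_arr(arrays, params.P)
    return F, float(np.hypot(F[:, 0], F[:, 1]).max(initial=0.0))


def potential_energy(arrays: MeshArrays, params: MechanicsParams) -> float:
    """Spring strain energy minus the turgor pressure-area work.

    The forces above are exactly -grad of this potential, so the overdamped
    dynamics decreases it monotonically; it is the acceptance metric for the
    implicit steps (the max force norm itself can rise transiently while the
    boundary load propagates inward).
    """
    d = arrays.pos[arrays.wall_v] - arrays.pos[arrays.wall_u]
    r = np.hypot(d[:, 0], d[:, 1])
    spring = (0.5 * params.k * (r - arrays.wall_rest) ** 2
              / arrays.wall_rest).sum()
    return float(spring - params.P * arrays.areas().sum())


def relax_to_equilibrium(mesh: TissueMesh, params: MechanicsParams | None = None,
                         arrays: MeshArrays | None = None) -> dict:
    """Relax vertex positions to mechanical equilibrium (in place).

    Implicit steps of the overdamped dynamics, realised as damped Newton
    iterations: the PSD-projected stiffness matrix with Levenberg-style
    damping (1/(dt*damping) in units of the local stiffness) gives the step
    direction, and a backtracking line search on the potential energy —
    which the overdamped flow decreases monotonically — accepts it.  Stops
    when the maximum residual force norm falls below relax_tol.  Returns
    diagnostics {"steps", "residual", "converged"}.
    """
    params = params or MechanicsParams()
    own = arrays is None
    if own:
        arrays = compile_arrays(mesh)
    x = arrays.pos
    F, res = _residual(arrays, params)
    energy = potential_energy(arrays, params)
    steps = 0
    # Levenberg-style damping factor, warm-started from the previous
    # relaxation of the same mesh; 1/(dt*damping) in units of the local
    # stiffness.  Small values give near-Newton steps.
    lam_max = 1.0 / (params.euler_dt * params.damping)
    lam = min(getattr(arrays, "_relax_lam", 1e-2), lam_max)
    slack = 1e-12 * (1.0 + abs(energy))
    while res > params.relax_tol and steps < params.relax_max_steps:
        A = _assemble(arrays, params.k, lam * params.damping)
        try:
            lu = spla.splu(A)
        except RuntimeError as exc:  # pragma: no cover - solver breakdown
            raise FloatingPointError(f"implicit solver breakdown: {exc}")
        delta = lu.solve(F.ravel()).reshape(-1, 2)
        if not np.all(np.isfinite(delta)):
            raise FloatingPointError("implicit solver produced non-finite step")
        # backtracking line search on the potential energy
        alpha = 1.0
        accepted = False
        while alpha > 1e-3:
            arrays.pos = x + alpha * delta
            energy_new = potential_energy(arrays, params)
            if energy_new <= energy + slack:
                accepted = True
                break
            alpha *= 0.5
        steps += 1
        if accepted:
            x = arrays.pos
            energy = energy_new
            F, res = _residual(arrays, params)
            if alpha >= 1.0:
                lam = max(lam * 0.3, 1e-5)
            elif alpha < 0.5:
                lam = min(lam * 4.0, lam_max)
        else:
            arrays.pos = x
            if lam >= lam_max:
                break
            lam = min(lam * 10.0, lam_max)
    arrays.pos = x
    arrays._relax_lam = max(lam, 1e-5)
    arrays.sync_positions()
    diag = {"steps": steps, "residual": res,
            "converged": res <= params.relax_tol}
    if not diag["converged"]:
        mesh.warnings.append(
            f"relaxation not converged: residual {res:.3e} after {steps} steps")
    return diag


# -- growth -------------------------------------------------------------------


def grow_rest_lengths(mesh: TissueMesh, params: GrowthParams | None = None,
                      arrays: MeshArrays | None = None) -> TissueMesh:
    """Integrate dL/dt = g (length - L) / L over one growth step.

    The rate equation is stiff for short segments (the relative rate scales
    as g/L), so it is integrated with adaptive explicit substeps bounded by
    half the local stability limit; a single step reproduces the plain Euler
    update whenever it is stable.  Compressed springs shrink (negative
    growth), as the rate law dictates.
    """
    params = params or GrowthParams()
    if arrays is not None:
        r = arrays.wall_lengths()
        L = arrays.wall_rest
    else:
        walls = list(mesh.walls.values())
        verts = mesh.vertices
        p1 = np.array([verts[w.v1].pos for w in walls])
        p2 = np.array([verts[w.v2].pos for w in walls])
        d = p2 - p1
        r = np.hypot(d[:, 0], d[:, 1])
        L = np.array([w.rest_length for w in walls])
    g = params.g
    remaining = params.dt_growth
    if g > 0:
        for _ in range(10000):
            if remaining <= 0:
                break
            dt = min(remaining, float(L.min()) / g)  # half of 2L/g stability bound
            L += dt * g * (r - L) / L
            np.maximum(L, 1e-6, out=L)
            remaining -= dt
    if arrays is not None:
        arrays.wall_rest = L
        arrays.sync_rest_lengths()
    else:
        for w, val in zip(walls, L.tolist()):
            w.rest_length = val
    return mesh
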