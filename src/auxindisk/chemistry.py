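"""Auxin-CUC-PIN dynamics on the cellular mesh.

Per cell i and interior neighbour j (interface length L_j = summed lengths of
the wall segments they share), PIN relaxes towards an up-the-gradient target
with speed alpha:

    pin_{i->j} <- (1 - alpha) pin_{i->j} + alpha aux_j^n L_j / sum_k aux_k^n L_k

where the sensitivity exponent n is 1 below the CUC threshold and 2 above it:
CUC's sole effect is to make PIN repolarisation quadratically sensitive to
neighbour auxin.  Auxin obeys production (with a per-cell noise multiplier
delta drawn from N(1, SD) and clamped at 0), first-order decay, and polar
transport scaled by 1/Area; CUC is produced under Hill repression by auxin
and decays.  No PIN faces the outer boundary and no auxin crosses it
(zero-flux boundary).

Within one chemical substep the PIN, auxin and CUC updates are computed
concomitantly from the same pre-step state and committed together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._arrays import MeshArrays, compile_arrays
from .mesh import TissueMesh


@dataclass
class ChemParams:
    alpha: float = 0.01       # PIN repolarisation speed per substep
    cuc_thres: float = 2.0    # CUC level switching the sensitivity exponent
    prod_aux: float = 1.0
    dec_aux: float = 0.2
    tran_aux: float = 400.0
    prod_cuc: float = 1.0     # 0 in cuc1 backgrounds
    dec_cuc: float = 0.2
    k_aux: float = 5.0        # auxin level halving CUC production
    hill: float = 4.0
    sd_aux: float = 0.1       # noise SD: 0.1 (WT, cuc1) or 1 (drmy1 backgrounds)
    dt_chem: float = 0.1
    n_substeps: int = 10
    frozen_noise: bool = False

    def __post_init__(self):
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")
        for name in ("cuc_thres", "prod_aux", "dec_aux", "tran_aux",
                     "prod_cuc", "dec_cuc", "k_aux", "hill", "sd_aux",
                     "dt_chem"):
            if getattr(self, name) < 0:
                raise ValueError(f"ChemParams.{name} must be >= 0")


def pin_sensitivity(cuc: float, cuc_thres: float = 2.0) -> int:
    """Sensitivity exponent: 1 below the CUC threshold, 2 at or above it."""
    return 2 if cuc >= cuc_thres else 1


# -- PIN ----------------------------------------------------------------------


def init_pin(mesh: TissueMesh) -> TissueMesh:
    """Apolar initial PIN: each interior wall segment gets a share of the
    cell's unit PIN proportional to its length; boundary walls get zero."""
    for cell in mesh.cells.values():
        interior = []
        for wid in cell.wall_ids:
            w = mesh.walls[wid]
            if len(w.cells) == 2:
                interior.append(w)
            else:
                w.pin[cell.id] = 0.0
        if not interior:
            mesh.warnings.append(f"cell {cell.id} isolated: PIN left empty")
            continue
        lengths = np.array([mesh.wall_length(w) for w in interior])
        total = lengths.sum()
        for w, ln in zip(interior, lengths):
            w.pin[cell.id] = float(ln / total)
    return mesh


def _pin_target(arrays: MeshArrays, params: ChemParams, pair_len, n_cells):
    """Eq.-style up-the-gradient PIN target per directed interface."""
    aux_d = arrays.aux[arrays.pair_dst]
    quad = arrays.cuc[arrays.pair_src] >= params.cuc_thres
    w = np.where(quad, aux_d * aux_d, aux_d) * pair_len
    denom = np.bincount(arrays.pair_src, weights=w, minlength=n_cells)
    lsum = np.bincount(arrays.pair_src, weights=pair_len, minlength=n_cells)
    d = denom[arrays.pair_src]
    with np.errstate(invalid="ignore", divide="ignore"):
        target = np.where(d > 0, w / np.where(d > 0, d, 1.0),
                          pair_len / lsum[arrays.pair_src])
    return target


def update_pin(mesh: TissueMesh, params: ChemParams | None = None,
               arrays: MeshArrays | None = None) -> TissueMesh:
    """One PIN repolarisation step (per-cell allocations keep summing to 1)."""
    params = params or ChemParams()
    own = arrays is None
    if own:
        arrays = compile_arrays(mesh)
    pair_len = arrays.pair_lengths()
    target = _pin_target(arrays, params, pair_len, arrays.n_cells)
    pin = arrays.pair_pins()
    pin_new = (1.0 - params.alpha) * pin + params.alpha * target
    _scatter_pair_pins(arrays, pin_new, pair_len)
    if own:
        arrays.sync_chem()
    return mesh


def _scatter_pair_pins(arrays, pair_pin, pair_len):
    seg_len = arrays.wall_lengths()[arrays.side_wall]
    arrays.side_pin = pair_pin[arrays.side_pair] * seg_len / pair_len[arrays.side_pair]


# -- noise --------------------------------------------------------------------


def draw_noise(mesh: TissueMesh, sd_aux: float, frozen_noise: bool, rng,
               at_init: bool = False, arrays: MeshArrays | None = None
               ) -> TissueMesh:
    """Redraw each cell's auxin-production noise multiplier from N(1, SD).

    Negative draws are clamped to 0.  With frozen noise the multipliers are
    drawn only at initialisation and left untouched afterwards.  Draw order
    is ascending cell id for reproducibility.
    """
    if frozen_noise and not at_init:
        return mesh
    cells = sorted(mesh.cells)
    draws = np.maximum(rng.normal(1.0, sd_aux, size=len(cells)), 0.0)
    for cid, d in zip(cells, draws):
        mesh.cells[cid].delta_aux = float(d)
    if arrays is not None:
        arrays.delta = np.array([mesh.cells[c].delta_aux for c in arrays.cids])
    return mesh


# -- concentration updates ----------------------------------------------------


def _aux_rhs(arrays: MeshArrays, params: ChemParams, pair_pin, areas):
    n = arrays.n_cells
    influx = np.bincount(arrays.pair_dst,
                         weights=arrays.aux[arrays.pair_src] * pair_pin,
                         minlength=n)
    out_pin = np.bincount(arrays.pair_src, weights=pair_pin, minlength=n)
    transport = params.tran_aux * (influx - arrays.aux * out_pin) / areas
    return params.prod_aux * arrays.delta - params.dec_aux * arrays.aux + transport


def _cuc_rhs(arrays: MeshArrays, params: ChemParams):
    rep = 1.0 / (1.0 + (arrays.aux / params.k_aux) ** params.hill)
    return params.prod_cuc * rep - params.dec_cuc * arrays.cuc


def _check_finite(values, arrays, what):
    if not np.all(np.isfinite(values)):
        cid = arrays.cids[int(np.argmin(np.isfinite(values)))]
        raise FloatingPointError(f"non-finite {what} in cell {cid}")


def auxin_substep(mesh: TissueMesh, params: ChemParams | None = None,
                  arrays: MeshArrays | None = None) -> TissueMesh:
    """One explicit-Euler auxin step (production, decay, polar transport)."""
    params = params or ChemParams()
    own = arrays is None
    if own:
        arrays = compile_arrays(mesh)
    rhs = _aux_rhs(arrays, params, arrays.pair_pins(), arrays.areas())
    arrays.aux = np.maximum(arrays.aux + params.dt_chem * rhs, 0.0)
    _check_finite(arrays.aux, arrays, "auxin")
    if own:
        arrays.sync_chem()
    return mesh


def cuc_substep(mesh: TissueMesh, params: ChemParams | None = None,
                arrays: MeshArrays | None = None) -> TissueMesh:
    """One explicit-Euler CUC step (Hill-repressed production, decay)."""
    params = params or ChemParams()
    own = arrays is None
    if own:
        arrays = compile_arrays(mesh)
    arrays.cuc = np.maximum(
        arrays.cuc + params.dt_chem * _cuc_rhs(arrays, params), 0.0)
    _check_finite(arrays.cuc, arrays, "CUC")
    if own:
        arrays.sync_chem()
    return mesh


def run_chemistry(mesh: TissueMesh, params: ChemParams | None = None,
                  arrays: MeshArrays | None = None) -> TissueMesh:
    """Run n_substeps chemical rounds.

    Within a round the PIN, auxin and CUC updates are all computed from the
    same pre-round state (concomitant semantics) and applied together: PIN
    makes its single repolarisation step towards the pre-round target, while
    the auxin/CUC rate equations are advanced over dt_chem with the
    pre-round PIN held fixed.  That advance uses inner explicit-Euler steps
    bounded by half the transport stability limit (dt < 2 Area / (Tran_aux
    * outgoing PIN) at the smallest cell), so the integration stays stable
    regardless of how small cells get; a single inner step reproduces the
    plain Euler update whenever it is stable.
    """
    params = params or ChemParams()
    own = arrays is None
    if own:
        arrays = compile_arrays(mesh)
    areas = arrays.areas()
    pair_len = arrays.pair_lengths()
    for _ in range(params.n_substeps):
        pair_pin = arrays.pair_pins()
        target = _pin_target(arrays, params, pair_len, arrays.n_cells)
        pin_new = (1.0 - params.alpha) * pair_pin + params.alpha * target
        # stability bound for the explicit transport update
        out_pin = np.bincount(arrays.pair_src, weights=pair_pin,
                              minlength=arrays.n_cells)
        with np.errstate(divide="ignore"):
            rate = params.tran_aux * out_pin / areas + params.dec_aux
        max_rate = float(rate.max(initial=0.0))
        n_inner = max(1, int(np.ceil(params.dt_chem * max_rate)))
        dt = params.dt_chem / n_inner
        aux = arrays.aux
        cuc = arrays.cuc
        for _inner in range(n_inner):
            arrays.aux = aux  # the rate functions read from arrays
            arrays.cuc = cuc
            daux = _aux_rhs(arrays, params, pair_pin, areas)
            dcuc = _cuc_rhs(arrays, params)
            aux = np.maximum(aux + dt * daux, 0.0)
            cuc = np.maximum(cuc + dt * dcuc, 0.0)
        _check_finite(aux, arrays, "auxin")
        _check_finite(cuc, arrays, "CUC")
        _scatter_pair_pins(arrays, pin_new, pair_len)
        arrays.aux = aux
        arrays.cuc = cuc
    arrays.sync_chem()
    return mesh


# -- dilution -----------------------------------------------------------------


def dilute_concentrations(mesh: TissueMesh, areas_before: dict,
                          areas_after: dict) -> TissueMesh:
    """Scale aux and cuc by area_before/area_after (amounts conserved)."""
    for cid, cell in mesh.cells.items():
        before = areas_before[cid]
        after = areas_after[cid]
        if after <= 0:
            raise FloatingPointError(
                f"cell {cid}: non-positive area {after} in dilution")
        f = before / after
        cell.aux *= f
        cell.cuc *= f
    return mesh
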