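"""Genotype presets, the per-iteration process order, and full runs.

One driver iteration executes, in this fixed order:

  1. mechanical relaxation under turgor (to convergence),
  2. dilution of auxin and CUC by the relaxation-induced area changes,
  3. redraw of the per-cell auxin-production noise (unless frozen),
  4. ten chemical substeps (PIN repolarisation, auxin, CUC),
  5. division of every cell whose area exceeds the 50 µm² threshold,
  6. subdivision of wall segments longer than 1 µm,
  7. rest-length growth,
  8. reinitialisation (rebuild of cached adjacency/solver structures),
  9. data output (snapshot when due).

Genotypes differ only in the auxin-production noise SD and the CUC
production coefficient: WT (0.1, 1), cuc1 (0.1, 0), drmy1 (1, 1),
drmy1_cuc1 (1, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chemistry, mechanics, mesh as meshmod
from ._arrays import compile_arrays
from .chemistry import ChemParams
from .mechanics import GrowthParams, MechanicsParams
from .mesh import DivisionNoise, TissueMesh

STAGES = ("relax", "dilute", "noise", "chemistry", "division",
          "split_walls", "growth", "reinit", "output")


@dataclass(frozen=True)
class GenotypeSpec:
    name: str
    sd_aux: float
    prod_cuc: float


_GENOTYPES = {
    "WT": GenotypeSpec("WT", 0.1, 1.0),
    "cuc1": GenotypeSpec("cuc1", 0.1, 0.0),
    "drmy1": GenotypeSpec("drmy1", 1.0, 1.0),
    "drmy1_cuc1": GenotypeSpec("drmy1_cuc1", 1.0, 0.0),
}


def genotype_preset(name: str) -> GenotypeSpec:
    """Return the (noise SD, CUC production) pair encoding a genotype."""
    key = name.replace(" ", "_")
    if key not in _GENOTYPES:
        raise ValueError(
            f"unknown genotype {name!r}; valid names: {sorted(_GENOTYPES)}")
    return _GENOTYPES[key]


@dataclass
class SimulationConfig:
    genotype: GenotypeSpec = field(default_factory=lambda: _GENOTYPES["WT"])
    growth_rate: float = 0.8
    n_iterations: int = 100
    seed: int = 1
    snapshot_every: int = 10
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    chemistry: ChemParams = field(default_factory=ChemParams)
    division_noise: DivisionNoise = field(default_factory=DivisionNoise)
    division_area_thres: float = 50.0
    max_wall_len: float = 1.0
    frozen_noise: bool = False

    def __post_init__(self):
        if isinstance(self.genotype, str):
            self.genotype = genotype_preset(self.genotype)
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")

    def resolved_chemistry(self) -> ChemParams:
        """Chemistry parameters with the genotype and noise flag applied."""
        return replace(self.chemistry, sd_aux=self.genotype.sd_aux,
                       prod_cuc=self.genotype.prod_cuc,
                       frozen_noise=self.frozen_noise)

    def growth(self) -> GrowthParams:
        return GrowthParams(g=self.growth_rate, dt_growth=1.0)


@dataclass
class Trajectory:
    config: SimulationConfig
    snapshots: list = field(default_factory=list)  # (iteration, TissueMesh)
    diagnostics: list = field(default_factory=list)
    stage_log: list = field(default_factory=list)  # stages of last iteration
    chem_substeps: int = 0

    @property
    def final(self) -> TissueMesh:
        return self.snapshots[-1][1]


class SimulationError(RuntimeError):
    """Fatal numerical failure; carries the trajectory up to the last good
    snapshot."""

    def __init__(self, msg, trajectory):
        super().__init__(msg)
        self.trajectory = trajectory


class _SimState:
    """Mutable state threaded through run_iteration."""

    def __init__(self, mesh: TissueMesh, config: SimulationConfig):
        self.mesh = mesh
        self.config = config
        self.chem = config.resolved_chemistry()
        ss = np.random.SeedSequence(config.seed)
        noise_ss, div_ss = ss.spawn(2)
        self.rng_noise = np.random.default_rng(noise_ss)
        self.rng_div = np.random.default_rng(div_ss)
        self.arrays = compile_arrays(mesh)
        self.stage_log: list = []
        self.last_diag: dict = {}


def run_iteration(state: _SimState, config: SimulationConfig | None = None
                  ) -> _SimState:
    """Run one driver iteration in the fixed nine-stage order."""
    config = config or state.config
    mesh = state.mesh
    arrays = state.arrays
    log = []

    areas_before = {cid: a for cid, a in zip(arrays.cids, arrays.areas())}
    diag = mechanics.relax_to_equilibrium(mesh, config.mechanics, arrays)
    log.append("relax")

    after = arrays.areas()
    areas_after = {cid: a for cid, a in zip(arrays.cids, after)}
    chemistry.dilute_concentrations(mesh, areas_before, areas_after)
    arrays.aux = np.array([mesh.cells[c].aux for c in arrays.cids])
    arrays.cuc = np.array([mesh.cells[c].cuc for c in arrays.cids])
    arrays.sync_areas()
    log.append("dilute")

    chemistry.draw_noise(mesh, state.chem.sd_aux, state.chem.frozen_noise,
                         state.rng_noise, arrays=arrays)
    log.append("noise")

    chemistry.run_chemistry(mesh, state.chem, arrays)
    state.chem_substeps = state.chem.n_substeps
    log.append("chemistry")

    for cid in sorted(mesh.cells):
        cell = mesh.cells.get(cid)
        if cell is not None and cell.area > config.division_area_thres:
            meshmod.divide_cell(mesh, cell, config.division_noise,
                                state.rng_div)
    log.append("division")

    meshmod.split_long_walls(mesh, config.max_wall_len)
    log.append("split_walls")

    mechanics.grow_rest_lengths(mesh, config.growth())
    log.append("growth")

    relax_lam = getattr(arrays, "_relax_lam", None)
    state.arrays = compile_arrays(mesh)
    if relax_lam is not None:
        state.arrays._relax_lam = relax_lam
    state.arrays.sync_areas()
    log.append("reinit")

    mesh.iteration += 1
    log.append("output")
    state.stage_log = log
    state.last_diag = diag
    return state


def run_simulation(config: SimulationConfig,
                   initial_mesh: TissueMesh | None = None) -> Trajectory:
    """Run a full simulation; snapshots at 0, every snapshot_every, and the
    final iteration.  Fully reproducible from (config, seed)."""
    if initial_mesh is None:
        mesh = meshmod.load_default_disk()
    else:
        mesh = initial_mesh.copy()
        if not any(w.pin for w in mesh.walls.values()):
            chemistry.init_pin(mesh)
    meshmod.update_areas(mesh)
    state = _SimState(mesh, config)
    # per-cell noise is drawn once at initialisation (and redrawn each
    # iteration unless frozen)
    chemistry.draw_noise(mesh, state.chem.sd_aux, False, state.rng_noise,
                         at_init=True, arrays=state.arrays)

    traj = Trajectory(config=config)
    traj.snapshots.append((mesh.iteration, mesh.copy()))
    for it in range(config.n_iterations):
        try:
            run_iteration(state)
        except FloatingPointError as exc:
            traj.diagnostics.append({"iteration": mesh.iteration,
                                     "error": str(exc)})
            raise SimulationError(str(exc), traj) from exc
        traj.diagnostics.append(
            {"iteration": mesh.iteration, **state.last_diag,
             "n_cells": len(mesh.cells)})
        if (mesh.iteration % config.snapshot_every == 0
                or it == config.n_iterations - 1):
            traj.snapshots.append((mesh.iteration, mesh.copy()))
    traj.stage_log = state.stage_log
    traj.chem_substeps = state.chem_substeps
    return traj


class EnsembleError(RuntimeError):
    pass


def run_ensemble(config_template: SimulationConfig, n_runs: int,
                 base_seed: int, initial_mesh: TissueMesh | None = None,
                 extract_kwargs: dict | None = None) -> pd.DataFrame:
    """Run n_runs simulations with seeds base_seed..base_seed+n_runs-1 and
    collect per-run robustness summaries into a table."""
    from .analysis import summarize_run

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if initial_mesh is None:
        initial_mesh = meshmod.load_default_disk()
    rows = []
    failures = 0
    for i in range(n_runs):
        seed = base_seed + i
        config = replace(config_template, seed=seed)
        try:
            traj = run_simulation(config, initial_mesh)
            summary = summarize_run(traj, **(extract_kwargs or {}))
            rows.append({
                "run": i, "seed": seed,
                "genotype": config.genotype.name,
                "growth_rate": config.growth_rate,
                "iteration": traj.final.iteration,
                "n_cells": len(traj.final.cells),
                "maxima_count": summary.maxima_count,
                "mean_max_aux": summary.mean_max_aux,
                "angular_cv": summary.angular_cv,
                "failed": False,
            })
        except SimulationError as exc:
            failures += 1
            rows.append({"run": i, "seed": seed,
                         "genotype": config.genotype.name,
                         "growth_rate": config.growth_rate,
                         "iteration": np.nan, "n_cells": np.nan,
                         "maxima_count": np.nan, "mean_max_aux": np.nan,
                         "angular_cv": np.nan, "failed": True})
    if failures > 0.1 * n_runs:
        raise EnsembleError(f"{failures}/{n_runs} runs failed")
    return pd.DataFrame(rows)
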