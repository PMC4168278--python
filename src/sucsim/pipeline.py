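"""End-to-end experiment orchestration.

A single configuration drives the full chain: build the slab mesh, place
the contacts, assign conductivity (with a synthetic fiber field when the
white matter is anisotropic), solve once at 1 V, and derive the amplitude
sweep, impedance and field exports. Everything downstream of the single
linear solve uses linearity, so a run costs exactly one solve.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from . import fem, io, metrics as metrics_mod
from .conductivity import (
    AnisotropyModel,
    IsotropicTable,
    build_conductivity_field,
    fa_map,
)
from .geometry import (
    LabeledTetMesh,
    PaddleLayout,
    SlabSpec,
    build_slab_mesh,
    designate_reference,
    place_disc_electrode,
    place_paddle_array,
)
from .synthetic import DEFAULT_SEED, generate_fiber_field

CONDUCTIVITY_CHOICES = ("isotropic", "normalized", "ratio_2", "ratio_5", "ratio_10")


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serializable description of one stimulation experiment."""

    slab: SlabSpec = SlabSpec()
    electrode_mode: str = "paddle"  # "paddle" | "single"
    conductivity_model: str = "isotropic"  # one of CONDUCTIVITY_CHOICES
    fiber_pattern: str = "u_fiber"
    seed: int = DEFAULT_SEED
    stimulation_mode: str = "voltage"  # "voltage" | "current"
    amplitudes: tuple = ()  # empty -> default grid for the mode
    mct: float = metrics_mod.DEFAULT_MCT
    contact_diameter: float = 4.0
    contact_spacing: float = 10.0
    reference_tags: tuple = ("side", "bottom")
    solver_rtol: float = 1e-8
    table: IsotropicTable = IsotropicTable()

    def __post_init__(self) -> None:
        if self.electrode_mode not in ("paddle", "single"):
            raise ValueError(f"unknown electrode mode {self.electrode_mode!r}")
        if self.conductivity_model not in CONDUCTIVITY_CHOICES:
            raise ValueError(f"unknown conductivity model {self.conductivity_model!r}")
        if self.stimulation_mode not in ("voltage", "current"):
            raise ValueError(f"unknown stimulation mode {self.stimulation_mode!r}")
        if self.mct <= 0:
            raise ValueError("mct must be positive")

    def amplitude_grid(self) -> tuple:
        if self.amplitudes:
            return tuple(self.amplitudes)
        return (
            metrics_mod.VOLTAGE_GRID
            if self.stimulation_mode == "voltage"
            else tuple(float(a) for a in metrics_mod.CURRENT_GRID)
        )

    def anisotropy(self) -> AnisotropyModel:
        name = self.conductivity_model
        if name == "isotropic":
            return AnisotropyModel("isotropic", sigma_iso=self.table.WM)
        if name == "normalized":
            return AnisotropyModel("normalized", sigma_iso=self.table.WM)
        r = float(name.split("_")[1])
        return AnisotropyModel("fixed_ratio", r=r, sigma_iso=self.table.WM)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["slab"] = dataclasses.asdict(self.slab)
        d["table"] = dataclasses.asdict(self.table)
        d["amplitudes"] = list(self.amplitudes)
        d["reference_tags"] = list(self.reference_tags)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "slab" in d:
            d["slab"] = SlabSpec(**d["slab"])
        if "table" in d:
            d["table"] = IsotropicTable(**d["table"])
        for key in ("amplitudes", "reference_tags"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ExperimentResult:
    """In-memory result of one run (also materialized in the run directory)."""

    config: ExperimentConfig
    mesh: LabeledTetMesh
    solution: fem.PotentialSolution
    table: pd.DataFrame
    impedance: float
    output_current_ma: float
    middle_center: np.ndarray


def _build_stage(config: ExperimentConfig, log: list[str]):
    spec = config.slab
    mesh = build_slab_mesh(spec)
    vols = mesh.tet_volumes()
    log.append(
        f"mesh: {mesh.num_nodes} nodes, {mesh.num_tets} tetrahedra; "
        f"element volume {vols.min():.3e} to {vols.max():.3e} mm^3 "
        f"(mean {vols.mean():.3e} mm^3)"
    )
    center = (0.5 * spec.extent_x, 0.5 * spec.extent_y)
    if config.electrode_mode == "paddle":
        layout = PaddleLayout(center=center, contact_spacing=config.contact_spacing)
        patches = place_paddle_array(mesh, layout, config.contact_diameter)
        middle = patches[2]
    else:
        middle = place_disc_electrode(mesh, center, config.contact_diameter, tag="electrode_3")
        patches = [middle]
    log.append(f"contacts: {len(patches)} x {config.contact_diameter:.3g} mm discs")

    model = config.anisotropy()
    fibers = None
    if model.method != "isotropic":
        fibers = generate_fiber_field(mesh, config.fiber_pattern, config.seed, spec=spec)
        log.append(f"fiber field: pattern={config.fiber_pattern} seed={config.seed}")
    cfield = build_conductivity_field(mesh, config.table, model, fibers)
    return mesh, patches, middle, cfield


def _stage(name: str, fn, log: list[str]):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:  # annotate the failing stage, re-raise
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.append(f"stage {name}: {time.perf_counter() - t0:.2f} s")
    return out


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> ExperimentResult:
    """Run one experiment; optionally materialize a run directory.

    Outputs (when ``outdir`` is given): ``summary.csv`` (one row per
    amplitude), ``solution.vtu`` (nodal V, element |J| and J at 1 V, FA if
    anisotropic), ``config.yaml`` (verbatim archive) and ``run.log``.
    """
    log: list[str] = []
    mesh, patches, middle, cfield = _stage("build", lambda: _build_stage(config, log), log)

    def solve():
        system = fem.assemble_system(mesh, cfield)
        ref = designate_reference(mesh, config.reference_tags)
        bc = fem.BoundaryConditions(drives=[(p, 1.0) for p in patches], reference=ref)
        return fem.solve_potential(system, bc, rtol=config.solver_rtol)

    solution = _stage("solve", solve, log)
    log.append(f"solve: relative residual {solution.residual:.3e} at 1 V")

    def measure():
        i_1v = fem.total_drive_current(solution)
        z = metrics_mod.estimate_impedance(1.0, i_1v)
        cfg = metrics_mod.MCTConfig(mct=config.mct)
        table = metrics_mod.sweep_metrics(
            solution,
            mesh,
            middle.center,
            cfg,
            modes=(config.stimulation_mode,),
            voltage_grid=config.amplitude_grid(),
            current_grid=config.amplitude_grid(),
        )
        return z, 1000.0 * i_1v, table

    impedance, i_ma, table = _stage("metrics", measure, log)
    log.append(f"impedance {impedance:.1f} ohm; output current {i_ma:.2f} mA at 1 V")

    result = ExperimentResult(config, mesh, solution, table, impedance, i_ma, middle.center)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "summary.csv", index=False, float_format="%.6g")
        io.dump_config(config.to_dict(), str(outdir / "config.yaml"))
        cell = {"jmag_Apm2": solution.jmag, "J_Apm2": solution.J}
        if config.conductivity_model != "isotropic":
            cell["FA"] = fa_map(cfield)
        io.write_vtu(str(outdir / "solution.vtu"), mesh, {"V": solution.V}, cell)
        (outdir / "run.log").write_text("\n".join(log) + "\n")
    return result


def solve_slab(config: ExperimentConfig, z_refine: float = 1.0):
    """Build and solve the configured slab once at 1 V; returns (mesh, solution,
    middle-contact patch)."""
    spec = config.slab
    mesh = build_slab_mesh(spec, z_refine=z_refine)
    center = (0.5 * spec.extent_x, 0.5 * spec.extent_y)
    if config.electrode_mode == "paddle":
        layout = PaddleLayout(center=center, contact_spacing=config.contact_spacing)
        patches = place_paddle_array(mesh, layout, config.contact_diameter)
        middle = patches[2]
    else:
        middle = place_disc_electrode(mesh, center, config.contact_diameter, tag="electrode_3")
        patches = [middle]
    model = config.anisotropy()
    fibers = None
    if model.method != "isotropic":
        fibers = generate_fiber_field(mesh, config.fiber_pattern, config.seed, spec=spec)
    cfield = build_conductivity_field(mesh, config.table, model, fibers)
    system = fem.assemble_system(mesh, cfield)
    ref = designate_reference(mesh, config.reference_tags)
    bc = fem.BoundaryConditions(drives=[(p, 1.0) for p in patches], reference=ref)
    sol = fem.solve_potential(system, bc, rtol=config.solver_rtol)
    return mesh, sol, middle


def run_convergence(
    config: ExperimentConfig, z_factors: Sequence[float] = (1.0, 1.7)
) -> pd.DataFrame:
    """Mesh-refinement study along z with a fixed top-surface discretization.

    Each level multiplies the number of z subdivisions of the base slab by
    the given factor, leaving the x-y grid (and hence the contact Dirichlet
    patches) identical and keeping the grid conforming to the flat tissue
    interfaces, so consecutive levels compare solution convergence rather
    than electrode or interface re-discretization. Reports per level: node
    and element counts, impedance, and the maximum relative nodal-voltage
    difference against the previous level (coarse solution linearly
    interpolated at fine nodes, as a percentage of the applied voltage).
    """
    if len(z_factors) < 2:
        raise ValueError("at least two refinement levels are required")
    rows = []
    prev = None  # (grid, V)
    for lvl, f in enumerate(z_factors):
        mesh, sol, _ = solve_slab(config, z_refine=f)
        i_1v = fem.total_drive_current(sol)
        z_ohm = metrics_mod.estimate_impedance(1.0, i_1v)
        diff_pct = np.nan
        if prev is not None:
            gxs, gys, gzs = prev[0]
            shape = (len(gxs), len(gys), len(gzs))
            interp = RegularGridInterpolator((gxs, gys, gzs), prev[1].reshape(shape))
            vc = interp(mesh.nodes)
            diff_pct = 100.0 * float(np.abs(sol.V - vc).max()) / sol.v0
        rows.append(
            {
                "level": lvl,
                "z_factor": f,
                "nodes": mesh.num_nodes,
                "tets": mesh.num_tets,
                "impedance_ohm": z_ohm,
                "max_rel_voltage_diff_pct": diff_pct,
            }
        )
        prev = (mesh.grid, sol.V)
    return pd.DataFrame(rows)


def compare_models(results: Sequence[ExperimentResult], labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Side-by-side metric table with ratio columns against the first run.

    All runs must share the stimulation mode, amplitude grid and threshold.
    """
    if len(results) < 2:
        raise ValueError("need at least two runs to compare")
    labels = list(labels) if labels else [f"run{i}" for i in range(len(results))]
    base = results[0]
    grid0 = tuple(base.table["amplitude"])
    for r in results[1:]:
        if tuple(r.table["amplitude"]) != grid0 or r.config.mct != base.config.mct:
            raise ValueError("compared runs must share amplitude grid and threshold")
    out = base.table[["mode", "amplitude"]].copy()
    for lab, r in zip(labels, results):
        out[f"effective_volume_cm3_{lab}"] = r.table["effective_volume_cm3"].values
        out[f"effective_depth_cm_{lab}"] = r.table["effective_depth_cm"].values
    ref_v = out[f"effective_volume_cm3_{labels[0]}"]
    ref_d = out[f"effective_depth_cm_{labels[0]}"]
    for lab in labels[1:]:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"volume_ratio_{lab}"] = out[f"effective_volume_cm3_{lab}"] / ref_v
            out[f"depth_ratio_{lab}"] = out[f"effective_depth_cm_{lab}"] / ref_d
    return out
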