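"""Multiscale orchestration and the multiscale-vs-direct validation
protocol.

The multiscale run executes the full loop: partition the scaffold into
RVEs spanning its height → pore-scale Stokes solve per RVE (velocity
inlet, symmetric laterals) → Darcy permeability per RVE → arithmetic
average → macro Darcy–Brinkman channel solve → plane-averaged pressure
pair (p_top, p_bottom) per RVE footprint → pore-scale solve again under
the handed-off pressures → wall shear stress recovery.

Validation compares the WSS inside a central RVE computed this way against
a direct pore-scale solve of the whole (small) scaffold, via area-weighted
WSS histograms (Pearson correlation of paired bin weights) and
area-weighted mean WSS in square-annulus subregions at increasing distance
from the RVE boundary (percent error, direct CFD as the reference).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    FluidDomain,
    RVESpec,
    VoxelImage,
    build_fluid_domain,
    extract_rve,
    generate_scaffold,
    partition_rves,
)
from .homogenize import (
    PermeabilityResult,
    average_permeability,
    compute_permeability,
    permeability_table,
)
from .macro import MacroModel, MacroSolution, extract_pressure_bcs, solve_macro
from .stokes import FlowField, FluidProps, MicroBC, flow_rate, solve_stokes
from .wss import (
    WSSField,
    WSSHistogram,
    compute_wss,
    restrict_to_footprint,
    subregion_average_wss,
    wss_histogram,
)

__all__ = [
    "MultiscaleConfig",
    "MultiscaleRun",
    "ValidationReport",
    "PipelineError",
    "run_multiscale",
    "run_direct",
    "compare",
    "run_validation",
]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name and RVE index."""


@dataclass
class MultiscaleConfig:
    """Settings of a multiscale run (SI units internally).

    ``inlet_velocity`` is the superficial velocity prescribed at the macro
    channel inlet and at the RVE inlets of the permeability stage;
    ``flow_rate`` (m³/s), if set, takes precedence for the macro model.
    """

    props: FluidProps = field(default_factory=FluidProps)
    rve_grid: tuple[int, int] = (1, 1)
    rve_xy_um: float | None = None
    footprint: str = "auto"
    inlet_velocity: float = 500e-6
    flow_rate: float | None = None
    permeability_probe_dp: float = 0.5  # Pa; kappa is scale-free (Stokes)
    tol: float = 1e-4
    macro_cells_across_height: int = 24
    macro_wall_condition: str = "no_slip"
    macro_entrance_heights: float = 1.0
    macro_exit_heights: float = 1.0
    wss_surface_model: str = "smoothed-normal"
    bin_width_mpa: float = 5.0
    max_mpa: float = 100.0
    weighting: str = "area"
    subregion_count: int = 5
    subregion_width_um: float = 50.0
    direct_cell_limit: int = 2_000_000
    direct_pad_voxels: int = 4


@dataclass
class MultiscaleRun:
    """All artifacts of one multiscale execution."""

    scaffold: VoxelImage
    config: MultiscaleConfig
    rves: list[RVESpec]
    permeabilities: list[PermeabilityResult]
    kappa_bar: float
    macro: MacroSolution
    pressure_pairs: list[tuple[float, float]]
    wss_fields: list[WSSField]
    wss_flows: list[FlowField]
    runtime_log: dict[str, float]

    def micro_superficial_velocity(self, i: int = 0) -> float:
        """Superficial velocity (m/s) of RVE ``i`` under the handed-off
        pressure pair: flow rate over the full RVE cross-section."""
        f = self.wss_flows[i]
        nz = f.domain.shape[2]
        q = 0.5 * (flow_rate(f, 0) + flow_rate(f, nz))
        h = f.voxel_size_m
        area = f.domain.shape[0] * f.domain.shape[1] * h * h
        return q / area

    def save(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        artifacts = {}
        tab = permeability_table(self.permeabilities)
        tab.to_csv(out / "permeability_per_rve.csv", index=False)
        artifacts["permeability_per_rve"] = "permeability_per_rve.csv"
        macro_summary = {
            "kappa_bar_m2": self.kappa_bar,
            "p_top_Pa": self.macro.p_top,
            "p_bottom_Pa": self.macro.p_bottom,
            "dp_Pa": self.macro.dp,
            "residuals": self.macro.residuals,
        }
        (out / "macro_summary.json").write_text(
            json.dumps(macro_summary, indent=2, sort_keys=True)
        )
        artifacts["macro_summary"] = "macro_summary.json"
        import pandas as pd

        rows = []
        for rve, (pt, pb), w in zip(self.rves, self.pressure_pairs,
                                    self.wss_fields):
            rows.append({
                "rve_index": rve.index,
                "p_top_Pa": pt,
                "p_bottom_Pa": pb,
                "wall_area_um2": w.total_area,
                "mean_wss_mPa": w.area_weighted_mean() * 1e3,
            })
        pd.DataFrame(rows).to_csv(out / "wss_per_rve.csv", index=False)
        artifacts["wss_per_rve"] = "wss_per_rve.csv"
        (out / "manifest.json").write_text(json.dumps({
            "kind": "multiscale_run",
            "artifacts": artifacts,
            "runtime_s": self.runtime_log,
        }, indent=2, sort_keys=True))
        return artifacts


@dataclass
class ValidationReport:
    """Multiscale-vs-direct comparison summary."""

    hist_multiscale: WSSHistogram
    hist_direct: WSSHistogram
    pearson_r: float
    region_averages_multiscale: list[float]
    region_averages_direct: list[float]
    percent_errors: list[float]
    runtime_log: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "bin_edges_mPa": [float(e) for e in self.hist_multiscale.bin_edges],
            "hist_multiscale": list(self.hist_multiscale.weights),
            "hist_direct": list(self.hist_direct.weights),
            "region_averages_multiscale_mPa": self.region_averages_multiscale,
            "region_averages_direct_mPa": self.region_averages_direct,
            "percent_errors": self.percent_errors,
            "runtime_s": self.runtime_log,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True, default=float))


def _stage(name: str, rve_index: int | None = None):
    tag = name if rve_index is None else f"{name}[rve {rve_index}]"

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {tag}: {exc}") from exc
            return False

    return _Ctx()


def run_multiscale(
    scaffold: VoxelImage,
    config: MultiscaleConfig | None = None,
    out_dir: str | Path | None = None,
) -> MultiscaleRun:
    """Execute the full multiscale loop on a scaffold image.

    Deterministic: the result is a pure function of the scaffold image and
    the configuration.
    """
    cfg = config or MultiscaleConfig()
    log: dict[str, float] = {}
    t0 = time.perf_counter()

    ex, ey, ez = scaffold.extent
    rve_xy = cfg.rve_xy_um or min(ex, ey) / 2.0
    with _stage("partition_rves"):
        rves = partition_rves(scaffold, cfg.rve_grid, rve_xy, cfg.footprint)

    perms: list[PermeabilityResult] = []
    domains: list[FluidDomain] = []
    for rve in rves:
        with _stage("permeability", rve.index):
            sub = extract_rve(scaffold, rve)
            dom = build_fluid_domain(sub)
            # pressure-driven probe: the prescribed end-to-end drop is the
            # clean Darcy measurement the pressure handoff relies on
            bc = MicroBC("pressure", cfg.permeability_probe_dp, 0.0, "symmetric")
            f = solve_stokes(dom, bc, cfg.props, tol=cfg.tol)
            perms.append(compute_permeability(f, rve_index=rve.index))
            domains.append(dom)
    kappa_bar = average_permeability(perms)
    log["permeability_stage"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    with _stage("macro"):
        model = MacroModel(
            kappa=kappa_bar,
            porous_height_mm=ez * 1e-3,
            channel_xy_mm=(ex * 1e-3, ey * 1e-3),
            channel_shape="box",
            entrance_mm=cfg.macro_entrance_heights * ez * 1e-3,
            exit_mm=cfg.macro_exit_heights * ez * 1e-3,
            props=cfg.props,
            inlet_velocity=None if cfg.flow_rate else cfg.inlet_velocity,
            flow_rate=cfg.flow_rate,
            wall_condition=cfg.macro_wall_condition,
            cells_across_height=cfg.macro_cells_across_height,
            origin_xy_um=(scaffold.origin[0], scaffold.origin[1]),
        )
        macro = solve_macro(model, tol=cfg.tol)
    log["macro_stage"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    pairs: list[tuple[float, float]] = []
    wss_fields: list[WSSField] = []
    wss_flows: list[FlowField] = []
    for rve, dom in zip(rves, domains):
        with _stage("wss", rve.index):
            p_top, p_bottom = extract_pressure_bcs(macro, rve)
            bc = MicroBC("pressure", p_top, p_bottom, "symmetric")
            f = solve_stokes(dom, bc, cfg.props, tol=cfg.tol)
            w = compute_wss(f, surface_model=cfg.wss_surface_model)
            pairs.append((p_top, p_bottom))
            wss_fields.append(w)
            wss_flows.append(f)
    log["wss_stage"] = time.perf_counter() - t2
    log["total"] = time.perf_counter() - t0

    run = MultiscaleRun(
        scaffold=scaffold, config=cfg, rves=rves, permeabilities=perms,
        kappa_bar=kappa_bar, macro=macro, pressure_pairs=pairs,
        wss_fields=wss_fields, wss_flows=wss_flows, runtime_log=log,
    )
    if out_dir is not None:
        run.save(out_dir)
    return run


def run_direct(
    scaffold: VoxelImage, config: MultiscaleConfig | None = None
) -> tuple[FlowField, WSSField]:
    """Direct pore-scale solve of the whole scaffold.

    Thin all-fluid plenum slabs are added above and below the scaffold so
    that a uniform inlet velocity over the full cross-section prescribes
    the same superficial flux as the macro model; lateral box faces are
    no-slip outer walls, the outlet is at the reference pressure. Fails
    early when the cell count exceeds the configured budget, pointing at
    the multiscale mode instead.
    """
    cfg = config or MultiscaleConfig()
    if not scaffold.is_binary():
        raise PipelineError("stage direct: scaffold must be a label image")
    n_cells_est = int(np.count_nonzero(scaffold.data)) + (
        2 * cfg.direct_pad_voxels * scaffold.shape[0] * scaffold.shape[1]
    )
    if n_cells_est > cfg.direct_cell_limit:
        raise PipelineError(
            f"stage direct: ~{n_cells_est} fluid cells exceed the budget of "
            f"{cfg.direct_cell_limit}; use the multiscale mode for scaffolds "
            "of this size"
        )
    pad = cfg.direct_pad_voxels
    data = np.pad(scaffold.data, ((0, 0), (0, 0), (pad, pad)),
                  constant_values=1)
    padded = VoxelImage(
        data, scaffold.voxel_size,
        (scaffold.origin[0], scaffold.origin[1],
         scaffold.origin[2] - pad * scaffold.voxel_size),
    )
    with _stage("direct"):
        dom = build_fluid_domain(padded)
        bc = MicroBC("velocity", cfg.inlet_velocity, 0.0, "no_slip")
        f = solve_stokes(dom, bc, cfg.props, tol=cfg.tol)
        w = compute_wss(f, surface_model=cfg.wss_surface_model)
    return f, w


def compare(
    multiscale: WSSField,
    direct: WSSField,
    footprint: tuple[tuple[float, float], tuple[float, float]],
    config: MultiscaleConfig | None = None,
) -> ValidationReport:
    """Compare two WSS fields over a common RVE/ROI footprint.

    Histograms are computed on identical bins and correlated bin-by-bin
    (Pearson); subregion averages use the square annuli of the footprint,
    with the direct field as the percent-error reference.
    """
    from scipy import stats

    cfg = config or MultiscaleConfig()
    ms = restrict_to_footprint(multiscale, footprint)
    dr = restrict_to_footprint(direct, footprint)
    if len(ms) == 0 or len(dr) == 0:
        raise ValueError("cannot compare empty WSS fields")
    h_ms = wss_histogram(ms, cfg.bin_width_mpa, cfg.max_mpa, cfg.weighting)
    h_dr = wss_histogram(dr, cfg.bin_width_mpa, cfg.max_mpa, cfg.weighting)
    if np.ptp(h_ms.weights) == 0 or np.ptp(h_dr.weights) == 0:
        r = 1.0 if np.allclose(h_ms.weights, h_dr.weights) else 0.0
    else:
        r = float(stats.pearsonr(h_ms.weights, h_dr.weights).statistic)
    avg_ms = subregion_average_wss(ms, footprint, cfg.subregion_count,
                                   cfg.subregion_width_um)
    avg_dr = subregion_average_wss(dr, footprint, cfg.subregion_count,
                                   cfg.subregion_width_um)
    errs = [
        abs(a - b) / abs(b) * 100.0 if b != 0 else float("nan")
        for a, b in zip(avg_ms, avg_dr)
    ]
    return ValidationReport(
        hist_multiscale=h_ms, hist_direct=h_dr, pearson_r=r,
        region_averages_multiscale=avg_ms, region_averages_direct=avg_dr,
        percent_errors=errs,
    )


def run_validation(
    seed: int,
    size: int = 64,
    porosity: float = 0.8,
    mean_pore_diameter_um: float = 80.0,
    voxel_size_um: float = 10.0,
    config: MultiscaleConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ValidationReport, MultiscaleRun]:
    """Scaled-down validation-study analogue on a synthetic scaffold.

    Generates a ``size³`` scaffold, runs the multiscale loop with a single
    central RVE of half the footprint, runs the direct solve of the whole
    scaffold, and compares WSS in the shared RVE/ROI footprint. The
    subregion width is scaled so the annuli tile the RVE half-width.
    """
    cfg = config or MultiscaleConfig()
    scaffold = generate_scaffold(
        porosity, mean_pore_diameter_um, (size, size, size), voxel_size_um,
        seed=seed,
    )
    rve_xy = size // 2 * voxel_size_um
    width = rve_xy / 2.0 / cfg.subregion_count
    from dataclasses import replace

    cfg = replace(cfg, rve_grid=(1, 1), rve_xy_um=rve_xy,
                  subregion_width_um=width)
    t0 = time.perf_counter()
    run = run_multiscale(scaffold, cfg)
    t1 = time.perf_counter()
    _, w_direct = run_direct(scaffold, cfg)
    t2 = time.perf_counter()
    report = compare(run.wss_fields[0], w_direct, run.rves[0].footprint(), cfg)
    report.runtime_log = {
        "multiscale_s": t1 - t0,
        "direct_s": t2 - t1,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / "validation_report.json")
        run.save(out)
    return report, run
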