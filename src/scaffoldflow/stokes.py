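"""Pore-scale creeping-flow solver.

At perfusion velocities of order 100 µm/s through pores of order 100 µm the
Reynolds number is far below one, so inertia is dropped and the steady
Stokes equations

    ∇·v = 0,       μ∇²v − ∇p = 0

are solved on the voxelized fluid domain. Linearity of the Stokes limit is
exploited throughout the package (permeability independent of the driving
strength, exact scaling checks); a Reynolds audit warns when the creeping
assumption would be violated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._mac import ConvergenceError, MacBC, MacSolution, solve_mac
from .geometry import FluidDomain

__all__ = [
    "FluidProps",
    "MicroBC",
    "FlowField",
    "ConvergenceError",
    "solve_stokes",
    "flow_rate",
    "reynolds_number",
]


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid properties (culture medium defaults: μ = 1.0 mPa·s,
    ρ = 1000 kg/m³)."""

    mu: float = 1.0e-3   # Pa·s
    rho: float = 1000.0  # kg/m³

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass(frozen=True)
class MicroBC:
    """Boundary conditions of a pore-scale solve.

    Exactly one inlet condition: a uniform velocity (m/s, permeability
    stage) or a uniform pressure (Pa, the macro-model handoff stage). The
    outlet always carries a reference pressure. Lateral faces are symmetry
    planes (zero normal velocity, zero normal gradient of the tangential
    velocity) or no-slip walls (the outer boundary of a direct solve).
    """

    inlet_kind: str = "velocity"
    inlet_value: float = 0.0
    outlet_pressure: float = 0.0
    lateral_kind: str = "symmetric"

    def to_mac(self) -> MacBC:
        return MacBC(
            inlet_kind=self.inlet_kind,
            inlet_value=self.inlet_value,
            outlet_pressure=self.outlet_pressure,
            lateral_kind=self.lateral_kind,
        )


@dataclass
class FlowField:
    """Converged velocity/pressure fields on a :class:`FluidDomain`.

    ``u, v, w`` are face-normal velocities on the staggered lattices (m/s);
    ``p`` cell-center pressures (Pa). No-slip on walls holds exactly by
    construction; the discrete divergence of every fluid cell is below the
    solver tolerance.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    domain: FluidDomain
    bc: MicroBC
    props: FluidProps
    residuals: dict[str, float] = field(default_factory=dict)
    iterations: int = 0

    @property
    def voxel_size_m(self) -> float:
        return self.domain.voxel_size * 1e-6

    def mean_pore_velocity(self) -> float:
        """Mean interstitial speed over fluid cells (m/s)."""
        m = self.domain.mask
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        speed = np.sqrt(uc**2 + vc**2 + wc**2)
        return float(speed[m].mean())

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for name in ("u", "v", "w", "p"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.create_dataset("mask", data=self.domain.mask)
            fh.attrs["voxel_size_um"] = self.domain.voxel_size
            fh.attrs["origin_um"] = self.domain.origin
            fh.attrs["mu_Pa_s"] = self.props.mu
            fh.attrs["rho_kg_m3"] = self.props.rho
            for k, v in self.residuals.items():
                fh.attrs[f"residual_{k}"] = v


def solve_stokes(
    domain: FluidDomain,
    bc: MicroBC,
    props: FluidProps,
    tol: float = 1e-4,
    maxiter: int = 5000,
) -> FlowField:
    """Solve steady Stokes flow on a percolating fluid domain.

    ``tol`` is the relative RMS residual target for both mass and momentum
    (default 1e-4; tighten for oracle tests). On success the inlet/outlet
    flux mismatch is audited against ``10·tol`` and the Reynolds number is
    checked against the creeping-flow regime.
    """
    sol: MacSolution = solve_mac(
        domain.mask, domain.voxel_size * 1e-6, props.mu, bc.to_mac(),
        tol=tol, maxiter=maxiter,
    )
    fld = FlowField(
        sol.u, sol.v, sol.w, sol.p, domain, bc, props,
        residuals=sol.residuals, iterations=sol.iterations,
    )
    q_in = flow_rate(fld, 0)
    q_out = flow_rate(fld, domain.shape[2])
    if q_in != 0.0:
        mismatch = abs(q_in - q_out) / abs(q_in)
        fld.residuals["flux_mismatch"] = mismatch
        if mismatch > 10 * tol:
            raise ConvergenceError(
                f"inlet/outlet flux mismatch {mismatch:.2e} exceeds 10*tol"
            )
        re = reynolds_number(fld)
        fld.residuals["reynolds"] = re
        if re > 1.0:
            warnings.warn(
                f"Re = {re:.2f} > 1: inertia is not negligible; the creeping-"
                "flow solution may misrepresent this regime", stacklevel=2,
            )
    return fld


def flow_rate(field: FlowField, plane: int) -> float:
    """Volumetric flow (m³/s) through the z-face plane ``plane`` ∈ [0, nz]:
    the sum of face-normal velocity times face area over fluid faces."""
    nz = field.domain.shape[2]
    if not 0 <= plane <= nz:
        raise ValueError(f"plane {plane} outside [0, {nz}]")
    h = field.voxel_size_m
    return float(field.w[:, :, plane].sum() * h * h)


def reynolds_number(field: FlowField) -> float:
    """Re = ρ·ū·d_pore/μ with ū the mean interstitial speed and the pore
    scale d_pore = 4·V_fluid/S_wall (hydraulic diameter of the pore space).
    All-fluid domains fall back to the lateral box size."""
    dom = field.domain
    h = field.voxel_size_m
    walls = dom.wall_faces()
    s_wall = sum(int(f.sum()) for f in walls.values()) * h * h
    v_fluid = int(dom.mask.sum()) * h**3
    if s_wall > 0:
        d_pore = 4.0 * v_fluid / s_wall
    else:
        d_pore = min(dom.shape[0], dom.shape[1]) * h
    return field.props.rho * field.mean_pore_velocity() * d_pore / field.props.mu
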