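"""Macro model: free-fluid perfusion channel containing a homogenized
porous scaffold region.

Rather than coupling a Darcy domain to a Navier–Stokes domain through
explicit interface conditions, the whole channel is solved as a single
Darcy–Brinkman (penalized Stokes) problem

    ∇·v = 0,      μ∇²v − (μ/κ_loc)·v − ∇p = 0,

with κ_loc equal to the homogenized scaffold permeability inside the
porous region and the drag term switched off in the free fluid. In the
creeping regime this is equivalent to the segregated two-domain
formulation, and continuity of the normal mass flux across the
fluid–porous interface holds by construction. The quantities handed back
to the pore-scale model are the plane-averaged pressures on the upstream
(``p_top``) and downstream (``p_bottom``) faces of the porous region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mac import MacBC, solve_mac
from .geometry import RVESpec
from .stokes import FluidProps

__all__ = ["MacroModel", "MacroSolution", "solve_macro", "extract_pressure_bcs"]


@dataclass
class MacroModel:
    """Geometry and driving conditions of the macro (channel) model.

    The channel axis is z; flow enters at z = 0 ("top" = upstream face of
    the porous region) and leaves at the outlet reference pressure. The
    porous region fills the channel cross-section between the entrance and
    exit free-fluid segments.

    Parameters
    ----------
    kappa:
        Homogenized scaffold permeability (m²).
    porous_height_mm:
        Scaffold height along the flow axis (mm).
    channel_shape / channel_xy_mm:
        ``"box"`` with (Lx, Ly) side lengths, or ``"cylinder"`` with a
        diameter (mm).
    entrance_mm / exit_mm:
        Free-fluid segments before/after the scaffold; default one scaffold
        height each.
    inlet_velocity / flow_rate:
        Superficial inlet velocity (m/s) or volumetric flow rate (m³/s);
        exactly one must be set.
    wall_condition:
        ``"no_slip"`` channel side walls (bioreactor) or ``"free_slip"``
        (idealized unbounded column).
    cells_across_height:
        Grid resolution: number of cells across the porous height.
    """

    kappa: float
    porous_height_mm: float
    channel_xy_mm: tuple[float, float] | float = 1.5
    channel_shape: str = "cylinder"
    entrance_mm: float | None = None
    exit_mm: float | None = None
    props: FluidProps = field(default_factory=FluidProps)
    inlet_velocity: float | None = None   # m/s, superficial
    flow_rate: float | None = None        # m³/s
    outlet_pressure: float = 0.0
    wall_condition: str = "no_slip"
    cells_across_height: int = 24
    origin_xy_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if (self.inlet_velocity is None) == (self.flow_rate is None):
            raise ValueError("set exactly one of inlet_velocity / flow_rate")
        if self.channel_shape not in ("box", "cylinder"):
            raise ValueError("channel_shape must be 'box' or 'cylinder'")
        if self.wall_condition not in ("no_slip", "free_slip"):
            raise ValueError("wall_condition must be 'no_slip' or 'free_slip'")
        if self.entrance_mm is None:
            self.entrance_mm = self.porous_height_mm
        if self.exit_mm is None:
            self.exit_mm = self.porous_height_mm

    @property
    def channel_area_m2(self) -> float:
        if self.channel_shape == "cylinder":
            d = float(self.channel_xy_mm) * 1e-3
            return np.pi * d * d / 4.0
        lx, ly = self.channel_xy_mm
        return lx * 1e-3 * ly * 1e-3

    @property
    def superficial_velocity(self) -> float:
        if self.inlet_velocity is not None:
            return self.inlet_velocity
        return self.flow_rate / self.channel_area_m2


@dataclass
class MacroSolution:
    """Macro velocity/pressure fields plus the pressure handoff pair."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    porous: np.ndarray
    cell_size_m: float
    model: MacroModel
    p_top: float
    p_bottom: float
    residuals: dict[str, float]

    @property
    def dp(self) -> float:
        """Pressure drop over the scaffold height (Pa)."""
        return self.p_top - self.p_bottom

    def _interface_planes(self) -> tuple[int, int]:
        kz = np.flatnonzero(self.porous.any(axis=(0, 1)))
        return int(kz[0]), int(kz[-1] + 1)

    def superficial_velocity(
        self,
        footprint_um: tuple[tuple[float, float], tuple[float, float]] | None = None,
    ) -> float:
        """Darcy (superficial) axial velocity at the porous mid-height
        (m/s), averaged over the full cross-section or over an xy
        footprint (µm). With no-slip channel walls the core velocity
        exceeds the channel mean; an RVE handoff is consistent with the
        macro field *at the RVE's own footprint*."""
        k0, k1 = self._interface_planes()
        km = (k0 + k1) // 2
        w = self.w[:, :, km]
        if footprint_um is None:
            return float(w.mean())
        (x0, x1), (y0, y1) = footprint_um
        dz_um = self.cell_size_m * 1e6
        ox, oy = self.model.origin_xy_um
        cx = ox + (np.arange(w.shape[0]) + 0.5) * dz_um
        cy = oy + (np.arange(w.shape[1]) + 0.5) * dz_um
        sel = np.ix_((cx >= x0) & (cx < x1), (cy >= y0) & (cy < y1))
        if w[sel].size == 0:
            raise ValueError("footprint selects no macro cells")
        return float(w[sel].mean())


def _face_pressure_from_inside(sol_p, mask, k_face, into, foot=None):
    """Fluid-averaged pressure at the z-face plane ``k_face``, linearly
    extrapolated from the two cell layers on the ``into`` side (+1 = layers
    above the face, -1 = below). Extrapolating from inside the porous
    region avoids the half-cell bias of interpolating across the kink in
    the pressure profile at the fluid–porous interface."""
    k0 = k_face if into > 0 else k_face - 1
    k1 = k0 + into
    m = mask[:, :, k0] & mask[:, :, k1]
    if foot is not None:
        m = m & foot
    if not m.any():
        raise ValueError("no fluid cells under the requested footprint")
    p0 = sol_p[:, :, k0][m].mean()
    p1 = sol_p[:, :, k1][m].mean()
    return float(p0 + 0.5 * (p0 - p1))


def solve_macro(model: MacroModel, tol: float = 1e-4) -> MacroSolution:
    """Solve the Darcy–Brinkman macro model on a uniform Cartesian grid."""
    hz = model.porous_height_mm * 1e-3
    dz = hz / model.cells_across_height
    ent = model.entrance_mm * 1e-3
    ext = model.exit_mm * 1e-3
    k0 = int(round(ent / dz))
    kp = model.cells_across_height
    k1 = k0 + kp
    nz = k1 + int(round(ext / dz))
    if model.channel_shape == "cylinder":
        d = float(model.channel_xy_mm) * 1e-3
        n = max(4, int(round(d / dz)))
        x = (np.arange(n) + 0.5 - n / 2.0) * dz
        X, Y = np.meshgrid(x, x, indexing="ij")
        section = X**2 + Y**2 < (d / 2.0) ** 2
        nx = ny = n
    else:
        lx, ly = model.channel_xy_mm
        nx = max(2, int(round(lx * 1e-3 / dz)))
        ny = max(2, int(round(ly * 1e-3 / dz)))
        section = np.ones((nx, ny), dtype=bool)
    mask = np.repeat(section[:, :, None], nz, axis=2)

    porous = np.zeros_like(mask)
    porous[:, :, k0:k1] = mask[:, :, k0:k1]
    drag = np.where(porous, model.props.mu / model.kappa, 0.0)

    # uniform inlet velocity over the open section carrying the target
    # superficial flux through the full channel cross-section
    u_in = model.superficial_velocity * model.channel_area_m2 / (
        section.sum() * dz * dz
    )
    bc = MacBC(
        inlet_kind="velocity",
        inlet_value=u_in,
        outlet_pressure=model.outlet_pressure,
        lateral_kind="no_slip" if model.wall_condition == "no_slip" else "symmetric",
    )
    sol = solve_mac(mask, dz, model.props.mu, bc, drag=drag, tol=tol)
    p_top = _face_pressure_from_inside(sol.p, mask, k0, +1)
    p_bottom = _face_pressure_from_inside(sol.p, mask, k1, -1)
    out = MacroSolution(
        sol.u, sol.v, sol.w, sol.p, mask, porous, dz, model,
        p_top=p_top, p_bottom=p_bottom, residuals=sol.residuals,
    )
    if out.dp <= 0:
        raise RuntimeError(
            f"non-physical macro pressure drop {out.dp:.3e} Pa over the scaffold"
        )
    return out


def extract_pressure_bcs(
    sol: MacroSolution, rve: RVESpec | None = None
) -> tuple[float, float]:
    """Pressure pair (p_top, p_bottom) for the pore-scale model.

    With no RVE (or a homogeneous κ) these are the global plane averages
    over the porous faces. Given an RVE, the averages are restricted to
    the RVE's xy footprint (macro cells whose centers fall inside it; the
    RVE must span the full porous height, which holds by construction).
    """
    if rve is None:
        return sol.p_top, sol.p_bottom
    (x0, x1), (y0, y1) = rve.footprint()
    dz_um = sol.cell_size_m * 1e6
    ox, oy = sol.model.origin_xy_um
    nx, ny, nz = sol.mask.shape
    cx = ox + (np.arange(nx) + 0.5) * dz_um
    cy = oy + (np.arange(ny) + 0.5) * dz_um
    in_x = (cx >= x0) & (cx < x1)
    in_y = (cy >= y0) & (cy < y1)
    foot = np.outer(in_x, in_y)
    if not foot.any():
        raise ValueError("RVE footprint lies outside the macro porous region")
    k0, k1 = sol._interface_planes()
    p_top = _face_pressure_from_inside(sol.p, sol.mask, k0, +1, foot)
    p_bottom = _face_pressure_from_inside(sol.p, sol.mask, k1, -1, foot)
    return p_top, p_bottom
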