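"""Darcy permeability homogenization of pore-scale flow solutions.

The axial permeability κ follows from Darcy's law in the form

    Q = (κ A / μ) · (Δp / H)

with Q the volumetric flow rate, A the *full* cross-sectional area of the
sample (solid + fluid), H the sample height along the flow axis, μ the
dynamic viscosity and Δp the axial pressure drop. Only the scalar axial
component is computed by default — the macro model consumes nothing else;
the full tensor (three orthogonal solves) is available as an extension
through :func:`permeability_tensor_axial`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .stokes import FlowField, FluidProps, flow_rate

__all__ = [
    "PermeabilityResult",
    "compute_permeability",
    "average_permeability",
    "permeability_table",
]


@dataclass(frozen=True)
class PermeabilityResult:
    """Axial Darcy permeability with the quantities that produced it.

    The stored fields satisfy Q = κA/μ · Δp/H exactly; ``check()``
    verifies the identity.
    """

    kappa: float   # m²
    Q: float       # m³/s
    A: float       # m² (full cross-section, solid + fluid)
    H: float       # m
    mu: float      # Pa·s
    dp: float      # Pa
    rve_index: int = 0

    def check(self, rtol: float = 1e-12) -> bool:
        lhs = self.Q
        rhs = self.kappa * self.A / self.mu * self.dp / self.H
        return bool(abs(lhs - rhs) <= rtol * max(abs(lhs), abs(rhs)))


def compute_permeability(
    field: FlowField, props: FluidProps | None = None, rve_index: int = 0
) -> PermeabilityResult:
    """Permeability of the RVE a converged flow field was solved on.

    For a pressure-driven solve the end-to-end pressure drop is the
    prescribed ghost difference, acting over ``H = (nz + 1)·h`` (the ghost
    planes sit half a voxel beyond either end); this is the clean probe
    the multiscale pressure handoff relies on, and the pipeline's
    permeability stage uses it. For a velocity-driven solve the forced
    uniform inlet produces a local entrance pressure loss, so the axial
    gradient is instead estimated by least-squares regression of the
    fluid-averaged plane pressure over the interior layers (margin
    ``max(2, nz // 8)``) and scaled by ``H = nz·h``; on columns much
    shorter than a few pore lengths this weights the interior and can
    deviate from the end-to-end resistance.
    """
    props = props or field.props
    dom = field.domain
    h = field.voxel_size_m
    nx, ny, nz = dom.shape
    area = nx * ny * h * h
    q = 0.5 * (flow_rate(field, 0) + flow_rate(field, nz))
    if field.bc.inlet_kind == "pressure":
        dp = field.bc.inlet_value - field.bc.outlet_pressure
        height = (nz + 1) * h
    else:
        margin = max(2, nz // 8)
        ks = np.arange(nz)
        if nz - 2 * margin < 2:  # sample too short to trim; use all planes
            margin = 0
        ks = ks[margin: nz - margin]
        pbar = np.array([
            field.p[:, :, k][dom.mask[:, :, k]].mean() for k in ks
        ])
        slope = -np.polyfit(ks, pbar, 1)[0] / h  # Pa/m, positive for +z flow
        height = nz * h
        dp = slope * height
    if dp <= 0:
        raise ValueError(f"non-physical axial pressure drop dp = {dp:.3e} Pa")
    kappa = q * props.mu * height / (area * dp)
    return PermeabilityResult(
        kappa=kappa, Q=q, A=area, H=height, mu=props.mu, dp=dp,
        rve_index=rve_index,
    )


def average_permeability(results: Sequence[PermeabilityResult]) -> float:
    """Arithmetic mean permeability over RVEs (m²)."""
    if len(results) == 0:
        raise ValueError("cannot average an empty list of permeabilities")
    return float(np.mean([r.kappa for r in results]))


def permeability_table(results: Iterable[PermeabilityResult]):
    """Per-RVE permeability summary as a DataFrame (units in headers)."""
    import pandas as pd

    rows = [
        {
            "rve_index": r.rve_index,
            "kappa_m2": r.kappa,
            "Q_m3_s": r.Q,
            "A_m2": r.A,
            "H_m": r.H,
            "mu_Pa_s": r.mu,
            "dp_Pa": r.dp,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
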