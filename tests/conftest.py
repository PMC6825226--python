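"""Shared fixtures: analytic channel geometries, solved flow fields, and
the (expensive, session-cached) multiscale-vs-direct validation study."""

from __future__ import annotations

import numpy as np
import pytest

from scaffoldflow import (
    FluidProps,
    MicroBC,
    VoxelImage,
    build_fluid_domain,
    solve_stokes,
)

VOX_UM = 10.0


@pytest.fixture(scope="session")
def props() -> FluidProps:
    return FluidProps(mu=1.0e-3, rho=1000.0)


def make_plates_image(gap: int = 20, ny: int = 4, nz: int = 60) -> VoxelImage:
    """Slot between two solid plates: gap voxels of fluid along x, solid
    walls at both x-extremes, open (symmetric) in y, flow along z."""
    data = np.ones((gap + 2, ny, nz), np.uint8)
    data[0] = 0
    data[-1] = 0
    return VoxelImage(data, VOX_UM)


def make_cylinder_image(radius: int = 10, pad: int = 2, nz: int = 40) -> VoxelImage:
    """Straight circular channel of ``radius`` voxels through a solid block."""
    n = 2 * (radius + pad)
    x = np.arange(n) + 0.5 - n / 2.0
    xx, yy = np.meshgrid(x, x, indexing="ij")
    data = np.zeros((n, n, nz), np.uint8)
    data[xx**2 + yy**2 < radius**2] = 1
    return VoxelImage(data, VOX_UM)


@pytest.fixture(scope="session")
def plates_field(props):
    """Velocity-driven plane-Poiseuille solve, tight tolerance."""
    dom = build_fluid_domain(make_plates_image())
    bc = MicroBC("velocity", 500e-6, 0.0, "symmetric")
    return solve_stokes(dom, bc, props, tol=1e-8)


@pytest.fixture(scope="session")
def cylinder_field(props):
    """Pressure-driven Hagen–Poiseuille solve, tight tolerance."""
    dom = build_fluid_domain(make_cylinder_image())
    bc = MicroBC("pressure", 1.0, 0.0, "symmetric")
    return solve_stokes(dom, bc, props, tol=1e-8)


@pytest.fixture(scope="session")
def validation_study():
    """Scaled-down multiscale-vs-direct study: ten 64³ synthetic scaffolds
    at porosity 0.8. Heavy — computed once per session and shared by the
    self-consistency and validation-analogue acceptance tests."""
    from scaffoldflow import run_validation

    out = []
    for seed in range(1, 11):
        report, run = run_validation(seed=seed, size=64)
        out.append({
            "seed": seed,
            "pearson_r": report.pearson_r,
            "percent_errors": report.percent_errors,
            "kappa_bar": run.kappa_bar,
            "v_micro": run.micro_superficial_velocity(0),
            "v_macro_fp": run.macro.superficial_velocity(
                run.rves[0].footprint()),
            "flux_mismatch": run.wss_flows[0].residuals.get("flux_mismatch"),
        })
    return out
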