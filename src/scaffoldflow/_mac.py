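"""Marker-and-cell (MAC) staggered-grid finite-volume discretization of
steady incompressible creeping flow on binary voxel domains, with optional
Brinkman drag, and a Schur-complement (Uzawa) conjugate-gradient solver.

Unknowns are face-normal velocities on fluid–fluid faces and pressures at
fluid cell centers. No-slip on fluid–solid interfaces is built into the
stencil (mirror ghosts at half-voxel distance), so walls are satisfied
exactly by construction. The assembled system is the symmetric saddle form

    A u + G p = fu,      -Gᵀ u = -fp   (continuity),

with A symmetric positive definite and block-diagonal over the three
velocity components. Small systems are solved by a sparse direct
factorization; larger ones by MINRES on the saddle system with an SPD
block-diagonal preconditioner — one smoothed-aggregation multigrid V-cycle
per velocity component and a SIMPLE-style diagonal Schur approximation
diag(Gᵀ diag(A)⁻¹ G) for the pressure block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

__all__ = ["MacBC", "MacSolution", "ConvergenceError", "solve_mac"]

# out-of-grid neighbor rules
_FREE = 0      # zero normal gradient (symmetry / outflow)
_MIRROR = 2    # Dirichlet 0 at half-voxel distance (no-slip / pinned plane)

# saddle systems up to this many unknowns go through SuperLU directly
_DIRECT_LIMIT = 20_000


class ConvergenceError(RuntimeError):
    """Raised when the iterative solver misses the residual target."""

    def __init__(self, message: str, history: list[float] | None = None):
        super().__init__(message)
        self.history = history or []


@dataclass
class MacBC:
    """Boundary conditions for a MAC solve.

    ``inlet_kind`` is ``"velocity"`` (uniform normal velocity on the fluid
    part of the −z box face, tangential components pinned to zero) or
    ``"pressure"`` (uniform ghost pressure, free tangential slip).
    The outlet (+z) always carries a reference ghost pressure. Lateral box
    faces are ``"no_slip"`` walls or ``"symmetric"`` planes (zero normal
    velocity, zero normal gradient of tangential velocity).
    """

    inlet_kind: str = "velocity"
    inlet_value: float = 0.0          # m/s or Pa
    outlet_pressure: float = 0.0      # Pa
    lateral_kind: str = "no_slip"

    def __post_init__(self) -> None:
        if self.inlet_kind not in ("velocity", "pressure"):
            raise ValueError("inlet_kind must be 'velocity' or 'pressure'")
        if self.lateral_kind not in ("no_slip", "symmetric"):
            raise ValueError("lateral_kind must be 'no_slip' or 'symmetric'")
        if not np.isfinite(self.outlet_pressure):
            raise ValueError("outlet pressure must be finite")


@dataclass
class MacSolution:
    """Dense face-velocity and cell-pressure fields of a converged solve.

    ``u, v, w`` live on the face lattices (``(nx+1, ny, nz)`` etc., m/s,
    zero on solid and wall faces); ``p`` on cells (Pa, zero in solid).
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    residuals: dict[str, float]
    iterations: int


def _face_shape(shape: tuple[int, int, int], ax: int) -> tuple[int, int, int]:
    s = list(shape)
    s[ax] += 1
    return tuple(s)


def _shift(arr: np.ndarray, ax: int, step: int, fill) -> np.ndarray:
    """out[idx] = arr[idx + step·e_ax], out-of-grid entries get ``fill``."""
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step == 1:
        src[ax] = slice(1, None)
        dst[ax] = slice(0, -1)
    else:
        src[ax] = slice(0, -1)
        dst[ax] = slice(1, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _outside_rule(a: int, b: int, step: int, bc: MacBC) -> int:
    """Ghost treatment for a neighbor face beyond the box boundary."""
    if b == a:
        # along-normal: only z-boundary w-faces reach here → free outflow
        return _FREE
    if b < 2:  # lateral box face
        return _MIRROR if bc.lateral_kind == "no_slip" else _FREE
    if step == -1:  # below the inlet plane (tangential component)
        return _MIRROR if bc.inlet_kind == "velocity" else _FREE
    return _FREE  # beyond the outlet


def _build_system(mask, h, mu, bc, drag):
    nx, ny, nz = mask.shape
    cid = np.full(mask.shape, -1, dtype=np.int64)
    n_cells = int(mask.sum())
    cid[mask] = np.arange(n_cells)

    fid, kval, unk = [], [], []
    offset = 0
    offsets = []
    for a in range(3):
        fs = _face_shape(mask.shape, a)
        f = np.full(fs, -1, dtype=np.int64)
        kv = np.zeros(fs)
        lo = _shift_cells(mask, a, -1)   # cell below the face along a
        hi = _shift_cells(mask, a, +1)   # cell above
        u = lo & hi
        if a == 2:
            if bc.inlet_kind == "pressure":
                u[:, :, 0] = mask[:, :, 0]
            else:
                kv[:, :, 0][mask[:, :, 0]] = bc.inlet_value
            u[:, :, -1] = mask[:, :, -1]
        nf = int(u.sum())
        f[u] = np.arange(offset, offset + nf)
        offsets.append((offset, nf))
        offset += nf
        fid.append(f)
        kval.append(kv)
        unk.append(u)
    n_faces = offset

    diag = np.zeros(n_faces)
    rows, cols, vals = [], [], []
    fu = np.zeros(n_faces)
    muh = mu * h

    for a in range(3):
        f, kv, u = fid[a], kval[a], unk[a]
        ids = f[u]
        for b in range(3):
            for step in (-1, +1):
                nb_id = _shift(f, b, step, -2)[u]
                nb_kv = _shift(kv, b, step, 0.0)[u]
                known = nb_id == -1
                inside = nb_id >= 0
                outside = nb_id == -2
                # fluid–fluid neighbor: standard 7-point viscous coupling
                np.add.at(diag, ids[inside], muh)
                rows.append(ids[inside])
                cols.append(nb_id[inside])
                vals.append(np.full(int(inside.sum()), -muh))
                if b == a:
                    # in-grid known face: velocity prescribed at distance h
                    np.add.at(diag, ids[known], muh)
                    np.add.at(fu, ids[known], muh * nb_kv[known])
                else:
                    # in-grid known tangential neighbor ⇒ wall at h/2
                    np.add.at(diag, ids[known], 2.0 * muh)
                rule = _outside_rule(a, b, step, bc)
                if rule == _MIRROR:
                    np.add.at(diag, ids[outside], 2.0 * muh)

        if drag is not None:
            alo = _shift_cells_val(drag, a, -1)
            ahi = _shift_cells_val(drag, a, +1)
            nlo = _shift_cells(np.ones(mask.shape, bool), a, -1)
            nhi = _shift_cells(np.ones(mask.shape, bool), a, +1)
            wsum = nlo.astype(float) + nhi.astype(float)
            aface = (alo + ahi) / np.maximum(wsum, 1.0)
            diag[ids] += aface[u] * h**3

    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_faces, n_faces),
    )
    A = A + sparse.diags(diag)

    # pressure gradient G (faces x cells) and continuity source fp
    g_rows, g_cols, g_vals = [], [], []
    h2 = h * h
    fp = np.zeros(n_cells)
    for a in range(3):
        f, kv, u = fid[a], kval[a], unk[a]
        ids = f[u]
        clo = _shift_cid(cid, a, -1)[u]
        chi = _shift_cid(cid, a, +1)[u]
        has_lo = clo >= 0
        has_hi = chi >= 0
        g_rows += [ids[has_hi], ids[has_lo]]
        g_cols += [chi[has_hi], clo[has_lo]]
        g_vals += [np.full(int(has_hi.sum()), h2), np.full(int(has_lo.sum()), -h2)]
        if a == 2:
            if bc.inlet_kind == "pressure":
                inlet_ids = f[:, :, 0][unk[2][:, :, 0]]
                fu[inlet_ids] += h2 * bc.inlet_value
            outlet_ids = f[:, :, -1][unk[2][:, :, -1]]
            fu[outlet_ids] += -h2 * bc.outlet_pressure
        # known faces feed the continuity source of their adjacent cells
        kn = (f == -1) & (kv != 0.0)
        if kn.any():
            clo_k = _shift_cid(cid, a, -1)[kn]
            chi_k = _shift_cid(cid, a, +1)[kn]
            kvk = kv[kn]
            sel = chi_k >= 0   # known face is the lower face of cell chi
            np.add.at(fp, chi_k[sel], h2 * kvk[sel])
            sel = clo_k >= 0   # known face is the upper face of cell clo
            np.add.at(fp, clo_k[sel], -h2 * kvk[sel])

    G = sparse.csr_matrix(
        (np.concatenate(g_vals), (np.concatenate(g_rows), np.concatenate(g_cols))),
        shape=(n_faces, n_cells),
    )
    comps = [slice(o, o + n) for o, n in offsets]
    return A, G, fu, fp, fid, unk, kval, comps


def _shift_cells(mask: np.ndarray, a: int, side: int) -> np.ndarray:
    """Fluid flag of the cell on the ``side`` of each face along axis a."""
    fs = _face_shape(mask.shape, a)
    out = np.zeros(fs, dtype=bool)
    sl = [slice(None)] * 3
    if side < 0:
        sl[a] = slice(1, None)
        out[tuple(sl)] = mask
    else:
        sl[a] = slice(0, -1)
        out[tuple(sl)] = mask
    return out


def _shift_cells_val(arr: np.ndarray, a: int, side: int) -> np.ndarray:
    fs = _face_shape(arr.shape, a)
    out = np.zeros(fs, dtype=float)
    sl = [slice(None)] * 3
    sl[a] = slice(1, None) if side < 0 else slice(0, -1)
    out[tuple(sl)] = arr
    return out


def _shift_cid(cid: np.ndarray, a: int, side: int) -> np.ndarray:
    fs = _face_shape(cid.shape, a)
    out = np.full(fs, -1, dtype=np.int64)
    sl = [slice(None)] * 3
    sl[a] = slice(1, None) if side < 0 else slice(0, -1)
    out[tuple(sl)] = cid
    return out


def solve_mac(
    mask: np.ndarray,
    voxel_size_m: float,
    mu: float,
    bc: MacBC,
    *,
    drag: np.ndarray | None = None,
    tol: float = 1e-4,
    maxiter: int = 20000,
) -> MacSolution:
    """Solve steady Stokes (or Brinkman, if ``drag`` = μ/κ per cell in
    Pa·s/m² is given) flow on the fluid ``mask``.

    ``tol`` is the convergence criterion: the root-mean-square mass and
    momentum residuals, relative to their initial (zero-field) values, must
    both drop below it.
    """
    mask = np.ascontiguousarray(mask, dtype=bool)
    h = float(voxel_size_m)
    A, G, fu, fp, fid, unk, kval, comps = _build_system(mask, h, mu, bc, drag)
    n_faces, n_cells = G.shape
    n_tot = n_faces + n_cells

    norm0 = np.sqrt(
        (np.linalg.norm(fu) ** 2 + np.linalg.norm(fp) ** 2) / max(n_tot, 1)
    )
    if norm0 == 0.0:
        return _package(mask, fid, unk, kval, np.zeros(n_faces),
                        np.zeros(n_cells), {"mass": 0.0, "momentum": 0.0}, 0)

    Gt = G.T.tocsr()
    rhs = np.concatenate([fu, -fp])

    def residuals(u, p):
        r_u = fu - A @ u - G @ p
        r_p = fp + Gt @ u
        return {
            "momentum": float(np.sqrt(np.mean(r_u**2)) / norm0),
            "mass": float(np.sqrt(np.mean(r_p**2)) / norm0),
        }

    if n_tot <= _DIRECT_LIMIT:
        K = sparse.bmat([[A, G], [Gt, None]], format="csc")
        lu = spla.splu(K)
        x = lu.solve(rhs)
        u, p = x[:n_faces], x[n_faces:]
        res = residuals(u, p)
        if max(res.values()) > tol:
            raise ConvergenceError(f"direct solve residuals {res} above tol")
        return _package(mask, fid, unk, kval, u, p, res, 0)

    # Symmetric equilibration: velocity rows by diag(A)^-1/2, pressure rows
    # by the SIMPLE Schur diagonal diag(G' diag(A)^-1 G)^-1/2. This brings
    # all blocks to O(1) so Krylov stopping tests behave.
    Ad = A.diagonal()
    Gc = G.tocoo()
    dS = np.zeros(n_cells)
    np.add.at(dS, Gc.col, Gc.data**2 / Ad[Gc.row])
    su = 1.0 / np.sqrt(Ad)
    sp = 1.0 / np.sqrt(dS)
    Du = sparse.diags(su)
    Dp = sparse.diags(sp)
    As = (Du @ A @ Du).tocsr()
    Gs = (Du @ G @ Dp).tocsr()
    K = sparse.bmat([[As, Gs], [Gs.T, None]], format="csr")
    scale = np.concatenate([su, sp])
    rhs_s = scale * rhs

    # SPD block-diagonal preconditioner: SA-multigrid V-cycle per velocity
    # component (unit pressure block after equilibration).
    from ._amg import VCyclePreconditioner

    amgs = []
    for a, sl in enumerate(comps):
        blk = As[sl, sl].tocsr()
        coords = np.argwhere(unk[a]).astype(np.int64)
        amgs.append(VCyclePreconditioner(blk, coords))

    def precond(x):
        out = np.array(x)
        for sl, amg in zip(comps, amgs):
            out[sl] = amg.solve(x[sl])
        return out

    M = spla.LinearOperator((n_tot, n_tot), precond)

    y = np.zeros(n_tot)
    history: list[float] = []
    rtol = max(1e-14, tol * 1e-3)
    iters = 0
    for attempt in range(5):
        cb = _IterCounter()
        y, info = spla.minres(K, rhs_s, x0=y, M=M, rtol=rtol,
                              maxiter=maxiter, callback=cb)
        iters += cb.n
        x = scale * y
        u, p = x[:n_faces], x[n_faces:]
        res = residuals(u, p)
        history.append(max(res.values()))
        if max(res.values()) <= tol:
            return _package(mask, fid, unk, kval, u, p, res, iters)
        rtol *= 0.05
    raise ConvergenceError(
        f"solver missed tol={tol}: residual history {history}", history
    )


class _IterCounter:
    def __init__(self):
        self.n = 0

    def __call__(self, _):
        self.n += 1


def _package(mask, fid, unk, kval, u_vec, p_vec, res, iters) -> MacSolution:
    fields = []
    for a in range(3):
        arr = np.array(kval[a])  # known faces carry their prescribed values
        arr[unk[a]] = u_vec[fid[a][unk[a]]]
        fields.append(arr)
    p = np.zeros(mask.shape)
    p[mask] = p_vec
    return MacSolution(fields[0], fields[1], fields[2], p, res, iters)
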