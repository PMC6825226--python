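"""Smoothed-aggregation multigrid for the face-Laplacian velocity blocks.

The MAC momentum blocks are 7-point Laplacians on irregular (masked)
uniform lattices. Aggregates are formed geometrically from the face lattice
coordinates (2x2x2 blocks), the tentative prolongator is smoothed by one
damped-Jacobi step, and coarse operators are Galerkin products. One
symmetric V(1,1) cycle with damped-Jacobi smoothing is used as an SPD
preconditioner inside MINRES/CG.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

__all__ = ["VCyclePreconditioner"]

_OMEGA = 2.0 / 3.0  # damped Jacobi weight; lambda_max(D^-1 A) <= 2 here


class _Level:
    def __init__(self, A: sparse.csr_matrix, P: sparse.csr_matrix):
        self.A = A
        self.P = P
        self.R = P.T.tocsr()
        self.dinv = 1.0 / A.diagonal()


class VCyclePreconditioner:
    """One symmetric V(1,1) smoothed-aggregation cycle per application."""

    def __init__(
        self,
        A: sparse.csr_matrix,
        coords: np.ndarray,
        *,
        direct_limit: int = 2500,
        max_levels: int = 12,
    ):
        self.levels: list[_Level] = []
        coords = np.asarray(coords, dtype=np.int64)
        while A.shape[0] > direct_limit and len(self.levels) < max_levels:
            P, coords = self._prolongator(A, coords)
            if P.shape[1] >= A.shape[0]:
                break
            lvl = _Level(A.tocsr(), P)
            self.levels.append(lvl)
            A = (lvl.R @ A @ P).tocsr()
            A.sum_duplicates()
        self.coarse = spla.splu(A.tocsc())
        self.shape = (self.levels[0].A.shape if self.levels
                      else A.shape)

    @staticmethod
    def _prolongator(A, coords):
        cc = coords // 2
        key = (cc[:, 0] * (2**21) + cc[:, 1]) * (2**21) + cc[:, 2]
        uniq, agg = np.unique(key, return_inverse=True)
        n, nc = A.shape[0], uniq.size
        P0 = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), agg)), shape=(n, nc)
        )
        dinv = 1.0 / A.diagonal()
        P = P0 - _OMEGA * sparse.diags(dinv) @ (A @ P0)
        # one representative lattice coordinate per aggregate
        order = np.argsort(key, kind="stable")
        first = order[np.searchsorted(key[order], uniq)]
        ccoords = cc[first]
        return P.tocsr(), ccoords

    def _cycle(self, k: int, b: np.ndarray) -> np.ndarray:
        if k == len(self.levels):
            return self.coarse.solve(b)
        lvl = self.levels[k]
        x = _OMEGA * lvl.dinv * b                     # pre-smooth from x0=0
        r = b - lvl.A @ x
        x = x + lvl.P @ self._cycle(k + 1, lvl.R @ r)
        r = b - lvl.A @ x
        x = x + _OMEGA * lvl.dinv * r                 # post-smooth
        return x

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self._cycle(0, b)
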