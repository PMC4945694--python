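"""Minimal quadratic-element finite-element core.

Provides the two isoparametric reference elements used by the cell model
(10-node tetrahedron, 6-node triangle, VTK node ordering), quadrature
rules, precomputed physical shape-function gradients per quadrature point,
and vectorized scalar assembly (mass / diffusion-stiffness matrices).
Geometry is quadratic, so boundary and interface facets snapped to the
spheres are integrated with their curvature.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.special import roots_jacobi, roots_legendre


# ---------------------------------------------------------------------------
# Reference elements (VTK orderings)

class RefTet10:
    """Quadratic tetrahedron; barycentric L = (1-x-y-z, x, y, z)."""

    dim = 3
    nnodes = 10
    vtk_type = 24
    edges = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]

    @staticmethod
    def shape(pts):
        pts = np.atleast_2d(pts)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        L = np.stack([1 - x - y - z, x, y, z], axis=1)
        N = np.empty((len(pts), 10))
        for i in range(4):
            N[:, i] = L[:, i] * (2 * L[:, i] - 1)
        for k, (i, j) in enumerate(RefTet10.edges):
            N[:, 4 + k] = 4 * L[:, i] * L[:, j]
        return N

    @staticmethod
    def shape_grad(pts):
        pts = np.atleast_2d(pts)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        L = np.stack([1 - x - y - z, x, y, z], axis=1)
        dL = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        dN = np.empty((len(pts), 10, 3))
        for i in range(4):
            dN[:, i, :] = (4 * L[:, i, None] - 1) * dL[i]
        for k, (i, j) in enumerate(RefTet10.edges):
            dN[:, 4 + k, :] = 4 * (L[:, i, None] * dL[j] + L[:, j, None] * dL[i])
        return dN


class RefTri6:
    """Quadratic triangle; barycentric L = (1-x-y, x, y)."""

    dim = 2
    nnodes = 6
    vtk_type = 22
    edges = [(0, 1), (1, 2), (2, 0)]

    @staticmethod
    def shape(pts):
        pts = np.atleast_2d(pts)
        x, y = pts[:, 0], pts[:, 1]
        L = np.stack([1 - x - y, x, y], axis=1)
        N = np.empty((len(pts), 6))
        for i in range(3):
            N[:, i] = L[:, i] * (2 * L[:, i] - 1)
        for k, (i, j) in enumerate(RefTri6.edges):
            N[:, 3 + k] = 4 * L[:, i] * L[:, j]
        return N

    @staticmethod
    def shape_grad(pts):
        pts = np.atleast_2d(pts)
        x, y = pts[:, 0], pts[:, 1]
        L = np.stack([1 - x - y, x, y], axis=1)
        dL = np.array([[-1.0, -1.0], [1, 0], [0, 1]])
        dN = np.empty((len(pts), 6, 2))
        for i in range(3):
            dN[:, i, :] = (4 * L[:, i, None] - 1) * dL[i]
        for k, (i, j) in enumerate(RefTri6.edges):
            dN[:, 3 + k, :] = 4 * (L[:, i, None] * dL[j] + L[:, j, None] * dL[i])
        return dN


# ---------------------------------------------------------------------------
# Quadrature

def tet_rule(degree: int):
    """Quadrature on the reference tetrahedron (weights sum to 1/6).

    degree <= 2 returns the classical 4-point rule; higher degrees use a
    positive-weight conical (Duffy / Gauss-Jacobi) product rule exact to the
    requested total degree.
    """
    if degree <= 2:
        a, b = (5 + 3 * np.sqrt(5)) / 20, (5 - np.sqrt(5)) / 20
        bary = np.full((4, 4), b) + (a - b) * np.eye(4)
        pts = bary[:, 1:]
        w = np.full(4, 1.0 / 24.0)
        return pts, w
    n = degree // 2 + 1
    # conical product: x = u, y = v(1-u), z = w(1-u)(1-v)
    xu, wu = roots_jacobi(n, 2, 0)   # weight (1-u)^2 on [-1,1]
    xv, wv = roots_jacobi(n, 1, 0)
    xw, ww = roots_legendre(n)
    xu, wu = (xu + 1) / 2, wu / 8
    xv, wv = (xv + 1) / 2, wv / 4
    xw, ww = (xw + 1) / 2, ww / 2
    pts, wts = [], []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                u, v, w_ = xu[i], xv[j], xw[k]
                pts.append((u, v * (1 - u), w_ * (1 - u) * (1 - v)))
                wts.append(wu[i] * wv[j] * ww[k])
    return np.array(pts), np.array(wts)


def tri_rule(degree: int):
    """Symmetric 6-point degree-4 rule on the reference triangle (area 1/2);
    sufficient for every 2D integrand used here."""
    a1, w1 = 0.445948490915965, 0.223381589678011
    a2, w2 = 0.091576213509771, 0.109951743655322
    pts = np.array([
        [a1, a1], [1 - 2 * a1, a1], [a1, 1 - 2 * a1],
        [a2, a2], [1 - 2 * a2, a2], [a2, 1 - 2 * a2],
    ])
    w = np.array([w1, w1, w1, w2, w2, w2]) / 2.0
    return pts, w


# ---------------------------------------------------------------------------
# FE space: precomputed per-quadrature-point data

class FESpace:
    """Isoparametric evaluation data on a mesh for one quadrature rule.

    Attributes
    ----------
    xq : (nel, nq, dim) physical quadrature-point coordinates
    w : (nel, nq) quadrature weights including |det J|
    dNdX : (nel, nq, nnodes, dim) physical shape-function gradients
    N : (nq, nnodes) reference shape values
    """

    def __init__(self, mesh, degree: int = 2):
        self.mesh = mesh
        ref = RefTet10 if mesh.dim == 3 else RefTri6
        self.ref = ref
        pts, wq = tet_rule(degree) if mesh.dim == 3 else tri_rule(degree)
        self.qpts, self.qw = pts, wq
        N = ref.shape(pts)                      # (nq, nn)
        dN = ref.shape_grad(pts)                # (nq, nn, dim)
        X = mesh.coords[mesh.conn]              # (nel, nn, dim)
        # mapping Jacobian J[e,q,i,j] = d x_i / d xi_j
        Jm = np.einsum("qnd,eni->eqid", dN, X)
        detJ = np.linalg.det(Jm)
        if np.any(detJ <= 0):
            bad = int(np.sum(detJ <= 0))
            raise ValueError(f"non-positive mapping Jacobian at {bad} quadrature points")
        Jinv = np.linalg.inv(Jm)
        self.dNdX = np.einsum("qnd,eqdi->eqni", dN, Jinv)
        self.w = detJ * wq[None, :]
        self.xq = np.einsum("qn,eni->eqi", N, X)
        self.N = N

    # -- scalar assembly ----------------------------------------------------

    def _ij(self):
        conn = self.mesh.conn
        nn = conn.shape[1]
        rows = np.repeat(conn, nn, axis=1)
        cols = np.tile(conn, (1, nn))
        return rows.ravel(), cols.ravel()

    def mass_matrix(self, weight=None) -> sparse.csr_matrix:
        """M_ij = integral weight * N_i N_j (weight per (e, q), default 1)."""
        w = self.w if weight is None else self.w * weight
        Ke = np.einsum("eq,qn,qm->enm", w, self.N, self.N)
        r, c = self._ij()
        n = self.mesh.nnodes
        return sparse.coo_matrix((Ke.ravel(), (r, c)), shape=(n, n)).tocsr()

    def stiffness_matrix(self, coeff=None) -> sparse.csr_matrix:
        """K_ij = integral coeff * grad N_i . grad N_j (coeff per (e, q))."""
        w = self.w if coeff is None else self.w * coeff
        Ke = np.einsum("eq,eqnd,eqmd->enm", w, self.dNdX, self.dNdX)
        r, c = self._ij()
        n = self.mesh.nnodes
        return sparse.coo_matrix((Ke.ravel(), (r, c)), shape=(n, n)).tocsr()

    def integrate(self, field=None) -> float:
        """Integral of a per-(e, q) field (default 1) over the mesh."""
        if field is None:
            return float(self.w.sum())
        return float((self.w * field).sum())

    def interpolate(self, nodal: np.ndarray) -> np.ndarray:
        """Nodal field -> values at quadrature points, (nel, nq, ...)."""
        vals = nodal[self.mesh.conn]            # (nel, nn, ...)
        return np.einsum("qn,en...->eq...", self.N, vals)

    def gradient(self, nodal: np.ndarray) -> np.ndarray:
        """Nodal scalar field -> physical gradient at qps, (nel, nq, dim)."""
        vals = nodal[self.mesh.conn]
        return np.einsum("eqnd,en->eqd", self.dNdX, vals)
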