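"""Lagrange finite elements (order 1 and 2) on tetrahedral meshes.

Provides stiffness assembly with per-tetrahedron conductivity, boundary
mass/load terms on triangle facet sets (for Robin conditions and surface
integrals), gradient-based flux integration, and point evaluation of
solutions.  Everything is assembled with scipy.sparse; quadrature rules are
exact for the polynomial degrees involved (degree-2 rule on tets for P2
stiffness, degree-4 rule on triangles for P2 boundary mass).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .mesh import Mesh, tet_volumes, triangle_areas

__all__ = ["FESpace", "PointLocator"]

# tet quadrature, degree 2 (4 points, weights sum to 1)
_TA = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_TB = (5.0 - np.sqrt(5.0)) / 20.0
_TET_Q = np.array([
    [_TA, _TB, _TB, _TB],
    [_TB, _TA, _TB, _TB],
    [_TB, _TB, _TA, _TB],
    [_TB, _TB, _TB, _TA],
])
_TET_W = np.full(4, 0.25)

# triangle quadrature, degree 4 (6 points, weights sum to 1)
_TRI_Q = np.array([
    [0.816847572980459, 0.091576213509771, 0.091576213509771],
    [0.091576213509771, 0.816847572980459, 0.091576213509771],
    [0.091576213509771, 0.091576213509771, 0.816847572980459],
    [0.108103018168070, 0.445948490915965, 0.445948490915965],
    [0.445948490915965, 0.108103018168070, 0.445948490915965],
    [0.445948490915965, 0.445948490915965, 0.108103018168070],
])
_TRI_W = np.array([0.109951743655322] * 3 + [0.223381589678011] * 3)

_TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_TRI_EDGES = [(0, 1), (1, 2), (0, 2)]


def _p2_tet_shape(lam: np.ndarray) -> np.ndarray:
    """P2 shape values at barycentric coordinates lam (..., 4) -> (..., 10)."""
    out = np.empty(lam.shape[:-1] + (10,))
    for i in range(4):
        out[..., i] = lam[..., i] * (2.0 * lam[..., i] - 1.0)
    for k, (i, j) in enumerate(_TET_EDGES):
        out[..., 4 + k] = 4.0 * lam[..., i] * lam[..., j]
    return out


def _p2_tri_shape(lam: np.ndarray) -> np.ndarray:
    out = np.empty(lam.shape[:-1] + (6,))
    for i in range(3):
        out[..., i] = lam[..., i] * (2.0 * lam[..., i] - 1.0)
    for k, (i, j) in enumerate(_TRI_EDGES):
        out[..., 3 + k] = 4.0 * lam[..., i] * lam[..., j]
    return out


class FESpace:
    """Continuous Lagrange space of order 1 or 2 on a tetrahedral mesh."""

    def __init__(self, mesh: Mesh, order: int = 1):
        if order not in (1, 2):
            raise ValueError("element order must be 1 or 2")
        self.mesh = mesh
        self.order = order
        if order == 1:
            self.ndof = mesh.n_nodes
            self._edge_index = None
        else:
            edges = np.vstack([np.sort(mesh.tets[:, e], axis=1) for e in
                               (np.array(p) for p in _TET_EDGES)])
            uniq, inv = np.unique(edges, axis=0, return_inverse=True)
            self._edges = uniq                       # (E, 2)
            self._edge_index = {(int(a), int(b)): k
                                for k, (a, b) in enumerate(uniq)}
            ne = len(mesh.tets)
            self._tet_edge_dofs = (mesh.n_nodes +
                                   inv.reshape(6, ne).T)  # (M, 6)
            self.ndof = mesh.n_nodes + len(uniq)
        self._grads = None
        self._vols = None

    # -- dof bookkeeping -------------------------------------------------

    def tet_dofs(self) -> np.ndarray:
        """(M, 4) or (M, 10) global dof indices per tetrahedron."""
        if self.order == 1:
            return self.mesh.tets
        return np.hstack([self.mesh.tets, self._tet_edge_dofs])

    def tri_dofs(self, tris: np.ndarray) -> np.ndarray:
        """(K, 3) or (K, 6) dof indices per triangle facet."""
        tris = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
        if self.order == 1:
            return tris
        out = np.empty((len(tris), 6), dtype=np.int64)
        out[:, :3] = tris
        for k, (i, j) in enumerate(_TRI_EDGES):
            pairs = np.sort(tris[:, [i, j]], axis=1)
            out[:, 3 + k] = [self.mesh.n_nodes + self._edge_index[(int(a), int(b))]
                             for a, b in pairs]
        return out

    def dof_coords(self) -> np.ndarray:
        if self.order == 1:
            return self.mesh.nodes
        mid = 0.5 * (self.mesh.nodes[self._edges[:, 0]] +
                     self.mesh.nodes[self._edges[:, 1]])
        return np.vstack([self.mesh.nodes, mid])

    # -- geometry --------------------------------------------------------

    def _bary_grads(self):
        """Gradients of barycentric coordinates per tet: (M, 4, 3); and volumes."""
        if self._grads is None:
            nodes, tets = self.mesh.nodes, self.mesh.tets
            a = nodes[tets[:, 0]]
            # rows of E are the edge vectors p_k - p_0; lam_k = (E^{-T} (x-a))_k,
            # so grad lam_k is column k of E^{-1}.
            E = np.stack([nodes[tets[:, k]] - a for k in (1, 2, 3)], axis=1)
            Einv = np.linalg.inv(E)
            g = np.empty((len(tets), 4, 3))
            g[:, 1:, :] = np.transpose(Einv, (0, 2, 1))
            g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
            self._grads = g
            self._vols = np.abs(tet_volumes(nodes, tets))
        return self._grads, self._vols

    def volumes(self) -> np.ndarray:
        return self._bary_grads()[1]

    # -- assembly --------------------------------------------------------

    def assemble_stiffness(self, sigma_per_tet) -> sp.csr_matrix:
        """Assemble int sigma grad(u).grad(v) dx."""
        g, vols = self._bary_grads()
        sig = np.broadcast_to(np.asarray(sigma_per_tet, dtype=float),
                              (self.mesh.n_tets,))
        dofs = self.tet_dofs()
        nloc = dofs.shape[1]
        rows_all, cols_all, vals_all = [], [], []
        chunk = 200_000 if self.order == 1 else 50_000
        for s in range(0, self.mesh.n_tets, chunk):
            sl = slice(s, min(s + chunk, self.mesh.n_tets))
            gc, vc, sc, dc = g[sl], vols[sl], sig[sl], dofs[sl]
            if self.order == 1:
                Ke = np.einsum("tid,tjd->tij", gc, gc) * (vc * sc)[:, None, None]
            else:
                Ke = np.zeros((len(vc), 10, 10))
                for q, wq in zip(_TET_Q, _TET_W):
                    # gradients of P2 shapes at this quadrature point
                    B = np.empty((len(vc), 10, 3))
                    for i in range(4):
                        B[:, i, :] = (4.0 * q[i] - 1.0) * gc[:, i, :]
                    for k, (i, j) in enumerate(_TET_EDGES):
                        B[:, 4 + k, :] = 4.0 * (q[i] * gc[:, j, :] +
                                                q[j] * gc[:, i, :])
                    Ke += wq * np.einsum("tid,tjd->tij", B, B)
                Ke *= (vc * sc)[:, None, None]
            rows_all.append(np.repeat(dc, nloc, axis=1).ravel())
            cols_all.append(np.tile(dc, (1, nloc)).ravel())
            vals_all.append(Ke.ravel())
        K = sp.coo_matrix((np.concatenate(vals_all),
                           (np.concatenate(rows_all), np.concatenate(cols_all))),
                          shape=(self.ndof, self.ndof))
        return K.tocsr()

    def assemble_boundary_mass(self, tris) -> sp.csr_matrix:
        """int u v ds over the given facet set."""
        tris = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
        areas = triangle_areas(self.mesh.nodes, tris)
        dofs = self.tri_dofs(tris)
        nloc = dofs.shape[1]
        if self.order == 1:
            base = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0
            Me = base[None, :, :] * areas[:, None, None]
        else:
            N = _p2_tri_shape(_TRI_Q)                   # (6q, 6)
            base = np.einsum("q,qi,qj->ij", _TRI_W, N, N)
            Me = base[None, :, :] * areas[:, None, None]
        rows = np.repeat(dofs, nloc, axis=1).ravel()
        cols = np.tile(dofs, (1, nloc)).ravel()
        M = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(self.ndof, self.ndof))
        return M.tocsr()

    def assemble_boundary_load(self, tris) -> np.ndarray:
        """Vector of int N_i ds over the given facet set (so b @ u = int u ds)."""
        tris = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
        areas = triangle_areas(self.mesh.nodes, tris)
        dofs = self.tri_dofs(tris)
        b = np.zeros(self.ndof)
        if self.order == 1:
            be = np.repeat(areas[:, None] / 3.0, 3, axis=1)
        else:
            N = _p2_tri_shape(_TRI_Q)
            base = _TRI_W @ N                           # (6,)
            be = areas[:, None] * base[None, :]
        np.add.at(b, dofs.ravel(), be.ravel())
        return b

    def lumped_boundary_mass(self, tris) -> np.ndarray:
        """Row-sum (lumped) diagonal of the boundary mass matrix, as a vector."""
        return self.assemble_boundary_load(tris)

    def facet_dof_set(self, tris) -> np.ndarray:
        """Unique dof indices lying on the given facet set."""
        return np.unique(self.tri_dofs(tris).ravel())

    # -- evaluation ------------------------------------------------------

    def eval_in_tets(self, u: np.ndarray, tet_idx: np.ndarray,
                     lam: np.ndarray) -> np.ndarray:
        """Evaluate u at barycentric coordinates lam (n,4) inside tets tet_idx."""
        dofs = self.tet_dofs()[tet_idx]
        if self.order == 1:
            N = lam
        else:
            N = _p2_tet_shape(lam)
        return np.einsum("ni,ni->n", u[dofs], N)

    def grad_in_tets(self, u: np.ndarray, tet_idx: np.ndarray,
                     lam: np.ndarray) -> np.ndarray:
        """Gradient of u at barycentric points inside the given tets: (n, 3)."""
        g, _ = self._bary_grads()
        g = g[tet_idx]                                  # (n, 4, 3)
        dofs = self.tet_dofs()[tet_idx]
        if self.order == 1:
            B = g
        else:
            n = len(tet_idx)
            B = np.empty((n, 10, 3))
            for i in range(4):
                B[:, i, :] = (4.0 * lam[:, i, None] - 1.0) * g[:, i, :]
            for k, (i, j) in enumerate(_TET_EDGES):
                B[:, 4 + k, :] = 4.0 * (lam[:, i, None] * g[:, j, :] +
                                        lam[:, j, None] * g[:, i, :])
        return np.einsum("nid,ni->nd", B, u[dofs])

    def gradient_flux(self, u: np.ndarray, tris, owners, sigma_per_tet) -> float:
        """int sigma grad(u).n ds over facets, n the outward normal of the owner."""
        tris = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
        owners = np.asarray(owners, dtype=np.int64)
        mesh = self.mesh
        areas = triangle_areas(mesh.nodes, tris)
        normals = mesh.outward_normals(tris, owners)
        sig = np.broadcast_to(np.asarray(sigma_per_tet, dtype=float),
                              (mesh.n_tets,))[owners]
        total = 0.0
        for q, wq in zip(_TRI_Q, _TRI_W):
            pts = (q[0] * mesh.nodes[tris[:, 0]] + q[1] * mesh.nodes[tris[:, 1]] +
                   q[2] * mesh.nodes[tris[:, 2]])
            lam = _barycentric(mesh, owners, pts)
            gr = self.grad_in_tets(u, owners, lam)
            total += wq * np.sum(sig * areas * np.einsum("nd,nd->n", gr, normals))
        return float(total)


def _barycentric(mesh: Mesh, tet_idx: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of pts w.r.t. the given tets."""
    tets = mesh.tets[tet_idx]
    a = mesh.nodes[tets[:, 0]]
    T = np.stack([mesh.nodes[tets[:, k]] - a for k in (1, 2, 3)], axis=2)  # (n,3,3)
    rhs = pts - a
    lam123 = np.linalg.solve(T, rhs[..., None])[..., 0]
    lam0 = 1.0 - lam123.sum(axis=1)
    return np.column_stack([lam0, lam123])


class PointLocator:
    """Locates points inside a tetrahedral mesh via a centroid kd-tree."""

    def __init__(self, mesh: Mesh, tet_subset: np.ndarray | None = None):
        self.mesh = mesh
        self.subset = (np.arange(mesh.n_tets) if tet_subset is None
                       else np.asarray(tet_subset, dtype=np.int64))
        cent = mesh.nodes[mesh.tets[self.subset]].mean(axis=1)
        self.tree = cKDTree(cent)

    def locate(self, points: np.ndarray, tol: float = 1e-8):
        """Return (tet_idx, lam) for each point; tet_idx = -1 if not found."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        n = len(points)
        out_tet = np.full(n, -1, dtype=np.int64)
        out_lam = np.zeros((n, 4))
        k = min(32, len(self.subset))
        _, idx = self.tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        pending = np.arange(n)
        for col in range(idx.shape[1]):
            if not len(pending):
                break
            cand = self.subset[idx[pending, col]]
            lam = _barycentric(self.mesh, cand, points[pending])
            ok = np.all(lam > -tol, axis=1) & np.all(lam < 1 + tol, axis=1)
            hit = pending[ok]
            out_tet[hit] = cand[ok]
            out_lam[hit] = lam[ok]
            pending = pending[~ok]
        if len(pending):
            # exhaustive fallback for stragglers (rare: points near facets)
            for p in pending:
                cand = self.subset
                lam = _barycentric(self.mesh, cand, np.repeat(points[p][None], len(cand), axis=0))
                ok = np.all(lam > -1e-6, axis=1)
                if np.any(ok):
                    j = int(np.argmax(np.min(lam, axis=1)))
                    out_tet[p] = cand[j]
                    out_lam[p] = lam[j]
        return out_tet, out_lam
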