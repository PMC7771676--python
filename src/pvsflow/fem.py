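"""Minimal P2/P1 tetrahedral finite-element core.

This module provides exactly what the moving-domain Stokes solver needs:

* :class:`TetMesh` — tetrahedral volume mesh with unique edges, tagged
  oriented boundary faces, and quadratic (P2) node bookkeeping;
* isoparametric quadratic geometry: every element carries 10 geometry nodes,
  so meshes whose edge nodes are placed on curved surfaces (cylinders)
  represent those surfaces to third order;
* vectorized assembly of the scalar mass/stiffness/ALE-advection operators,
  the velocity-pressure divergence coupling, boundary traction load vectors,
  surface fluxes/areas and nodal boundary normals;
* a direct saddle-point solve with Dirichlet elimination.

Velocity uses continuous piecewise quadratics (one scalar block per
component, dof = 3*node + component), pressure continuous piecewise linears
on the vertices — the lowest-order Taylor-Hood pair, which is inf-sup
stable. Quadrature is a conical-product Gauss-Jacobi rule exact to total
degree 5 (27 points per tetrahedron, 9 per boundary triangle).

Coordinates handed to the assembly routines are in metres; the mesh
container itself is unit-agnostic.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import roots_jacobi, roots_legendre

from .errors import GeometryError, SolverError

# boundary tag ids (documented in output metadata)
TAG_INNER_WALL = 1
TAG_OUTER_WALL = 2
TAG_INLET = 3
TAG_OUTLET_1 = 4
TAG_OUTLET_2 = 5
TAG_NAMES = {1: "inner_wall", 2: "outer_wall", 3: "inlet", 4: "outlet_1", 5: "outlet_2"}

_EDGE_LOCAL = np.array([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
# local faces of a positively oriented tet, ordered so the triangle normal
# (cross of its first two edge vectors) points outward
_FACE_LOCAL = np.array([(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)])


# ---------------------------------------------------------------------------
# quadrature and basis functions


def _gauss01(n, alpha):
    """Gauss points/weights on [0,1] with weight (1-x)^alpha."""
    if alpha == 0:
        x, w = roots_legendre(n)
        return (x + 1.0) / 2.0, w / 2.0
    x, w = roots_jacobi(n, alpha, 0.0)
    return (x + 1.0) / 2.0, w * 0.5 ** (alpha + 1)


def tet_quadrature(n: int = 3):
    """Conical-product rule on the reference tetrahedron, degree 2n-1."""
    u, wu = _gauss01(n, 2)
    v, wv = _gauss01(n, 1)
    t, wt = _gauss01(n, 0)
    U, V, T = np.meshgrid(u, v, t, indexing="ij")
    WU, WV, WT = np.meshgrid(wu, wv, wt, indexing="ij")
    xi = U.ravel()
    eta = (V * (1 - U)).ravel()
    zeta = (T * (1 - U) * (1 - V)).ravel()
    w = (WU * WV * WT).ravel()
    return np.column_stack([xi, eta, zeta]), w


def tri_quadrature(n: int = 3):
    """Conical-product rule on the reference triangle, degree 2n-1."""
    u, wu = _gauss01(n, 1)
    v, wv = _gauss01(n, 0)
    U, V = np.meshgrid(u, v, indexing="ij")
    WU, WV = np.meshgrid(wu, wv, indexing="ij")
    xi = U.ravel()
    eta = (V * (1 - U)).ravel()
    return np.column_stack([xi, eta]), (WU * WV).ravel()


def p2_tet_basis(pts):
    """P2 shape functions / reference gradients at points (nq, 3)."""
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    lam = np.column_stack([1 - xi - eta - zeta, xi, eta, zeta])  # (nq, 4)
    dlam = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    nq = pts.shape[0]
    N = np.empty((nq, 10))
    dN = np.empty((nq, 10, 3))
    for i in range(4):
        N[:, i] = lam[:, i] * (2 * lam[:, i] - 1)
        dN[:, i, :] = (4 * lam[:, i] - 1)[:, None] * dlam[i]
    for k, (i, j) in enumerate(_EDGE_LOCAL):
        N[:, 4 + k] = 4 * lam[:, i] * lam[:, j]
        dN[:, 4 + k, :] = 4 * (lam[:, i][:, None] * dlam[j] + lam[:, j][:, None] * dlam[i])
    return N, dN


def p1_tet_basis(pts):
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    N = np.column_stack([1 - xi - eta - zeta, xi, eta, zeta])
    dN = np.broadcast_to(
        np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float),
        (pts.shape[0], 4, 3),
    ).copy()
    return N, dN


def p2_tri_basis(pts):
    """6-node triangle: vertices a,b,c then edge nodes (a,b),(b,c),(c,a)."""
    u, v = pts[:, 0], pts[:, 1]
    lam = np.column_stack([1 - u - v, u, v])
    dlam = np.array([[-1, -1], [1, 0], [0, 1]], dtype=float)
    nq = pts.shape[0]
    N = np.empty((nq, 6))
    dN = np.empty((nq, 6, 2))
    for i in range(3):
        N[:, i] = lam[:, i] * (2 * lam[:, i] - 1)
        dN[:, i, :] = (4 * lam[:, i] - 1)[:, None] * dlam[i]
    for k, (i, j) in enumerate([(0, 1), (1, 2), (2, 0)]):
        N[:, 3 + k] = 4 * lam[:, i] * lam[:, j]
        dN[:, 3 + k, :] = 4 * (lam[:, i][:, None] * dlam[j] + lam[:, j][:, None] * dlam[i])
    return N, dN


_QTET, _WTET = tet_quadrature(3)
_NTET10, _DNTET10 = p2_tet_basis(_QTET)
_NTET4, _DNTET4 = p1_tet_basis(_QTET)
_QTRI, _WTRI = tri_quadrature(3)
_NTRI6, _DNTRI6 = p2_tri_basis(_QTRI)
# reference coordinates of the 6 triangle nodes (for nodal normals)
_TRI_NODE_REF = np.array(
    [[0, 0], [1, 0], [0, 1], [0.5, 0], [0.5, 0.5], [0, 0.5]], dtype=float
)
_NTRI6_AT_NODES, _DNTRI6_AT_NODES = p2_tri_basis(_TRI_NODE_REF)


# ---------------------------------------------------------------------------
# mesh container


class TetMesh:
    """Tetrahedral mesh with P2 node bookkeeping and tagged boundary faces.

    Parameters
    ----------
    verts : (V, 3) float array
    cells : (T, 4) int array; reoriented in place to positive volume.
    """

    def __init__(self, verts, cells):
        verts = np.asarray(verts, dtype=float)
        cells = np.asarray(cells, dtype=np.int64)
        if cells.size == 0:
            raise GeometryError("empty mesh")
        # orient all tets positively
        e1 = verts[cells[:, 1]] - verts[cells[:, 0]]
        e2 = verts[cells[:, 2]] - verts[cells[:, 0]]
        e3 = verts[cells[:, 3]] - verts[cells[:, 0]]
        vol6 = np.einsum("ij,ij->i", e1, np.cross(e2, e3))
        neg = vol6 < 0
        cells[neg] = cells[neg][:, [0, 1, 3, 2]]
        if np.any(np.abs(vol6) < 1e-30):
            raise GeometryError("degenerate (zero-volume) tetrahedra in mesh")
        self.verts = verts
        self.cells = cells
        self.n_verts = verts.shape[0]
        self.n_cells = cells.shape[0]

        # unique edges
        e = cells[:, _EDGE_LOCAL]  # (T, 6, 2)
        e = np.sort(e.reshape(-1, 2), axis=1)
        edges, inv = np.unique(e, axis=0, return_inverse=True)
        self.edges = edges
        self.cell_edges = inv.reshape(self.n_cells, 6)
        self.n_edges = edges.shape[0]
        self.n_p2 = self.n_verts + self.n_edges
        # P2 connectivity: 4 vertex nodes then 6 edge nodes
        self.cells_p2 = np.hstack([cells, self.n_verts + self.cell_edges])

        # boundary faces (oriented outward, owner cell recorded)
        faces = cells[:, _FACE_LOCAL].reshape(-1, 3)
        keys = np.sort(faces, axis=1)
        _, idx, counts = np.unique(keys, axis=0, return_index=True, return_counts=True)
        bidx = np.sort(idx[counts == 1])
        self.boundary_faces = faces[bidx]
        self.boundary_face_cell = bidx // 4
        self.n_boundary_faces = self.boundary_faces.shape[0]
        self.face_tags = np.zeros(self.n_boundary_faces, dtype=np.int32)

        # face P2 connectivity (3 vertex + 3 edge nodes)
        code_e = self.edges[:, 0] * self.n_verts + self.edges[:, 1]
        f = self.boundary_faces
        fedges = np.stack(
            [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=1
        )  # (F, 3, 2)
        fe = np.sort(fedges.reshape(-1, 2), axis=1)
        code_q = fe[:, 0] * self.n_verts + fe[:, 1]
        eid = np.searchsorted(code_e, code_q)
        if not np.array_equal(code_e[eid], code_q):
            raise GeometryError("boundary face edge lookup failed")
        self.faces_p2 = np.hstack(
            [f, self.n_verts + eid.reshape(-1, 3)]
        )

        # default P2 coordinates: edge midpoints (generators may override to
        # place them on curved surfaces)
        self.coords_p2 = np.vstack(
            [verts, 0.5 * (verts[edges[:, 0]] + verts[edges[:, 1]])]
        )

    # -- queries ----------------------------------------------------------

    def faces_with_tag(self, tag: int) -> np.ndarray:
        return self.faces_p2[self.face_tags == tag]

    def p2_nodes_with_tag(self, tag: int) -> np.ndarray:
        return np.unique(self.faces_with_tag(tag))

    def verts_with_tag(self, tag: int) -> np.ndarray:
        return np.unique(self.boundary_faces[self.face_tags == tag])


# ---------------------------------------------------------------------------
# geometry at quadrature points


def _inv_det_3x3(J):
    """Vectorized inverse and determinant of (..., 3, 3) arrays."""
    a, b, c = J[..., 0, 0], J[..., 0, 1], J[..., 0, 2]
    d, e, f = J[..., 1, 0], J[..., 1, 1], J[..., 1, 2]
    g, h, i = J[..., 2, 0], J[..., 2, 1], J[..., 2, 2]
    A, B, C = e * i - f * h, c * h - b * i, b * f - c * e
    D, E, F = f * g - d * i, a * i - c * g, c * d - a * f
    G, H, I = d * h - e * g, b * g - a * h, a * e - b * d
    det = a * A + d * B + g * C
    inv = np.empty_like(J)
    inv[..., 0, 0], inv[..., 0, 1], inv[..., 0, 2] = A, B, C
    inv[..., 1, 0], inv[..., 1, 1], inv[..., 1, 2] = D, E, F
    inv[..., 2, 0], inv[..., 2, 1], inv[..., 2, 2] = G, H, I
    inv /= det[..., None, None]
    return inv, det


def element_geometry(coords_p2, cells_p2):
    """detJ (T, nq) and physical P2/P1 gradients at quadrature points."""
    Xe = coords_p2[cells_p2]  # (T, 10, 3)
    J = np.einsum("tia,qib->tqab", Xe, _DNTET10)
    invJ, detJ = _inv_det_3x3(J)
    if np.any(detJ <= 0):
        raise GeometryError(
            f"{int(np.sum(detJ <= 0))} inverted quadrature points after mesh motion; "
            "reduce the time step or forcing amplitude"
        )
    # grad_x N = J^{-T} grad_ref N, i.e. G_a = (J^{-1})_{ba} dN_b
    G10 = np.einsum("qib,tqba->tqia", _DNTET10, invJ)
    G4 = np.einsum("qib,tqba->tqia", _DNTET4, invJ)
    return detJ, G10, G4


def mesh_volume(coords_p2, cells_p2) -> float:
    Xe = coords_p2[cells_p2]
    J = np.einsum("tia,qib->tqab", Xe, _DNTET10)
    _, detJ = _inv_det_3x3(J)
    return float(np.einsum("q,tq->", _WTET, detJ))


# ---------------------------------------------------------------------------
# volume assembly


def _scatter(cells_a, cells_b, vals, shape):
    T, na = cells_a.shape
    nb = cells_b.shape[1]
    rows = np.broadcast_to(cells_a[:, :, None], (T, na, nb)).ravel()
    cols = np.broadcast_to(cells_b[:, None, :], (T, na, nb)).ravel()
    return sp.coo_matrix((vals.ravel(), (rows, cols)), shape=shape).tocsr()


def assemble_scalar_operators(coords_p2, cells_p2, n_p2):
    """Scalar P2 mass and stiffness matrices (shared by all components)."""
    detJ, G10, _ = element_geometry(coords_p2, cells_p2)
    wdet = _WTET[None, :] * detJ  # (T, nq)
    Me = np.einsum("tq,qi,qj->tij", wdet, _NTET10, _NTET10)
    Ke = np.einsum("tq,tqia,tqja->tij", wdet, G10, G10)
    shape = (n_p2, n_p2)
    return (
        _scatter(cells_p2, cells_p2, Me, shape),
        _scatter(cells_p2, cells_p2, Ke, shape),
        (detJ, G10),
    )


def assemble_ale_advection(coords_p2, cells_p2, n_p2, w_nodal, geom, conservative=True):
    """Scalar matrix of the ALE advection term.

    conservative: C[i,j] = int N_i * div(w N_j) = int N_i (w . grad N_j + (div w) N_j)
    non-conservative: drop the (div w) N_j part.
    The caller multiplies by -rho (the ALE correction enters the momentum
    equation as -rho * div(w x v)).
    """
    detJ, G10 = geom
    wdet = _WTET[None, :] * detJ
    We = w_nodal[cells_p2]  # (T, 10, 3)
    w_q = np.einsum("qi,tia->tqa", _NTET10, We)
    adv = np.einsum("tqa,tqja->tqj", w_q, G10)  # w . grad N_j
    if conservative:
        divw = np.einsum("tqia,tia->tq", G10, We)
        adv = adv + divw[:, :, None] * _NTET10[None, :, :]
    Ce = np.einsum("tq,qi,tqj->tij", wdet, _NTET10, adv)
    return _scatter(cells_p2, cells_p2, Ce, (n_p2, n_p2))


def assemble_divergence(coords_p2, cells_p2, cells, n_p2, n_verts, geom):
    """B with B[l, 3j+a] = int N1_l * d(N2_j)/dx_a (continuity operator)."""
    detJ, G10 = geom
    wdet = _WTET[None, :] * detJ
    Be = np.einsum("tq,ql,tqja->tlja", wdet, _NTET4, G10)  # (T, 4, 10, 3)
    T = cells.shape[0]
    rows = np.broadcast_to(cells[:, :, None, None], (T, 4, 10, 3)).ravel()
    cols = (3 * np.broadcast_to(cells_p2[:, None, :, None], (T, 4, 10, 3))
            + np.broadcast_to(np.arange(3)[None, None, None, :], (T, 4, 10, 3))).ravel()
    return sp.coo_matrix((Be.ravel(), (rows, cols)), shape=(n_verts, 3 * n_p2)).tocsr()


def assemble_p1_stiffness(verts, cells):
    """P1 stiffness on the vertex mesh (affine elements, exact one-point rule)."""
    x = verts[cells]  # (T, 4, 3)
    J = np.einsum("tia,ib->tab", x, np.array(
        [[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float))
    invJ, detJ = _inv_det_3x3(J)
    dref = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    G = np.einsum("ib,tba->tia", dref, invJ)
    Ke = np.einsum("t,tia,tja->tij", np.abs(detJ) / 6.0, G, G)
    V = verts.shape[0]
    return _scatter(cells, cells, Ke, (V, V))


# ---------------------------------------------------------------------------
# surface integrals


def _surface_geometry(coords_p2, faces_p2):
    """Scaled normals (F, nq, 3) at surface quadrature points (outward)."""
    Xf = coords_p2[faces_p2]  # (F, 6, 3)
    T1 = np.einsum("fia,qi->fqa", Xf, _DNTRI6[:, :, 0])
    T2 = np.einsum("fia,qi->fqa", Xf, _DNTRI6[:, :, 1])
    return np.cross(T1, T2)  # |n| = surface Jacobian


def surface_area(coords_p2, faces_p2) -> float:
    n = _surface_geometry(coords_p2, faces_p2)
    return float(np.einsum("q,fq->", _WTRI, np.linalg.norm(n, axis=2)))


def boundary_flux(coords_p2, faces_p2, v_nodal) -> float:
    """int v . n ds over the given faces (outflow positive)."""
    n = _surface_geometry(coords_p2, faces_p2)
    Vf = v_nodal[faces_p2]  # (F, 6, 3)
    v_q = np.einsum("qi,fia->fqa", _NTRI6, Vf)
    return float(np.einsum("q,fqa,fqa->", _WTRI, v_q, n))


def traction_rhs(coords_p2, faces_p2, p_tilde: float, n_p2: int) -> np.ndarray:
    """Load vector of int (-p_tilde) n . phi ds on the given faces."""
    n = _surface_geometry(coords_p2, faces_p2)
    fe = -p_tilde * np.einsum("q,qi,fqa->fia", _WTRI, _NTRI6, n)  # (F, 6, 3)
    rhs = np.zeros(3 * n_p2)
    cols = (3 * faces_p2[:, :, None] + np.arange(3)[None, None, :]).ravel()
    np.add.at(rhs, cols, fe.ravel())
    return rhs


def nodal_normals(coords_p2, faces_p2, n_p2) -> np.ndarray:
    """Unit outward normals at the P2 nodes of the given boundary faces.

    Averaged (area-weighted) over adjacent faces; rows of nodes not on the
    faces are zero.
    """
    Xf = coords_p2[faces_p2]
    T1 = np.einsum("fia,qi->fqa", Xf, _DNTRI6_AT_NODES[:, :, 0])
    T2 = np.einsum("fia,qi->fqa", Xf, _DNTRI6_AT_NODES[:, :, 1])
    n = np.cross(T1, T2)  # (F, 6nodes, 3), area-weighted
    acc = np.zeros((n_p2, 3))
    np.add.at(acc, faces_p2.ravel(), n.reshape(-1, 3))
    norm = np.linalg.norm(acc, axis=1)
    mask = norm > 0
    acc[mask] /= norm[mask, None]
    return acc


# ---------------------------------------------------------------------------
# linear algebra


def solve_dirichlet(K: sp.csr_matrix, rhs: np.ndarray, dir_dofs, dir_vals) -> np.ndarray:
    """Solve K x = rhs with x[dir_dofs] = dir_vals eliminated, direct LU."""
    n = K.shape[0]
    x = np.zeros(n)
    x[dir_dofs] = dir_vals
    free = np.setdiff1d(np.arange(n), dir_dofs, assume_unique=False)
    r = rhs - K @ x
    Kff = K[free][:, free].tocsr()
    # Pressure dofs whose entire velocity patch is Dirichlet have empty
    # rows/columns after elimination (their multiplier is indeterminate);
    # pin them to zero. Occurs in shell meshes only one cell thick.
    row_max = np.abs(Kff).max(axis=1).toarray().ravel()
    locked = np.nonzero(row_max == 0.0)[0]
    if locked.size:
        Kff = Kff + sp.coo_matrix(
            (np.ones(locked.size), (locked, locked)), shape=Kff.shape)
        rf = r[free]
        rf[locked] = 0.0
    else:
        rf = r[free]
    Kff = Kff.tocsc()
    try:
        x[free] = spla.spsolve(Kff, rf)
    except Exception as exc:  # pragma: no cover - solver backend failure
        raise SolverError(f"sparse direct solve failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("singular system: non-finite solution")
    return x


class HarmonicExtension:
    """Componentwise harmonic extension of boundary displacement.

    The Laplace operator is assembled once on the reference vertex mesh with
    Dirichlet nodes given; inlet/outlet faces keep the natural (zero-flux)
    condition so end faces follow the wall smoothly. The factorization is
    reused for every time step and every component.
    """

    def __init__(self, verts, cells, dirichlet_verts):
        self.n = verts.shape[0]
        self.dir = np.asarray(dirichlet_verts, dtype=np.int64)
        self.free = np.setdiff1d(np.arange(self.n), self.dir)
        K = assemble_p1_stiffness(verts, cells)
        self._Kfd = K[self.free][:, self.dir].tocsr()
        self._lu = spla.splu(K[self.free][:, self.free].tocsc())

    def extend(self, dir_vals: np.ndarray) -> np.ndarray:
        """dir_vals: (n_dir, 3) prescribed displacement; returns (V, 3)."""
        out = np.zeros((self.n, 3))
        out[self.dir] = dir_vals
        rhs = -self._Kfd @ dir_vals
        for a in range(3):
            out[self.free, a] = self._lu.solve(rhs[:, a])
        return out
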