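"""PVS computational domains.

Four kinds of domain are supported, mirroring the study setup:

* :func:`make_idealized_annulus` — the 1D axial mesh of an axisymmetric
  annular cylinder (inner radius = arterial wall, outer radius = rigid outer
  boundary), used by the reduced lubrication model;
* :func:`make_annulus_mesh_3d` — a structured, isoparametrically curved
  tetrahedral mesh of the same annulus, used to cross-validate the 3D
  solver against the reduced model and closed-form Poiseuille flow;
* :func:`make_synthetic_bifurcation` — a parametric Y-shaped annular PVS
  around an arterial bifurcation at mouse scale (one inlet, two outlets);
* :func:`import_artery_and_extrude` — a PVS extruded around an externally
  supplied artery surface mesh along a supplied centerline.

Coordinates are in mm throughout; radii arguments in um (the field's
customary unit at these scales). Boundary facets carry integer tags
(inner_wall=1, outer_wall=2, inlet=3, outlet_1=4, outlet_2=5).

The bifurcation and imported geometries are meshed by a body-fitted lattice
method: the PVS is described implicitly as the shell between an inner
(arterial) and an outer tube-union surface, a background cube lattice is
split into tetrahedra, lattice vertices near the surfaces are snapped onto
them, and only tetrahedra inside the shell are kept. The PVS width is set
proportional to the local arterial diameter (default ratio 0.9, which
reproduces the observed mouse-scale width/diameter ranges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, GeometryError, ParameterError
from . import fem
from .fem import (
    TAG_INLET,
    TAG_INNER_WALL,
    TAG_OUTER_WALL,
    TAG_OUTLET_1,
    TAG_OUTLET_2,
    TetMesh,
)

# mouse-scale plausibility ranges (um), from in vivo imaging of pial PVS
MOUSE_GAP_RANGE_UM = (28.0, 42.0)
MOUSE_DIAMETER_RANGE_UM = (32.0, 46.0)
DEFAULT_PVS_WIDTH_RATIO = 0.9


@dataclass
class IdealizedPVS:
    """Axisymmetric annular PVS reduced to a 1D axial mesh.

    L in mm, radii in um; ``z`` is the strictly increasing axial coordinate
    array from 0 to L with ``round(L/mesh_size) + 1`` vertices.
    """

    L: float
    R_in: float
    R_out: float
    mesh_size: float
    z: np.ndarray = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.z)

    @property
    def gap_um(self) -> float:
        return self.R_out - self.R_in


def make_idealized_annulus(L: float, R_in: float, R_out: float,
                           mesh_size: float = 0.1) -> IdealizedPVS:
    """Uniform 1D axial mesh of an annular cylinder.

    With the default mesh size of 0.1 mm a length-L (mm) domain has
    10 L + 1 vertices.
    """
    if L <= 0 or mesh_size <= 0:
        raise ParameterError("L and mesh_size must be positive")
    if not (R_out > R_in > 0):
        raise ParameterError("need R_out > R_in > 0")
    n = int(round(L / mesh_size)) + 1
    if n < 2:
        raise ParameterError("mesh_size too large for domain length")
    z = np.linspace(0.0, L, n)
    return IdealizedPVS(L=L, R_in=R_in, R_out=R_out, mesh_size=mesh_size, z=z)


@dataclass
class PVSGeometry3D:
    """Tagged tetrahedral PVS domain with centerline metadata.

    ``branch_lengths`` are centerline arclengths from the inlet to each
    outlet (mm); areas in mm^2; ``normal_fn`` maps points on the inner wall
    to the unit outward normal of the *fluid* domain (pointing into the
    artery), used to direct the prescribed wall displacement.
    """

    mesh: TetMesh
    centerline: list
    X0: np.ndarray
    Xc: np.ndarray | None
    branch_lengths: tuple
    inlet_area: float
    outlet_areas: tuple
    gap_width_um: tuple
    inner_diameter_um: tuple
    normal_fn: object = None
    metadata: dict = field(default_factory=dict)

    @property
    def outlet_tags(self) -> tuple:
        tags = []
        for tag in (TAG_OUTLET_1, TAG_OUTLET_2):
            if np.any(self.mesh.face_tags == tag):
                tags.append(tag)
        return tuple(tags)


def _check_tags_complete(mesh: TetMesh) -> None:
    if np.any(mesh.face_tags == 0):
        raise GeometryError(
            f"{int(np.sum(mesh.face_tags == 0))} boundary faces left untagged"
        )


# ---------------------------------------------------------------------------
# structured annulus


def _kuhn_tets(v):
    """Split hex vertex array v[2,2,2] -> 6 tets (Kuhn subdivision)."""
    paths = [
        (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
    ]
    tets = []
    for p in paths:
        idx = np.zeros(3, dtype=int)
        tet = [v[tuple(idx)]]
        for ax in p:
            idx[ax] = 1
            tet.append(v[tuple(idx)])
        tets.append(tet)
    return tets


def make_annulus_mesh_3d(L: float, R_in: float, R_out: float,
                         resolution: float = 0.02,
                         n_theta: int | None = None,
                         n_r: int | None = None,
                         n_z: int | None = None) -> PVSGeometry3D:
    """Structured curved tetrahedral mesh of a straight annular cylinder.

    L in mm, radii in um, resolution (target cell size) in mm. The axis is
    z; the inlet is the z=0 face and the single outlet the z=L face
    (tagged outlet_1; outlet_2 is empty). Edge midside nodes are placed at
    cylindrical midpoints so the isoparametric elements follow the circular
    walls; mesh volume and boundary areas then agree with the closed forms
    to well below 1%.
    """
    if L <= 0 or resolution <= 0:
        raise ParameterError("L and resolution must be positive")
    if not (R_out > R_in > 0):
        raise ParameterError("need R_out > R_in > 0")
    r_in, r_out = R_in * 1e-3, R_out * 1e-3  # mm
    gap = r_out - r_in
    if resolution > gap and n_r is None:
        raise GeometryError(
            f"resolution {resolution} mm exceeds the PVS gap {gap:.4f} mm; "
            "no cell fits across the annulus"
        )
    nt = n_theta or max(12, int(round(2 * np.pi * 0.5 * (r_in + r_out) / resolution)))
    nr = n_r or max(2, int(round(gap / resolution)))
    nz = n_z or max(2, int(round(L / resolution)))

    theta = 2 * np.pi * np.arange(nt) / nt
    rad = np.linspace(r_in, r_out, nr + 1)
    zax = np.linspace(0.0, L, nz + 1)

    def vid(iz, ir, it):
        return (iz * (nr + 1) + ir) * nt + (it % nt)

    IZ, IR, IT = np.meshgrid(np.arange(nz + 1), np.arange(nr + 1), np.arange(nt),
                             indexing="ij")
    rr = rad[IR].ravel()
    tt = theta[IT].ravel()
    zz = zax[IZ].ravel()
    verts = np.column_stack([rr * np.cos(tt), rr * np.sin(tt), zz])

    cells = []
    for iz in range(nz):
        for ir in range(nr):
            for it in range(nt):
                v = np.empty((2, 2, 2), dtype=np.int64)
                for a in range(2):       # theta
                    for b in range(2):   # r
                        for c in range(2):  # z
                            v[a, b, c] = vid(iz + c, ir + b, it + a)
                cells.extend(_kuhn_tets(v))
    mesh = TetMesh(verts, np.array(cells))

    # curve edge nodes: cylindrical midpoints (keeps nodes on the walls)
    rv = np.hypot(verts[:, 0], verts[:, 1])
    thv = np.arctan2(verts[:, 1], verts[:, 0])
    e0, e1 = mesh.edges[:, 0], mesh.edges[:, 1]
    rm = 0.5 * (rv[e0] + rv[e1])
    cm = np.cos(thv[e0]) + np.cos(thv[e1])
    sm = np.sin(thv[e0]) + np.sin(thv[e1])
    thm = np.arctan2(sm, cm)
    zm = 0.5 * (verts[e0, 2] + verts[e1, 2])
    mesh.coords_p2[mesh.n_verts:] = np.column_stack(
        [rm * np.cos(thm), rm * np.sin(thm), zm])

    # tag boundary faces by vertex cylindrical position
    tol = 1e-9 + 1e-6 * gap
    fr = rv[mesh.boundary_faces]
    fz = verts[mesh.boundary_faces, 2]
    inner = np.all(np.abs(fr - r_in) < tol, axis=1)
    outer = np.all(np.abs(fr - r_out) < tol, axis=1)
    inlet = np.all(np.abs(fz) < tol, axis=1) & ~inner & ~outer
    outlet = np.all(np.abs(fz - L) < tol, axis=1) & ~inner & ~outer
    mesh.face_tags[inner] = TAG_INNER_WALL
    mesh.face_tags[outer] = TAG_OUTER_WALL
    mesh.face_tags[inlet] = TAG_INLET
    mesh.face_tags[outlet] = TAG_OUTLET_1
    _check_tags_complete(mesh)

    def normal_fn(X):
        X = np.atleast_2d(X)
        n = np.zeros_like(X)
        r = np.hypot(X[:, 0], X[:, 1])
        n[:, 0] = -X[:, 0] / r
        n[:, 1] = -X[:, 1] / r
        return n

    inlet_area = fem.surface_area(mesh.coords_p2, mesh.faces_with_tag(TAG_INLET))
    outlet_area = fem.surface_area(mesh.coords_p2, mesh.faces_with_tag(TAG_OUTLET_1))
    return PVSGeometry3D(
        mesh=mesh,
        centerline=[np.column_stack([np.zeros(2), np.zeros(2), [0.0, L]])],
        X0=np.array([0.0, 0.0, 0.0]),
        Xc=np.array([0.0, 0.0, L / 2]),
        branch_lengths=(L,),
        inlet_area=inlet_area,
        outlet_areas=(outlet_area,),
        gap_width_um=(R_out - R_in, R_out - R_in),
        inner_diameter_um=(2 * R_in, 2 * R_in),
        normal_fn=normal_fn,
        metadata={"kind": "annulus3d", "L": L, "R_in_um": R_in, "R_out_um": R_out,
                  "n_theta": nt, "n_r": nr, "n_z": nz},
    )


# ---------------------------------------------------------------------------
# implicit shell description (bifurcation, imported arteries)


class _ImplicitShell:
    """PVS shell between tube-union inner/outer surfaces.

    branches: list of (p0, p1, r0, r1, g0, g1) — straight segments with
    linearly varying inner radius r and gap g (all mm).
    spheres: list of (center, r, g) junction fillets.
    caps: list of (point, inward unit normal) end planes.
    """

    def __init__(self, branches, spheres, caps):
        self.branches = [tuple(np.asarray(v, dtype=float) if i < 2 else float(v)
                               for i, v in enumerate(b)) for b in branches]
        self.spheres = [(np.asarray(c, dtype=float), float(r), float(g))
                        for c, r, g in spheres]
        self.caps = [(np.asarray(p, dtype=float), np.asarray(n, dtype=float))
                     for p, n in caps]

    def _seg_terms(self, X):
        """Per branch: distance to segment, interpolated r and gap, closest pt."""
        out = []
        for p0, p1, r0, r1, g0, g1 in self.branches:
            d = p1 - p0
            L2 = float(d @ d)
            t = np.clip((X - p0) @ d / L2, 0.0, 1.0)
            q = p0 + t[:, None] * d
            dist = np.linalg.norm(X - q, axis=1)
            out.append((dist, r0 + t * (r1 - r0), g0 + t * (g1 - g0), q))
        return out

    def terms(self, X):
        """List of (signed value >=0 inside, kind, projection data).

        The domain is {min_k value_k >= 0}.
        """
        X = np.atleast_2d(X)
        vals, projs = [], []
        segs = self._seg_terms(X)
        # inner: fluid needs dist >= r for ALL branches/spheres -> value = dist - r
        for (dist, r, g, q), br in zip(segs, self.branches):
            vals.append(dist - r)
            projs.append(("tube", q, r))
        for c, r, g in self.spheres:
            dist = np.linalg.norm(X - c, axis=1)
            vals.append(dist - r)
            projs.append(("sphere", c, r))
        # outer: fluid needs dist <= r+g for SOME branch -> value = max_k (R_k - dist)
        outer = np.full(X.shape[0], -np.inf)
        outer_q = np.zeros_like(X)
        outer_R = np.zeros(X.shape[0])
        for (dist, r, g, q), br in zip(segs, self.branches):
            better = (r + g - dist) > outer
            outer = np.where(better, r + g - dist, outer)
            outer_q[better] = q[better]
            outer_R[better] = (r + g)[better]
        for c, r, g in self.spheres:
            dist = np.linalg.norm(X - c, axis=1)
            better = (r + g - dist) > outer
            outer = np.where(better, r + g - dist, outer)
            outer_q[better] = c
            outer_R[better] = r + g
        vals.append(outer)
        projs.append(("outer", outer_q, outer_R))
        for p, n in self.caps:
            vals.append((X - p) @ n)
            projs.append(("plane", p, n))
        return np.array(vals), projs

    def psi(self, X):
        vals, _ = self.terms(X)
        return vals.min(axis=0)

    def inner_value(self, X):
        X = np.atleast_2d(X)
        v = None
        for (dist, r, g, q) in self._seg_terms(X):
            v = dist - r if v is None else np.minimum(v, dist - r)
        for c, r, g in self.spheres:
            v = np.minimum(v, np.linalg.norm(X - c, axis=1) - r)
        return v

    def inner_normal(self, X):
        """Unit outward normal of the fluid at the inner wall (toward artery)."""
        X = np.atleast_2d(X)
        eps = 1e-6
        grad = np.zeros_like(X)
        for a in range(3):
            dX = np.zeros(3)
            dX[a] = eps
            grad[:, a] = (self.inner_value(X + dX) - self.inner_value(X - dX)) / (2 * eps)
        grad /= np.linalg.norm(grad, axis=1)[:, None]
        return -grad  # inner_value grows away from the artery

    def snap(self, X, active):
        """Project points onto their active surface term."""
        X = X.copy()
        vals, projs = self.terms(X)
        for k, (kind, a, b) in enumerate(projs):
            m = active == k
            if not np.any(m):
                continue
            if kind == "tube":
                q, r = a[m], b[m]
                d = X[m] - q
                nrm = np.linalg.norm(d, axis=1)
                ok = nrm > 1e-12
                d[ok] /= nrm[ok, None]
                X[m] = q + r[:, None] * d
            elif kind == "sphere":
                d = X[m] - a
                nrm = np.linalg.norm(d, axis=1)
                d[nrm > 1e-12] /= nrm[nrm > 1e-12, None]
                X[m] = a + b * d
            elif kind == "outer":
                q, R = a[m], b[m]
                d = X[m] - q
                nrm = np.linalg.norm(d, axis=1)
                ok = nrm > 1e-12
                d[ok] /= nrm[ok, None]
                X[m] = q + R[:, None] * d
            else:  # plane
                c = (X[m] - a) @ b
                X[m] = X[m] - c[:, None] * b
        return X


def _mesh_implicit_shell(shell: _ImplicitShell, h: float,
                         max_tets: int = 2_000_000) -> TetMesh:
    """Body-fitted lattice mesh of the implicit shell."""
    pts = [b[0] for b in shell.branches] + [b[1] for b in shell.branches]
    margins = [b[2] + b[4] for b in shell.branches] + [b[3] + b[5] for b in shell.branches]
    lo = np.min([p - (m + 2 * h) for p, m in zip(pts, margins)], axis=0)
    hi = np.max([p + (m + 2 * h) for p, m in zip(pts, margins)], axis=0)
    nxyz = np.maximum(2, np.ceil((hi - lo) / h).astype(int))
    if int(np.prod(nxyz + 1)) * 6 > max_tets:
        raise GeometryError(
            f"lattice of {nxyz} cells at spacing {h} mm exceeds the mesh budget; "
            "increase the lattice spacing"
        )
    axes = [np.linspace(lo[a], hi[a], nxyz[a] + 1) for a in range(3)]
    GX, GY, GZ = np.meshgrid(*axes, indexing="ij")
    verts = np.column_stack([GX.ravel(), GY.ravel(), GZ.ravel()])
    shp = nxyz + 1

    def gid(i, j, k):
        return (i * shp[1] + j) * shp[2] + k

    I, J, K = np.meshgrid(*(np.arange(n) for n in nxyz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corners = np.empty((2, 2, 2, I.size), dtype=np.int64)
    for a in range(2):
        for b in range(2):
            for c in range(2):
                corners[a, b, c] = gid(I + a, J + b, K + c)
    tets = np.concatenate(
        [np.stack(t, axis=1) for t in _kuhn_tets(corners)], axis=0)

    # snap lattice vertices near the surfaces onto them
    vals, _ = shell.terms(verts)
    psi = vals.min(axis=0)
    active = np.argmin(vals, axis=0)
    near = np.abs(psi) < 0.45 * h
    snapped = verts.copy()
    snapped[near] = shell.snap(verts[near], active[near])
    moved = np.linalg.norm(snapped - verts, axis=1)
    bad_move = moved > 0.75 * h
    snapped[bad_move] = verts[bad_move]
    psi_new = shell.psi(snapped)

    inside = psi_new >= -1e-9 * h
    keep = np.all(inside[tets], axis=1)
    tets = tets[keep]
    # drop degenerate tets squashed by snapping
    e1 = snapped[tets[:, 1]] - snapped[tets[:, 0]]
    e2 = snapped[tets[:, 2]] - snapped[tets[:, 0]]
    e3 = snapped[tets[:, 3]] - snapped[tets[:, 0]]
    vol = np.abs(np.einsum("ij,ij->i", e1, np.cross(e2, e3))) / 6.0
    tets = tets[vol > 1e-4 * h ** 3]
    if len(tets) == 0:
        raise GeometryError("implicit shell meshing produced no cells; "
                            "the lattice spacing may exceed the PVS gap")
    # keep the largest connected component (snapping can leave isolated
    # pockets whose pressure would be undetermined)
    import scipy.sparse as _sp
    import scipy.sparse.csgraph as _csg
    ncand = verts.shape[0]
    rows = np.repeat(np.arange(len(tets)), 4)
    inc = _sp.coo_matrix((np.ones(4 * len(tets)), (rows, tets.ravel())),
                         shape=(len(tets), ncand)).tocsr()
    adj = inc @ inc.T
    n_comp, labels = _csg.connected_components(adj, directed=False)
    if n_comp > 1:
        largest = np.argmax(np.bincount(labels))
        tets = tets[labels == largest]
    used = np.unique(tets)
    remap = -np.ones(verts.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    mesh = TetMesh(snapped[used], remap[tets])

    # tag boundary faces by the nearest surface term at the face centroid
    centroids = mesh.verts[mesh.boundary_faces].mean(axis=1)
    vals, projs = shell.terms(centroids)
    kinds = [p[0] for p in projs]
    n_inner = sum(1 for k in kinds if k in ("tube", "sphere"))
    score = np.abs(vals)
    which = np.argmin(score, axis=0)
    cap_start = n_inner + 1
    tags = np.where(which < n_inner, TAG_INNER_WALL, TAG_OUTER_WALL)
    cap_tags = [TAG_INLET, TAG_OUTLET_1, TAG_OUTLET_2]
    for j in range(len(shell.caps)):
        tags = np.where(which == cap_start + j, cap_tags[j], tags)
    mesh.face_tags[:] = tags
    return mesh


def make_synthetic_bifurcation(parent_diameter: float,
                               daughter_diameters: tuple,
                               branch_lengths: tuple,
                               pvs_width_ratio: float = DEFAULT_PVS_WIDTH_RATIO,
                               half_angle_deg: float = 35.0,
                               lattice_spacing: float | None = None) -> PVSGeometry3D:
    """Parametric Y-shaped annular PVS around an arterial bifurcation.

    Diameters in um, branch lengths (parent, daughter1, daughter2) in mm.
    The PVS gap of each branch is ``pvs_width_ratio`` times the local
    arterial diameter. The junction is blended with a spherical fillet of
    the parent radius at the pivot point Xc. Deterministic for fixed
    parameters.
    """
    dds = tuple(daughter_diameters)
    lens = tuple(branch_lengths)
    if len(dds) != 2 or len(lens) != 3:
        raise ParameterError("need two daughter diameters and three branch lengths")
    if parent_diameter <= 0 or any(d <= 0 for d in dds) or any(L <= 0 for L in lens):
        raise ParameterError("diameters and lengths must be positive")
    if not (0.0 < pvs_width_ratio < 2.0):
        raise GeometryError("pvs_width_ratio must lie in (0, 2)")
    diam = (parent_diameter,) + dds
    gaps = tuple(pvs_width_ratio * d for d in diam)
    for d in diam:
        if not (MOUSE_DIAMETER_RANGE_UM[0] <= d <= MOUSE_DIAMETER_RANGE_UM[1]):
            raise ParameterError(
                f"arterial diameter {d} um outside the mouse-scale range "
                f"{MOUSE_DIAMETER_RANGE_UM}")
    for g in gaps:
        if not (MOUSE_GAP_RANGE_UM[0] <= g <= MOUSE_GAP_RANGE_UM[1]):
            raise ParameterError(
                f"PVS width {g:.1f} um outside the mouse-scale range "
                f"{MOUSE_GAP_RANGE_UM}")
    Lp, L1, L2 = lens
    if Lp + max(L1, L2) > 1.0 + 1e-9:
        raise ParameterError("maximal inlet->outlet centerline length exceeds 1 mm")

    r = [0.5 * d * 1e-3 for d in diam]       # mm
    g = [gg * 1e-3 for gg in gaps]           # mm
    alpha = np.deg2rad(half_angle_deg)
    X0 = np.zeros(3)
    Xc = np.array([Lp, 0.0, 0.0])
    u1 = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    u2 = np.array([np.cos(alpha), -np.sin(alpha), 0.0])
    p1 = Xc + L1 * u1
    p2 = Xc + L2 * u2
    if np.linalg.norm(p1 - p2) < (r[1] + g[1]) + (r[2] + g[2]):
        raise GeometryError("daughter branches self-intersect at the given "
                            "angle/lengths; increase half_angle_deg or lengths")

    branches = [
        (X0, Xc, r[0], r[0], g[0], g[0]),
        (Xc, p1, r[1], r[1], g[1], g[1]),
        (Xc, p2, r[2], r[2], g[2], g[2]),
    ]
    spheres = [(Xc, r[0], g[0])]
    caps = [
        (X0, np.array([1.0, 0.0, 0.0])),
        (p1, -u1),
        (p2, -u2),
    ]
    shell = _ImplicitShell(branches, spheres, caps)
    h = lattice_spacing or min(g) / 3.0
    mesh = _mesh_implicit_shell(shell, h)
    _check_tags_complete(mesh)

    inlet_area = fem.surface_area(mesh.coords_p2, mesh.faces_with_tag(TAG_INLET))
    outlet_areas = tuple(
        fem.surface_area(mesh.coords_p2, mesh.faces_with_tag(t))
        for t in (TAG_OUTLET_1, TAG_OUTLET_2))
    return PVSGeometry3D(
        mesh=mesh,
        centerline=[np.vstack([X0, Xc]), np.vstack([Xc, p1]), np.vstack([Xc, p2])],
        X0=X0,
        Xc=Xc,
        branch_lengths=(Lp + L1, Lp + L2),
        inlet_area=inlet_area,
        outlet_areas=outlet_areas,
        gap_width_um=(min(gaps), max(gaps)),
        inner_diameter_um=(min(diam), max(diam)),
        normal_fn=shell.inner_normal,
        metadata={"kind": "bifurcation", "parent_diameter_um": parent_diameter,
                  "daughter_diameters_um": dds, "branch_lengths_mm": lens,
                  "pvs_width_ratio": pvs_width_ratio, "gap_widths_um": gaps,
                  "half_angle_deg": half_angle_deg, "lattice_spacing_mm": h},
    )


def import_artery_and_extrude(surface_path, centerline_path,
                              pvs_width_ratio: float = DEFAULT_PVS_WIDTH_RATIO,
                              target_length: float = 1.0,
                              lattice_spacing: float | None = None) -> PVSGeometry3D:
    """Extrude a PVS around an externally supplied artery surface.

    ``surface_path``: closed triangulated surface (STL/PLY/OBJ, mm);
    ``centerline_path``: CSV with one "x,y,z" row per centerline vertex (mm).
    The local arterial diameter is measured as twice the centerline-to-wall
    distance; the PVS gap is ``pvs_width_ratio`` times that diameter. The
    whole geometry is uniformly scaled so the centerline arclength equals
    ``target_length`` (mm). Mouse-scale width/diameter ranges are reported
    with a warning (not enforced) for imported geometries.
    """
    import trimesh

    if not (0.0 < pvs_width_ratio < 2.0):
        raise GeometryError("pvs_width_ratio must lie in (0, 2)")
    try:
        surf = trimesh.load(str(surface_path), force="mesh")
    except Exception as exc:
        raise FormatError(f"cannot read surface mesh {surface_path}: {exc}") from exc
    if surf.vertices.shape[0] == 0:
        raise FormatError(f"surface mesh {surface_path} is empty")
    if not surf.is_watertight:
        raise FormatError("surface mesh is open; a closed (capped) tube segment "
                          "is required")
    try:
        cl = np.loadtxt(str(centerline_path), delimiter=",", ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot read centerline {centerline_path}: {exc}") from exc
    if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
        raise FormatError("centerline must have >= 2 rows of x,y,z (mm)")

    # local arterial radius: centerline-to-wall distance
    _, dist, _ = trimesh.proximity.closest_point_naive(surf, cl)
    radii = np.asarray(dist, dtype=float)
    if np.any(radii <= 0):
        raise FormatError("centerline touches the surface; not a tube interior line")

    seglen = np.linalg.norm(np.diff(cl, axis=0), axis=1)
    total = float(seglen.sum())
    if total <= 0:
        raise FormatError("degenerate centerline")
    scale = target_length / total
    cl = cl * scale
    radii = radii * scale
    gaps = pvs_width_ratio * 2.0 * radii

    diam_um = 2.0 * radii * 1e3
    gap_um = gaps * 1e3
    if (diam_um.min() < MOUSE_DIAMETER_RANGE_UM[0]
            or diam_um.max() > MOUSE_DIAMETER_RANGE_UM[1]):
        warnings.warn(
            f"imported arterial diameters {diam_um.min():.1f}-{diam_um.max():.1f} um "
            f"outside the mouse-scale range {MOUSE_DIAMETER_RANGE_UM}")
    if gap_um.min() < MOUSE_GAP_RANGE_UM[0] or gap_um.max() > MOUSE_GAP_RANGE_UM[1]:
        warnings.warn(
            f"imported PVS widths {gap_um.min():.1f}-{gap_um.max():.1f} um outside "
            f"the mouse-scale range {MOUSE_GAP_RANGE_UM}")

    branches = [
        (cl[i], cl[i + 1], radii[i], radii[i + 1], gaps[i], gaps[i + 1])
        for i in range(cl.shape[0] - 1)
    ]
    t0 = cl[1] - cl[0]
    t1 = cl[-1] - cl[-2]
    caps = [
        (cl[0], t0 / np.linalg.norm(t0)),
        (cl[-1], -t1 / np.linalg.norm(t1)),
    ]
    shell = _ImplicitShell(branches, [], caps)
    h = lattice_spacing or float(gaps.min()) / 3.0
    mesh = _mesh_implicit_shell(shell, h)
    _check_tags_complete(mesh)

    inlet_area = fem.surface_area(mesh.coords_p2, mesh.faces_with_tag(TAG_INLET))
    outlet_area = fem.surface_area(mesh.coords_p2, mesh.faces_with_tag(TAG_OUTLET_1))
    return PVSGeometry3D(
        mesh=mesh,
        centerline=[cl],
        X0=cl[0].copy(),
        Xc=None,
        branch_lengths=(target_length,),
        inlet_area=inlet_area,
        outlet_areas=(outlet_area,),
        gap_width_um=(float(gap_um.min()), float(gap_um.max())),
        inner_diameter_um=(float(diam_um.min()), float(diam_um.max())),
        normal_fn=shell.inner_normal,
        metadata={"kind": "imported", "surface": str(surface_path),
                  "pvs_width_ratio": pvs_width_ratio,
                  "target_length_mm": target_length, "lattice_spacing_mm": h},
    )
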