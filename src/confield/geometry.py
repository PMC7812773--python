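"""Surface geometry: triangular meshes and geodesic distances.

Connective fields live on the cortical sheet, so the fundamental geometric
quantity is the geodesic (along-surface) distance between source-region
vertices, computed per hemisphere. Distances are estimated with the heat
method (diffuse heat from a source vertex, normalize the gradient of the
heat field, and recover distance as the potential whose gradient matches
it), and are clamped from above by exact shortest paths along mesh edges,
which are a true upper bound on the geodesic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import splu


class InvalidGeometryError(ValueError):
    """Raised for malformed meshes or vertex sets."""


@dataclass
class TriangleMesh:
    """A single-hemisphere triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Counter-clockwise vertex index triples.
    hemisphere : {"L", "R"}
        Hemisphere tag; distance matrices are never mixed across hemispheres.
    region_labels : dict, optional
        Named vertex index arrays (e.g. ``{"V1": indices}``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "L"
    region_labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidGeometryError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidGeometryError("faces must be an (m, 3) array")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise InvalidGeometryError("face indices out of range")
        if self.hemisphere not in ("L", "R"):
            raise InvalidGeometryError(
                f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) index array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def adjacency(self) -> sp.csr_matrix:
        """Sparse edge-length-weighted adjacency matrix."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        a = sp.coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return a.tocsr()


@dataclass
class GeodesicDistanceMatrix:
    """Pairwise geodesic distances (mm) over a source-region vertex set."""

    dists: np.ndarray
    vertex_ids: np.ndarray
    hemisphere: str

    def __post_init__(self):
        self.dists = np.asarray(self.dists, dtype=float)
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        n = len(self.vertex_ids)
        if self.dists.shape != (n, n):
            raise ValueError("distance matrix shape does not match vertex list")
        if not np.all(np.isfinite(self.dists)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.dists < 0):
            raise ValueError("distance matrix contains negative entries")

    @property
    def n(self) -> int:
        return len(self.vertex_ids)

    def index_of(self, vertex_id: int) -> int:
        hits = np.flatnonzero(self.vertex_ids == vertex_id)
        if len(hits) == 0:
            raise KeyError(f"vertex {vertex_id} not in source set")
        return int(hits[0])


@dataclass
class MeshReport:
    """Diagnostic report from :func:`validate_mesh` (report-only, never raises)."""

    n_vertices: int
    n_faces: int
    n_components: int
    degenerate_faces: np.ndarray
    out_of_range_faces: np.ndarray
    nonfinite_vertices: np.ndarray

    @property
    def is_clean(self) -> bool:
        return (
            self.n_components == 1
            and len(self.degenerate_faces) == 0
            and len(self.out_of_range_faces) == 0
            and len(self.nonfinite_vertices) == 0
        )


def validate_mesh(mesh: TriangleMesh) -> MeshReport:
    """Check connectivity, degenerate faces and non-finite coordinates."""
    verts, faces = mesh.vertices, mesh.faces
    nonfinite = np.flatnonzero(~np.isfinite(verts).all(axis=1))
    oor = np.flatnonzero((faces < 0).any(axis=1) | (faces >= len(verts)).any(axis=1))
    ok = np.setdiff1d(np.arange(len(faces)), oor)
    # degenerate: repeated vertex in a face or (numerically) zero area
    dup = (
        (faces[ok, 0] == faces[ok, 1])
        | (faces[ok, 1] == faces[ok, 2])
        | (faces[ok, 0] == faces[ok, 2])
    )
    v = verts[faces[ok]]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )
    degen = ok[dup | (areas < 1e-12)]
    if len(oor) == 0:
        n_comp = connected_components(mesh.adjacency(), directed=False)[0]
    else:
        n_comp = -1
    return MeshReport(
        n_vertices=len(verts),
        n_faces=len(faces),
        n_components=n_comp,
        degenerate_faces=degen,
        out_of_range_faces=oor,
        nonfinite_vertices=nonfinite,
    )


def _cotangent_laplacian(mesh: TriangleMesh) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Cotangent-weight Laplacian (positive semidefinite) and lumped mass matrix."""
    verts, faces = mesh.vertices, mesh.faces
    n = len(verts)
    i0, i1, i2 = faces[:, 0], faces[:, 1], faces[:, 2]
    v0, v1, v2 = verts[i0], verts[i1], verts[i2]

    def cot(a, b):
        # cotangent of the angle between edge vectors a and b
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        return np.einsum("ij,ij->i", a, b) / np.maximum(cross, 1e-300)

    c0 = cot(v1 - v0, v2 - v0)  # angle at vertex 0, opposite edge (1,2)
    c1 = cot(v2 - v1, v0 - v1)
    c2 = cot(v0 - v2, v1 - v2)

    rows = np.r_[i1, i2, i2, i0, i0, i1]
    cols = np.r_[i2, i1, i0, i2, i1, i0]
    vals = 0.5 * np.r_[c0, c0, c1, c1, c2, c2]
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    L = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W

    areas = mesh.face_areas()
    mass = np.zeros(n)
    for k in range(3):
        np.add.at(mass, faces[:, k], areas / 3.0)
    M = sp.diags(mass)
    return L.tocsc(), M.tocsc()


def _boundary_vertices(mesh: TriangleMesh) -> np.ndarray:
    e = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    e.sort(axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


class _HeatGeodesicSolver:
    """Single-source geodesic distances by the heat method.

    Pre-factorizes the heat and Poisson systems so that many sources can be
    queried cheaply. On meshes with boundary, the heat step averages the
    Neumann and Dirichlet solutions, which markedly improves accuracy near
    the boundary.
    """

    def __init__(self, mesh: TriangleMesh, t_factor: float = 1.0):
        self.mesh = mesh
        L, M = _cotangent_laplacian(mesh)
        mean_edge = float(np.mean(mesh.edge_lengths()))
        t = t_factor * mean_edge**2
        n = mesh.n_vertices

        A_neu = (M + t * L).tocsc()
        self._heat_neu = splu(A_neu)
        bnd = _boundary_vertices(mesh)
        self._boundary = bnd
        if len(bnd):
            # Dirichlet: pin boundary rows/cols to the identity
            A_dir = (M + t * L).tolil()
            A_dir[bnd, :] = 0.0
            A_dir[:, bnd] = 0.0
            A_dir[bnd, bnd] = 1.0
            self._heat_dir = splu(A_dir.tocsc())
        else:
            self._heat_dir = None
        # Poisson solve: L is singular (constant nullspace); regularize lightly
        self._poisson = splu((L + 1e-9 * sp.eye(n, format="csc")).tocsc())

        # Precompute per-face geometry for gradient / divergence
        faces = mesh.faces
        verts = mesh.vertices
        v = verts[faces]
        e0 = v[:, 2] - v[:, 1]  # edge opposite vertex 0
        e1 = v[:, 0] - v[:, 2]
        e2 = v[:, 1] - v[:, 0]
        normal = np.cross(e2, -e1)
        dblA = np.linalg.norm(normal, axis=1)
        unit_n = normal / np.maximum(dblA, 1e-300)[:, None]
        # gradient of hat function of vertex k on each face: (N x e_opp) / (2A)
        self._grad_basis = np.stack(
            [
                np.cross(unit_n, e0) / np.maximum(dblA, 1e-300)[:, None],
                np.cross(unit_n, e1) / np.maximum(dblA, 1e-300)[:, None],
                np.cross(unit_n, e2) / np.maximum(dblA, 1e-300)[:, None],
            ],
            axis=1,
        )  # (m, 3 vertices, 3 xyz)
        self._faces = faces
        self._n = n
        self._edges = (e0, e1, e2)

        def cotpair(a, b):
            cross = np.linalg.norm(np.cross(a, b), axis=1)
            return np.einsum("ij,ij->i", a, b) / np.maximum(cross, 1e-300)

        # cotangents at each face corner, for the divergence operator
        self._cots = (
            cotpair(-e1, e2),  # at vertex 0 (between edges to v1 and v2)
            cotpair(-e2, e0),  # at vertex 1
            cotpair(-e0, e1),  # at vertex 2
        )

    def distances_from(self, source: int) -> np.ndarray:
        n = self._n
        delta = np.zeros(n)
        delta[source] = 1.0
        u = self._heat_neu.solve(delta)
        if self._heat_dir is not None:
            rhs = delta.copy()
            rhs[self._boundary] = 0.0
            u = 0.5 * (u + self._heat_dir.solve(rhs))

        faces = self._faces
        uf = u[faces]  # (m, 3)
        grad = np.einsum("mk,mkx->mx", uf, self._grad_basis)
        gnorm = np.linalg.norm(grad, axis=1)
        X = -grad / np.maximum(gnorm, 1e-300)[:, None]

        e0, e1, e2 = self._edges
        c0, c1, c2 = self._cots
        div = np.zeros(n)
        # integrated divergence at each corner of each face
        x_e0 = np.einsum("ij,ij->i", X, e0)
        x_e1 = np.einsum("ij,ij->i", X, e1)
        x_e2 = np.einsum("ij,ij->i", X, e2)
        np.add.at(div, faces[:, 0], 0.5 * (c2 * x_e2 - c1 * x_e1))
        np.add.at(div, faces[:, 1], 0.5 * (c0 * x_e0 - c2 * x_e2))
        np.add.at(div, faces[:, 2], 0.5 * (c1 * x_e1 - c0 * x_e0))

        # L here is positive semidefinite (D - W), so the Poisson step solves
        # L phi = -div
        phi = self._poisson.solve(-div)
        phi -= phi[source]
        return np.maximum(phi, 0.0)


def _place_apex(u2, v2, du, dv, other2):
    """2D position of a vertex at distances du/dv from u2/v2, on the side of
    line (u2, v2) opposite ``other2``. Returns None for degenerate edges."""
    e = v2 - u2
    L = np.linalg.norm(e)
    if L <= 0:
        return None
    t = (du**2 - dv**2 + L**2) / (2 * L)
    h = np.sqrt(max(du**2 - t**2, 0.0))
    dirv = e / L
    n = np.array([-dirv[1], dirv[0]])
    side = np.dot(other2 - u2, n)
    sign = -1.0 if side > 0 else 1.0
    return u2 + t * dirv + sign * h * n


def _segments_cross(a, b, c, d, eps=1e-12):
    """True if segment a-b properly crosses segment c-d (2D)."""

    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    return (o1 * o2 < eps) and (o3 * o4 < eps)


def _shortcut_graph(mesh: TriangleMesh) -> sp.csr_matrix:
    """Edge graph augmented with shortcut edges from face-strip unfolding.

    For every interior edge the two opposite vertices are connected with the
    exact geodesic length across the pair of faces (flattened about the
    shared edge) when that straight segment actually crosses the shared
    edge; the unfolding is then extended one face further, connecting
    vertices across three-face strips. Every added length is realized by a
    straight path on the unfolded surface, so graph distances on this
    adjacency remain a true upper bound on the geodesic distance.
    """
    faces = mesh.faces
    verts = mesh.vertices
    n = mesh.n_vertices

    # undirected edge -> up to two (opposite vertex) entries
    e_all = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    opp_all = np.r_[faces[:, 2], faces[:, 0], faces[:, 1]]
    edge_map: dict[tuple[int, int], list[int]] = {}
    for (a, b), o in zip(np.sort(e_all, axis=1), opp_all):
        edge_map.setdefault((int(a), int(b)), []).append(int(o))

    def dist(a, b):
        return float(np.linalg.norm(verts[a] - verts[b]))

    rows, cols, vals = [], [], []
    for (i, j), opps in edge_map.items():
        if len(opps) != 2:
            continue
        L = dist(i, j)
        if L <= 0:
            continue
        i2 = np.array([0.0, 0.0])
        j2 = np.array([L, 0.0])
        a2 = _place_apex(i2, j2, dist(opps[0], i), dist(opps[0], j), np.array([0.0, -1.0]))
        b2 = _place_apex(i2, j2, dist(opps[1], i), dist(opps[1], j), np.array([0.0, 1.0]))
        if a2 is None or b2 is None:
            continue
        # depth-1: straight segment across the hinge
        if _segments_cross(a2, b2, i2, j2):
            rows.append(opps[0])
            cols.append(opps[1])
            vals.append(float(np.linalg.norm(a2 - b2)))
        # depth-2: from each side, unfold one more face beyond the far edges
        # of the opposite triangle
        for p, q, p2, q2 in ((opps[0], opps[1], a2, b2), (opps[1], opps[0], b2, a2)):
            pos = {i: i2, j: j2, q: q2}
            for (u, v) in ((i, q), (j, q)):
                ekey = (min(u, v), max(u, v))
                far = edge_map.get(ekey, [])
                if len(far) != 2:
                    continue
                third = j if u == i else i  # vertex of (i,j,q) off this edge
                # the neighbor face across (u,v) away from triangle (i,j,q)
                cand = [o for o in far if o != third]
                if not cand:
                    continue
                r = cand[0]
                r2 = _place_apex(pos[u], pos[v], dist(r, u), dist(r, v), pos[third])
                if r2 is None or r == p:
                    continue
                if _segments_cross(p2, r2, i2, j2) and _segments_cross(
                    p2, r2, pos[u], pos[v]
                ):
                    rows.append(p)
                    cols.append(r)
                    vals.append(float(np.linalg.norm(p2 - r2)))

    base = mesh.adjacency().tocoo()
    all_r = np.concatenate([base.row, np.asarray(rows + cols, dtype=np.int64)])
    all_c = np.concatenate([base.col, np.asarray(cols + rows, dtype=np.int64)])
    all_v = np.concatenate([base.data, np.asarray(vals + vals, dtype=float)])
    # duplicate (row, col) pairs keep the minimum weight (COO would sum them)
    key = all_r * n + all_c
    order = np.argsort(key, kind="stable")
    key, all_r, all_c, all_v = key[order], all_r[order], all_c[order], all_v[order]
    starts = np.r_[0, np.flatnonzero(np.diff(key)) + 1]
    vmin = np.minimum.reduceat(all_v, starts)
    return sp.csr_matrix((vmin, (all_r[starts], all_c[starts])), shape=(n, n))


def geodesic_distances(
    mesh: TriangleMesh,
    source_vertices,
    method: str = "heat",
) -> GeodesicDistanceMatrix:
    """Pairwise geodesic distances among ``source_vertices`` on one hemisphere.

    Heat-method estimates are clamped from above by exact shortest edge-path
    distances (a true upper bound on the geodesic) and symmetrized by
    averaging. ``method="dijkstra"`` returns the pure edge-graph distances.

    Raises
    ------
    InvalidGeometryError
        If the source set is empty or contains a vertex disconnected from
        the rest of the source set.
    """
    source_vertices = np.asarray(source_vertices, dtype=np.int64)
    if source_vertices.size == 0:
        raise InvalidGeometryError("source vertex set is empty")
    if source_vertices.min() < 0 or source_vertices.max() >= mesh.n_vertices:
        raise InvalidGeometryError("source vertex index out of range")

    adj = mesh.adjacency()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        lab = labels[source_vertices]
        if len(np.unique(lab)) > 1:
            ref = lab[0]
            bad = source_vertices[lab != ref][0]
            raise InvalidGeometryError(
                f"source vertex {bad} is disconnected from the rest of the source set"
            )

    d_graph = dijkstra(adj, directed=False, indices=source_vertices)
    d_graph = d_graph[:, source_vertices]
    if not np.all(np.isfinite(d_graph)):
        bad_i = int(np.argwhere(~np.isfinite(d_graph))[0][0])
        raise InvalidGeometryError(
            f"source vertex {source_vertices[bad_i]} is unreachable on the mesh"
        )

    if method == "dijkstra":
        d = d_graph
    elif method == "heat":
        solver = _HeatGeodesicSolver(mesh)
        d = np.empty((len(source_vertices), len(source_vertices)))
        for i, s in enumerate(source_vertices):
            d[i] = solver.distances_from(int(s))[source_vertices]
        # Sandwich the estimate between provable bounds: the straight-line
        # 3D distance (never longer than the surface path) and graph
        # distances on the edge graph and the hinge-shortcut graph (both
        # realized by actual surface paths, hence upper bounds).
        shortcuts = _shortcut_graph(mesh)
        d_short = dijkstra(shortcuts, directed=False, indices=source_vertices)
        upper = np.minimum(d_graph, d_short[:, source_vertices])
        pts = mesh.vertices[source_vertices]
        lower = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        d = np.clip(d, lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")

    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return GeodesicDistanceMatrix(
        dists=d, vertex_ids=source_vertices, hemisphere=mesh.hemisphere
    )
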