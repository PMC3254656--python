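"""Labeled triangle meshes for the two-cell system.

The two blastomeres are represented as two polyhedra that share part of their
surface: a single vertex/triangle pool in which every triangle carries a patch
label (AB outer surface, P1 outer surface, or the shared contact surface).
Contact triangles are stored once, oriented with their normal pointing from AB
into P1, and are referenced by both bodies with opposite orientation sense, so
the two enclosed volumes are automatically consistent.

Lengths are in micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np


class Patch(IntEnum):
    AB_OUTER = 0
    P1_OUTER = 1
    CONTACT = 2


class Body(IntEnum):
    AB = 0
    P1 = 1


#: orientation sign of each patch within each body (0 = patch not in body)
_BODY_PATCH_SIGN = {
    Body.AB: {Patch.AB_OUTER: 1, Patch.CONTACT: 1, Patch.P1_OUTER: 0},
    Body.P1: {Patch.P1_OUTER: 1, Patch.CONTACT: -1, Patch.AB_OUTER: 0},
}


@dataclass
class TriSurfaceMesh:
    """Triangulated two-cell surface with patch labels.

    Attributes
    ----------
    vertices : (n, 3) float array, um
    triangles : (m, 3) int array of vertex indices; outer triangles are
        oriented outward from their body, contact triangles from AB toward P1.
    patch : (m,) int array of Patch labels
    """

    vertices: np.ndarray
    triangles: np.ndarray
    patch: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.patch = np.asarray(self.patch, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if self.patch.shape != (len(self.triangles),):
            raise ValueError("patch must have one label per triangle")

    def copy(self) -> "TriSurfaceMesh":
        return TriSurfaceMesh(
            self.vertices.copy(), self.triangles.copy(), self.patch.copy()
        )

    # -- basic per-triangle quantities -------------------------------------

    def triangle_cross(self) -> np.ndarray:
        """Un-normalized normals (cross products), (m, 3)."""
        v = self.vertices[self.triangles]
        return np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_cross(), axis=1)

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def patch_mask(self, label: Patch) -> np.ndarray:
        return self.patch == int(label)

    def bodies_present(self) -> list[Body]:
        out = []
        if np.any(self.patch_mask(Patch.AB_OUTER)) or np.any(self.patch_mask(Patch.CONTACT)):
            out.append(Body.AB)
        if np.any(self.patch_mask(Patch.P1_OUTER)):
            out.append(Body.P1)
        return out

    def body_faces(self, body: Body) -> tuple[np.ndarray, np.ndarray]:
        """Oriented faces bounding a body.

        Returns (triangles, signs): triangle index triples plus the
        orientation sign (+1 as stored / -1 reversed) of each face within the
        body's outward-oriented boundary.
        """
        body = Body(body)
        signs_by_patch = _BODY_PATCH_SIGN[body]
        keep = np.zeros(len(self.triangles), dtype=bool)
        sign = np.zeros(len(self.triangles), dtype=np.int64)
        for p, s in signs_by_patch.items():
            if s != 0:
                m = self.patch_mask(p)
                keep |= m
                sign[m] = s
        return self.triangles[keep], sign[keep]

    def is_body_closed(self, body: Body) -> bool:
        tris, signs = self.body_faces(body)
        if len(tris) == 0:
            return False
        oriented = tris.copy()
        flip = signs < 0
        oriented[flip] = oriented[flip][:, ::-1]
        edges = np.concatenate(
            [oriented[:, [0, 1]], oriented[:, [1, 2]], oriented[:, [2, 0]]]
        )
        # Closed + consistently oriented: every undirected edge appears exactly
        # twice, once in each direction.
        directed = {}
        for a, b in edges:
            directed[(a, b)] = directed.get((a, b), 0) + 1
        for (a, b), cnt in directed.items():
            if cnt != 1 or directed.get((b, a), 0) != 1:
                return False
        return True

    # -- topology helpers ---------------------------------------------------

    def edge_triangle_map(self) -> dict[tuple[int, int], list[int]]:
        """Map undirected edge -> incident triangle indices."""
        out: dict[tuple[int, int], list[int]] = {}
        for ti, (a, b, c) in enumerate(self.triangles):
            for u, v in ((a, b), (b, c), (c, a)):
                key = (u, v) if u < v else (v, u)
                out.setdefault(key, []).append(ti)
        return out

    def triple_line_vertices(self) -> np.ndarray:
        """Vertices on the triple line (boundary ring of the contact patch)."""
        contact = np.unique(self.triangles[self.patch_mask(Patch.CONTACT)])
        outer = np.unique(self.triangles[~self.patch_mask(Patch.CONTACT)])
        return np.intersect1d(contact, outer)

    def vertex_patches(self) -> list[set[int]]:
        """Set of patch labels incident to each vertex."""
        out: list[set[int]] = [set() for _ in range(len(self.vertices))]
        for tri, p in zip(self.triangles, self.patch):
            for v in tri:
                out[v].add(int(p))
        return out


# ---------------------------------------------------------------------------
# Measures


def surface_area(mesh: TriSurfaceMesh, label: Patch) -> float:
    """Total area (um^2) of the triangles carrying a patch label."""
    label = Patch(label)
    mask = mesh.patch_mask(label)
    if not np.any(mask):
        return 0.0
    v = mesh.vertices[mesh.triangles[mask]]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def enclosed_volume(mesh: TriSurfaceMesh, body: Body, check_closed: bool = True) -> float:
    """Divergence-theorem volume (um^3) of a body's bounding surface.

    The result is independent of the coordinate origin because the bounding
    surface is closed; positive for outward orientation.
    """
    if check_closed and not mesh.is_body_closed(body):
        raise ValueError(f"body {Body(body).name} is not a closed surface")
    return _body_volume_raw(mesh, body)


def _body_volume_raw(mesh: TriSurfaceMesh, body: Body) -> float:
    tris, signs = mesh.body_faces(body)
    v = mesh.vertices[tris]
    vol6 = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2]))
    return float(np.sum(signs * vol6) / 6.0)


def body_centroid(mesh: TriSurfaceMesh, body: Body) -> np.ndarray:
    """Volume centroid of a closed body via the divergence theorem."""
    tris, signs = mesh.body_faces(body)
    v = mesh.vertices[tris]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    # integral of x over the volume: sum over faces of n * ((a+b)^2+(b+c)^2+(c+a)^2)/48
    a, b, c = v[:, 0], v[:, 1], v[:, 2]
    sq = np.square(a + b) + np.square(b + c) + np.square(c + a)
    contrib = cross * sq / 48.0
    moment = np.sum(signs[:, None] * contrib, axis=0)
    return moment / _body_volume_raw(mesh, body)


# ---------------------------------------------------------------------------
# Gradients (used by the energy minimizer)


def area_gradient(mesh: TriSurfaceMesh, weights: np.ndarray) -> np.ndarray:
    """Gradient of sum_t w_t * area_t with respect to vertex positions.

    weights is a per-triangle array (e.g. the tension of each triangle's
    patch).  For a single triangle, d area / d v0 = 0.5 (v1 - v2) x n_hat.
    """
    v = mesh.vertices[mesh.triangles]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norm = np.linalg.norm(cross, axis=1, keepdims=True)
    nhat = cross / np.where(norm == 0, 1.0, norm)
    w = np.asarray(weights, dtype=float)[:, None]
    grad = np.zeros_like(mesh.vertices)
    g0 = 0.5 * np.cross(v[:, 1] - v[:, 2], nhat) * w
    g1 = 0.5 * np.cross(v[:, 2] - v[:, 0], nhat) * w
    g2 = 0.5 * np.cross(v[:, 0] - v[:, 1], nhat) * w
    np.add.at(grad, mesh.triangles[:, 0], g0)
    np.add.at(grad, mesh.triangles[:, 1], g1)
    np.add.at(grad, mesh.triangles[:, 2], g2)
    return grad


def volume_gradient(mesh: TriSurfaceMesh, body: Body) -> np.ndarray:
    """Gradient of the body's enclosed volume with respect to vertices."""
    tris, signs = mesh.body_faces(body)
    v = mesh.vertices[tris]
    s = signs[:, None] / 6.0
    grad = np.zeros_like(mesh.vertices)
    np.add.at(grad, tris[:, 0], s * np.cross(v[:, 1], v[:, 2]))
    np.add.at(grad, tris[:, 1], s * np.cross(v[:, 2], v[:, 0]))
    np.add.at(grad, tris[:, 2], s * np.cross(v[:, 0], v[:, 1]))
    return grad


def vertex_lumped_areas(mesh: TriSurfaceMesh) -> np.ndarray:
    """One third of the incident triangle area per vertex (mass lumping)."""
    areas = mesh.triangle_areas()
    out = np.zeros(len(mesh.vertices))
    for k in range(3):
        np.add.at(out, mesh.triangles[:, k], areas / 3.0)
    return out


# ---------------------------------------------------------------------------
# Refinement and quality maintenance


def subdivide(mesh: TriSurfaceMesh) -> TriSurfaceMesh:
    """Uniform 4-way (midpoint) subdivision.

    Each triangle is split at its edge midpoints; patch labels are inherited
    and shared edges (including contact/outer boundaries) are split with a
    single midpoint vertex, so bodies stay closed.
    """
    verts = [mesh.vertices]
    midpoint_index: dict[tuple[int, int], int] = {}
    next_index = len(mesh.vertices)
    new_vert_rows = []

    def midpoint(a: int, b: int) -> int:
        nonlocal next_index
        key = (a, b) if a < b else (b, a)
        idx = midpoint_index.get(key)
        if idx is None:
            idx = next_index
            midpoint_index[key] = idx
            new_vert_rows.append(0.5 * (mesh.vertices[a] + mesh.vertices[b]))
            next_index += 1
        return idx

    tris = []
    labels = []
    for (a, b, c), p in zip(mesh.triangles, mesh.patch):
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        tris.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
        labels.extend([p, p, p, p])

    if new_vert_rows:
        verts.append(np.array(new_vert_rows))
    return TriSurfaceMesh(
        np.vstack(verts), np.array(tris, dtype=np.int64), np.array(labels, dtype=np.int64)
    )


def _tri_min_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    e = np.array([p1 - p0, p2 - p1, p0 - p2])
    ln = np.linalg.norm(e, axis=1)
    if np.any(ln == 0):
        return 0.0
    # angle at each vertex from the law of cosines
    a, b, c = ln
    cosines = np.clip(
        [
            (a * a + c * c - b * b) / (2 * a * c),
            (a * a + b * b - c * c) / (2 * a * b),
            (b * b + c * c - a * a) / (2 * b * c),
        ],
        -1.0,
        1.0,
    )
    return float(np.min(np.arccos(cosines)))


def equiangulate(mesh: TriSurfaceMesh, max_passes: int = 3, coplanar_deg: float = 30.0) -> int:
    """Flip interior edges toward better-shaped (Delaunay-like) triangles.

    Only edges interior to a single patch are candidates; patch-boundary and
    triple-line edges are never flipped.  An edge is flipped when the flip
    strictly increases the minimum angle of the triangle pair and the pair is
    nearly coplanar (dihedral below `coplanar_deg`), so the flip is
    shape-neutral.  Returns the number of flips performed (in place).
    """
    cos_thresh = np.cos(np.deg2rad(coplanar_deg))
    total = 0
    for _ in range(max_passes):
        flips = 0
        emap = mesh.edge_triangle_map()
        done_tris: set[int] = set()
        for (u, v), tris in emap.items():
            if len(tris) != 2:
                continue
            t0, t1 = tris
            if t0 in done_tris or t1 in done_tris:
                continue
            if mesh.patch[t0] != mesh.patch[t1]:
                continue
            tri0, tri1 = mesh.triangles[t0], mesh.triangles[t1]
            w0 = int(tri0[~np.isin(tri0, (u, v))][0])
            w1 = int(tri1[~np.isin(tri1, (u, v))][0])
            if w0 == w1:
                continue
            P = mesh.vertices
            n0 = np.cross(P[tri0[1]] - P[tri0[0]], P[tri0[2]] - P[tri0[0]])
            n1 = np.cross(P[tri1[1]] - P[tri1[0]], P[tri1[2]] - P[tri1[0]])
            nn = np.linalg.norm(n0) * np.linalg.norm(n1)
            if nn == 0 or np.dot(n0, n1) / nn < cos_thresh:
                continue
            old_q = min(
                _tri_min_angle(P[u], P[v], P[w0]), _tri_min_angle(P[u], P[v], P[w1])
            )
            new_q = min(
                _tri_min_angle(P[w0], P[w1], P[u]), _tri_min_angle(P[w0], P[w1], P[v])
            )
            if new_q <= old_q + 1e-12:
                continue
            # Rebuild both triangles preserving orientation: in tri0 replace v
            # by w1, in tri1 replace u by w0.
            new0 = [w1 if x == v else x for x in tri0]
            new1 = [w0 if x == u else x for x in tri1]
            # Reject if a rebuilt triangle flips its normal.
            m0 = np.cross(P[new0[1]] - P[new0[0]], P[new0[2]] - P[new0[0]])
            m1 = np.cross(P[new1[1]] - P[new1[0]], P[new1[2]] - P[new1[0]])
            if np.dot(m0, n0 + n1) <= 0 or np.dot(m1, n0 + n1) <= 0:
                continue
            mesh.triangles[t0] = new0
            mesh.triangles[t1] = new1
            done_tris.update((t0, t1))
            flips += 1
        total += flips
        if flips == 0:
            break
    return total


def smooth_tangential(mesh: TriSurfaceMesh, relax: float = 0.5) -> None:
    """Tangential (shape-neutral) vertex smoothing, in place.

    Interior patch vertices move toward their neighborhood centroid with the
    normal component removed (no motion along the surface normal).  Triple
    line vertices move only along the triple line; vertices incident to two
    patches but off the triple line are treated like triple-line vertices of
    their shared boundary curve.
    """
    n_vert = len(mesh.vertices)
    vpatch = mesh.vertex_patches()

    # adjacency
    neighbors: list[set[int]] = [set() for _ in range(n_vert)]
    for a, b, c in mesh.triangles:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))

    # boundary-curve adjacency: edges whose two incident triangles belong to
    # different patches (or that have !=2 incident triangles)
    line_neighbors: list[set[int]] = [set() for _ in range(n_vert)]
    for (u, v), tris in mesh.edge_triangle_map().items():
        patches = {int(mesh.patch[t]) for t in tris}
        if len(tris) != 2 or len(patches) > 1:
            line_neighbors[u].add(v)
            line_neighbors[v].add(u)

    # area-weighted vertex normals
    cross = mesh.triangle_cross()
    vnorm = np.zeros((n_vert, 3))
    for k in range(3):
        np.add.at(vnorm, mesh.triangles[:, k], cross)
    lens = np.linalg.norm(vnorm, axis=1, keepdims=True)
    vnorm = vnorm / np.where(lens == 0, 1.0, lens)

    new_pos = mesh.vertices.copy()
    for i in range(n_vert):
        if not neighbors[i]:
            continue
        if len(vpatch[i]) > 1 or line_neighbors[i]:
            ln = line_neighbors[i]
            if len(ln) != 2:
                continue  # junctions / irregular line vertices stay put
            a, b = tuple(ln)
            mid = 0.5 * (mesh.vertices[a] + mesh.vertices[b])
            t = mesh.vertices[b] - mesh.vertices[a]
            tl = np.linalg.norm(t)
            if tl == 0:
                continue
            t /= tl
            delta = np.dot(mid - mesh.vertices[i], t) * t
        else:
            centroid = mesh.vertices[list(neighbors[i])].mean(axis=0)
            delta = centroid - mesh.vertices[i]
            delta -= np.dot(delta, vnorm[i]) * vnorm[i]
        new_pos[i] = mesh.vertices[i] + relax * delta
    mesh.vertices = new_pos


# ---------------------------------------------------------------------------
# Constructors


def make_icosphere(radius: float, subdivisions: int = 3, center=(0.0, 0.0, 0.0),
                   label: Patch = Patch.AB_OUTER) -> TriSurfaceMesh:
    """Single closed sphere mesh (one body), mainly for tests and oracles."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    tris = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    mesh = TriSurfaceMesh(verts, tris, np.full(len(tris), int(label)))
    for _ in range(subdivisions):
        mesh = subdivide(mesh)
    # push all vertices to the sphere
    norms = np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    mesh.vertices = mesh.vertices / norms * radius + np.asarray(center, dtype=float)
    return mesh


def make_two_cube_mesh(side: float, faces_per_edge: int = 2,
                       center=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0)) -> TriSurfaceMesh:
    """Two axis-aligned cubes of the given side sharing one face.

    The shared face is the contact patch; the AB cube sits on the negative
    (anterior) side of `axis`, P1 on the positive side.  Each square face is
    split into faces_per_edge^2 quads, each quad into two triangles.
    """
    n = int(faces_per_edge)
    if n < 1:
        raise ValueError("faces_per_edge must be >= 1")
    h = side / 2.0

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame with x' = axis
    tmp = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, tmp)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    frame = np.column_stack([axis, u, w])  # local -> world

    # Build in local coordinates: AB cube spans x in [-side, 0], P1 in [0, side].
    vert_index: dict[tuple[int, int, int], int] = {}
    verts: list[np.ndarray] = []

    def vid(i: int, j: int, k: int) -> int:
        # lattice coordinates: i in 0..2n along x (x = -side + i*side/n),
        # j,k in 0..n over the square cross-section
        key = (i, j, k)
        idx = vert_index.get(key)
        if idx is None:
            p = np.array([-side + i * side / n, -h + j * side / n, -h + k * side / n])
            idx = len(verts)
            verts.append(p)
            vert_index[key] = idx
        return idx

    tris: list[tuple[int, int, int]] = []
    labels: list[int] = []

    def add_quad(v00, v10, v11, v01, label):
        # split along one diagonal; orientation given by vertex order (CCW
        # seen from the outward side)
        tris.append((v00, v10, v11))
        tris.append((v00, v11, v01))
        labels.extend([label, label])

    def grid_face(corner_fn, label, flip=False):
        # corner_fn(j, k) -> vertex id over an (n+1)x(n+1) lattice
        for j in range(n):
            for k in range(n):
                v00 = corner_fn(j, k)
                v10 = corner_fn(j + 1, k)
                v11 = corner_fn(j + 1, k + 1)
                v01 = corner_fn(j, k + 1)
                if flip:
                    add_quad(v00, v01, v11, v10, label)
                else:
                    add_quad(v00, v10, v11, v01, label)

    ab, p1, cnt = int(Patch.AB_OUTER), int(Patch.P1_OUTER), int(Patch.CONTACT)

    # x = -side face of AB (outward normal -x)
    grid_face(lambda j, k: vid(0, j, k), ab, flip=True)
    # x = +side face of P1 (outward normal +x)
    grid_face(lambda j, k: vid(2 * n, j, k), p1, flip=False)
    # contact face at x = 0, normal +x (from AB toward P1)
    grid_face(lambda j, k: vid(n, j, k), cnt, flip=False)

    # side faces of both cubes
    for cube, label in ((0, ab), (1, p1)):
        i0 = cube * n
        for jk in range(n):
            for i in range(n):
                ii = i0 + i
                # y = -h (normal -y): quad over (x, z)
                add_quad(vid(ii, 0, jk), vid(ii + 1, 0, jk),
                         vid(ii + 1, 0, jk + 1), vid(ii, 0, jk + 1), label)
                # y = +h (normal +y)
                add_quad(vid(ii, n, jk), vid(ii, n, jk + 1),
                         vid(ii + 1, n, jk + 1), vid(ii + 1, n, jk), label)
                # z = -h (normal -z): quad over (x, y)
                add_quad(vid(ii, jk, 0), vid(ii, jk + 1, 0),
                         vid(ii + 1, jk + 1, 0), vid(ii + 1, jk, 0), label)
                # z = +h (normal +z)
                add_quad(vid(ii, jk, n), vid(ii + 1, jk, n),
                         vid(ii + 1, jk + 1, n), vid(ii, jk + 1, n), label)

    V = np.array(verts) @ frame.T + np.asarray(center, dtype=float)
    return TriSurfaceMesh(V, np.array(tris, dtype=np.int64), np.array(labels, dtype=np.int64))
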