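"""Triangulated surfaces, volume-conductor geometry and mesh operators.

All geometric quantities use millimetres; times are milliseconds and
conduction velocities mm/ms.  Surfaces are closed, consistently oriented
2-manifolds; the outward orientation convention (positive signed volume)
is enforced on load and on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "TriSurface",
    "ConductorModel",
    "MeshLaplacian",
    "MeshError",
    "NestingError",
    "load_surface",
    "save_surface",
    "make_nested_spheres",
    "make_myocardial_surface",
    "solid_angle",
    "triangle_solid_angles",
    "mesh_laplacian",
    "fastest_route_times",
]

ROLES = ("torso", "lung", "blood", "epicardium", "endocardium", "myocardial")


class MeshError(ValueError):
    """Raised for non-manifold, degenerate or otherwise invalid meshes."""


class NestingError(ValueError):
    """Raised when surfaces of a conductor model are not properly nested."""


@dataclass
class TriSurface:
    """Closed oriented triangle mesh with barycentric vertex areas.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    triangles : (F, 3) int array
        Vertex index triples, consistently ordered so that right-hand-rule
        normals point out of the enclosed volume.
    role : str
        One of ``torso, lung, blood, epicardium, endocardium, myocardial``.
    extra_edges : (K, 2) int array, optional
        Additional conduction links (e.g. transmural connections on a
        two-sheet myocardial surface) used by the fastest-route solver but
        not part of the triangulation.
    sheet : (V,) array of str, optional
        Sheet label per vertex for composite surfaces (``epi``/``endo``).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    role: str = "torso"
    extra_edges: np.ndarray | None = None
    sheet: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.role not in ROLES:
            raise ValueError(f"unknown surface role {self.role!r}")

    # -- basic quantities ------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric lumped areas: one third of incident triangle area."""
        areas = self.triangle_areas()
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.triangles.ravel(), np.repeat(areas / 3.0, 3))
        return va

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def signed_volume(self) -> float:
        v = self.vertices
        t = self.triangles
        c = v.mean(axis=0)
        a, b, d = v[t[:, 0]] - c, v[t[:, 1]] - c, v[t[:, 2]] - c
        return float(np.einsum("ij,ij->i", np.cross(a, b), d).sum() / 6.0)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2)."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_triangles

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(
            np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean()
        )

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- validation / repair --------------------------------------------

    def validate(self) -> None:
        """Check the closed-manifold and orientation invariants."""
        t = self.triangles
        if t.min() < 0 or t.max() >= self.n_vertices:
            raise MeshError("triangle indices out of range")
        areas = self.triangle_areas()
        bad = np.flatnonzero(areas <= 0)
        if bad.size:
            raise MeshError(f"degenerate (zero-area) triangle {int(bad[0])}")
        # directed edge counts: a closed consistently oriented 2-manifold has
        # every undirected edge appearing exactly twice, once per direction
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        es = np.sort(e, axis=1)
        uniq, counts = np.unique(es, axis=0, return_counts=True)
        not2 = counts != 2
        if not2.any():
            boundary = uniq[counts == 1]
            k = int(not2.sum())
            first = uniq[not2][0]
            raise MeshError(
                f"non-manifold mesh: {k} edges not shared by exactly 2 triangles "
                f"(boundary edge count {len(boundary)}); first offending edge "
                f"({int(first[0])}, {int(first[1])})"
            )
        if self.signed_volume() <= 0:
            raise MeshError("inward orientation: signed volume not positive")

    def oriented_copy(self) -> "TriSurface":
        """Return a copy with outward orientation (flip if needed)."""
        s = TriSurface(self.vertices.copy(), self.triangles.copy(), self.role,
                       None if self.extra_edges is None else self.extra_edges.copy(),
                       None if self.sheet is None else self.sheet.copy())
        if s.signed_volume() < 0:
            s.triangles = s.triangles[:, [0, 2, 1]]
        return s

    def flipped(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.triangles[:, [0, 2, 1]].copy(),
                          self.role)

    @classmethod
    def icosphere(cls, radius: float, center=(0.0, 0.0, 0.0), refinement: int = 3,
                  role: str = "torso") -> "TriSurface":
        if refinement < 0:
            raise ValueError("refinement must be >= 0")
        m = trimesh.creation.icosphere(subdivisions=refinement, radius=radius)
        return cls(np.asarray(m.vertices) + np.asarray(center, dtype=float),
                   np.asarray(m.faces), role=role)

    def contains_points(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        """Winding-number inside test via the Gauss solid-angle identity."""
        om = triangle_solid_angles(self.vertices, self.triangles, np.atleast_2d(points))
        return om.sum(axis=1) > 2.0 * np.pi


# ---------------------------------------------------------------------------
# mesh I/O

def save_surface(surface: TriSurface, path, fmt: str | None = None) -> None:
    """Write an ASCII OFF or PLY file."""
    fmt = _infer_format(path, fmt)
    v, t = surface.vertices, surface.triangles
    lines = []
    if fmt == "off":
        lines.append("OFF")
        lines.append(f"{len(v)} {len(t)} 0")
        lines += [f"{float(x):.17g} {float(y):.17g} {float(z):.17g}" for x, y, z in v]
    else:
        # ASCII PLY written with double precision (trimesh exports float32)
        lines += ["ply", "format ascii 1.0",
                  f"element vertex {len(v)}",
                  "property double x", "property double y", "property double z",
                  f"element face {len(t)}",
                  "property list uchar int vertex_indices", "end_header"]
        lines += [f"{float(x):.17g} {float(y):.17g} {float(z):.17g}" for x, y, z in v]
    lines += [f"3 {a} {b} {c}" for a, b, c in t]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_surface(path, fmt: str | None = None, role: str = "torso") -> TriSurface:
    """Load an OFF/PLY surface, check manifoldness and repair orientation."""
    fmt = _infer_format(path, fmt)
    m = trimesh.load(str(path), file_type=fmt, process=False)
    s = TriSurface(np.asarray(m.vertices, dtype=float),
                   np.asarray(m.faces, dtype=np.int64), role=role)
    s = s.oriented_copy()
    s.validate()
    return s


def _infer_format(path, fmt):
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1]
    fmt = fmt.lower().lstrip(".")
    if fmt not in ("off", "ply"):
        raise ValueError(f"unknown mesh format {fmt!r}; supported: off, ply")
    return fmt


# ---------------------------------------------------------------------------
# conductor model

@dataclass
class ConductorModel:
    """Nested closed surfaces with per-compartment conductivities.

    ``surfaces`` is ordered outermost first.  ``conductivities[k]`` is the
    conductivity (S/m) of the compartment directly inside ``surfaces[k]``,
    down to the next nested surface.  Outside the outermost surface the
    conductivity is zero (insulated body).  ``source_surface`` carries the
    equivalent source and is not a conductivity interface.
    """

    surfaces: list
    conductivities: list
    electrodes: np.ndarray = field(default=None)
    electrode_labels: list = field(default=None)
    source_surface: TriSurface | None = None

    def __post_init__(self):
        if len(self.conductivities) != len(self.surfaces):
            raise ValueError("need one conductivity per surface")
        self.validate_nesting()
        if self.electrodes is not None:
            self.electrodes = np.asarray(self.electrodes, dtype=np.int64)
            nt = self.surfaces[0].n_vertices
            if self.electrodes.min() < 0 or self.electrodes.max() >= nt:
                raise ValueError("electrode index outside the torso vertex range")
            if self.electrode_labels is None:
                self.electrode_labels = [f"E{i:03d}" for i in range(len(self.electrodes))]
            if len(set(self.electrode_labels)) != len(self.electrode_labels):
                raise ValueError("electrode lead labels must be unique")

    @property
    def torso(self) -> TriSurface:
        return self.surfaces[0]

    def validate_nesting(self) -> None:
        for k in range(1, len(self.surfaces)):
            outer, inner = self.surfaces[k - 1], self.surfaces[k]
            if not outer.contains_points(inner.vertices).all():
                raise NestingError(
                    f"surface {k} ({inner.role}) is not strictly inside "
                    f"surface {k - 1} ({outer.role})"
                )
        if self.source_surface is not None:
            if not self.torso.contains_points(self.source_surface.vertices).all():
                raise NestingError("source surface is not strictly inside the torso")

    def electrode_positions(self) -> np.ndarray:
        return self.torso.vertices[self.electrodes]

    def electrode_nearest(self, point) -> int:
        """Index (into the electrode list) of the electrode closest to a point."""
        d = np.linalg.norm(self.electrode_positions() - np.asarray(point), axis=1)
        return int(np.argmin(d))


def _farthest_point_sample(points: np.ndarray, n: int, start: int = 0) -> np.ndarray:
    """Deterministic farthest-point subsampling (greedy, fixed start)."""
    chosen = [start]
    d = np.linalg.norm(points - points[start], axis=1)
    for _ in range(1, n):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(sorted(chosen), dtype=np.int64)


def make_nested_spheres(
    torso_radius: float = 200.0,
    epi_radius: float = 50.0,
    endo_radius: float = 35.0,
    heart_center=(-40.0, 0.0, 0.0),
    torso_center=(0.0, 0.0, 0.0),
    torso_refinement: int = 3,
    heart_refinement: int = 2,
    conductivity: float = 0.2,
    n_electrodes: int = 400,
) -> ConductorModel:
    """Build the default nested-sphere torso/heart fixture.

    A homogeneous spherical torso encloses an eccentric spherical heart;
    the myocardial wall is bounded by concentric epicardial and
    endocardial spheres.  Electrodes are a farthest-point subsample of the
    torso vertices with unique lead labels.
    """
    torso = TriSurface.icosphere(torso_radius, torso_center, torso_refinement, "torso")
    epi = TriSurface.icosphere(epi_radius, heart_center, heart_refinement, "epicardium")
    endo = TriSurface.icosphere(endo_radius, heart_center, heart_refinement, "endocardium")
    electrodes = _farthest_point_sample(torso.vertices, n_electrodes)
    model = ConductorModel(
        surfaces=[torso],
        conductivities=[conductivity],
        electrodes=electrodes,
    )
    # nesting of the heart inside the torso and endo inside epi is checked
    # here even though only the torso is a conductivity interface
    ConductorModel(surfaces=[torso, epi, endo],
                   conductivities=[conductivity, conductivity, conductivity])
    model.epicardium = epi
    model.endocardium = endo
    return model


def make_myocardial_surface(epi: TriSurface, endo: TriSurface,
                            transmural_links: int = 1) -> TriSurface:
    """Merge epicardium and flipped endocardium into one source surface.

    Both sheets end up with normals pointing out of the myocardial wall
    (epicardial normals outward, endocardial normals into the cavity).  The
    basal connection between the sheets is left open; ``transmural_links``
    nearest-epicardial-neighbour edges per endocardial vertex are recorded
    as conduction links so activation can cross the wall.
    """
    endo_f = endo.flipped()
    nv = epi.n_vertices
    vertices = np.vstack([epi.vertices, endo_f.vertices])
    triangles = np.vstack([epi.triangles, endo_f.triangles + nv])
    sheet = np.array(["epi"] * epi.n_vertices + ["endo"] * endo.n_vertices)
    links = []
    if transmural_links > 0:
        d = np.linalg.norm(endo.vertices[:, None, :] - epi.vertices[None, :, :], axis=2)
        order = np.argsort(d, axis=1)[:, :transmural_links]
        for j in range(endo.n_vertices):
            for i in order[j]:
                links.append((int(i), nv + j))
    extra = np.array(links, dtype=np.int64) if links else None
    return TriSurface(vertices, triangles, role="myocardial",
                      extra_edges=extra, sheet=sheet)


# ---------------------------------------------------------------------------
# solid angles

def triangle_solid_angles(vertices: np.ndarray, triangles: np.ndarray,
                          observations: np.ndarray) -> np.ndarray:
    """Signed solid angles of each triangle seen from each observation point.

    Uses the van Oosterom-Strackee closed form.  Sign follows the triangle
    orientation: positive when the right-hand-rule normal faces away from
    the observer, so that the sum over a closed outward-oriented surface is
    4*pi from inside and 0 from outside.

    Returns an (n_obs, n_tri) array in steradians.
    """
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    out = np.empty((len(obs), len(triangles)))
    # chunk over observations to bound the (n_obs, n_tri, 3) temporaries
    chunk = max(1, int(4e6 // max(1, len(triangles))))
    p0 = vertices[triangles[:, 0]]
    p1 = vertices[triangles[:, 1]]
    p2 = vertices[triangles[:, 2]]
    for s in range(0, len(obs), chunk):
        o = obs[s:s + chunk, None, :]
        y1 = p0[None] - o
        y2 = p1[None] - o
        y3 = p2[None] - o
        n1 = np.linalg.norm(y1, axis=2)
        n2 = np.linalg.norm(y2, axis=2)
        n3 = np.linalg.norm(y3, axis=2)
        num = np.einsum("oij,oij->oi", y1, np.cross(y2, y3))
        den = (n1 * n2 * n3 + np.einsum("oij,oij->oi", y1, y2) * n3
               + np.einsum("oij,oij->oi", y1, y3) * n2
               + np.einsum("oij,oij->oi", y2, y3) * n1)
        out[s:s + chunk] = 2.0 * np.arctan2(num, den)
    return out


def solid_angle(triangle: np.ndarray, observation: np.ndarray) -> float:
    """Signed solid angle (sr) of one triangle from one observation point.

    Raises for observations lying in the plane of (and within) the
    triangle, where the double-layer kernel is singular.
    """
    tri = np.asarray(triangle, dtype=float)
    obs = np.asarray(observation, dtype=float)
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    nn = np.linalg.norm(n)
    if nn == 0:
        raise MeshError("degenerate triangle")
    dist = abs(np.dot(obs - tri[0], n / nn))
    if dist < 1e-9:
        # in-plane: singular only if inside the triangle
        if _point_in_triangle(obs, tri):
            raise MeshError("observation point lies on the triangle (singular)")
        return 0.0
    return float(triangle_solid_angles(tri, np.array([[0, 1, 2]]), obs[None])[0, 0])


def _point_in_triangle(p, tri) -> bool:
    v0, v1 = tri[1] - tri[0], tri[2] - tri[0]
    w = p - tri[0]
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    dw0, dw1 = w @ v0, w @ v1
    den = d00 * d11 - d01 * d01
    u = (d11 * dw0 - d01 * dw1) / den
    v = (d00 * dw1 - d01 * dw0) / den
    return (u >= -1e-12) and (v >= -1e-12) and (u + v <= 1 + 1e-12)


# ---------------------------------------------------------------------------
# mesh Laplacian

@dataclass
class MeshLaplacian:
    """Sparse node-by-node Laplacian operator on one surface."""

    matrix: sparse.csr_matrix
    scheme: str = "cotangent"

    def __matmul__(self, x):
        return self.matrix @ x

    @property
    def shape(self):
        return self.matrix.shape

    def toarray(self):
        return self.matrix.toarray()


def mesh_laplacian(surface: TriSurface, scheme: str = "cotangent") -> MeshLaplacian:
    """Cotangent-weighted (default) or umbrella graph Laplacian.

    Both variants are symmetric with zero row sums: ``L = diag(W 1) - W``
    with ``W`` the edge weights.  The cotangent weights make ``L x`` vanish
    at interior nodes for fields linear over a flat patch.
    """
    v, t = surface.vertices, surface.triangles
    areas = surface.triangle_areas()
    bad = np.flatnonzero(areas <= 1e-12)
    if bad.size:
        raise MeshError(f"degenerate (zero-area) triangle {int(bad[0])}")
    n = surface.n_vertices
    rows, cols, vals = [], [], []
    if scheme == "cotangent":
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            # cotangent of angle at vertex c, opposite edge (a, b)
            u = v[t[:, a]] - v[t[:, c]]
            w = v[t[:, b]] - v[t[:, c]]
            cot = np.einsum("ij,ij->i", u, w) / np.linalg.norm(np.cross(u, w), axis=1)
            rows.append(t[:, a]); cols.append(t[:, b]); vals.append(0.5 * cot)
            rows.append(t[:, b]); cols.append(t[:, a]); vals.append(0.5 * cot)
    elif scheme == "umbrella":
        e = surface.edges()
        rows.append(e[:, 0]); cols.append(e[:, 1]); vals.append(np.ones(len(e)))
        rows.append(e[:, 1]); cols.append(e[:, 0]); vals.append(np.ones(len(e)))
    else:
        raise ValueError(f"unknown Laplacian scheme {scheme!r}")
    W = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    L = sparse.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    return MeshLaplacian(L.tocsr(), scheme)


# ---------------------------------------------------------------------------
# fastest-route (graph geodesic) activation times

def fastest_route_times(surface: TriSurface, sources, velocity: float) -> np.ndarray:
    """Multi-source Dijkstra travel times over the surface edge graph.

    ``sources`` maps vertex index -> onset time (ms); a bare iterable of
    indices means onset 0.  Edge weights are Euclidean edge length divided
    by ``velocity`` (mm/ms); ``extra_edges`` of the surface participate.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if not isinstance(sources, dict):
        sources = {int(s): 0.0 for s in sources}
    if not sources:
        raise ValueError("sources must be nonempty")
    e = surface.edges()
    if surface.extra_edges is not None:
        e = np.vstack([e, surface.extra_edges])
    w = np.linalg.norm(surface.vertices[e[:, 0]] - surface.vertices[e[:, 1]], axis=1)
    w = w / velocity
    n = surface.n_vertices
    g = sparse.coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    idx = np.fromiter(sources.keys(), dtype=np.int64)
    onsets = np.fromiter(sources.values(), dtype=float)
    d = dijkstra(g, directed=False, indices=idx)
    times = (d + onsets[:, None]).min(axis=0)
    unreachable = ~np.isfinite(times)
    if unreachable.any():
        raise MeshError(
            f"disconnected surface: {int(unreachable.sum())} nodes unreachable "
            "from the given sources"
        )
    return times
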