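"""Mesh representation, solid angles, Laplacian and fastest-route times."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardinv import geometry as G


@pytest.fixture(scope="module")
def sphere3():
    return G.TriSurface.icosphere(50.0, (0.0, 0.0, 0.0), 3)


# ---------------------------------------------------------------------------
# TriSurface invariants and I/O

def test_icosphere_counts_and_euler():
    s = G.TriSurface.icosphere(50.0, refinement=2)
    assert s.n_vertices == 162          # 10 * 4^n + 2
    assert len(s.edges()) == 480
    assert s.n_triangles == 320
    assert s.euler_characteristic() == 2


def test_sphere_area_within_discretization_bound(sphere3):
    exact = 4 * np.pi * 50.0**2
    assert abs(sphere3.total_area() - exact) / exact < 0.01


def test_vertex_areas_sum_to_total_area(sphere3):
    assert sphere3.vertex_areas().sum() == pytest.approx(sphere3.total_area(),
                                                         rel=1e-12)
    assert (sphere3.vertex_areas() > 0).all()


@pytest.mark.parametrize("fmt", ["off", "ply"])
def test_mesh_roundtrip_identity(tmp_path, fmt):
    s = G.TriSurface.icosphere(200.0, (3.1, -2.2, 0.7), 2)
    p = tmp_path / f"mesh.{fmt}"
    G.save_surface(s, p)
    s2 = G.load_surface(p)
    assert np.abs(s2.vertices - s.vertices).max() < 1e-9
    assert np.array_equal(s2.triangles, s.triangles)


def test_open_surface_rejected_with_boundary_count(tmp_path):
    s = G.TriSurface.icosphere(10.0, refinement=1)
    open_s = G.TriSurface(s.vertices, s.triangles[1:], role="torso")
    with pytest.raises(G.MeshError, match="boundary edge count 3"):
        open_s.validate()


def test_inward_orientation_repaired_on_load(tmp_path):
    s = G.TriSurface.icosphere(10.0, refinement=1).flipped()
    assert s.signed_volume() < 0
    p = tmp_path / "inward.off"
    G.save_surface(s, p)
    s2 = G.load_surface(p)
    assert s2.signed_volume() > 0


def test_unknown_format_rejected(tmp_path):
    with pytest.raises(ValueError, match="unknown mesh format"):
        G.load_surface(tmp_path / "mesh.stl")


# ---------------------------------------------------------------------------
# solid angles

def test_gauss_identity_interior_and_exterior(sphere3, rng):
    r_in = rng.uniform(0, 45, 100)
    u = rng.normal(size=(100, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    om = G.triangle_solid_angles(sphere3.vertices, sphere3.triangles,
                                 u * r_in[:, None]).sum(axis=1)
    assert np.abs(om - 4 * np.pi).max() / (4 * np.pi) < 1e-10
    r_out = rng.uniform(55, 500, 100)
    om = G.triangle_solid_angles(sphere3.vertices, sphere3.triangles,
                                 u * r_out[:, None]).sum(axis=1)
    assert np.abs(om).max() / (4 * np.pi) < 1e-10


def test_solid_angle_sign_follows_orientation():
    tri = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    obs = np.zeros(3)
    om = G.solid_angle(tri, obs)
    om_flipped = G.solid_angle(tri[[0, 2, 1]], obs)
    assert om == pytest.approx(-om_flipped)
    assert om > 0  # (e1,e2,e3) normal faces away from the origin


def test_solid_angle_far_field_approximation(rng):
    # one triangle, far observation: Omega ~ area * cos(theta) / r^2
    tri = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0]])
    area = 2.0
    diam = 2 * np.sqrt(2)
    r = 20 * diam
    theta = 0.3
    obs = np.array([0.5, 0.5, 0.0]) + r * np.array(
        [np.sin(theta), 0, np.cos(theta)])
    om = G.solid_angle(tri[[0, 2, 1]], obs)   # orient normal toward +z
    # independent oracle: dense barycentric quadrature of the kernel
    n_q = 60
    a = rng.uniform(0, 1, (n_q * n_q, 2))
    a = a[a.sum(axis=1) <= 1]
    pts = tri[0] + a[:, :1] * (tri[1] - tri[0]) + a[:, 1:] * (tri[2] - tri[0])
    d = obs - pts
    quad = area * np.mean(np.array([0, 0, 1.0]) @ (d / np.linalg.norm(
        d, axis=1, keepdims=True)**3).T)
    assert om == pytest.approx(quad, rel=0.01)
    assert om == pytest.approx(area * np.cos(theta) / r**2, rel=0.01)


def test_solid_angle_singular_on_triangle():
    tri = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
    with pytest.raises(G.MeshError, match="singular"):
        G.solid_angle(tri, np.array([0.2, 0.2, 0.0]))
    # in-plane but outside the triangle is regular (zero)
    assert G.solid_angle(tri, np.array([5.0, 5.0, 0.0])) == 0.0


@settings(max_examples=25, deadline=None)
@given(st.floats(0.1, 0.9), st.floats(0.0, 2 * np.pi), st.floats(-1.0, 1.0))
def test_gauss_identity_property(rfrac, phi, costh):
    surf = G.TriSurface.icosphere(30.0, refinement=2)
    sinth = np.sqrt(1 - costh**2)
    p = 30.0 * rfrac * np.array(
        [sinth * np.cos(phi), sinth * np.sin(phi), costh])
    om = G.triangle_solid_angles(surf.vertices, surf.triangles, p[None]).sum()
    assert om == pytest.approx(4 * np.pi, rel=1e-10)


# ---------------------------------------------------------------------------
# mesh Laplacian

def test_laplacian_annihilates_constants_and_is_symmetric(sphere3):
    L = G.mesh_laplacian(sphere3)
    ones = np.ones(sphere3.n_vertices)
    assert np.abs(L @ ones).max() < 1e-12
    diff = (L.matrix - L.matrix.T)
    assert abs(diff).max() == 0.0


def test_laplacian_annihilates_linear_fields_on_flat_patch():
    # regular triangulated planar grid; interior nodes only
    n = 8
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    surf = G.TriSurface(pts, np.array(tris), role="torso")
    L = G.mesh_laplacian(surf)
    f = 2.0 * pts[:, 0] - 3.0 * pts[:, 1] + 1.0
    res = L @ f
    interior = np.array([i * n + j for i in range(1, n - 1)
                         for j in range(1, n - 1)])
    assert np.abs(res[interior]).max() < 1e-8 * np.abs(f).max()


def test_laplacian_rejects_degenerate_triangle():
    pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
    tris = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    with pytest.raises(G.MeshError, match="degenerate"):
        G.mesh_laplacian(G.TriSurface(pts, tris))


def test_umbrella_scheme_available(sphere3):
    L = G.mesh_laplacian(sphere3, scheme="umbrella")
    assert L.scheme == "umbrella"
    assert np.abs(L @ np.ones(sphere3.n_vertices)).max() < 1e-12


# ---------------------------------------------------------------------------
# fastest-route times

def test_fastest_route_single_source(sphere3):
    tau = G.fastest_route_times(sphere3, [7], 1.0)
    assert tau[7] == 0.0
    mask = np.ones(len(tau), bool)
    mask[7] = False
    assert (tau[mask] > 0).all()


def test_fastest_route_velocity_scaling(sphere3):
    t1 = G.fastest_route_times(sphere3, [0], 1.0)
    t2 = G.fastest_route_times(sphere3, [0], 2.0)
    assert np.allclose(t2, t1 / 2.0, rtol=1e-12)


def test_fastest_route_antipodal_great_circle():
    s4 = G.TriSurface.icosphere(50.0, refinement=4)
    i0 = int(np.argmax(s4.vertices[:, 2]))
    i1 = int(np.argmin(s4.vertices[:, 2]))
    tau = G.fastest_route_times(s4, [i0], 1.0)
    exact = np.pi * 50.0
    # chordal edges underestimate arcs, zig-zag paths overestimate; the
    # net deviation stays within a few percent on this mesh
    assert abs(tau[i1] - exact) <= 0.08 * exact


def test_fastest_route_triangle_inequality(sphere3, rng):
    nodes = rng.integers(0, sphere3.n_vertices, 12)
    times = {int(k): G.fastest_route_times(sphere3, [int(k)], 1.0)
             for k in nodes}
    for a in nodes[:4]:
        for b in nodes[4:8]:
            for c in nodes[8:]:
                assert times[int(a)][b] <= times[int(a)][c] \
                    + times[int(c)][b] + 1e-9


def test_fastest_route_unreachable_errors(myocardial):
    # strip the transmural links: the two sheets disconnect
    import dataclasses
    detached = dataclasses.replace(myocardial, extra_edges=None)
    with pytest.raises(G.MeshError, match="unreachable"):
        G.fastest_route_times(detached, [0], 1.0)


def test_fastest_route_onset_times_respected(sphere3):
    tau = G.fastest_route_times(sphere3, {3: 25.0}, 1.0)
    assert tau[3] == 25.0


# ---------------------------------------------------------------------------
# nested-sphere conductor fixture

def test_nested_spheres_default_fixture(model):
    assert model.torso.n_vertices == 642
    assert model.epicardium.n_vertices == 162
    assert len(model.electrodes) == 400
    assert len(set(model.electrode_labels)) == 400


def test_nesting_violation_detected():
    with pytest.raises(G.NestingError):
        G.make_nested_spheres(epi_radius=50.0, endo_radius=60.0)


def test_myocardial_surface_orientation(model, myocardial):
    nepi = model.epicardium.n_vertices
    assert (myocardial.sheet[:nepi] == "epi").all()
    assert (myocardial.sheet[nepi:] == "endo").all()
    # flipped endocardium: its triangles enclose negative volume
    endo_part = G.TriSurface(myocardial.vertices,
                             myocardial.triangles[model.epicardium.n_triangles:],
                             role="endocardium")
    assert endo_part.signed_volume() < 0
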