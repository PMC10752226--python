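"""Boundary-element forward models and transfer matrices.

Two transfer matrices are built on a piecewise-homogeneous volume
conductor discretized by closed triangulated interfaces:

* the EP (epicardial potential) matrix ``T`` maps potentials impressed on
  a closed surface around the heart to body-surface electrode potentials.
  It is assembled from the boundary integral equations of the passive
  annular region between the source surface (Dirichlet data) and the
  insulated torso.  A uniform impressed potential produces the same
  uniform body potential, so every row of ``T`` sums to one.

* the EDL (equivalent dipole layer) matrix ``A`` maps the strength of a
  dipole layer on the full myocardial surface (epicardium plus flipped
  endocardium, normals out of the wall) to electrode potentials.  A closed
  layer of uniform strength generates no external field, so rows of ``A``
  sum to zero.

The double-layer operators use analytic van Oosterom-Strackee solid
angles with vertex (hat-function) lumping; diagonal terms are closed via
the Gauss identity so that constant potentials are reproduced exactly.
The single-layer operators use midpoint-rule quadrature with an analytic
formula for the vertex-singular (incident-triangle) integrals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .geometry import ConductorModel, TriSurface, triangle_solid_angles

__all__ = [
    "TransferMatrix",
    "SensitivityMap",
    "BEMSolver",
    "bem_interface_solve",
    "build_ep_transfer",
    "build_edl_transfer",
    "sensitivity_map",
    "save_transfer",
    "load_transfer",
]

FOUR_PI = 4.0 * np.pi


# ---------------------------------------------------------------------------
# containers

@dataclass
class TransferMatrix:
    """Dense electrode-by-source-node transfer matrix with registry metadata.

    ``flavor`` is ``"ep"`` (mV body potential per mV impressed epicardial
    potential) or ``"edl"`` (mV body potential per mV of dipole-layer
    template strength).
    """

    matrix: np.ndarray
    flavor: str
    electrode_labels: list
    source_role: str
    source_vertex_areas: np.ndarray
    source_vertices: np.ndarray
    source_sheet: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.flavor not in ("ep", "edl"):
            raise ValueError("flavor must be 'ep' or 'edl'")
        ne, nh = self.matrix.shape
        if ne != len(self.electrode_labels):
            raise ValueError("electrode registry does not match matrix rows")
        if nh != len(self.source_vertex_areas):
            raise ValueError("source registry does not match matrix columns")

    @property
    def n_electrodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]

    def electrode_index(self, label: str) -> int:
        try:
            return self.electrode_labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in registry") from None


@dataclass
class SensitivityMap:
    """Per-source-node sensitivity of one electrode (mV per cm^2)."""

    values: np.ndarray
    electrode_label: str
    flavor: str
    scale_mv: float
    source_sheet: np.ndarray | None = None


def save_transfer(tm: TransferMatrix, path) -> None:
    """Persist matrix as .npz with a JSON sidecar of registry metadata."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             matrix=tm.matrix,
             source_vertex_areas=tm.source_vertex_areas,
             source_vertices=tm.source_vertices,
             source_sheet=(tm.source_sheet if tm.source_sheet is not None
                           else np.array([])))
    side = {
        "flavor": tm.flavor,
        "electrode_labels": list(tm.electrode_labels),
        "source_role": tm.source_role,
        "meta": tm.meta,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(side, fh, indent=1)


def load_transfer(path) -> TransferMatrix:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with np.load(base + ".npz", allow_pickle=False) as z:
        matrix = z["matrix"]
        areas = z["source_vertex_areas"]
        verts = z["source_vertices"]
        sheet = z["source_sheet"]
    with open(base + ".json") as fh:
        side = json.load(fh)
    return TransferMatrix(
        matrix=matrix, flavor=side["flavor"],
        electrode_labels=side["electrode_labels"],
        source_role=side["source_role"],
        source_vertex_areas=areas, source_vertices=verts,
        source_sheet=(sheet if sheet.size else None),
        meta=side.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# integral operators

def patch_solid_angles(surface: TriSurface, obs: np.ndarray) -> np.ndarray:
    """Vertex-lumped double-layer matrix: (n_obs, n_vertices).

    Each triangle's solid angle is split in thirds over its vertices (hat
    functions with barycentric lumping).
    """
    om_tri = triangle_solid_angles(surface.vertices, surface.triangles, obs)
    out = np.zeros((len(np.atleast_2d(obs)), surface.n_vertices))
    for c in range(3):
        np.add.at(out.T, surface.triangles[:, c], om_tri.T / 3.0)
    return out


def _vertex_singular_single_layer(p, q1, q2) -> float:
    """Analytic integral of 1/r over a triangle from its own vertex ``p``."""
    u = q2 - q1
    lu = np.linalg.norm(u)
    if lu == 0:
        return 0.0
    u = u / lu
    f = q1 + ((p - q1) @ u) * u          # foot of perpendicular from p
    h = np.linalg.norm(p - f)
    t1 = (q1 - f) @ u
    t2 = (q2 - f) @ u
    if h < 1e-12:
        return 0.0
    return float(h * abs(np.arcsinh(t2 / h) - np.arcsinh(t1 / h)))


def single_layer_matrix(surface: TriSurface, obs: np.ndarray,
                        obs_is_surface: bool = False) -> np.ndarray:
    """Vertex-lumped single-layer matrix G_ij ~ integral of dS/r over patches.

    Midpoint (edge-midpoint, degree-2) quadrature per triangle; when
    ``obs_is_surface`` the observation points are the surface's own
    vertices and incident-triangle integrals use the analytic
    vertex-singular formula.
    """
    obs = np.atleast_2d(obs)
    v, t = surface.vertices, surface.triangles
    areas = surface.triangle_areas()
    # edge midpoints quadrature, weight 1/3 each
    mids = np.stack([(v[t[:, 0]] + v[t[:, 1]]) / 2,
                     (v[t[:, 1]] + v[t[:, 2]]) / 2,
                     (v[t[:, 2]] + v[t[:, 0]]) / 2], axis=1)  # (F, 3, 3)
    g_tri = np.zeros((len(obs), len(t)))
    chunk = max(1, int(4e6 // max(1, len(t))))
    for s in range(0, len(obs), chunk):
        o = obs[s:s + chunk]
        d = np.linalg.norm(mids[None, :, :, :] - o[:, None, None, :], axis=3)
        g_tri[s:s + chunk] = areas[None, :] * np.mean(1.0 / d, axis=2)
    if obs_is_surface:
        for f, tri in enumerate(t):
            for c in range(3):
                i = tri[c]
                g_tri[i, f] = _vertex_singular_single_layer(
                    v[i], v[tri[(c + 1) % 3]], v[tri[(c + 2) % 3]])
    out = np.zeros((len(obs), surface.n_vertices))
    for c in range(3):
        np.add.at(out.T, t[:, c], g_tri.T / 3.0)
    return out


# ---------------------------------------------------------------------------
# interface potential solver (impressed sources in a closed conductor)

class BEMSolver:
    """Double-layer collocation solver for nested homogeneous compartments.

    Solves for potentials on all conductivity interfaces generated by
    impressed sources given through their infinite-medium potential.  The
    insulated outer boundary leaves the potential defined up to a
    constant; the singular system is regularized by rank-one deflation
    against area weights, and returned potentials are re-referenced to
    zero mean over the electrode set (or over the torso if no electrodes).
    """

    def __init__(self, model: ConductorModel):
        self.model = model
        surfaces = model.surfaces
        sig_in = list(model.conductivities)
        sig_out = [0.0] + sig_in[:-1]
        self.sigma_source = sig_in[-1]   # conductivity of the innermost compartment
        offs = np.cumsum([0] + [s.n_vertices for s in surfaces])
        self.offsets = offs
        n = offs[-1]
        all_verts = np.vstack([s.vertices for s in surfaces])
        self.n = n
        C = np.zeros((n, n))
        for i in range(n):
            C[i, i] = 0.0
        # assemble -(1/4pi) sum_l (sig_in - sig_out) D^(l), plus the jump term
        for li, s in enumerate(surfaces):
            D = patch_solid_angles(s, all_verts)
            # diagonal closure on the self-surface block: total solid angle
            # subtended by a closed surface at a point on it is 2*pi
            a, b = offs[li], offs[li + 1]
            block = D[a:b, :]
            rs = block.sum(axis=1)
            block[np.arange(b - a), np.arange(b - a)] += 2.0 * np.pi - rs
            D[a:b, :] = block
            C -= (sig_in[li] - sig_out[li]) / FOUR_PI * D
        for li in range(len(surfaces)):
            a, b = offs[li], offs[li + 1]
            C[np.arange(a, b), np.arange(a, b)] += 0.5 * (sig_in[li] + sig_out[li])
        # deflation: the constant vector spans the kernel (insulated body)
        w = np.concatenate([s.vertex_areas() for s in surfaces])
        w = w / w.sum()
        C = C + np.outer(np.ones(n), w) * self.sigma_source
        self.lu = linalg.lu_factor(C)
        piv = np.abs(np.diag(self.lu[0]))
        if piv.min() < 1e-12 * piv.max():
            raise ValueError(
                "BEM system singular after deflation (duplicate surfaces?)")
        self.all_vertices = all_verts

    def solve_from_infinite(self, phi_inf) -> np.ndarray:
        """Interface potentials from infinite-medium source potentials.

        ``phi_inf``: (n,) or (n, k) potentials of the impressed sources in
        an unbounded medium of the source-compartment conductivity,
        evaluated at every interface vertex.
        """
        rhs = self.sigma_source * np.asarray(phi_inf, dtype=float)
        phi = linalg.lu_solve(self.lu, rhs)
        return self._reference(phi)

    def _reference(self, phi):
        m = self.model
        if m.electrodes is not None:
            ref = phi[m.electrodes].mean(axis=0)
        else:
            ref = phi[: self.offsets[1]].mean(axis=0)
        return phi - ref

    def torso_rows(self, phi):
        return phi[: self.offsets[1]]


def bem_interface_solve(model: ConductorModel) -> BEMSolver:
    """Assemble and factorize the interface-potential operator."""
    return BEMSolver(model)


# ---------------------------------------------------------------------------
# transfer matrices

def build_ep_transfer(model: ConductorModel, source_surface: TriSurface = None,
                      include_endocardium: TriSurface = None) -> TransferMatrix:
    """EP transfer matrix of the passive annulus between heart and torso.

    ``source_surface`` (default: ``model.epicardium``) is the closed
    surface carrying impressed potentials.  If ``include_endocardium`` is
    given, endocardial nodes are appended to the source registry; with
    closed sheets the epicardial Dirichlet boundary fully separates them
    from the passive region, so their columns are exactly zero — the
    shielding that makes an endocardial EP source unobservable.
    """
    if source_surface is None:
        source_surface = getattr(model, "epicardium", None)
    if source_surface is None:
        raise ValueError("EP transfer requires a source surface")
    torso = model.torso
    if not torso.contains_points(source_surface.vertices).all():
        raise ValueError("source surface is not strictly inside the torso")

    B, H = torso, source_surface
    nb, nh = B.n_vertices, H.n_vertices
    # double-layer blocks with annulus orientation: torso outward, heart
    # surface flipped (its annulus-outward normal points into the heart)
    D_BB = patch_solid_angles(B, B.vertices)
    rs = D_BB.sum(axis=1)
    D_BB[np.arange(nb), np.arange(nb)] += 2.0 * np.pi - rs
    D_BH = -patch_solid_angles(H, B.vertices)
    D_HB = patch_solid_angles(B, H.vertices)
    D_HH = -patch_solid_angles(H, H.vertices)
    rs = (-D_HH).sum(axis=1)
    D_HH[np.arange(nh), np.arange(nh)] -= 2.0 * np.pi - rs

    c_B = (D_BB.sum(axis=1) + D_BH.sum(axis=1))
    c_H = (D_HB.sum(axis=1) + D_HH.sum(axis=1))

    G_BH = single_layer_matrix(H, B.vertices)
    G_HH = single_layer_matrix(H, H.vertices, obs_is_surface=True)

    GG = linalg.solve(G_HH, np.hstack([
        (np.diag(c_H) - D_HH), -D_HB]))
    X_H = GG[:, :nh]      # G_HH^-1 (4pi c_H - D_HH)
    X_B = GG[:, nh:]      # -G_HH^-1 D_HB
    M_B = np.diag(c_B) - D_BB - G_BH @ X_B
    R = D_BH + G_BH @ X_H
    T_full = linalg.solve(M_B, R)

    matrix = T_full[model.electrodes]
    areas = H.vertex_areas()
    verts = H.vertices
    sheet = np.array(["epi"] * nh)
    meta = {"formulation": "annulus-dirichlet", "n_torso_vertices": nb}
    if include_endocardium is not None:
        ne_v = include_endocardium.n_vertices
        matrix = np.hstack([matrix, np.zeros((matrix.shape[0], ne_v))])
        areas = np.concatenate([areas, include_endocardium.vertex_areas()])
        verts = np.vstack([verts, include_endocardium.vertices])
        sheet = np.concatenate([sheet, np.array(["endo"] * ne_v)])
        meta["endocardium"] = "shielded (closed epicardial Dirichlet boundary)"
    return TransferMatrix(matrix=matrix, flavor="ep",
                          electrode_labels=list(model.electrode_labels),
                          source_role="epicardium" if include_endocardium is None
                          else "myocardial",
                          source_vertex_areas=areas, source_vertices=verts,
                          source_sheet=sheet, meta=meta)


DEFAULT_EDL_SCALE = 0.28
"""Dimensionless dipole-layer scale (intra/extracellular conductivity
ratio folded with layer strength); the default gives ~1 mV peak body-surface
QRS for a full-amplitude depolarization front on the default fixture."""


def build_edl_transfer(model: ConductorModel, myocardial_surface: TriSurface,
                       edl_scale: float = DEFAULT_EDL_SCALE) -> TransferMatrix:
    """EDL transfer matrix: unit dipole-layer strength per node -> electrodes.

    Column j is the body response to a unit-strength dipole layer on the
    barycentric patch of myocardial node j, oriented along the local
    out-of-wall normal, propagated through the volume-conductor solve.
    The infinite-medium potential of a layer of strength d on a patch is
    ``edl_scale * d * Omega / (4 pi)`` with Omega the signed patch solid
    angle.
    """
    if myocardial_surface is None:
        raise ValueError("EDL transfer requires the myocardial source surface")
    solver = BEMSolver(model)
    # infinite-medium dipole-layer potentials at every interface vertex
    omega = patch_solid_angles(myocardial_surface, solver.all_vertices)
    phi_inf = edl_scale * omega / FOUR_PI
    phi = solver.solve_from_infinite(phi_inf)
    matrix = solver.torso_rows(phi)[model.electrodes]
    return TransferMatrix(
        matrix=matrix, flavor="edl",
        electrode_labels=list(model.electrode_labels),
        source_role="myocardial",
        source_vertex_areas=myocardial_surface.vertex_areas(),
        source_vertices=myocardial_surface.vertices,
        source_sheet=myocardial_surface.sheet,
        meta={"edl_scale": edl_scale},
    )


def sensitivity_map(tm: TransferMatrix, electrode_label: str,
                    scale_mv: float = 15.0) -> SensitivityMap:
    """Per-node sensitivity of one electrode, mV per cm^2 of active source.

    ``value_j = T_ij / alpha_j * scale`` with alpha_j in cm^2.  The default
    15 mV activity scale for the EP flavor makes the peak epicardial
    contribution comparable to that of a full-amplitude dipole layer; for
    the EDL flavor pass the template amplitude.
    """
    i = tm.electrode_index(electrode_label)
    areas_cm2 = tm.source_vertex_areas / 100.0
    if (areas_cm2 <= 0).any():
        raise ValueError("zero-area source node in registry")
    values = tm.matrix[i] / areas_cm2 * scale_mv
    return SensitivityMap(values=values, electrode_label=electrode_label,
                          flavor=tm.flavor, scale_mv=scale_mv,
                          source_sheet=tm.source_sheet)
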