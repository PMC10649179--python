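"""Three-shell volume-conduction head model and BEM forward solution.

The head is modelled as nested closed triangulated surfaces (cortex,
skull, scalp) with piecewise-constant conductivity.  Scalp potentials of
a current dipole follow the quasi-static Poisson equation; on the
interfaces the potential satisfies a boundary integral equation which is
discretised by collocation with a constant potential per triangle,
evaluated at panel centroids.  The integral kernel is the solid angle
each panel subtends at each collocation point.

Everything is SI internally: metres, Siemens/metre, Ampere-metres,
Volts.  Microvolts appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.linalg import lu_factor, lu_solve
from scipy.special import eval_legendre, lpmv

#: Standard 3-shell conductivities, S/m: brain, skull, scalp.
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)


class MeshError(ValueError):
    """Raised when a surface is not a closed, consistently oriented mesh."""


@dataclass
class TriMesh:
    """A closed, outward-oriented triangulated surface.

    ``vertices`` is (n_v, 3) in metres, ``triangles`` (n_t, 3) vertex
    index triplets with counter-clockwise winding seen from outside.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, int)

    # --- derived geometry -------------------------------------------------
    @property
    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    @property
    def _cross(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])

    @property
    def areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self._cross, axis=1)

    @property
    def normals(self) -> np.ndarray:
        c = self._cross
        return c / np.linalg.norm(c, axis=1, keepdims=True)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def validate(self) -> None:
        """Check closedness, winding consistency and non-degeneracy."""
        tm = trimesh.Trimesh(self.vertices, self.triangles, process=False)
        if not tm.is_watertight:
            raise MeshError("surface is not closed (open edges present)")
        if not tm.is_winding_consistent:
            raise MeshError("inconsistent triangle winding")
        if np.any(self.areas < 1e-18):
            raise MeshError("degenerate (zero-area) triangles present")

    def signed_volume(self) -> float:
        """Volume enclosed by the surface (positive for outward winding)."""
        v = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->", v[:, 0],
                               np.cross(v[:, 1], v[:, 2])) / 6.0)

    # --- I/O ----------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write as OFF or PLY, chosen by suffix."""
        trimesh.Trimesh(self.vertices, self.triangles,
                        process=False).export(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "TriMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


def make_icosphere(radius: float, subdivisions: int) -> TriMesh:
    """Icosphere of given radius; 20 * 4**subdivisions triangles."""
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@dataclass
class ShellModel:
    """Nested shells, innermost (cortex boundary) to outermost (scalp).

    ``conductivities`` are per-layer values, inside each surface in
    order, so ``conductivities[i]`` fills the region bounded outwardly
    by ``shells[i]``; the exterior of the last shell is air (sigma = 0).
    ``sigma_s`` is the conductivity of the source region (the innermost
    layer unless stated otherwise).
    """

    shells: list[TriMesh]
    conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES
    sigma_s: float | None = None

    def __post_init__(self) -> None:
        if len(self.shells) != len(self.conductivities):
            raise ValueError("one conductivity per shell required")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.sigma_s is None:
            self.sigma_s = self.conductivities[0]

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    def sigma_in(self, k: int) -> float:
        """Conductivity just inside interface k."""
        return self.conductivities[k]

    def sigma_out(self, k: int) -> float:
        """Conductivity just outside interface k (0 = air for the scalp)."""
        return self.conductivities[k + 1] if k + 1 < self.n_shells else 0.0

    @property
    def outer(self) -> TriMesh:
        return self.shells[-1]

    @property
    def inner(self) -> TriMesh:
        return self.shells[0]


def make_concentric_sphere_model(
    radii: tuple[float, float, float] = (0.08, 0.085, 0.092),
    conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES,
    subdivision: int = 2,
) -> ShellModel:
    """Concentric-sphere stand-in for the real head geometry.

    Radii are metres, strictly increasing, innermost first; the default
    (8.0, 8.5, 9.2) cm approximates cortex/skull/scalp radii of an adult
    head.
    """
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    radii = tuple(float(r) for r in radii)
    if not all(a < b for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    shells = [make_icosphere(r, subdivision) for r in radii]
    return ShellModel(shells=shells, conductivities=tuple(conductivities))


@dataclass
class Dipole:
    """A current dipole: position (m) and moment (A*m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)
        self.moment = np.asarray(self.moment, float).reshape(3)


def infinite_medium_potential(dipole: Dipole, points: np.ndarray,
                              sigma: float) -> np.ndarray:
    """Potential of a current dipole in an unbounded homogeneous medium.

    u(r) = D . (r - r0) / (4 pi sigma |r - r0|^3), in Volts.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = np.atleast_2d(np.asarray(points, float))
    d = pts - dipole.position
    r3 = np.linalg.norm(d, axis=1) ** 3
    if np.any(r3 < 1e-300):
        raise ZeroDivisionError("observation point coincides with the dipole")
    u = d @ dipole.moment / (4.0 * np.pi * sigma * r3)
    return u if np.ndim(points) > 1 else float(u[0])


# ---------------------------------------------------------------------------
# Solid angles (Van Oosterom & Strackee closed form)
# ---------------------------------------------------------------------------

def solid_angles(vertices: np.ndarray, triangles: np.ndarray,
                 observation: np.ndarray) -> np.ndarray:
    """Signed solid angles of each triangle at each observation point.

    Sign follows the triangle winding: a panel of a closed outward
    surface seen from inside subtends a positive angle, and the panels
    sum to 4 pi (inside) or 0 (outside).  Shape (n_obs, n_tri).
    """
    obs = np.atleast_2d(np.asarray(observation, float))
    tri = np.asarray(vertices, float)[np.asarray(triangles, int)]
    out = np.empty((len(obs), len(tri)))
    # chunk over observation points to bound temporary memory
    step = max(1, int(4e6 // max(len(tri), 1)))
    for a in range(0, len(obs), step):
        o = obs[a : a + step]
        r = tri[None, :, :, :] - o[:, None, None, :]   # (o, t, 3 verts, xyz)
        n = np.linalg.norm(r, axis=3)                   # (o, t, 3)
        r1, r2, r3 = r[..., 0, :], r[..., 1, :], r[..., 2, :]
        n1, n2, n3 = n[..., 0], n[..., 1], n[..., 2]
        num = np.einsum("otj,otj->ot", r1, np.cross(r2, r3))
        den = (n1 * n2 * n3
               + np.einsum("otj,otj->ot", r1, r2) * n3
               + np.einsum("otj,otj->ot", r1, r3) * n2
               + np.einsum("otj,otj->ot", r2, r3) * n1)
        out[a : a + step] = 2.0 * np.arctan2(num, den)
    return out if np.ndim(observation) > 1 else out[0]


def solid_angle(triangle: np.ndarray, observation: np.ndarray) -> float:
    """Solid angle of one triangle at one point (singular in-plane inside)."""
    tri = np.asarray(triangle, float)
    obs = np.asarray(observation, float).reshape(3)
    r = tri - obs
    nrm = np.linalg.norm(r, axis=1)
    if np.any(nrm < 1e-300):
        raise ZeroDivisionError("observation point on a triangle vertex")
    num = r[0] @ np.cross(r[1], r[2])
    den = (nrm.prod() + (r[0] @ r[1]) * nrm[2] + (r[0] @ r[2]) * nrm[1]
           + (r[1] @ r[2]) * nrm[0])
    if abs(num) < 1e-300 and den < 0:
        raise ZeroDivisionError(
            "observation point lies in the triangle plane inside the triangle")
    return float(2.0 * np.arctan2(num, den))


# ---------------------------------------------------------------------------
# BEM assembly and forward solution
# ---------------------------------------------------------------------------

def assemble_bem_system(model: ShellModel) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the collocation matrix B of the potential equation U = G + B U.

    Block (k, l) scales the panel-to-panel solid angles by
    (sigma_l^- - sigma_l^+) / (2 pi (sigma_k^- + sigma_k^+)).  Within a
    surface the diagonal (auto) solid angle is fixed by the closed-
    surface identity so that a constant surface potential is reproduced
    exactly, which makes the constant vector the exact null direction of
    (I - B).

    Returns ``(B, centroids)`` with centroids stacked over all shells.
    """
    for s in model.shells:
        s.validate()
    n_per = [s.n_triangles for s in model.shells]
    offs = np.concatenate([[0], np.cumsum(n_per)])
    n_tot = offs[-1]
    centroids = np.vstack([s.centroids for s in model.shells])

    B = np.empty((n_tot, n_tot))
    for l, surf in enumerate(model.shells):
        omega = solid_angles(surf.vertices, surf.triangles, centroids)
        # auto-solid-angle: on surface l itself the panels must close to 2 pi
        blk = slice(offs[l], offs[l + 1])
        sub = omega[blk]
        np.fill_diagonal(sub, 0.0)
        np.fill_diagonal(sub, 2.0 * np.pi - sub.sum(axis=1))
        omega[blk] = sub
        dsig = model.sigma_in(l) - model.sigma_out(l)
        for k in range(model.n_shells):
            coef = dsig / (2.0 * np.pi * (model.sigma_in(k)
                                          + model.sigma_out(k)))
            B[offs[k] : offs[k + 1], blk] = \
                coef * omega[offs[k] : offs[k + 1]]
    return B, centroids


class BemSolver:
    """Factorised BEM forward solver for one head model.

    The singular system (I - B) U = G is deflated by the rank-one term
    (1/N) 1 1^T (the potential is defined up to a constant), factorised
    once, and reused for every dipole.
    """

    def __init__(self, model: ShellModel):
        self.model = model
        B, centroids = assemble_bem_system(model)
        self.centroids_ = centroids
        n = len(B)
        A = np.eye(n) - B + np.full((n, n), 1.0 / n)
        self._lu = lu_factor(A)
        # conductivity sum at the collocation surfaces, panel-wise
        sig = np.concatenate([
            np.full(s.n_triangles, model.sigma_in(k) + model.sigma_out(k))
            for k, s in enumerate(model.shells)
        ])
        self._g_scale = 2.0 * model.sigma_s / sig
        self._outer_slice = slice(
            len(B) - model.outer.n_triangles, len(B))

    # -- source terms --------------------------------------------------------
    def _source_vector(self, dipoles: list[Dipole]) -> np.ndarray:
        g = np.empty((len(self.centroids_), len(dipoles)))
        for j, dip in enumerate(dipoles):
            u_inf = infinite_medium_potential(dip, self.centroids_,
                                              self.model.sigma_s)
            g[:, j] = self._g_scale * u_inf
        return g

    def panel_potentials(self, dipoles: Dipole | list[Dipole]) -> np.ndarray:
        """Potential at every panel centroid, one column per dipole."""
        single = isinstance(dipoles, Dipole)
        dips = [dipoles] if single else list(dipoles)
        for dip in dips:
            self._check_inside(dip)
        U = lu_solve(self._lu, self._source_vector(dips))
        return U[:, 0] if single else U

    def _check_inside(self, dip: Dipole) -> None:
        inner = self.model.inner
        # generalized winding number: ~4 pi inside, ~0 outside
        total = solid_angles(inner.vertices, inner.triangles,
                             dip.position).sum()
        if total < 2.0 * np.pi:
            raise ValueError(
                f"dipole at {dip.position} lies outside the innermost shell")

    # -- electrode mapping ---------------------------------------------------
    def electrode_matrix(self, electrodes: np.ndarray) -> np.ndarray:
        """Interpolation matrix from panel potentials to electrode potentials.

        Panel values are first gathered to mesh vertices by area-weighted
        averaging of the incident panels, then interpolated barycentrically
        inside the outer-shell triangle hit by the radial ray through each
        electrode.  Returns shape (n_electrodes, n_panels_total).
        """
        el = np.atleast_2d(np.asarray(electrodes, float))
        outer = self.model.outer
        n_vert = len(outer.vertices)
        # vertex <- panel area-weighted average
        areas = outer.areas
        A_vp = np.zeros((n_vert, outer.n_triangles))
        for j, tri in enumerate(outer.triangles):
            A_vp[tri, j] += areas[j]
        A_vp /= A_vp.sum(axis=1, keepdims=True)
        # electrode <- vertex barycentric weights
        A_ev = np.zeros((len(el), n_vert))
        verts = outer.vertices[outer.triangles]
        v0, e1, e2 = (verts[:, 0], verts[:, 1] - verts[:, 0],
                      verts[:, 2] - verts[:, 0])
        for i, e in enumerate(el):
            d = e / np.linalg.norm(e)
            p = np.cross(np.broadcast_to(d, e1.shape), e2)
            det = np.einsum("ij,ij->i", e1, p)
            with np.errstate(divide="ignore", invalid="ignore"):
                u = np.einsum("ij,ij->i", -v0, p) / det
                q = np.cross(-v0, e1)
                v = np.einsum("j,ij->i", d, q) / det
                t = np.einsum("ij,ij->i", e2, q) / det
            hit = ((np.abs(det) > 1e-300) & (u >= -1e-9) & (v >= -1e-9)
                   & (u + v <= 1 + 1e-9) & (t > 0))
            idx = np.where(hit)[0]
            if len(idx) == 0:
                raise ValueError(
                    f"electrode {e} does not project onto the outer shell")
            j = idx[np.argmax(t[idx])]
            tri = outer.triangles[j]
            A_ev[i, tri] = (1.0 - u[j] - v[j], u[j], v[j])
        mat = np.zeros((len(el), len(self.centroids_)))
        mat[:, self._outer_slice] = A_ev @ A_vp
        return mat

    def solve_forward(self, dipole: Dipole | list[Dipole],
                      electrodes: np.ndarray) -> np.ndarray:
        """Average-referenced electrode potentials (V) of the dipole(s)."""
        U = self.panel_potentials(dipole)
        u = self.electrode_matrix(electrodes) @ U
        return u - u.mean(axis=0)


def solve_forward(model: ShellModel, dipole: Dipole,
                  electrodes: np.ndarray) -> np.ndarray:
    """One-shot forward solution (assembles the system; prefer BemSolver
    when solving for many dipoles)."""
    return BemSolver(model).solve_forward(dipole, electrodes)


# ---------------------------------------------------------------------------
# Source space and lead field
# ---------------------------------------------------------------------------

@dataclass
class SourceSpace:
    """Cortical source space: fixed-orientation dipoles on a mesh.

    Vertices carry one dipole each, oriented along ``normals`` (the
    outward surface normal, i.e. perpendicular to the cortex surface).
    ``triangles`` give the neighbourhood graph used for the smoothness
    prior and for geodesic distances.
    """

    vertices: np.ndarray
    normals: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.normals = np.asarray(self.normals, float)
        self.triangles = np.asarray(self.triangles, int)

    @property
    def n_sources(self) -> int:
        return len(self.vertices)

    def hemisphere(self, tol: float = 1e-9) -> np.ndarray:
        """Per-vertex hemisphere label: -1 left (x<0), +1 right, 0 midline."""
        x = self.vertices[:, 0]
        return np.where(x < -tol, -1, np.where(x > tol, 1, 0))

    def edges(self) -> np.ndarray:
        """Unique undirected edges of the mesh graph, shape (n_e, 2)."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


def make_spherical_source_space(radius: float,
                                subdivisions: int = 3) -> SourceSpace:
    """Source dipoles on a sphere of ``radius`` with radial orientation.

    A spherical stand-in for a cortical surface; the icosphere vertex
    set is mirror-symmetric about the mid-sagittal plane x = 0, which
    the virtual-electrode pairing relies on.
    """
    mesh = make_icosphere(radius, subdivisions)
    normals = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1,
                                             keepdims=True)
    return SourceSpace(vertices=mesh.vertices, normals=normals,
                       triangles=mesh.triangles)


@dataclass
class LeadField:
    """Gain matrix K: electrode potentials per unit source amplitude.

    Under the fixed-orientation constraint K is (n_electrodes,
    n_sources), in V/(A*m), average-referenced, so u = K J for a source
    amplitude vector J.  ``K_free`` (n_electrodes, 3*n_sources) is the
    free-orientation gain, retained for the unconstrained formulation.
    """

    K: np.ndarray
    electrodes: np.ndarray
    electrode_names: list[str]
    source_space: SourceSpace
    K_free: np.ndarray | None = None


def lead_field(model: ShellModel | BemSolver, source_space: SourceSpace,
               electrodes: np.ndarray,
               electrode_names: list[str] | None = None,
               keep_free: bool = False) -> LeadField:
    """Assemble the lead-field matrix column by column.

    Each fixed-orientation column is the forward solution of a unit
    dipole (1 A*m) along the source normal.  With ``keep_free`` the
    three Cartesian gain columns per source are retained as well; the
    constrained gain is their combination with the normal vector.
    """
    solver = model if isinstance(model, BemSolver) else BemSolver(model)
    el = np.atleast_2d(np.asarray(electrodes, float))
    if electrode_names is None:
        electrode_names = [f"E{i}" for i in range(len(el))]
    axes = np.eye(3)
    dipoles: list[Dipole] = []
    for pos in source_space.vertices:
        for ax in axes:
            dipoles.append(Dipole(position=pos, moment=ax))
    U = solver.panel_potentials(dipoles)          # (n_panels, 3M)
    Kf = solver.electrode_matrix(el) @ U
    Kf = Kf - Kf.mean(axis=0, keepdims=True)       # average reference
    M = source_space.n_sources
    Kf3 = Kf.reshape(len(el), M, 3)
    K = np.einsum("nmj,mj->nm", Kf3, source_space.normals)
    return LeadField(K=K, electrodes=el, electrode_names=list(electrode_names),
                     source_space=source_space,
                     K_free=Kf if keep_free else None)


# ---------------------------------------------------------------------------
# Analytic oracle: dipole in a homogeneous conducting sphere
# ---------------------------------------------------------------------------

def homogeneous_sphere_potential(dipole: Dipole, points: np.ndarray,
                                 radius: float, sigma: float,
                                 n_terms: int = 60) -> np.ndarray:
    """Closed-form surface potential of a dipole inside an insulated
    homogeneous conducting sphere (Legendre series).

    With the dipole at distance f from the centre, moment split into a
    radial part m_r and tangential part m_t, the surface potential is

        u = 1/(4 pi sigma R^2) * sum_n (f/R)^(n-1) *
            [ (2n+1) m_r P_n(cos th)
              + ((2n+1)/n) m_t sin th P_n'(cos th) cos ph ]

    where th is the angle from the dipole axis and ph the azimuth from
    the tangential moment direction.  Independent reference for the BEM
    solution (single-shell, equal conductivities).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    r0 = dipole.position
    f = np.linalg.norm(r0)
    if f >= radius:
        raise ValueError("dipole must be strictly inside the sphere")
    if f < 1e-12:
        zhat = np.array([0.0, 0.0, 1.0])
    else:
        zhat = r0 / f
    m_r = float(dipole.moment @ zhat)
    m_t_vec = dipole.moment - m_r * zhat
    m_t = np.linalg.norm(m_t_vec)
    xhat = (m_t_vec / m_t) if m_t > 1e-15 * (abs(m_r) + m_t + 1e-300) \
        else _any_perpendicular(zhat)
    yhat = np.cross(zhat, xhat)

    rp = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    cos_t = np.clip(rp @ zhat, -1.0, 1.0)
    phi = np.arctan2(rp @ yhat, rp @ xhat)
    sin_t = np.sqrt(1.0 - cos_t**2)

    ns = np.arange(1, n_terms + 1)
    ratio = np.where(ns == 1, 1.0, (f / radius) ** (ns - 1.0))
    u = np.zeros(len(pts))
    for n, rr in zip(ns, ratio):
        pn = eval_legendre(n, cos_t)
        pn1 = -lpmv(1, n, cos_t)   # P_n^1 without the Condon-Shortley phase
        u += rr * ((2 * n + 1) * m_r * pn
                   + ((2 * n + 1) / n) * m_t * pn1 * np.cos(phi))
    u /= 4.0 * np.pi * sigma * radius**2
    return u if np.ndim(points) > 1 else float(u[0])


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0])
    if abs(v @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    p = a - (a @ v) * v
    return p / np.linalg.norm(p)


# ---------------------------------------------------------------------------
# Electrode positions
# ---------------------------------------------------------------------------

def standard_electrode_positions(channel_names: list[str],
                                 scalp_radius: float) -> np.ndarray:
    """10-20 electrode positions projected radially onto a scalp sphere.

    Positions come from the standard 10-20 template montage shipped
    with MNE and are rescaled to ``scalp_radius``.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [c for c in channel_names if c not in pos]
    if missing:
        raise ValueError(f"channels missing from the 10-20 template: {missing}")
    xyz = np.array([pos[c] for c in channel_names])
    return xyz / np.linalg.norm(xyz, axis=1, keepdims=True) * scalp_radius
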