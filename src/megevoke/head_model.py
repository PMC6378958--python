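"""Sensor-anatomy registration and spherical forward models.

Registration goes fiducial alignment (closed-form rigid fit on NAS/LPA/RPA)
→ ICP refinement against the scalp mesh → electrode projection onto the
scalp. Forward fields use analytic sphere models: the Sarvas closed form for
MEG (a current dipole in a spherically symmetric conductor, optionally with
a sphere fitted locally per sensor) and a truncated Legendre series for EEG
in three concentric shells (brain / skull / scalp). The source space is a
triangulated cortical mesh with dipoles at the vertices; the free-orientation
gain has three columns per vertex, contracted with the vertex normals when
the orientation constraint is applied.

Head frame: right-handed, X toward the nasion, Y toward the left
pre-auricular point, Z superior; meters everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import MU0, ChannelInfo, ChannelKind, logger

#: planar gradiometer baseline, meters
GRADIOMETER_BASELINE = 0.0168
#: default brain/skull/scalp conductivities, S/m
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (m), triangles (0-based), unit normals."""

    vertices: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, int)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, float)
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean())

    def compute_vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (outward for a CCW-oriented surface)."""
        v, t = self.vertices, self.triangles
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, t[:, k], fn)
        vn /= np.maximum(np.linalg.norm(vn, axis=1, keepdims=True), 1e-300)
        self.normals = vn
        return vn


def write_mesh_off(mesh: SurfaceMesh, path) -> None:
    """ASCII OFF export (vertices then triangle fans)."""
    lines = ["OFF", f"{mesh.n_vertices} {len(mesh.triangles)} 0"]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_off(path) -> SurfaceMesh:
    tokens = Path(path).read_text().split()
    if tokens[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    ptr = 4
    verts = np.array(tokens[ptr:ptr + 3 * nv], float).reshape(nv, 3)
    ptr += 3 * nv
    tris = []
    for _ in range(nf):
        k = int(tokens[ptr])
        tris.append([int(t) for t in tokens[ptr + 1:ptr + 1 + k]])
        ptr += 1 + k
    return SurfaceMesh(verts, np.array(tris, int))


def icosphere(subdiv: int = 2, radius: float = 1.0, center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Geodesic sphere from subdividing an icosahedron (42/162/642… vertices)."""
    phi = (1 + np.sqrt(5)) / 2
    v = np.array([[-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
                  [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
                  [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]], float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array([[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
                  [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
                  [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
                  [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]], int)
    for _ in range(subdiv):
        midpoint: dict[tuple, int] = {}
        verts = list(v)
        faces = []

        def mid(i, j):
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                midpoint[key] = len(verts)
                verts.append(m)
            return midpoint[key]

        for a, b, c in f:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v, f = np.array(verts), np.array(faces, int)
    verts = v * radius + np.asarray(center, float)
    mesh = SurfaceMesh(verts, f)
    mesh.normals = v.copy()  # radial: unit normals of the unit sphere
    return mesh


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

@dataclass
class Fiducials:
    """NAS/LPA/RPA landmark triplets in the digitizer and anatomy frames."""

    digitizer: np.ndarray  # (3, 3): rows NAS, LPA, RPA
    anatomy: np.ndarray

    def __post_init__(self):
        self.digitizer = np.asarray(self.digitizer, float)
        self.anatomy = np.asarray(self.anatomy, float)
        for pts, frame in ((self.digitizer, "digitizer"), (self.anatomy, "anatomy")):
            if pts.shape != (3, 3):
                raise ValueError(f"{frame} fiducials must be a 3×3 array")
            if np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])) < 1e-12:
                raise ValueError(f"{frame} fiducials are collinear")


@dataclass
class RigidTransform:
    """x ↦ R x + t, with the residual of the fit that produced it."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _kabsch(src: np.ndarray, dst: np.ndarray, weights: np.ndarray | None = None) -> RigidTransform:
    """Closed-form least-squares rigid transform src → dst (SVD, det-corrected)."""
    w = np.ones(len(src)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mu_s = (w[:, None] * src).sum(0)
    mu_d = (w[:, None] * dst).sum(0)
    H = (src - mu_s).T @ (w[:, None] * (dst - mu_d))
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    res = np.sqrt((w * np.linalg.norm(src @ R.T + t - dst, axis=1) ** 2).sum())
    return RigidTransform(R, t, res)


def align_fiducials(fid: Fiducials) -> RigidTransform:
    """Rigid digitizer→anatomy transform from the three landmark pairs."""
    return _kabsch(fid.digitizer, fid.anatomy)


def remove_points_below_nasion(points: np.ndarray, nasion: np.ndarray) -> np.ndarray:
    """Drop digitized head points whose superior (Z) coordinate is below the nasion."""
    points = np.asarray(points, float)
    keep = points[:, 2] >= nasion[2]
    if not keep.any():
        logger.warning("all head points below the nasion; empty point set")
    return points[keep]


def _closest_on_mesh(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Closest point on the triangulated surface for each query point.

    Exact point-to-triangle projection (vertex/edge/face cases), minimized
    over all triangles per point; meshes here are small so brute force is fine.
    """
    v = mesh.vertices
    tri = mesh.triangles
    a, b, c = v[tri[:, 0]], v[tri[:, 1]], v[tri[:, 2]]
    ab, ac = b - a, c - a
    out = np.empty_like(np.asarray(points, float))
    for i, p in enumerate(np.atleast_2d(points)):
        ap = p - a
        d1 = (ab * ap).sum(1)
        d2 = (ac * ap).sum(1)
        bp = p - b
        d3 = (ab * bp).sum(1)
        d4 = (ac * bp).sum(1)
        cp = p - c
        d5 = (ab * cp).sum(1)
        d6 = (ac * cp).sum(1)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = np.maximum(va + vb + vc, 1e-300)
        w1 = np.clip(vb / denom, 0, 1)
        w2 = np.clip(vc / denom, 0, 1)
        cand = a + w1[:, None] * ab + w2[:, None] * ac   # face interior guess
        # region clamps
        vertex_a = (d1 <= 0) & (d2 <= 0)
        vertex_b = (d3 >= 0) & (d4 <= d3)
        vertex_c = (d6 >= 0) & (d5 <= d6)
        edge_ab = (d1 >= 0) & (d3 <= 0) & (d1 * d4 - d3 * d2 <= 0)
        edge_ac = (d2 >= 0) & (d6 <= 0) & (d5 * d2 - d1 * d6 <= 0)
        edge_bc = ((d4 - d3 >= 0) & (d5 - d6 >= 0) & (d3 * d6 - d5 * d4 <= 0))
        t_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1e-300, d1 - d3), 0, 1)
        t_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1e-300, d2 - d6), 0, 1)
        t_bc = np.clip((d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1e-300,
                                            (d4 - d3) + (d5 - d6)), 0, 1)
        cand[edge_ab] = (a + t_ab[:, None] * ab)[edge_ab]
        cand[edge_ac] = (a + t_ac[:, None] * ac)[edge_ac]
        cand[edge_bc] = (b + t_bc[:, None] * (c - b))[edge_bc]
        cand[vertex_a] = a[vertex_a]
        cand[vertex_b] = b[vertex_b]
        cand[vertex_c] = c[vertex_c]
        j = np.argmin(((cand - p) ** 2).sum(1))
        out[i] = cand[j]
    return out


def icp_refine(points: np.ndarray, scalp_mesh: SurfaceMesh,
               init_transform: RigidTransform | None = None,
               max_iter: int = 50, tol: float = 1e-10) -> RigidTransform:
    """Iterative closest point: head-point cloud → scalp surface.

    Alternates closest-point association on the mesh with the closed-form
    rigid update; the mean squared distance is non-increasing by construction
    and iteration stops when its decrease falls below ``tol``.
    """
    points = np.asarray(points, float)
    if len(points) < 10:
        raise ValueError("ICP needs at least 10 head points")
    transform = init_transform or RigidTransform.identity()
    prev_cost = np.inf
    for _ in range(max_iter):
        moved = transform.apply(points)
        targets = _closest_on_mesh(moved, scalp_mesh)
        cost = float(np.mean(np.linalg.norm(moved - targets, axis=1) ** 2))
        if prev_cost - cost < tol:
            break
        prev_cost = cost
        transform = _kabsch(points, targets)
    transform.residual = np.sqrt(prev_cost if np.isfinite(prev_cost) else cost)
    return transform


def project_electrodes_to_scalp(electrodes: np.ndarray, scalp_mesh: SurfaceMesh):
    """Move each electrode to its nearest scalp-surface point; report displacement."""
    electrodes = np.atleast_2d(np.asarray(electrodes, float))
    projected = _closest_on_mesh(electrodes, scalp_mesh)
    displacement = np.linalg.norm(projected - electrodes, axis=1)
    return projected, displacement


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

@dataclass
class SphereModel:
    """Conductor geometry: single sphere (MEG) or nested shells (EEG)."""

    center: np.ndarray
    radius: float
    shell_radii: tuple | None = None       # (r_brain, r_skull, r_scalp), increasing
    conductivities: tuple | None = None    # S/m, per shell

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        if self.shell_radii is not None:
            r = tuple(self.shell_radii)
            if not all(r[i] < r[i + 1] for i in range(len(r) - 1)):
                raise ValueError("shell radii must be strictly increasing")
            if self.conductivities is None or any(c <= 0 for c in self.conductivities):
                raise ValueError("positive conductivity required per shell")


def fit_sphere(points: np.ndarray, weights: np.ndarray | None = None) -> SphereModel:
    """Algebraic least-squares sphere through a point cloud.

    Linearizes |p - c|² = r² into 2p·c + (r² - |c|²) = |p|²; exact for exact
    sphere samples, equal to the algebraic-norm optimum otherwise.
    """
    points = np.asarray(points, float)
    if len(points) < 4:
        raise ValueError("sphere fit needs at least 4 points")
    if np.linalg.matrix_rank(points - points.mean(0)) < 3:
        raise ValueError("points are coplanar; sphere is undetermined")
    A = np.hstack([2 * points, np.ones((len(points), 1))])
    y = (points ** 2).sum(1)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, float))[:, None]
        A, y = A * w, y * w[:, 0]
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return SphereModel(center, radius)


def fit_local_sphere(sensor_pos: np.ndarray, scalp_mesh: SurfaceMesh,
                     kernel_arc_rad: float = 0.1) -> SphereModel:
    """Sphere fitted to scalp vertices near one sensor.

    Vertices are weighted by a Gaussian of arc distance (along the scalp)
    from the scalp point closest to the sensor; kernel width 0.1 rad of arc.
    """
    anchor = _closest_on_mesh(np.asarray(sensor_pos, float)[None], scalp_mesh)[0]
    global_fit = fit_sphere(scalp_mesh.vertices)
    rel = scalp_mesh.vertices - global_fit.center
    rel_a = anchor - global_fit.center
    cosang = (rel @ rel_a) / np.maximum(np.linalg.norm(rel, axis=1)
                                        * np.linalg.norm(rel_a), 1e-300)
    arc = np.arccos(np.clip(cosang, -1, 1))
    w = np.exp(-0.5 * (arc / kernel_arc_rad) ** 2)
    return fit_sphere(scalp_mesh.vertices, weights=w)


# ---------------------------------------------------------------------------
# MEG forward: Sarvas closed form
# ---------------------------------------------------------------------------

def meg_forward_sphere(dipole_pos, dipole_moment, sensor_pos, sensor_orient,
                       sphere: SphereModel) -> float:
    """Magnetic field of a current dipole in a spherical conductor (tesla).

    Sarvas closed form, projected on the sensor orientation. The sphere
    center is the only geometry that matters: radially oriented dipoles
    produce exactly zero external field.
    """
    b = _sarvas_field(np.asarray(dipole_pos, float) - sphere.center,
                      np.asarray(dipole_moment, float),
                      np.asarray(sensor_pos, float) - sphere.center)
    return float(b @ np.asarray(sensor_orient, float))


def _sarvas_field(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """B(r) for dipole q at r0, both relative to the sphere center."""
    a_vec = r - r0
    a = np.linalg.norm(a_vec)
    rn = np.linalg.norm(r)
    if a < 1e-12:
        raise ValueError("sensor coincides with the dipole")
    F = a * (rn * a + rn ** 2 - r0 @ r)
    if abs(F) < 1e-30:
        return np.zeros(3)
    gradF = ((a ** 2 / rn + (a_vec @ r) / a + 2 * a + 2 * rn) * r
             - (a + 2 * rn + (a_vec @ r) / a) * r0)
    qxr0 = np.cross(q, r0)
    return MU0 / (4 * np.pi * F ** 2) * (F * qxr0 - (qxr0 @ r) * gradF)


def meg_forward_gradiometer(dipole_pos, dipole_moment, sensor_pos, sensor_orient,
                            sphere: SphereModel,
                            baseline: float = GRADIOMETER_BASELINE) -> float:
    """Planar gradiometer: field difference across the baseline / baseline (T/m).

    The baseline direction is derived deterministically from the sensor
    orientation (tangential unit vector orthogonal to it).
    """
    o = np.asarray(sensor_orient, float)
    ref = np.array([0.0, 0.0, 1.0]) if abs(o[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    bdir = np.cross(o, ref)
    bdir /= np.linalg.norm(bdir)
    p = np.asarray(sensor_pos, float)
    bp = meg_forward_sphere(dipole_pos, dipole_moment, p + 0.5 * baseline * bdir, o, sphere)
    bm = meg_forward_sphere(dipole_pos, dipole_moment, p - 0.5 * baseline * bdir, o, sphere)
    return (bp - bm) / baseline


# ---------------------------------------------------------------------------
# EEG forward: concentric three-shell Legendre series
# ---------------------------------------------------------------------------

def _legendre_pn_pn1(x: np.ndarray, nmax: int):
    """P_n(x) and the positive-convention P_n^1(x) = (1-x²)^½ dP_n/dx,
    for n = 1..nmax, via stable upward recurrences."""
    x = np.asarray(x, float)
    p = np.empty((nmax + 1,) + x.shape)
    p[0] = 1.0
    p[1] = x
    for n in range(1, nmax):
        p[n + 1] = ((2 * n + 1) * x * p[n] - n * p[n - 1]) / (n + 1)
    s = np.sqrt(np.clip(1 - x ** 2, 0, None))
    p1 = np.empty_like(p)
    p1[0] = 0.0
    p1[1] = s
    # P_{n+1}^1 = ((2n+1) x P_n^1 - (n+1) P_{n-1}^1) / n
    for n in range(1, nmax):
        p1[n + 1] = ((2 * n + 1) * x * p1[n] - (n + 1) * p1[n - 1]) / n
    return p[1:], p1[1:]


_SURFACE_FACTOR_CACHE: dict = {}


def _shell_surface_factors_cached(nmax: int, sphere: SphereModel) -> np.ndarray:
    key = (nmax, tuple(sphere.shell_radii), tuple(sphere.conductivities))
    if key not in _SURFACE_FACTOR_CACHE:
        _SURFACE_FACTOR_CACHE[key] = _shell_surface_factors(nmax, sphere)
    return _SURFACE_FACTOR_CACHE[key]


def _shell_surface_factors(nmax: int, sphere: SphereModel):
    """Per-degree surface coefficients S_n of the multishell solution.

    For each n the potential in shell k is (A_k rⁿ + B_k r^-(n+1)); the
    source contributes a fixed r^-(n+1) term in the innermost region.
    Continuity of V and σ∂V/∂r at the interfaces plus the outer Neumann
    condition give a small linear system; S_n is the surface potential per
    unit source coefficient. Equal conductivities collapse to the
    homogeneous-sphere value (2n+1)/n · R^-(n+1).
    """
    radii = sphere.shell_radii
    sig = sphere.conductivities
    K = len(radii)
    R = radii[-1]
    out = np.empty(nmax)
    for n in range(1, nmax + 1):
        # unknowns: A_1..A_K, B_2..B_K (B_1 = 1, the source term)
        m = np.zeros((2 * K - 1, 2 * K - 1))
        rhs = np.zeros(2 * K - 1)

        def a_col(k):   # index of A_k
            return k
        def b_col(k):   # index of B_k (k >= 1)
            return K + k - 1

        row = 0
        for k in range(K - 1):  # interface between shell k and k+1 at radii[k]
            r = radii[k]
            # potential continuity
            m[row, a_col(k)] += r ** n
            m[row, a_col(k + 1)] -= r ** n
            m[row, b_col(k + 1)] -= r ** -(n + 1)
            if k == 0:
                rhs[row] = -r ** -(n + 1)  # B_1 = 1
            else:
                m[row, b_col(k)] += r ** -(n + 1)
            row += 1
            # radial current continuity
            m[row, a_col(k)] += sig[k] * n * r ** (n - 1)
            m[row, a_col(k + 1)] -= sig[k + 1] * n * r ** (n - 1)
            m[row, b_col(k + 1)] += sig[k + 1] * (n + 1) * r ** -(n + 2)
            if k == 0:
                rhs[row] = sig[0] * (n + 1) * r ** -(n + 2)
            else:
                m[row, b_col(k)] -= sig[k] * (n + 1) * r ** -(n + 2)
            row += 1
        # outer boundary: no radial current
        m[row, a_col(K - 1)] = n * R ** (n - 1)
        if K > 1:
            m[row, b_col(K - 1)] = -(n + 1) * R ** -(n + 2)
        else:
            rhs[row] = (n + 1) * R ** -(n + 2)  # source term (B_1 = 1)
        sol = np.linalg.solve(m, rhs)
        b_outer = sol[b_col(K - 1)] if K > 1 else 1.0
        out[n - 1] = sol[a_col(K - 1)] * R ** n + b_outer * R ** -(n + 1)
    return out


def eeg_forward_spheres(dipole_pos, dipole_moment, electrode_pos,
                        sphere: SphereModel, rel_tol: float = 1e-6,
                        max_terms: int = 200) -> float:
    """Scalp potential (volts) of a dipole in concentric conducting shells.

    Legendre series truncated when the relative term magnitude drops below
    ``rel_tol``; raises if 200 terms do not converge (dipole too close to
    the innermost boundary).
    """
    if sphere.shell_radii is None:
        raise ValueError("EEG forward needs a shell model (radii + conductivities)")
    r0 = np.asarray(dipole_pos, float) - sphere.center
    q = np.asarray(dipole_moment, float)
    re = np.asarray(electrode_pos, float) - sphere.center
    b = np.linalg.norm(r0)
    if b >= sphere.shell_radii[0]:
        raise ValueError("dipole outside the innermost shell")
    terms = _eeg_series_terms(r0, q, re[None, :], sphere, max_terms)
    total = 0.0
    prev = np.inf
    for n, term in enumerate(terms, start=1):
        total += term[0]
        scale = max(abs(total), 1e-300)
        if n > 2 and abs(term[0]) / scale < rel_tol and prev / scale < rel_tol:
            return float(total)
        prev = abs(term[0])
    raise RuntimeError("EEG Legendre series did not converge in "
                       f"{max_terms} terms (dipole eccentricity too high)")


def _eeg_series_terms(r0, q, electrodes, sphere, nmax):
    """Yield the n-th series term for every electrode at once."""
    b = np.linalg.norm(r0)
    sig1 = sphere.conductivities[0]
    S = _shell_surface_factors_cached(nmax, sphere)
    renorm = np.linalg.norm(electrodes, axis=1)
    if b < 1e-12:
        rhat0 = np.array([0.0, 0.0, 1.0])  # degenerate central dipole: any axis
    else:
        rhat0 = r0 / b
    ehat = electrodes / renorm[:, None]
    cosg = ehat @ rhat0
    q_r = q @ rhat0
    tang = q - q_r * rhat0
    # tangential unit direction in the (r0, re) plane, per electrode
    t_e = ehat - cosg[:, None] * rhat0
    sing = np.linalg.norm(t_e, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_e = np.where(sing[:, None] > 1e-12, t_e / np.maximum(sing, 1e-300)[:, None], 0.0)
    q_t = t_e @ tang
    pn, pn1 = _legendre_pn_pn1(cosg, nmax)
    for n in range(1, nmax + 1):
        radial = n * q_r * pn[n - 1]
        tangential = q_t * pn1[n - 1]
        yield (b ** (n - 1) / (4 * np.pi * sig1)) * S[n - 1] * (radial + tangential)


def _eeg_gain_block(verts: np.ndarray, electrodes: np.ndarray,
                    sphere: SphereModel, nmax: int) -> np.ndarray:
    """Vectorized multishell EEG gain: (n_electrodes, n_vertices, 3)."""
    c = sphere.center
    r0 = verts - c                      # (nv, 3)
    re = electrodes - c                 # (ne, 3)
    b = np.linalg.norm(r0, axis=1)      # (nv,)
    rhat0 = np.where(b[:, None] > 1e-12, r0 / np.maximum(b, 1e-300)[:, None],
                     [0.0, 0.0, 1.0])
    ehat = re / np.linalg.norm(re, axis=1, keepdims=True)
    cosg = ehat @ rhat0.T               # (ne, nv)
    t = ehat[:, None, :] - cosg[..., None] * rhat0[None, :, :]
    sing = np.linalg.norm(t, axis=2)
    t = np.where(sing[..., None] > 1e-12, t / np.maximum(sing, 1e-300)[..., None], 0.0)
    sig1 = sphere.conductivities[0]
    S = _shell_surface_factors_cached(nmax, sphere)
    pn, pn1 = _legendre_pn_pn1(cosg, nmax)          # (nmax, ne, nv)
    out = np.zeros((len(electrodes), len(verts), 3))
    for k in range(3):
        q = np.zeros(3)
        q[k] = 1.0
        q_r = rhat0[:, k]                           # (nv,)
        tang = q[None, :] - q_r[:, None] * rhat0    # (nv, 3)
        q_t = np.einsum("evk,vk->ev", t, tang)      # (ne, nv)
        acc = np.zeros((len(electrodes), len(verts)))
        for n in range(1, nmax + 1):
            radial = n * q_r[None, :] * pn[n - 1]
            acc += (b ** (n - 1) * S[n - 1])[None, :] * (radial + q_t * pn1[n - 1])
        out[:, :, k] = acc / (4 * np.pi * sig1)
    return out


def eeg_forward_single_sphere(dipole_pos, dipole_moment, electrode_pos,
                              radius: float, sigma: float, center=(0, 0, 0),
                              nmax: int = 400) -> float:
    """Homogeneous-sphere surface potential by direct series (reference path).

    Independent of the multishell machinery: uses the explicit coefficient
    (2n+1)/n · bⁿ⁻¹/Rⁿ⁺¹ of the homogeneous solution.
    """
    r0 = np.asarray(dipole_pos, float) - np.asarray(center, float)
    q = np.asarray(dipole_moment, float)
    re = np.asarray(electrode_pos, float) - np.asarray(center, float)
    b = np.linalg.norm(r0)
    rhat0 = r0 / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
    ehat = re / np.linalg.norm(re)
    cosg = float(ehat @ rhat0)
    q_r = q @ rhat0
    t_e = ehat - cosg * rhat0
    sing = np.linalg.norm(t_e)
    t_e = t_e / sing if sing > 1e-12 else np.zeros(3)
    q_t = t_e @ (q - q_r * rhat0)
    pn, pn1 = _legendre_pn_pn1(np.array([cosg]), nmax)
    total = 0.0
    ratio = b / radius
    for n in range(1, nmax + 1):
        coeff = (2 * n + 1) / n * ratio ** (n - 1) / radius ** 2
        total += coeff * (n * q_r * pn[n - 1, 0] + q_t * pn1[n - 1, 0])
    return float(total / (4 * np.pi * sigma))


# ---------------------------------------------------------------------------
# gain assembly
# ---------------------------------------------------------------------------

@dataclass
class GainMatrix:
    """Forward operator: sensors × (3·n_vertices) free or sensors × n_vertices."""

    matrix: np.ndarray
    ch_names: list
    source_space: SurfaceMesh
    constrained: bool

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1] if self.constrained else self.matrix.shape[1] // 3


def constrain_gain(free: GainMatrix) -> GainMatrix:
    """Contract the free-orientation gain with the vertex normals."""
    if free.constrained:
        return free
    normals = free.source_space.normals
    nv = free.source_space.n_vertices
    g = free.matrix.reshape(free.matrix.shape[0], nv, 3)
    fixed = np.einsum("cvk,vk->cv", g, normals)
    return GainMatrix(fixed, list(free.ch_names), free.source_space, True)


def assemble_gain(source_space: SurfaceMesh, channels: list[ChannelInfo],
                  meg_sphere: SphereModel | dict | None = None,
                  eeg_sphere: SphereModel | None = None,
                  constrained: bool = True, projectors=(),
                  eeg_nmax: int = 60) -> GainMatrix:
    """Assemble the forward gain for a mixed sensor array.

    ``meg_sphere`` may be one shared sphere or a per-channel-name dict of
    locally fitted spheres. Active projectors (including the EEG average
    reference) are applied to the rows after assembly. Raises when a source
    vertex lies outside its conductor.
    """
    if source_space.normals is None:
        source_space.compute_vertex_normals()
    verts = source_space.vertices
    nv = len(verts)
    use = [c for c in channels if c.kind in (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD,
                                             ChannelKind.EEG) and not c.is_bad]
    # conductor containment check
    offenders = []
    if eeg_sphere is not None:
        d = np.linalg.norm(verts - eeg_sphere.center, axis=1)
        offenders += list(np.flatnonzero(d >= eeg_sphere.shell_radii[0]))
    if isinstance(meg_sphere, SphereModel):
        d = np.linalg.norm(verts - meg_sphere.center, axis=1)
        offenders += list(np.flatnonzero(d >= meg_sphere.radius))
    if offenders:
        raise ValueError(f"source vertices outside the conductor: {sorted(set(offenders))[:10]}")

    G = np.zeros((len(use), 3 * nv))
    eye3 = np.eye(3)
    eeg_rows = [i for i, c in enumerate(use) if c.kind is ChannelKind.EEG]
    if eeg_rows:
        if eeg_sphere is None:
            raise ValueError("EEG channels present but no EEG shell model given")
        elec = np.array([use[i].position for i in eeg_rows])
        block = _eeg_gain_block(verts, elec, eeg_sphere, eeg_nmax)  # (ne, nv, 3)
        G[eeg_rows] = block.reshape(len(eeg_rows), 3 * nv)
    for ci, ch in enumerate(use):
        if ch.kind is ChannelKind.EEG:
            continue
        else:
            sphere = meg_sphere[ch.name] if isinstance(meg_sphere, dict) else meg_sphere
            if sphere is None:
                raise ValueError("MEG channels present but no MEG sphere model given")
            fwd = (meg_forward_gradiometer if ch.kind is ChannelKind.MEG_GRAD
                   else meg_forward_sphere)
            for vi in range(nv):
                for k in range(3):
                    G[ci, 3 * vi + k] = fwd(verts[vi], eye3[k], ch.position,
                                            ch.orientation, sphere)
    if not np.isfinite(G).all():
        raise ValueError("non-finite gain entries")
    names = [c.name for c in use]
    if projectors:
        from .ssp import apply_projectors
        G = apply_projectors(G, projectors, names)
    gain = GainMatrix(G, names, source_space, False)
    return constrain_gain(gain) if constrained else gain
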