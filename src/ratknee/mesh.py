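"""Shared-topology triangle surface meshes and low-level geometry kernels.

Every bone in a cohort is represented as a :class:`SurfaceMesh` built from one
fixed template grid, so that vertex ``i`` corresponds anatomically across all
specimens.  Anatomical landmarks and ligament attachment points are carried as
*marker vertices*: dedicated, unreferenced vertices appended after the surface
grid, which therefore ride along automatically through mirroring, rigid
posing, Procrustes alignment and PCA reconstruction.

Coordinates are millimetres throughout.  The right-side representation has +X
pointing laterally and +Z pointing from femur to tibia.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_REGIONS = ("medial", "lateral", "other")
VALID_BODIES = ("femur", "tibia_fibula", "patella")


class MeshError(ValueError):
    """Raised for topology or invariant violations on a SurfaceMesh."""


@dataclass
class SurfaceMesh:
    """Triangle mesh with per-vertex density and per-face compartment labels.

    Parameters
    ----------
    vertices : (n, 3) float array, mm.
    faces : (m, 3) int array of 0-based vertex indices.
    body : one of ``femur``, ``tibia_fibula``, ``patella``.
    vertex_density : optional (n,) array of equivalent mineral density
        (g/cm^3); finite and non-negative when present.
    face_region : (m,) array of labels in ``{medial, lateral, other}``.
    markers : name -> vertex index for landmark / attachment vertices.
    """

    vertices: np.ndarray
    faces: np.ndarray
    body: str
    vertex_density: np.ndarray | None = None
    face_region: np.ndarray | None = None
    markers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.face_region is None:
            self.face_region = np.full(len(self.faces), "other", dtype=object)
        else:
            self.face_region = np.asarray(self.face_region, dtype=object)
        if self.vertex_density is not None:
            self.vertex_density = np.asarray(self.vertex_density, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.body not in VALID_BODIES:
            raise MeshError(f"unknown body label {self.body!r}")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (m, 3)")
        n = len(self.vertices)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshError("face index out of range")
        if len(self.face_region) != len(self.faces):
            raise MeshError("face_region length mismatch")
        bad = set(np.unique(self.face_region)) - set(VALID_REGIONS)
        if bad:
            raise MeshError(f"unknown face regions {bad}")
        if self.vertex_density is not None:
            d = self.vertex_density
            if d.shape != (n,):
                raise MeshError("vertex_density length mismatch")
            if not np.all(np.isfinite(d)) or np.any(d < 0):
                raise MeshError("vertex_density must be finite and >= 0")
        for name, idx in self.markers.items():
            if not 0 <= idx < n:
                raise MeshError(f"marker {name!r} index out of range")

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def marker_point(self, name: str) -> np.ndarray:
        return self.vertices[self.markers[name]].copy()

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) triangle coordinates."""
        return self.vertices[self.faces]

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        areas = 0.5 * norm
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = np.where(norm[:, None] > 0, cross / np.where(norm == 0, 1, norm)[:, None], 0.0)
        return normals, areas

    def face_areas(self) -> np.ndarray:
        return self.face_normals_areas()[1]

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            body=self.body,
            vertex_density=None if self.vertex_density is None else self.vertex_density.copy(),
            face_region=self.face_region.copy(),
            markers=dict(self.markers),
        )

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        out = self.copy()
        out.vertices = np.asarray(vertices, dtype=float)
        out.validate()
        return out

    def mirrored_x(self) -> "SurfaceMesh":
        """Reflect through the sagittal plane x = 0, flipping face winding."""
        out = self.copy()
        out.vertices[:, 0] *= -1.0
        out.faces = out.faces[:, ::-1].copy()
        return out

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


# ----------------------------------------------------------------------
# rigid transforms
# ----------------------------------------------------------------------

def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)

def rotate_points(points: np.ndarray, axis: np.ndarray, origin: np.ndarray, angle_rad: float) -> np.ndarray:
    R = rotation_matrix(axis, angle_rad)
    origin = np.asarray(origin, dtype=float)
    return (points - origin) @ R.T + origin


# ----------------------------------------------------------------------
# directed ray casting (fixed direction, Moller-Trumbore, vectorised)
# ----------------------------------------------------------------------

def directed_distances(
    mesh: SurfaceMesh,
    origins: np.ndarray,
    direction: np.ndarray,
    face_mask: np.ndarray | None = None,
    eps: float = 1e-12,
) -> np.ndarray:
    """Distance from each origin to the nearest mesh intersection along one ray direction.

    Returns +inf where the ray misses.  All rays share ``direction``; the
    computation is a dense, chunked Moller-Trumbore over (rays x triangles),
    which is fast at the patch sizes used here (hundreds of each).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    tri = mesh.triangles()
    if face_mask is not None:
        tri = tri[np.asarray(face_mask, dtype=bool)]
    if len(tri) == 0 or len(origins) == 0:
        return np.full(len(origins), np.inf)

    # Candidate pruning: bin triangles on the plane orthogonal to the shared
    # ray direction, so each ray only tests triangles overlapping its cell.
    e1b = np.array([1.0, 0.0, 0.0])
    if abs(d @ e1b) > 0.9:
        e1b = np.array([0.0, 1.0, 0.0])
    e1b = e1b - (e1b @ d) * d
    e1b /= np.linalg.norm(e1b)
    e2b = np.cross(d, e1b)
    tri_u = tri @ e1b
    tri_v = tri @ e2b
    u_min, u_max = tri_u.min(axis=1), tri_u.max(axis=1)
    v_min, v_max = tri_v.min(axis=1), tri_v.max(axis=1)
    cell = 1.5 * max(np.median(u_max - u_min), np.median(v_max - v_min), 1e-6)
    u0, v0g = u_min.min(), v_min.min()

    def cells_of(lo, hi, base):
        return np.floor((lo - base) / cell).astype(int), np.floor((hi - base) / cell).astype(int)

    iu_lo, iu_hi = cells_of(u_min, u_max, u0)
    iv_lo, iv_hi = cells_of(v_min, v_max, v0g)
    buckets: dict[tuple[int, int], list[int]] = {}
    for idx in range(len(tri)):
        for iu in range(iu_lo[idx], iu_hi[idx] + 1):
            for iv in range(iv_lo[idx], iv_hi[idx] + 1):
                buckets.setdefault((iu, iv), []).append(idx)

    ray_u = origins @ e1b
    ray_v = origins @ e2b
    ray_iu = np.floor((ray_u - u0) / cell).astype(int)
    ray_iv = np.floor((ray_v - v0g) / cell).astype(int)
    cand_lists = [buckets.get((iu, iv), ()) for iu, iv in zip(ray_iu, ray_iv)]
    max_c = max((len(c) for c in cand_lists), default=0)
    best = np.full(len(origins), np.inf)
    if max_c == 0:
        return best
    cand = np.full((len(origins), max_c), -1, dtype=np.int64)
    for i, c in enumerate(cand_lists):
        cand[i, : len(c)] = c
    valid = cand >= 0
    safe = np.where(valid, cand, 0)

    v0t, e1t, e2t = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2t)
    det = np.einsum("ij,ij->i", e1t, pvec)
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)

    tvec = origins[:, None, :] - v0t[safe]                      # (r, c, 3)
    u = np.einsum("rcj,rcj->rc", tvec, pvec[safe]) * inv_det[safe]
    qvec = np.cross(tvec, e1t[safe])
    v = np.einsum("rcj,j->rc", qvec, d) * inv_det[safe]
    t = np.einsum("rcj,rcj->rc", qvec, e2t[safe]) * inv_det[safe]
    hit = valid & ok[safe] & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > eps)
    t = np.where(hit, t, np.inf)
    return t.min(axis=1)


def concat_meshes(parts: list[SurfaceMesh], body: str) -> SurfaceMesh:
    """Concatenate mesh parts (disjoint patches) into one SurfaceMesh."""
    offsets = np.cumsum([0] + [p.n_vertices for p in parts])
    verts = np.vstack([p.vertices for p in parts])
    faces = np.vstack([p.faces + off for p, off in zip(parts, offsets)])
    region = np.concatenate([p.face_region for p in parts])
    dens = None
    if all(p.vertex_density is not None for p in parts):
        dens = np.concatenate([p.vertex_density for p in parts])
    markers: dict[str, int] = {}
    for p, off in zip(parts, offsets):
        for name, idx in p.markers.items():
            markers[name] = idx + int(off)
    return SurfaceMesh(verts, faces, body, vertex_density=dens, face_region=region, markers=markers)


# ----------------------------------------------------------------------
# parametric grid builders (fixed topology given grid counts)
# ----------------------------------------------------------------------

def grid_faces(nu: int, nv: int) -> np.ndarray:
    """Faces of an (nu+1) x (nv+1) vertex grid, row-major vertex order."""
    idx = np.arange((nu + 1) * (nv + 1)).reshape(nu + 1, nv + 1)
    a, b = idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel()
    c, d = idx[1:, :-1].ravel(), idx[1:, 1:].ravel()
    return np.vstack([np.column_stack([a, b, d]), np.column_stack([a, d, c])])


def spherical_band(
    center: np.ndarray,
    radius: float,
    u_range: tuple[float, float],
    v_max: float,
    nu: int,
    nv: int,
    region: str,
) -> SurfaceMesh:
    """Condylar articular band: zone of a sphere centred on the epicondylar axis.

    ``u`` is the sagittal angle measured from +Z toward +Y (flexion sweep);
    ``v`` is the mediolateral angle toward +/-X.  Because the surface is a
    sphere centred on the X axis, rotation about that axis (flexion) maps the
    surface onto itself, making the 80 deg standing pose geometrically exact.
    """
    u = np.linspace(u_range[0], u_range[1], nu + 1)
    v = np.linspace(-v_max, v_max, nv + 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = center[0] + radius * np.sin(vv)
    y = center[1] + radius * np.cos(vv) * np.sin(uu)
    z = center[2] + radius * np.cos(vv) * np.cos(uu)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    faces = grid_faces(nu, nv)
    reg = np.full(len(faces), region, dtype=object)
    return SurfaceMesh(verts, faces, "femur", face_region=reg)


def plateau_dish(
    center_x: float,
    condyle_radius: float,
    conformity: float,
    standoff: float,
    planform_radius: float,
    n_r: int,
    n_t: int,
    region: str,
) -> SurfaceMesh:
    """Tibial plateau compartment: concave dish conforming to the condylar sphere.

    The dish is the condylar sphere profile offset distally by ``standoff``
    plus a paraboloid mismatch term, so the initial bone-to-bone separation
    along Z is exactly ``standoff + conformity * r^2 / 2`` -- an analytically
    controlled conforming-but-nonconforming contact.
    """
    if planform_radius >= condyle_radius:
        raise MeshError("plateau planform radius must be smaller than condyle radius")
    r = np.linspace(0.0, planform_radius, n_r + 1)[1:]
    t = np.linspace(0.0, 2 * np.pi, n_t, endpoint=False)
    rr, tt = np.meshgrid(r, t, indexing="ij")
    x = center_x + rr * np.cos(tt)
    y = rr * np.sin(tt)
    z = np.sqrt(condyle_radius**2 - rr**2) + standoff + 0.5 * conformity * rr**2
    verts = np.column_stack(
        [
            np.concatenate([[center_x], x.ravel()]),
            np.concatenate([[0.0], y.ravel()]),
            np.concatenate([[condyle_radius + standoff], z.ravel()]),
        ]
    )
    faces = []
    # fan around the apex vertex
    for j in range(n_t):
        faces.append([0, 1 + j, 1 + (j + 1) % n_t])
    # rings
    for i in range(n_r - 1):
        a0 = 1 + i * n_t
        b0 = 1 + (i + 1) * n_t
        for j in range(n_t):
            j1 = (j + 1) % n_t
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    faces = np.asarray(faces, dtype=np.int64)
    reg = np.full(len(faces), region, dtype=object)
    return SurfaceMesh(verts, faces, "tibia_fibula", face_region=reg)


def open_cylinder(
    center_xy: tuple[float, float],
    z_range: tuple[float, float],
    radius: float,
    n_z: int,
    n_c: int,
    body: str,
) -> SurfaceMesh:
    z = np.linspace(z_range[0], z_range[1], n_z + 1)
    t = np.linspace(0.0, 2 * np.pi, n_c, endpoint=False)
    zz, tt = np.meshgrid(z, t, indexing="ij")
    verts = np.column_stack(
        [
            center_xy[0] + radius * np.cos(tt).ravel(),
            center_xy[1] + radius * np.sin(tt).ravel(),
            zz.ravel(),
        ]
    )
    faces = []
    for i in range(n_z):
        a0, b0 = i * n_c, (i + 1) * n_c
        for j in range(n_c):
            j1 = (j + 1) % n_c
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    faces = np.asarray(faces, dtype=np.int64)
    return SurfaceMesh(verts, faces, body)


def uv_ellipsoid(center: np.ndarray, radii: tuple[float, float, float], n_u: int, n_v: int) -> SurfaceMesh:
    """Closed UV-sphere ellipsoid (poles duplicated into degenerate-free fans)."""
    u = np.linspace(0.0, np.pi, n_u + 1)[1:-1]      # polar, poles handled separately
    v = np.linspace(0.0, 2 * np.pi, n_v, endpoint=False)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = center[0] + radii[0] * np.sin(uu) * np.cos(vv)
    y = center[1] + radii[1] * np.sin(uu) * np.sin(vv)
    z = center[2] + radii[2] * np.cos(uu)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    top = np.asarray([center[0], center[1], center[2] + radii[2]])
    bot = np.asarray([center[0], center[1], center[2] - radii[2]])
    verts = np.vstack([verts, top, bot])
    i_top, i_bot = len(verts) - 2, len(verts) - 1
    faces = []
    rows = len(u)
    for i in range(rows - 1):
        a0, b0 = i * n_v, (i + 1) * n_v
        for j in range(n_v):
            j1 = (j + 1) % n_v
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    for j in range(n_v):
        j1 = (j + 1) % n_v
        faces.append([i_top, j1, j])                          # top fan
        faces.append([i_bot, (rows - 1) * n_v + j, (rows - 1) * n_v + j1])
    faces = np.asarray(faces, dtype=np.int64)
    return SurfaceMesh(verts, faces, "patella")
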