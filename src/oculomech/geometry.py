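"""Parametric closed eyeball surface mesh with labelled regions and a
heterogeneous per-element wall thickness.

The globe is an icosphere (subdivided icosahedron) of configurable radius.
Facets are labelled by centroid direction: a corneal cap around the anterior
pole (+z), an elliptical lamina-cribrosa patch at the posterior pole (-z),
and the remaining sclera split into anterior/posterior halves at the
equator.  Coordinates are right-handed, origin at the globe centre,
posterior pole on -z, units mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGIONS",
    "ThicknessMap",
    "EyeGeometryConfig",
    "EyeMesh",
    "build_eye_mesh",
    "build_uniform_sphere",
    "icosphere",
    "check_watertight",
    "euler_characteristic",
    "facet_min_angle",
    "facet_scaled_jacobian",
    "mesh_quality",
    "QualityReport",
    "write_vtk",
    "read_vtk",
    "write_mesh_txt",
    "read_mesh_txt",
]

#: Region code -> name.  Order is part of the file format.
REGIONS = ("cornea", "anterior_sclera", "posterior_sclera", "lamina_cribrosa")
REGION_CODES = {name: i for i, name in enumerate(REGIONS)}


@dataclass(frozen=True)
class ThicknessMap:
    """Per-region wall thickness in mm.

    Sclera varies linearly from ``sclera_anterior`` at the limbus to
    ``sclera_posterior`` at the posterior pole (the peripapillary range
    reported for the bovine globe is 1.55-1.86 mm).  The cornea blends from
    ``cornea_center`` at the apex to ``cornea_edge`` at the limbus —
    bovine corneas thicken toward the periphery.
    """

    cornea_center: float = 0.8
    cornea_edge: float = 1.0
    sclera_anterior: float = 1.0
    sclera_posterior: float = 1.7
    lamina: float = 0.4

    def __post_init__(self) -> None:
        vals = (self.cornea_center, self.cornea_edge, self.sclera_anterior,
                self.sclera_posterior, self.lamina)
        if min(vals) <= 0.0:
            raise ValueError("all thicknesses must be positive")


@dataclass(frozen=True)
class EyeGeometryConfig:
    globe_radius: float = 15.0  # mm
    cornea_half_angle_deg: float = 40.0
    thickness: ThicknessMap = field(default_factory=ThicknessMap)
    lc_axes: tuple[float, float] = (4.60, 3.68)  # full naso-temporal x longitudinal, mm
    refinement_level: int = 4  # icosphere subdivisions

    def __post_init__(self) -> None:
        if self.globe_radius <= 0.0:
            raise ValueError("globe_radius must be positive")
        if not 0.0 <= self.cornea_half_angle_deg < 90.0:
            raise ValueError("cornea_half_angle_deg must be in [0, 90)")
        if min(self.lc_axes) <= 0.0:
            raise ValueError("LC axes must be positive")
        if max(self.lc_axes) / 2.0 >= self.globe_radius:
            raise ValueError("LC semi-axes must be smaller than the globe radius")
        if self.refinement_level < 0:
            raise ValueError("refinement_level must be non-negative")


@dataclass
class EyeMesh:
    """Closed triangulated shell: nodes, facets, per-facet thickness and region."""

    points: np.ndarray  # (N, 3) mm
    faces: np.ndarray  # (M, 3) int, outward-oriented
    thickness: np.ndarray  # (M,) mm
    region: np.ndarray  # (M,) int codes into REGIONS
    outward_normals: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.region = np.asarray(self.region, dtype=np.int64)
        if np.any(self.thickness <= 0.0):
            raise ValueError("per-element thickness must be positive")
        if len(self.thickness) != len(self.faces) or len(self.region) != len(self.faces):
            raise ValueError("thickness and region must be per-facet arrays")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self, points: np.ndarray | None = None) -> np.ndarray:
        """Unnormalized facet normal vectors (2x facet area)."""
        p = self.points if points is None else points
        tri = p[self.faces]
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self, points: np.ndarray | None = None) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(points), axis=1)

    def face_centroids(self, points: np.ndarray | None = None) -> np.ndarray:
        p = self.points if points is None else points
        return p[self.faces].mean(axis=1)

    def region_mask(self, name: str) -> np.ndarray:
        return self.region == REGION_CODES[name]


# --- icosphere --------------------------------------------------------------


def icosphere(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere: `level` midpoint subdivisions of the icosahedron.

    Faces are consistently oriented with outward normals.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts[0])
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
    # enforce outward orientation (centroid test is exact on a sphere)
    normals = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                       verts[faces[:, 2]] - verts[faces[:, 0]])
    centroids = verts[faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centroids) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cache: dict[tuple[int, int], int] = {}
    new_verts = [v for v in verts]

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = verts[i] + verts[j]
            m /= np.linalg.norm(m)
            cache[key] = len(new_verts)
            new_verts.append(m)
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(new_verts), np.array(new_faces, dtype=np.int64)


# --- mesh construction ------------------------------------------------------


def build_eye_mesh(config: EyeGeometryConfig | None = None) -> EyeMesh:
    """Build the labelled heterogeneous-thickness eye shell.

    Raises if the refinement level resolves the LC ellipse with fewer than
    8 facets.
    """
    config = config or EyeGeometryConfig()
    unit_verts, faces = icosphere(config.refinement_level)
    points = config.globe_radius * unit_verts

    centroids = points[faces].mean(axis=1)
    c_norm = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    theta = np.arccos(np.clip(c_norm[:, 2], -1.0, 1.0))  # angle from anterior pole
    theta_c = np.radians(config.cornea_half_angle_deg)

    a = config.lc_axes[0] / 2.0  # naso-temporal semi-axis along x
    b = config.lc_axes[1] / 2.0  # longitudinal semi-axis along y
    proj = config.globe_radius * c_norm
    in_lc = (proj[:, 2] < 0.0) & ((proj[:, 0] / a) ** 2 + (proj[:, 1] / b) ** 2 <= 1.0)

    region = np.full(len(faces), REGION_CODES["anterior_sclera"], dtype=np.int64)
    region[theta > np.pi / 2.0] = REGION_CODES["posterior_sclera"]
    region[theta <= theta_c] = REGION_CODES["cornea"]
    region[in_lc] = REGION_CODES["lamina_cribrosa"]

    n_lc = int(np.sum(region == REGION_CODES["lamina_cribrosa"]))
    if n_lc < 8:
        raise ValueError(
            f"refinement level {config.refinement_level} resolves the LC with "
            f"only {n_lc} facets (need >= 8); increase refinement_level")

    tm = config.thickness
    thickness = np.empty(len(faces))
    is_cornea = region == REGION_CODES["cornea"]
    if theta_c > 0:
        frac = np.clip(theta[is_cornea] / theta_c, 0.0, 1.0)
    else:
        frac = np.zeros(int(is_cornea.sum()))
    thickness[is_cornea] = tm.cornea_center + (tm.cornea_edge - tm.cornea_center) * frac
    is_sclera = (region == REGION_CODES["anterior_sclera"]) | \
                (region == REGION_CODES["posterior_sclera"])
    span = np.pi - theta_c
    s = np.clip((theta[is_sclera] - theta_c) / span, 0.0, 1.0)
    thickness[is_sclera] = tm.sclera_anterior + (tm.sclera_posterior - tm.sclera_anterior) * s
    thickness[region == REGION_CODES["lamina_cribrosa"]] = tm.lamina

    return EyeMesh(points=points, faces=faces, thickness=thickness, region=region)


def build_uniform_sphere(radius: float, thickness: float, level: int = 3,
                         region: str = "posterior_sclera") -> EyeMesh:
    """Uniform single-region sphere, used by the analytic Laplace-law oracle."""
    verts, faces = icosphere(level)
    return EyeMesh(points=radius * verts, faces=faces,
                   thickness=np.full(len(faces), float(thickness)),
                   region=np.full(len(faces), REGION_CODES[region], dtype=np.int64))


# --- topology and quality ---------------------------------------------------


def _edge_counts(faces: np.ndarray) -> tuple[dict, dict]:
    undirected: dict[tuple[int, int], int] = {}
    directed: dict[tuple[int, int], int] = {}
    for f in faces:
        for i in range(3):
            u, v = int(f[i]), int(f[(i + 1) % 3])
            directed[(u, v)] = directed.get((u, v), 0) + 1
            key = (min(u, v), max(u, v))
            undirected[key] = undirected.get(key, 0) + 1
    return undirected, directed


def check_watertight(mesh: EyeMesh) -> bool:
    """True iff every edge is shared by exactly 2 facets with consistent
    orientation (each directed edge used exactly once)."""
    undirected, directed = _edge_counts(mesh.faces)
    return all(c == 2 for c in undirected.values()) and \
        all(c == 1 for c in directed.values())


def euler_characteristic(mesh: EyeMesh) -> int:
    undirected, _ = _edge_counts(mesh.faces)
    return mesh.n_points - len(undirected) + mesh.n_faces


def facet_min_angle(pts: np.ndarray) -> float:
    """Minimum interior angle (degrees) of a 3- or 4-node planar facet."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    angles = []
    for i in range(n):
        e1 = pts[(i - 1) % n] - pts[i]
        e2 = pts[(i + 1) % n] - pts[i]
        denom = np.linalg.norm(e1) * np.linalg.norm(e2)
        if denom == 0.0:
            return 0.0
        c = np.clip(np.dot(e1, e2) / denom, -1.0, 1.0)
        angles.append(np.degrees(np.arccos(c)))
    return float(min(angles))


def facet_scaled_jacobian(pts: np.ndarray) -> float:
    """Scaled Jacobian of a 3- or 4-node facet.

    Per-corner Jacobian = |e1 x e2| / (|e1| |e2|) for the two edges meeting
    at the corner; triangles carry the 2/sqrt(3) normalization so an
    equilateral triangle scores 1, a unit square scores 1, degenerate
    slivers score ~0.
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    vals = []
    for i in range(n):
        e1 = pts[(i + 1) % n] - pts[i]
        e2 = pts[(i - 1) % n] - pts[i]
        denom = np.linalg.norm(e1) * np.linalg.norm(e2)
        if denom == 0.0:
            return 0.0
        vals.append(np.linalg.norm(np.cross(e1, e2)) / denom)
    scale = 2.0 / np.sqrt(3.0) if n == 3 else 1.0
    return float(min(1.0, scale * min(vals)))


@dataclass
class QualityReport:
    scaled_jacobian: np.ndarray
    min_angle_deg: np.ndarray
    jacobian_threshold: float
    angle_threshold_deg: float
    flagged: np.ndarray  # facet indices below either threshold

    @property
    def fraction_passing(self) -> float:
        return 1.0 - len(self.flagged) / len(self.scaled_jacobian)


def mesh_quality(mesh: EyeMesh, jacobian_threshold: float = 0.47,
                 angle_threshold_deg: float = 43.53) -> QualityReport:
    """Per-facet scaled Jacobian and minimum interior angle, with facets
    below the (configurable) thresholds flagged."""
    tri = mesh.points[mesh.faces]
    sj = np.array([facet_scaled_jacobian(t) for t in tri])
    ang = np.array([facet_min_angle(t) for t in tri])
    flagged = np.flatnonzero((sj < jacobian_threshold) | (ang < angle_threshold_deg))
    return QualityReport(scaled_jacobian=sj, min_angle_deg=ang,
                         jacobian_threshold=jacobian_threshold,
                         angle_threshold_deg=angle_threshold_deg,
                         flagged=flagged)


# --- I/O: legacy ASCII VTK and a plain-text node/element format -------------


def write_vtk(path, mesh: EyeMesh, cell_data: dict[str, np.ndarray] | None = None,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    cell_data = dict(cell_data or {})
    cell_data.setdefault("thickness_mm", mesh.thickness)
    cell_data.setdefault("region", mesh.region.astype(float))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\neye shell mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_points} double\n")
        for p in mesh.points:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"CELL_DATA {mesh.n_faces}\n")
        for name, values in cell_data.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in np.asarray(values, dtype=float):
                fh.write(f"{float(v)!r}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_points}\n")
            for name, values in point_data.items():
                values = np.asarray(values, dtype=float)
                if values.ndim == 2 and values.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in values:
                        fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in values:
                        fh.write(f"{float(v)!r}\n")


def read_vtk(path) -> EyeMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    def find(word):
        return tokens.index(word)
    i = find("POINTS")
    n_pts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3: i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i = find("POLYGONS")
    n_faces = int(tokens[i + 1])
    raw = np.array(tokens[i + 3: i + 3 + 4 * n_faces], dtype=np.int64).reshape(n_faces, 4)
    faces = raw[:, 1:]
    cell_data: dict[str, np.ndarray] = {}
    j = 0
    while True:
        try:
            j = tokens.index("SCALARS", j)
        except ValueError:
            break
        name = tokens[j + 1]
        start = tokens.index("default", j) + 1
        cell_data[name] = np.array(tokens[start: start + n_faces], dtype=float)
        j = start
    thickness = cell_data.get("thickness_mm", np.ones(n_faces))
    region = cell_data.get("region", np.zeros(n_faces)).astype(np.int64)
    return EyeMesh(points=pts, faces=faces, thickness=thickness, region=region)


def write_mesh_txt(path, mesh: EyeMesh) -> None:
    """Minimal whitespace node/element format (NODES / ELEMENTS sections)."""
    with open(path, "w") as fh:
        fh.write(f"NODES {mesh.n_points}\n")
        for p in mesh.points:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        fh.write(f"ELEMENTS {mesh.n_faces}\n")
        for f, t, r in zip(mesh.faces, mesh.thickness, mesh.region):
            fh.write(f"{f[0]} {f[1]} {f[2]} {float(t)!r} {REGIONS[r]}\n")


def read_mesh_txt(path) -> EyeMesh:
    with open(path) as fh:
        header = fh.readline().split()
        n_pts = int(header[1])
        pts = np.array([fh.readline().split() for _ in range(n_pts)], dtype=float)
        header = fh.readline().split()
        n_faces = int(header[1])
        faces, thickness, region = [], [], []
        for _ in range(n_faces):
            parts = fh.readline().split()
            faces.append([int(x) for x in parts[:3]])
            thickness.append(float(parts[3]))
            region.append(REGION_CODES[parts[4]])
    return EyeMesh(points=pts, faces=np.array(faces, dtype=np.int64),
                   thickness=np.array(thickness), region=np.array(region, dtype=np.int64))
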