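"""Procedural volume-conductor geometry and triangle-mesh I/O.

Coordinate convention: SI meters, y vertical (uterine fundus at +y), the
maternal front (where the sensor array sits) toward +z.  The myometrium is
represented as its mid-wall surface plus a scalar wall thickness; the
thickness re-enters downstream as a volumetric scaling of source strength.

Default dimensions follow the validation geometry: a spherical uterus of
16 cm outer radius with a 1 cm wall (mid-wall radius 15.5 cm), a 12 cm
fetus, and a 21 cm abdomen whose anterior surface sits 2 cm in front of the
uterus.  A smooth pear-shaped uterus (wider fundus, tapered lower segment)
is available as a synthetic stand-in for an anatomical mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "GeometrySpec",
    "CompartmentModel",
    "make_spherical_uterus",
    "make_pear_uterus",
    "make_abdomen_surface",
    "load_surface_mesh",
    "save_surface_mesh",
]

_TRIMESH_FORMATS = {".off", ".obj", ".stl", ".ply"}


@dataclass
class SurfaceMesh:
    """Triangulated surface with derived normals, areas and diagnostics.

    ``metadata`` carries construction facts downstream code exploits when
    present (e.g. ``sphere_radius`` for exact arc lengths, cap parameters
    for sensor placement); ``thickness`` is the wall thickness in meters for
    shell-type surfaces.
    """

    vertices: np.ndarray
    faces: np.ndarray
    thickness: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) triangles")
        self._tm = trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )
        if np.any(self.element_areas <= 0):
            raise ValueError("mesh contains degenerate (zero-area) triangles")

    # -- derived quantities -------------------------------------------------
    @property
    def trimesh(self) -> trimesh.Trimesh:
        return self._tm

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.faces)

    @property
    def element_normals(self) -> np.ndarray:
        return np.asarray(self._tm.face_normals)

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self._tm.vertex_normals)

    @property
    def element_areas(self) -> np.ndarray:
        return np.asarray(self._tm.area_faces)

    @property
    def element_centroids(self) -> np.ndarray:
        return np.asarray(self._tm.triangles_center)

    @property
    def mean_edge_length(self) -> float:
        return float(self._tm.edges_unique_length.mean())

    @property
    def is_watertight(self) -> bool:
        return bool(self._tm.is_watertight)

    @property
    def euler_characteristic(self) -> int:
        return int(self._tm.euler_number)

    @property
    def area(self) -> float:
        return float(self._tm.area)

    @property
    def enclosed_volume(self) -> float:
        """Signed volume by the divergence theorem (positive if outward)."""
        return float(self._tm.volume)

    def diagnostics(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_elements": self.n_elements,
            "watertight": self.is_watertight,
            "euler_characteristic": self.euler_characteristic,
            "mean_edge_length_m": self.mean_edge_length,
            "area_m2": self.area,
        }


@dataclass(frozen=True)
class GeometrySpec:
    """Dimensions of the four-compartment geometry (meters)."""

    uterus_outer_radius: float = 0.16
    wall_thickness: float = 0.01
    fetus_radius: float = 0.12
    abdomen_radius: float = 0.21
    abdomen_offset: float = 0.02
    subdivisions: int = 5  # icosphere subdivision depth

    def __post_init__(self) -> None:
        inner = self.uterus_outer_radius - self.wall_thickness
        if not (0 < self.fetus_radius < inner):
            raise ValueError("fetus radius must fit inside the uterine wall")
        if self.wall_thickness <= 0 or self.subdivisions < 0:
            raise ValueError("positive wall thickness and subdivisions required")

    @property
    def midwall_radius(self) -> float:
        return self.uterus_outer_radius - 0.5 * self.wall_thickness


@dataclass(frozen=True)
class CompartmentModel:
    """Scalar conductivities of the homogeneous compartments (S/m).

    ``zeta`` is the intra/extracellular anisotropy ratio of the myometrium;
    ``fetal_boundary_factor`` scales flux continuity at the fetal boundary
    (1 = ordinary continuity).
    """

    G_abdomen: float = 0.2
    G_amniotic: float = 1.74
    G_fetus: float = 0.5
    G_air: float = 5e-15
    zeta: float = 0.818
    fetal_boundary_factor: float = 1.0
    wall_thickness: float = 0.01

    def __post_init__(self) -> None:
        for name in ("G_abdomen", "G_amniotic", "G_fetus", "G_air"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _icosphere(radius: float, subdivisions: int) -> trimesh.Trimesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    if len(m.faces) < 100:
        warnings.warn(
            f"sphere mesh has only {len(m.faces)} elements; results will be "
            "coarse",
            stacklevel=3,
        )
    return m


def make_spherical_uterus(spec: GeometrySpec | None = None) -> SurfaceMesh:
    """Mid-wall spherical uterus (default radius 15.5 cm, 1 cm wall)."""
    spec = spec or GeometrySpec()
    m = _icosphere(spec.midwall_radius, spec.subdivisions)
    return SurfaceMesh(
        m.vertices,
        m.faces,
        thickness=spec.wall_thickness,
        metadata={
            "kind": "sphere",
            "sphere_radius": spec.midwall_radius,
            "center": (0.0, 0.0, 0.0),
        },
    )


def make_pear_uterus(
    spec: GeometrySpec | None = None,
    elongation: float = 0.15,
    taper: float = 0.10,
    rng_seed: int | None = None,
    bumpiness: float = 0.0,
) -> SurfaceMesh:
    """Smooth pear-shaped uterus: a sphere with y-dependent radial scaling.

    The radial multiplier ``1 + elongation*cos(theta) - taper*sin(theta/2)``
    (theta = polar angle from +y) widens the fundus and narrows the lower
    segment; both zero reproduce the sphere exactly.  ``bumpiness`` adds a
    seeded smooth random perturbation for roughness studies.
    """
    spec = spec or GeometrySpec()
    m = _icosphere(spec.midwall_radius, spec.subdivisions)
    v = m.vertices.copy()
    r = np.linalg.norm(v, axis=1)
    cos_t = np.clip(v[:, 1] / r, -1.0, 1.0)
    theta = np.arccos(cos_t)
    mult = 1.0 + elongation * cos_t - taper * np.sin(theta / 2.0)
    if bumpiness > 0:
        rng = np.random.default_rng(rng_seed)
        ph = rng.uniform(0, 2 * np.pi, 3)
        az = np.arctan2(v[:, 2], v[:, 0])
        mult = mult + bumpiness * (
            np.sin(2 * az + ph[0]) * np.sin(theta) ** 2
            + 0.5 * np.sin(3 * theta + ph[1])
        )
    if mult.min() <= 0.2:
        raise ValueError("pear parameters collapse the surface")
    mesh = SurfaceMesh(
        v * mult[:, None],
        m.faces,
        thickness=spec.wall_thickness,
        metadata={"kind": "pear", "center": (0.0, 0.0, 0.0)},
    )
    if not mesh.is_watertight or mesh.enclosed_volume <= 0:
        raise ValueError("pear surface is self-intersecting or inverted")
    return mesh


def make_abdomen_surface(
    spec: GeometrySpec | None = None,
    shape: str = "sphere",
    cap_radius: float = 0.30,
    cap_half_angle: float = np.pi / 4,
    cap_rings: int = 24,
) -> SurfaceMesh:
    """Abdominal surface: full sphere or concave sensor-device-like cap.

    Both are positioned so their anterior surface lies ``abdomen_offset``
    (2 cm) in front of the uterus outer surface along +z.  The cap is a
    section of a sphere of curvature radius ``cap_radius`` whose concave
    side faces the body; its normals point toward the uterus.
    """
    spec = spec or GeometrySpec()
    z_front = spec.uterus_outer_radius + spec.abdomen_offset
    if shape == "sphere":
        m = _icosphere(spec.abdomen_radius, spec.subdivisions)
        center = np.array([0.0, 0.0, z_front - spec.abdomen_radius])
        return SurfaceMesh(
            m.vertices + center,
            m.faces,
            metadata={
                "kind": "sphere",
                "sphere_radius": spec.abdomen_radius,
                "center": tuple(center),
                "front_z": z_front,
            },
        )
    if shape != "concave_cap":
        raise ValueError("shape must be 'sphere' or 'concave_cap'")
    # bowl hugging the abdomen: curvature center inside the body, so the
    # concave side faces the patient and the rim wraps around the uterus
    center = np.array([0.0, 0.0, z_front - cap_radius])
    verts = [center + [0.0, 0.0, cap_radius]]
    faces: list[list[int]] = []
    ring_start = [0]
    for i in range(1, cap_rings + 1):
        th = cap_half_angle * i / cap_rings
        n_pts = max(6, int(round(2 * np.pi * i / 1.0)))  # ~6 per ring step
        start = len(verts)
        ring_start.append(start)
        for jj in range(n_pts):
            az = 2 * np.pi * jj / n_pts
            verts.append(
                center
                + cap_radius
                * np.array(
                    [
                        np.sin(th) * np.cos(az),
                        np.sin(th) * np.sin(az),
                        np.cos(th),
                    ]
                )
            )
    verts = np.asarray(verts)
    # stitch consecutive rings with a greedy zigzag triangulation
    for i in range(1, cap_rings + 1):
        a0 = ring_start[i - 1]
        a_n = (ring_start[i] - a0) if i > 1 else 1
        b0 = ring_start[i]
        b_n = (ring_start[i + 1] - b0) if i < cap_rings else len(verts) - b0
        if a_n == 1:  # apex fan
            for jj in range(b_n):
                faces.append([a0, b0 + jj, b0 + (jj + 1) % b_n])
            continue
        ia = ib = 0
        while ia < a_n or ib < b_n:
            frac_a = ia / a_n
            frac_b = ib / b_n
            if ib < b_n and (frac_b <= frac_a or ia >= a_n):
                faces.append(
                    [a0 + ia % a_n, b0 + ib % b_n, b0 + (ib + 1) % b_n]
                )
                ib += 1
            else:
                faces.append(
                    [a0 + ia % a_n, b0 + ib % b_n, a0 + (ia + 1) % a_n]
                )
                ia += 1
    mesh = SurfaceMesh(
        verts,
        np.asarray(faces),
        metadata={
            "kind": "concave_cap",
            "cap_radius": cap_radius,
            "cap_half_angle": cap_half_angle,
            "center": tuple(center),
            "front_z": z_front,
        },
    )
    # orient normals toward the uterus (-z side): flip faces where needed
    if np.median(mesh.element_normals[:, 2]) > 0:
        mesh = SurfaceMesh(
            verts, np.asarray(faces)[:, ::-1], metadata=mesh.metadata
        )
    return mesh


# -- I/O ---------------------------------------------------------------------

def save_surface_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a triangle mesh; format from the extension.

    Supported: OFF, OBJ, STL, PLY (via trimesh) and legacy ASCII VTK
    polydata.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _TRIMESH_FORMATS:
        mesh.trimesh.export(str(path))
    elif ext == ".vtk":
        _write_vtk(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {ext!r}")


def load_surface_mesh(path: str | Path) -> SurfaceMesh:
    """Read a triangle mesh; non-watertight input loads with a warning flag."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext in _TRIMESH_FORMATS:
        tm = trimesh.load(str(path), process=False, force="mesh")
        mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    elif ext == ".vtk":
        mesh = _read_vtk(path)
    else:
        raise ValueError(f"unsupported mesh format {ext!r}")
    mesh.metadata["watertight"] = mesh.is_watertight
    return mesh


def _write_vtk(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nuteromag surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_elements} {4 * mesh.n_elements}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_vtk(path: Path) -> SurfaceMesh:
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    idx = 0
    n_lines = len(lines)

    def fail(msg: str) -> None:
        raise ValueError(f"{path}:{idx + 1}: {msg}")

    while idx < n_lines and not lines[idx].upper().startswith("DATASET"):
        idx += 1
    if idx == n_lines or "POLYDATA" not in lines[idx].upper():
        fail("expected 'DATASET POLYDATA'")
    idx += 1
    while idx < n_lines and not lines[idx].upper().startswith("POINTS"):
        idx += 1
    if idx == n_lines:
        fail("missing POINTS record")
    n_pts = int(lines[idx].split()[1])
    idx += 1
    coords: list[float] = []
    while len(coords) < 3 * n_pts:
        if idx >= n_lines:
            fail("truncated POINTS block")
        coords.extend(float(x) for x in lines[idx].split())
        idx += 1
    verts = np.asarray(coords).reshape(n_pts, 3)
    while idx < n_lines and not lines[idx].upper().startswith("POLYGONS"):
        idx += 1
    if idx == n_lines:
        fail("missing POLYGONS record")
    n_poly = int(lines[idx].split()[1])
    idx += 1
    faces = []
    for _ in range(n_poly):
        if idx >= n_lines:
            fail("truncated POLYGONS block")
        rec = [int(x) for x in lines[idx].split()]
        if rec[0] != 3:
            fail("only triangle polygons are supported")
        faces.append(rec[1:4])
        idx += 1
    return SurfaceMesh(verts, np.asarray(faces))
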