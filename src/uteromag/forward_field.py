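"""Quasi-static magnetic forward computation and gradiometer sampling.

The myometrial source current density is ``J_s = -zeta Ge' grad(v_m)``;
each surface element contributes a current dipole ``Q = J_s * area *
thickness``.  The default forward path evaluates the primary-current field
in an infinite homogeneous medium,

    B(r) = (mu0 / 4 pi) sum_e Q_e x (r - r_e) / |r - r_e|^3,

which is sufficient for the sensor-map sensitivity questions this package
targets; volume (return) currents through the piecewise-homogeneous
compartments can optionally be added via a coarse boundary-element solve of
the interface potentials (:func:`solve_volume_potential`).

Sensors follow the SARA device: 151 hardware gradiometers on a concave
surface, each reporting the field difference between an inner coil on the
device surface and an outer coil displaced 8 cm along the sensor axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from uteromag.geometry import SurfaceMesh

__all__ = [
    "MU0",
    "SourceCurrentField",
    "SensorArray",
    "MMGRecord",
    "source_current_density",
    "magnetic_field",
    "sara_array",
    "ring_sensor_array",
    "gradiometer_readings",
    "normal_component_readings",
    "solve_volume_potential",
    "VolumePotential",
]

MU0 = 4e-7 * math.pi  # T*m/A

#: Default SARA-like ring layout: sensors per concentric ring, totalling 151.
SARA_RING_COUNTS = (1, 6, 12, 18, 24, 30, 60)


@dataclass(frozen=True)
class SourceCurrentField:
    """Per-element source current density and equivalent dipoles."""

    J: np.ndarray          # (n_elements, 3) A/m^2
    Q: np.ndarray          # (n_elements, 3) A*m current dipole moments
    positions: np.ndarray  # (n_elements, 3) element centroids
    exclusion_radius: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.J) == len(self.Q) == len(self.positions)):
            raise ValueError("source arrays must have equal length")
        if not np.all(np.isfinite(self.Q)):
            raise ValueError("non-finite source dipoles")


@dataclass
class SensorArray:
    """Gradiometer array: inner coil positions, axes and a common baseline."""

    positions: np.ndarray     # (n, 3) inner coil positions (m)
    orientations: np.ndarray  # (n, 3) unit sensor axes (outer = inner + b*axis)
    baseline: float = 0.08

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.orientations = np.asarray(self.orientations, float)
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must match in shape")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")

    @property
    def count(self) -> int:
        return len(self.positions)

    @property
    def outer_positions(self) -> np.ndarray:
        return self.positions + self.baseline * self.orientations

    def save(self, path: str | Path) -> None:
        head = "sensor_id,x,y,z,nx,ny,nz,baseline_m"
        rows = np.column_stack(
            [
                np.arange(self.count),
                self.positions,
                self.orientations,
                np.full(self.count, self.baseline),
            ]
        )
        np.savetxt(path, rows, delimiter=",", header=head, comments="",
                   fmt=["%d"] + ["%.9g"] * 7)

    @classmethod
    def load(cls, path: str | Path) -> "SensorArray":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(rows[:, 1:4], rows[:, 4:7], float(rows[0, 7]))


@dataclass
class MMGRecord:
    """Time series of per-sensor readings (Tesla)."""

    times: np.ndarray   # (n_t,)
    data: np.ndarray    # (n_t, n_sensors)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.data = np.asarray(self.data, float)
        if self.data.shape[0] != len(self.times):
            raise ValueError("time axis mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite sensor readings")

    @property
    def sample_rate(self) -> float:
        dt = np.diff(self.times)
        return float(1.0 / dt.mean())

    def save(self, path: str | Path) -> None:
        head = "time_s," + ",".join(
            f"b{i}_T" for i in range(self.data.shape[1])
        )
        np.savetxt(
            path,
            np.column_stack([self.times, self.data]),
            delimiter=",",
            header=head,
            comments="",
        )

    @classmethod
    def load(cls, path: str | Path) -> "MMGRecord":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(rows[:, 0], rows[:, 1:])


def source_current_density(
    v_m: np.ndarray,
    mesh: SurfaceMesh,
    tensors: np.ndarray,
    zeta: float,
    thickness: float | None = None,
) -> SourceCurrentField:
    """Element-wise ``J_s = -zeta Ge' grad(v_m)`` and dipole moments.

    The P1 tangential gradient is exact for fields linear on each triangle;
    dipole moments scale by element area times wall thickness (taken from
    the mesh if not given).
    """
    v_m = np.asarray(v_m, float)
    if len(v_m) != mesh.n_vertices:
        raise ValueError("need one v_m value per vertex")
    thickness = thickness if thickness is not None else (mesh.thickness or 0.01)
    V, F = mesh.vertices, mesh.faces
    n = mesh.element_normals
    opp = [
        V[F[:, 2]] - V[F[:, 1]],
        V[F[:, 0]] - V[F[:, 2]],
        V[F[:, 1]] - V[F[:, 0]],
    ]
    double_area = np.linalg.norm(np.cross(opp[1], opp[2]), axis=1)
    grad = sum(
        v_m[F[:, i], None] * np.cross(n, opp[i]) / double_area[:, None]
        for i in range(3)
    )
    J = -zeta * np.einsum("eij,ej->ei", np.asarray(tensors, float), grad)
    Q = J * (0.5 * double_area * thickness)[:, None]
    return SourceCurrentField(
        J=J,
        Q=Q,
        positions=mesh.element_centroids,
        exclusion_radius=1.5 * mesh.mean_edge_length,
    )


def magnetic_field(
    sources: SourceCurrentField,
    points: np.ndarray,
    check_exclusion: bool = True,
    chunk: int = 4_000_000,
) -> np.ndarray:
    """Primary-current (Biot-Savart dipole) field at ``points`` (Tesla)."""
    points = np.atleast_2d(np.asarray(points, float))
    n_pts, n_src = len(points), len(sources.positions)
    B = np.zeros((n_pts, 3))
    step = max(1, chunk // max(n_src, 1))
    for a in range(0, n_pts, step):
        pts = points[a : a + step]
        d = pts[:, None, :] - sources.positions[None, :, :]
        r = np.linalg.norm(d, axis=2)
        if check_exclusion and np.any(r < sources.exclusion_radius):
            raise ValueError(
                "singular evaluation: a field point lies within the source "
                f"exclusion radius {sources.exclusion_radius:.3g} m"
            )
        cr = np.cross(sources.Q[None, :, :], d)
        B[a : a + step] = (MU0 / (4 * math.pi)) * np.sum(
            cr / np.maximum(r, 1e-300)[:, :, None] ** 3, axis=1
        )
    return B


def ring_sensor_array(
    center: np.ndarray,
    axis: np.ndarray,
    radius: float,
    half_angle: float,
    counts: tuple[int, ...] = SARA_RING_COUNTS,
    baseline: float = 0.08,
    concave: bool = True,
) -> SensorArray:
    """Deterministic ring lattice of sensors on a spherical cap.

    ``center``/``radius`` define the cap's sphere; the cap opens around
    ``-axis`` (for a concave device facing the body along ``axis``).  Ring
    ``i`` sits at polar angle ``half_angle * i / (n_rings - 1)``.  Sensor
    axes point along the local cap normal away from the body.
    """
    center = np.asarray(center, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the cap axis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, seed)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    positions, orientations = [], []
    n_rings = len(counts)
    for i, n_s in enumerate(counts):
        th = half_angle * i / max(n_rings - 1, 1)
        for j in range(n_s):
            az = 2 * np.pi * j / n_s + (0.5 * np.pi * i)  # stagger rings
            radial = (
                math.sin(th) * (math.cos(az) * u + math.sin(az) * w)
                - math.cos(th) * axis
            )
            pos = center + radius * radial
            ori = -radial if concave else radial
            positions.append(pos)
            orientations.append(ori)
    return SensorArray(
        np.asarray(positions), np.asarray(orientations), baseline=baseline
    )


def sara_array(
    abdomen: SurfaceMesh,
    counts: tuple[int, ...] = SARA_RING_COUNTS,
    baseline: float = 0.08,
    aperture_radius: float = 0.18,
) -> SensorArray:
    """151-channel SARA-style array fitted to an abdomen surface.

    For a concave-cap abdomen the sensors tile the cap itself; for a
    spherical abdomen they tile its anterior (+z) cap.  Both layouts span
    the same lateral ``aperture_radius`` so maps recorded over different
    abdomen shapes stay sensor-wise comparable.  Sensor axes point away
    from the body: the outer coil of each gradiometer sits 8 cm behind the
    inner one.
    """
    md = abdomen.metadata
    kind = md.get("kind")
    if kind == "concave_cap":
        half = min(
            math.asin(min(aperture_radius / md["cap_radius"], 1.0)),
            md["cap_half_angle"],
        )
        return ring_sensor_array(
            center=np.asarray(md["center"]),
            axis=np.array([0.0, 0.0, -1.0]),  # bowl opens toward +z
            radius=md["cap_radius"],
            half_angle=half,
            counts=counts,
            baseline=baseline,
            concave=False,
        )
    if kind == "sphere":
        center = np.asarray(md.get("center", (0.0, 0.0, 0.0)))
        half = math.asin(min(aperture_radius / md["sphere_radius"], 0.99))
        return ring_sensor_array(
            center=center,
            axis=np.array([0.0, 0.0, -1.0]),  # cap opens toward +z
            radius=md["sphere_radius"],
            half_angle=half,
            counts=counts,
            baseline=baseline,
            concave=False,
        )
    raise ValueError(
        "abdomen mesh lacks cap/sphere metadata; build it with "
        "make_abdomen_surface or use ring_sensor_array directly"
    )


def gradiometer_readings(field_fn, array: SensorArray, times) -> MMGRecord:
    """Hardware-gradiometer records ``B_i = n.B(inner) - n.B(outer)``.

    ``field_fn(points, t)`` must return the field at the coil positions.
    """
    times = np.atleast_1d(np.asarray(times, float))
    inner, outer = array.positions, array.outer_positions
    data = np.empty((len(times), array.count))
    for i, t in enumerate(times):
        bi = field_fn(inner, t)
        bo = field_fn(outer, t)
        data[i] = np.einsum("sj,sj->s", array.orientations, bi - bo)
    return MMGRecord(times, data)


def normal_component_readings(field_fn, array: SensorArray, times) -> MMGRecord:
    """Axial field at the inner coils only (no baseline subtraction)."""
    times = np.atleast_1d(np.asarray(times, float))
    data = np.empty((len(times), array.count))
    for i, t in enumerate(times):
        data[i] = np.einsum(
            "sj,sj->s", array.orientations, field_fn(array.positions, t)
        )
    return MMGRecord(times, data)


# -- optional volume-conductor correction (boundary elements) ---------------

def _solid_angles(obs: np.ndarray, verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Solid angles (van Oosterom-Strackee) of each triangle from each point.

    Sign is positive when the triangle's outward normal faces away from the
    observation point; the angles of a closed outward-oriented surface sum
    to 4 pi seen from inside and 0 from outside.
    """
    out = np.empty((len(obs), len(faces)))
    tri = verts[faces]  # (n_tri, 3, 3)
    for i, p in enumerate(obs):
        r = tri - p  # (n_tri, 3 verts, 3)
        r1, r2, r3 = r[:, 0], r[:, 1], r[:, 2]
        n1 = np.linalg.norm(r1, axis=1)
        n2 = np.linalg.norm(r2, axis=1)
        n3 = np.linalg.norm(r3, axis=1)
        num = np.einsum("ij,ij->i", r1, np.cross(r2, r3))
        den = (
            n1 * n2 * n3
            + np.einsum("ij,ij->i", r1, r2) * n3
            + np.einsum("ij,ij->i", r1, r3) * n2
            + np.einsum("ij,ij->i", r2, r3) * n1
        )
        out[i] = 2.0 * np.arctan2(num, den)
    return out


@dataclass
class VolumePotential:
    """Interface potentials from the coarse boundary-element solve."""

    surfaces: list            # the interface SurfaceMesh objects
    sigma_in: np.ndarray      # conductivity inside each surface
    sigma_out: np.ndarray     # conductivity outside each surface
    phi: list                 # per-surface centroid potentials (V)
    sources: SourceCurrentField

    def secondary_field(self, points: np.ndarray) -> np.ndarray:
        """Volume-current contribution to B at ``points`` (Tesla)."""
        points = np.atleast_2d(np.asarray(points, float))
        B = np.zeros((len(points), 3))
        for mesh, s_in, s_out, phi in zip(
            self.surfaces, self.sigma_in, self.sigma_out, self.phi
        ):
            w = (s_in - s_out) * phi * mesh.element_areas  # weights per tri
            d = points[:, None, :] - mesh.element_centroids[None, :, :]
            r3 = np.linalg.norm(d, axis=2) ** 3
            cr = np.cross(mesh.element_normals[None, :, :], d)
            B -= (MU0 / (4 * math.pi)) * np.sum(
                (w[None, :, None]) * cr / r3[:, :, None], axis=1
            )
        return B

    def total_field(self, points: np.ndarray) -> np.ndarray:
        return magnetic_field(self.sources, points) + self.secondary_field(points)


def solve_volume_potential(
    sources: SourceCurrentField,
    interfaces: list[tuple[SurfaceMesh, float, float]],
) -> VolumePotential:
    """Interface potentials of the piecewise-homogeneous volume conductor.

    ``interfaces`` lists ``(surface, sigma_inside, sigma_outside)`` for each
    closed compartment boundary (outermost boundary insulating:
    ``sigma_outside ~ 0``).  The potential is expanded as constant per
    triangle and collocated at centroids using the double-layer (solid
    angle) operator; the outer-surface gauge freedom is fixed by mean
    deflation.  Intended for coarse meshes -- the cost is dense in the total
    number of triangles.
    """
    meshes = [it[0] for it in interfaces]
    s_in = np.array([it[1] for it in interfaces], float)
    s_out = np.array([it[2] for it in interfaces], float)
    centroids = [m.element_centroids for m in meshes]
    counts = [m.n_elements for m in meshes]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n_tot = offsets[-1]
    all_obs = np.vstack(centroids)

    # infinite-medium potential numerator g = (1/4pi) sum Q.(r-rq)/|r-rq|^3
    d = all_obs[:, None, :] - sources.positions[None, :, :]
    r3 = np.linalg.norm(d, axis=2) ** 3
    g = np.einsum("qj,pqj->p", sources.Q, d / r3[:, :, None]) / (4 * math.pi)

    A = np.zeros((n_tot, n_tot))
    for kk, mesh in enumerate(meshes):
        om = _solid_angles(all_obs, mesh.vertices, mesh.faces)
        a, b = offsets[kk], offsets[kk + 1]
        # self-surface diagonal via the 2 pi row-sum identity
        rows = slice(a, b)
        block = om[rows, :]
        np.fill_diagonal(block, 0.0)
        np.fill_diagonal(block, 2.0 * math.pi - block.sum(axis=1))
        om[rows, :] = block
        A[:, a:b] -= (s_in[kk] - s_out[kk]) / (4 * math.pi) * om
    for kk in range(len(meshes)):
        a, b = offsets[kk], offsets[kk + 1]
        A[a:b, a:b] += np.eye(counts[kk]) * (s_in[kk] + s_out[kk]) / 2.0
    # gauge deflation (insulated exterior leaves phi defined up to a constant)
    A += np.ones((n_tot, n_tot)) / n_tot * s_in.max()
    phi_all = np.linalg.solve(A, g)
    phi = [phi_all[offsets[i] : offsets[i + 1]] for i in range(len(meshes))]
    return VolumePotential(meshes, s_in, s_out, phi, sources)
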