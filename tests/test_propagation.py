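"""Surface monodomain operator and propagation dynamics."""

import numpy as np
import pytest

from uteromag.cell_dynamics import DEFAULT_CELL, resting_potential
from uteromag.fiber_tissue import build_fiber_field, conductivity_tensors
from uteromag.geometry import GeometrySpec, SurfaceMesh, make_spherical_uterus
from uteromag.propagation import (
    PacemakerSpec,
    RegionIonicConfig,
    TransmembraneSolution,
    assemble_diffusion_operator,
    measure_front_speed,
    pacemaker_current,
    simulate_propagation,
)
from uteromag.scenarios import OUTSIDE_CELL

ZETA, A_M, C_M = 0.518, 575870.0, 0.01


@pytest.fixture(scope="module")
def iso_operator(sphere_fine):
    tensors = np.tile(0.68 * np.eye(3), (sphere_fine.n_elements, 1, 1))
    return assemble_diffusion_operator(
        sphere_fine, tensors, zeta=ZETA, a_m=A_M, c_m=C_M
    )


class TestDiffusionOperator:
    def test_constant_in_kernel(self, iso_operator, sphere_fine):
        v = np.full(sphere_fine.n_vertices, 0.37)
        assert np.abs(iso_operator.apply(v)).max() < 1e-12

    def test_row_sums_vanish(self, iso_operator):
        assert np.abs(np.asarray(iso_operator.K.sum(axis=1))).max() < 1e-12

    def test_spherical_harmonic_eigenvalue(self, iso_operator, sphere_fine):
        """Y_1 ~ y/r has Laplace-Beltrami eigenvalue l(l+1)/r^2 = 2/r^2."""
        r = 0.155
        v = sphere_fine.vertices[:, 1] / r
        D = ZETA / (ZETA + 1) * 0.68 / (A_M * C_M)
        # Rayleigh quotient with the consistent mass matrix
        lam = (v @ (iso_operator.K @ v)) / (v @ (iso_operator.mass @ v))
        assert lam == pytest.approx(2 * D / r**2, rel=0.01)

    def test_non_spd_tensor_rejected(self, sphere_coarse):
        tensors = np.tile(-np.eye(3), (sphere_coarse.n_elements, 1, 1))
        with pytest.raises(ValueError, match="SPD"):
            assemble_diffusion_operator(
                sphere_coarse, tensors, zeta=ZETA, a_m=A_M, c_m=C_M
            )

    def test_zero_flux_conservation(self, iso_operator, sphere_fine, rng):
        """Pure diffusion conserves the mass-weighted integral of v."""
        v = rng.normal(size=sphere_fine.n_vertices)
        total0 = float(np.ones_like(v) @ (iso_operator.mass @ v))
        for _ in range(20):
            v = iso_operator.implicit_step(v, 0.01)
        total = float(np.ones_like(v) @ (iso_operator.mass @ v))
        assert total == pytest.approx(total0, rel=1e-10)


class TestPacemakerCurrent:
    SPEC = PacemakerSpec(center=(0.0, 0.155, 0.0))

    def test_zero_before_onset(self):
        pts = np.array([[0.0, 0.15, 0.0]])
        assert pacemaker_current(pts, -0.5, self.SPEC)[0] == 0.0

    def test_zero_outside_radius(self):
        pts = np.array([[0.0, 0.0, 0.155]])  # ~22 cm from the fundus center
        assert pacemaker_current(pts, 2.0, self.SPEC)[0] == 0.0

    def test_carrier_peak_at_stimulus_end(self):
        pts = np.array([[0.0, 0.15, 0.0]])
        val = pacemaker_current(pts, self.SPEC.duration, self.SPEC)[0]
        assert val == pytest.approx(self.SPEC.amplitude)

    def test_eps1_scaling(self):
        pts = np.array([[0.0, 0.15, 0.0]])
        bare = pacemaker_current(pts, 5.0, self.SPEC, eps1=1.0)[0]
        assert pacemaker_current(pts, 5.0, self.SPEC, eps1=10.0)[0] == bare / 10


class TestSimulation:
    def test_uniform_rest_stays_uniform(self, sphere_coarse, tensors_coarse):
        sol = simulate_propagation(
            sphere_coarse, tensors_coarse.Ge, DEFAULT_CELL, pacemaker=None,
            duration=0.5, dt=1e-3,
        )
        vr = resting_potential(DEFAULT_CELL)
        assert np.abs(sol.v_m[-1] - vr).max() < 1e-9

    def test_two_region_confinement(self, sphere_fine, tensors_coarse):
        """Activation stays inside the excitable zone around the pacemaker."""
        mesh = sphere_fine
        ff = build_fiber_field(mesh, fixed_angle=0.0)
        tensors = conductivity_tensors(ff)
        center = (0.0, 0.15 * np.cos(np.pi / 6), -0.15 * np.sin(np.pi / 6))
        ionic = RegionIonicConfig(
            center=center, inside=DEFAULT_CELL, outside=OUTSIDE_CELL
        )
        sol = simulate_propagation(
            mesh, tensors.Ge, ionic, PacemakerSpec(center=center),
            duration=8.0, dt=1e-3,
        )
        d = np.linalg.norm(mesh.vertices - np.asarray(center), axis=1)
        outside = d >= ionic.inside_radius
        # no threshold crossing anywhere outside the zone
        assert not np.any(np.isfinite(sol.arrival_times[outside]))
        # beyond a diffusive margin the tissue sits at its own rest state
        vr_out = resting_potential(OUTSIDE_CELL)
        far = d >= ionic.inside_radius + 0.02
        assert np.abs(sol.v_m[-1][far] - vr_out).max() < 2e-3
        # while the stimulated patch did activate
        assert np.any(np.isfinite(sol.arrival_times[~outside]))

    def test_divergence_reported_with_context(self, sphere_coarse, tensors_coarse):
        with pytest.raises((FloatingPointError, ValueError)):
            simulate_propagation(
                sphere_coarse, tensors_coarse.Ge, DEFAULT_CELL,
                PacemakerSpec(center=(0.0, 0.155, 0.0), amplitude=1e9),
                duration=0.2, dt=0.1,
            )


class TestFrontSpeed:
    @staticmethod
    def _strip_solution(speed=0.04):
        """Manufactured plane wave on a flat strip, exact arrival times."""
        nx, ny, h = 41, 5, 0.005
        xs, ys = np.meshgrid(np.arange(nx) * h, np.arange(ny) * h)
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
        faces = []
        for j in range(ny - 1):
            for i in range(nx - 1):
                a = j * nx + i
                faces.append([a, a + 1, a + nx])
                faces.append([a + 1, a + nx + 1, a + nx])
        mesh = SurfaceMesh(verts, np.asarray(faces))
        arrival = verts[:, 0] / speed
        n = len(verts)
        return TransmembraneSolution(
            times=np.array([0.0]),
            v_m=np.zeros((1, n)),
            w=np.zeros((1, n)),
            arrival_times=arrival,
            threshold=-0.035,
            mesh=mesh,
        )

    def test_recovers_plane_wave_speed(self):
        sol = self._strip_solution(speed=0.04)
        measured = measure_front_speed(
            sol, np.array([0.02, 0.01, 0.0]), np.array([0.18, 0.01, 0.0])
        )
        assert measured == pytest.approx(0.04, rel=1e-9)

    def test_identical_points_rejected(self):
        sol = self._strip_solution()
        with pytest.raises(ValueError, match="same mesh vertex"):
            measure_front_speed(
                sol, np.array([0.02, 0.01, 0.0]), np.array([0.021, 0.0101, 0.0])
            )

    def test_never_activated_point_rejected(self):
        sol = self._strip_solution()
        sol.arrival_times[-1] = np.nan
        pt = sol.mesh.vertices[-1]
        with pytest.raises(ValueError, match="no arrival"):
            measure_front_speed(sol, np.array([0.0, 0.0, 0.0]), pt)


def _flat_strip(nx=121, ny=21, h=5e-4):
    xs, ys = np.meshgrid(np.arange(nx) * h, np.arange(ny) * h)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces.append([a, a + 1, a + nx])
            faces.append([a + 1, a + nx + 1, a + nx])
    return SurfaceMesh(verts, np.asarray(faces))


class TestDirectionalEffects:
    def test_anisotropy_ratio_on_resolved_strip(self):
        """Front speed tracks sqrt(sigma_l/sigma_t) when fibers rotate.

        A flat 0.5 mm strip fully resolves both front widths, isolating the
        tensor-direction handling from mesh-resolution effects.
        """
        from uteromag.fiber_tissue import FiberField

        mesh = _flat_strip()
        verts = mesh.vertices
        vr = resting_potential(DEFAULT_CELL)
        wr = (DEFAULT_CELL.beta * vr + DEFAULT_CELL.delta) / DEFAULT_CELL.gamma
        v0 = np.full(mesh.n_vertices, vr)
        v0[verts[:, 0] < 3e-3] = -0.01
        w0 = np.full(mesh.n_vertices, wr)

        def front_speed(axis):
            a3 = np.tile(axis, (mesh.n_elements, 1)).astype(float)
            tensors = conductivity_tensors(
                FiberField(alpha=np.zeros(mesh.n_elements), a3=a3)
            )
            sol = simulate_propagation(
                mesh, tensors.Ge, DEFAULT_CELL, None, duration=3.0,
                dt=1e-3, initial=(v0, w0),
            )
            mid = np.abs(verts[:, 1] - 0.005) < 1e-6
            x, arr = verts[mid, 0], sol.arrival_times[mid]
            ia, ib = np.argmin(abs(x - 0.02)), np.argmin(abs(x - 0.05))
            return (x[ib] - x[ia]) / (arr[ib] - arr[ia])

        ratio = front_speed([1.0, 0.0, 0.0]) / front_speed([0.0, 1.0, 0.0])
        assert ratio == pytest.approx(np.sqrt(5.0), rel=0.20)

    def test_isotropic_front_depends_only_on_polar_angle(self):
        """With isotropic tensors a polar pacemaker gives azimuthally
        symmetric arrival times (spread < 2% of the mean)."""
        mesh = make_spherical_uterus(GeometrySpec(subdivisions=5))
        ff = build_fiber_field(mesh, fixed_angle=0.0)
        tensors = conductivity_tensors(ff, transverse_ratio=1.0)
        sol = simulate_propagation(
            mesh, tensors.Ge, DEFAULT_CELL,
            PacemakerSpec(center=(0.0, 0.155, 0.0)), duration=8.0, dt=1e-3,
        )
        V = mesh.vertices
        theta = np.arccos(np.clip(V[:, 1] / 0.155, -1, 1))
        band = np.abs(theta - np.radians(60.0)) < np.radians(4.0)
        arr = sol.arrival_times[band]
        assert np.all(np.isfinite(arr))
        # remove the polar-angle trend, then compare azimuthal sector means
        fit = np.polynomial.polynomial.polyfit(theta[band], arr, 1)
        resid = arr - np.polynomial.polynomial.polyval(theta[band], fit)
        az = np.arctan2(V[band, 2], V[band, 0])
        sector = ((az + np.pi) / (2 * np.pi) * 12).astype(int) % 12
        means = np.array([resid[sector == s].mean() for s in range(12)])
        assert means.std() < 0.02 * arr.mean()
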