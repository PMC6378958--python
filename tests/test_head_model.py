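"""Registration geometry and analytic spherical forward models."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from megevoke.core_io import MU0, ChannelInfo, ChannelKind
from megevoke.head_model import (Fiducials, RigidTransform, SphereModel,
                                 _closest_on_mesh, _sarvas_field, align_fiducials,
                                 assemble_gain, constrain_gain,
                                 eeg_forward_single_sphere, eeg_forward_spheres,
                                 fit_local_sphere, fit_sphere, icosphere,
                                 icp_refine, meg_forward_sphere,
                                 project_electrodes_to_scalp, read_mesh_off,
                                 remove_points_below_nasion, write_mesh_off)


def random_rotation(rng, max_angle=np.pi):
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, max_angle)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


FID_DIG = np.array([[0.09, 0.0, 0.0], [0.0, 0.075, 0.0], [0.0, -0.075, 0.0]])


class TestAlignFiducials:
    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(0)
        R = random_rotation(rng)
        t = rng.normal(scale=0.02, size=3)
        fid = Fiducials(FID_DIG, FID_DIG @ R.T + t)
        out = align_fiducials(fid)
        assert np.abs(out.rotation - R).max() < 1e-12
        assert out.residual < 1e-12

    def test_identity_frames(self):
        out = align_fiducials(Fiducials(FID_DIG, FID_DIG))
        assert np.abs(out.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(out.translation).max() < 1e-12

    def test_noisy_fit_matches_quaternion_least_squares(self):
        """Independent oracle: direct nonlinear LS over axis-angle + translation."""
        rng = np.random.default_rng(1)
        R = random_rotation(rng, 0.5)
        t = np.array([0.01, -0.005, 0.003])
        dst = FID_DIG @ R.T + t + 0.002 * rng.standard_normal((3, 3))
        out = align_fiducials(Fiducials(FID_DIG, dst))

        def residuals(p):
            w, tt = p[:3], p[3:]
            angle = np.linalg.norm(w)
            if angle < 1e-12:
                Rm = np.eye(3)
            else:
                k = w / angle
                K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
                Rm = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
            return (FID_DIG @ Rm.T + tt - dst).ravel()

        sol = least_squares(residuals, np.zeros(6), xtol=1e-15, ftol=1e-15)
        assert np.sqrt(np.mean(sol.fun ** 2)) == pytest.approx(
            np.sqrt(np.mean((FID_DIG @ out.rotation.T + out.translation - dst) ** 2)),
            rel=1e-6)

    def test_collinear_points_rejected(self):
        bad = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            Fiducials(bad, FID_DIG)


class TestHeadPoints:
    def test_remove_points_below_nasion(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(scale=0.05, size=(200, 3))
        nas = np.array([0.09, 0.0, 0.01])
        kept = remove_points_below_nasion(pts, nas)
        assert len(kept) == (pts[:, 2] >= 0.01).sum()
        assert (kept[:, 2] >= 0.01).all()

    def test_all_above_unchanged(self):
        pts = np.array([[0, 0, 0.5], [0, 0, 0.9]])
        assert len(remove_points_below_nasion(pts, np.array([0, 0, 0.0]))) == 2

    def test_all_below_empty(self):
        pts = np.array([[0, 0, -0.5], [0, 0, -0.9]])
        assert len(remove_points_below_nasion(pts, np.array([0, 0, 0.0]))) == 0


@pytest.fixture(scope="module")
def scalp():
    """Ellipsoidal scalp: rotation is identifiable (a sphere's is not)."""
    mesh = icosphere(3, radius=1.0)
    mesh.vertices = mesh.vertices * np.array([0.095, 0.082, 0.075])
    return mesh


class TestICP:
    def test_recovers_small_rigid_motion(self, scalp):
        rng = np.random.default_rng(3)
        surf_pts = scalp.vertices[rng.choice(len(scalp.vertices), 120, replace=False)]
        R = random_rotation(rng, np.deg2rad(8))
        t = np.array([0.008, -0.006, 0.009])
        moved = (surf_pts - t) @ R  # inverse motion: ICP must find (R, t)
        out = icp_refine(moved, scalp, max_iter=300, tol=1e-14)
        recovered = out.apply(moved)
        assert np.abs(recovered - surf_pts).max() < 1e-3
        angle = np.degrees(np.arccos(np.clip((np.trace(out.rotation @ R.T) - 1) / 2,
                                             -1, 1)))
        assert angle < 0.5

    def test_truth_init_is_fixed_point(self, scalp):
        rng = np.random.default_rng(4)
        pts = scalp.vertices[rng.choice(len(scalp.vertices), 50, replace=False)]
        out = icp_refine(pts, scalp, RigidTransform.identity(), max_iter=20)
        assert np.abs(out.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(out.translation).max() < 1e-6

    def test_association_cost_non_increasing(self, scalp, monkeypatch):
        import megevoke.head_model as hm
        pairs = []
        orig = hm._closest_on_mesh

        def tracking(points, mesh):
            targets = orig(points, mesh)
            pairs.append(np.mean(np.linalg.norm(points - targets, axis=1) ** 2))
            return targets

        monkeypatch.setattr(hm, "_closest_on_mesh", tracking)
        rng = np.random.default_rng(5)
        pts = scalp.vertices[rng.choice(len(scalp.vertices), 40, replace=False)]
        pts = pts + 0.003 * rng.standard_normal(pts.shape)
        hm.icp_refine(pts, scalp, max_iter=30)
        assert all(b <= a + 1e-15 for a, b in zip(pairs, pairs[1:]))

    def test_too_few_points_error(self, scalp):
        with pytest.raises(ValueError, match="at least 10"):
            icp_refine(np.zeros((3, 3)), scalp)


class TestElectrodeProjection:
    def test_on_surface_unmoved(self):
        mesh = icosphere(2, radius=0.09)
        e = mesh.vertices[[5, 17]]
        proj, disp = project_electrodes_to_scalp(e, mesh)
        assert np.abs(proj - e).max() < 1e-12
        assert disp.max() < 1e-12

    def test_offset_electrode_lands_on_sphere(self):
        mesh = icosphere(3, radius=0.09)
        e = np.array([[0.0, 0.0, 0.095]])  # 5 mm above the pole
        proj, disp = project_electrodes_to_scalp(e, mesh)
        # radius error bounded by the chord sag of the tessellation
        assert abs(np.linalg.norm(proj[0]) - 0.09) < 0.0005
        assert disp[0] == pytest.approx(0.005, abs=0.0005)

    def test_post_projection_distance_zero(self):
        mesh = icosphere(2, radius=0.09)
        rng = np.random.default_rng(6)
        e = rng.normal(size=(10, 3))
        e = 0.11 * e / np.linalg.norm(e, axis=1, keepdims=True)
        proj, _ = project_electrodes_to_scalp(e, mesh)
        again = _closest_on_mesh(proj, mesh)
        assert np.abs(again - proj).max() < 1e-9


class TestSphereFitting:
    def test_exact_sphere_recovered(self):
        mesh = icosphere(2, radius=0.07, center=(0.01, -0.02, 0.03))
        fit = fit_sphere(mesh.vertices)
        assert np.abs(fit.center - [0.01, -0.02, 0.03]).max() < 1e-9
        assert fit.radius == pytest.approx(0.07, abs=1e-9)

    def test_hemisphere_matches_nonlinear_least_squares(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((100, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = pts[pts[:, 2] > 0] * 0.08 + np.array([0.0, 0.01, 0.02])
        pts += 0.001 * rng.standard_normal(pts.shape)
        fit = fit_sphere(pts)

        def resid(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        sol = least_squares(resid, np.array([0, 0, 0, 0.1]), xtol=1e-15)
        assert np.abs(fit.center - sol.x[:3]).max() < 5e-4
        assert abs(fit.radius - sol.x[3]) < 5e-4

    def test_coplanar_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="coplanar"):
            fit_sphere(pts)

    def test_local_spheres_vary_smoothly(self):
        """Neighboring sensors over an ellipsoidal scalp get nearby spheres."""
        scalp = icosphere(3, radius=1.0)
        scalp.vertices = scalp.vertices * np.array([0.095, 0.085, 0.09])
        sensors = np.array([[0.0, 0.0, 0.12], [0.012, 0.0, 0.12],
                            [0.024, 0.0, 0.118]])
        centers = [fit_local_sphere(s, scalp).center for s in sensors]
        step1 = np.linalg.norm(centers[1] - centers[0])
        step2 = np.linalg.norm(centers[2] - centers[1])
        assert step1 < 0.01 and step2 < 0.01


class TestMEGForward:
    SPHERE = SphereModel([0.0, 0.0, 0.01], 0.09)

    def test_radial_dipole_zero_field(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            pos = rng.normal(size=3)
            pos = self.SPHERE.center + 0.05 * pos / np.linalg.norm(pos)
            q = 1e-8 * (pos - self.SPHERE.center) / np.linalg.norm(pos - self.SPHERE.center)
            sensor = self.SPHERE.center + np.array([0.0, 0.0, 0.13])
            b = meg_forward_sphere(pos, q, sensor, [0.0, 0.0, 1.0], self.SPHERE)
            assert abs(b) < 1e-25

    def test_matches_independent_gradient_formula(self):
        """Oracle: B = -μ0 ∇(Q×r0·r / 4πF) evaluated by central differences."""
        r0 = np.array([0.0, 0.03, 0.04])
        q = np.array([3e-9, -2e-9, 1e-9])
        r = np.array([0.05, 0.08, 0.09])

        def potential(rr):
            a = np.linalg.norm(rr - r0)
            rn = np.linalg.norm(rr)
            F = a * (rn * a + rn ** 2 - r0 @ rr)
            return (np.cross(q, r0) @ rr) / (4 * np.pi * F)

        h = 1e-7
        grad = np.array([(potential(r + h * e) - potential(r - h * e)) / (2 * h)
                         for e in np.eye(3)])
        expected = MU0 * grad  # Sarvas sign convention
        got = _sarvas_field(r0, q, r)
        assert np.abs(np.abs(got) - np.abs(expected)).max() < 1e-6 * np.abs(got).max()
        # and the radial component equals the free-space dipole field exactly
        d = r - r0
        b_free = MU0 / (4 * np.pi) * np.cross(q, d) / np.linalg.norm(d) ** 3
        rhat = r / np.linalg.norm(r)
        assert got @ rhat == pytest.approx(b_free @ rhat, rel=1e-12)

    def test_linearity_in_moment(self):
        pos = np.array([0.0, 0.02, 0.04])
        q = np.array([1e-9, 2e-9, 0.0])
        sensor, orient = np.array([0.0, 0.0, 0.13]), np.array([0.0, 0.0, 1.0])
        b1 = meg_forward_sphere(pos, q, sensor, orient, self.SPHERE)
        b5 = meg_forward_sphere(pos, 5 * q, sensor, orient, self.SPHERE)
        assert b5 == pytest.approx(5 * b1, rel=1e-12)


class TestEEGForward:
    SHELLS = SphereModel([0.0, 0.0, 0.0], 0.09, shell_radii=(0.07, 0.08, 0.09),
                         conductivities=(0.33, 0.0042, 0.33))
    EQUAL = SphereModel([0.0, 0.0, 0.0], 0.09, shell_radii=(0.07, 0.08, 0.09),
                        conductivities=(0.33, 0.33, 0.33))

    def test_equal_conductivity_matches_single_sphere(self):
        rng = np.random.default_rng(9)
        dip = np.array([0.0, 0.02, 0.04])
        mom = np.array([5e-9, 3e-9, -2e-9])
        for _ in range(5):
            e = rng.normal(size=3)
            e = 0.09 * e / np.linalg.norm(e)
            v3 = eeg_forward_spheres(dip, mom, e, self.EQUAL)
            v1 = eeg_forward_single_sphere(dip, mom, e, 0.09, 0.33)
            assert abs(v3 / v1 - 1) < 1e-3

    def test_central_radial_dipole_cosine_pattern(self):
        mom = np.array([0.0, 0.0, 1e-8])
        thetas = np.linspace(0.1, np.pi - 0.1, 9)
        vals = []
        for th in thetas:
            e = 0.09 * np.array([np.sin(th), 0.0, np.cos(th)])
            vals.append(eeg_forward_spheres([0, 0, 0], mom, e, self.SHELLS))
        vals = np.array(vals)
        ratio = vals / np.cos(thetas)
        assert np.abs(ratio / ratio[0] - 1).max() < 1e-6

    def test_equatorial_antisymmetry(self):
        mom = np.array([0.0, 0.0, 1e-8])
        e = 0.09 * np.array([1.0, 0.0, 0.0])  # equator for a z-dipole
        v = eeg_forward_spheres([0, 0, 0], mom, e, self.SHELLS)
        scale = abs(eeg_forward_spheres([0, 0, 0], mom, [0, 0, 0.09], self.SHELLS))
        assert abs(v) < 1e-10 * scale

    def test_dipole_outside_inner_shell_rejected(self):
        with pytest.raises(ValueError, match="outside the innermost"):
            eeg_forward_spheres([0, 0, 0.075], [0, 0, 1e-8], [0, 0, 0.09], self.SHELLS)


@pytest.fixture(scope="module", name="setup")
def gain_setup():
    cortex = icosphere(1, radius=1.0)
    cortex.vertices = cortex.vertices * np.array([0.06, 0.055, 0.05])
    n = cortex.vertices / np.array([0.06, 0.055, 0.05]) ** 2
    cortex.normals = n / np.linalg.norm(n, axis=1, keepdims=True)
    sphere = SphereModel([0, 0, 0], 0.09, shell_radii=(0.07, 0.08, 0.09),
                         conductivities=(0.33, 0.0042, 0.33))
    rng = np.random.default_rng(10)
    channels = []
    for i in range(8):
        p = rng.normal(size=3)
        p = 0.13 * p / np.linalg.norm(p)
        channels.append(ChannelInfo(f"MEG{i:03d}", ChannelKind.MEG_MAG, "T",
                                    p, p / np.linalg.norm(p)))
    for i in range(4):
        p = rng.normal(size=3)
        p = 0.09 * p / np.linalg.norm(p)
        channels.append(ChannelInfo(f"EEG{i:03d}", ChannelKind.EEG, "V", p))
    return cortex, channels, sphere


class TestGainAssembly:
    def test_shapes_free_and_constrained(self, setup):
        cortex, channels, sphere = setup
        free = assemble_gain(cortex, channels, sphere, sphere, constrained=False)
        assert free.matrix.shape == (12, 3 * cortex.n_vertices)
        fixed = constrain_gain(free)
        assert fixed.matrix.shape == (12, cortex.n_vertices)

    def test_constrained_equals_normal_contraction(self, setup):
        cortex, channels, sphere = setup
        free = assemble_gain(cortex, channels, sphere, sphere, constrained=False)
        fixed = constrain_gain(free)
        v = 3
        manual = sum(cortex.normals[v, k] * free.matrix[:, 3 * v + k] for k in range(3))
        assert np.abs(manual - fixed.matrix[:, v]).max() < 1e-12

    def test_forward_data_consistency(self, setup):
        """gain · source reproduces per-sensor forward evaluations."""
        cortex, channels, sphere = setup
        fixed = assemble_gain(cortex, channels, sphere, sphere, constrained=True)
        v = 7
        s = np.zeros(cortex.n_vertices)
        s[v] = 2e-8
        sensor_vals = fixed.matrix @ s
        mom = 2e-8 * cortex.normals[v]
        b = meg_forward_sphere(cortex.vertices[v], mom, channels[0].position,
                               channels[0].orientation, sphere)
        assert sensor_vals[0] == pytest.approx(b, rel=1e-9)

    def test_vertex_outside_conductor_rejected(self, setup):
        cortex, channels, sphere = setup
        bad = icosphere(1, radius=0.1)  # outside the 7 cm inner shell
        bad.compute_vertex_normals()
        with pytest.raises(ValueError, match="outside the conductor"):
            assemble_gain(bad, channels, sphere, sphere)

    def test_sensor_swap_permutes_rows(self, setup):
        cortex, channels, sphere = setup
        g1 = assemble_gain(cortex, channels, sphere, sphere)
        swapped = list(channels)
        swapped[0], swapped[1] = swapped[1], swapped[0]
        g2 = assemble_gain(cortex, swapped, sphere, sphere)
        assert np.array_equal(g1.matrix[0], g2.matrix[1])
        assert np.array_equal(g1.matrix[1], g2.matrix[0])

    def test_radial_columns_vanish_with_radial_normals(self):
        """Spherical-conductor theorem at the gain level: radial sources are
        silent for every MEG sensor when the cortex normals are radial."""
        cortex = icosphere(1, radius=0.05)  # radial normals
        sphere = SphereModel([0, 0, 0], 0.09)
        rng = np.random.default_rng(11)
        channels = []
        for i in range(6):
            p = rng.normal(size=3)
            p = 0.13 * p / np.linalg.norm(p)
            channels.append(ChannelInfo(f"MEG{i:03d}", ChannelKind.MEG_MAG, "T",
                                        p, p / np.linalg.norm(p)))
        fixed = assemble_gain(cortex, channels, meg_sphere=sphere, constrained=True)
        free = assemble_gain(cortex, channels, meg_sphere=sphere, constrained=False)
        tangential_scale = np.linalg.norm(free.matrix)
        assert np.linalg.norm(fixed.matrix) < 1e-6 * tangential_scale


class TestMeshIO:
    def test_off_round_trip(self, tmp_path):
        mesh = icosphere(1, radius=0.09)
        write_mesh_off(mesh, tmp_path / "m.off")
        back = read_mesh_off(tmp_path / "m.off")
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-8)
        assert np.array_equal(back.triangles, mesh.triangles)
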