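import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from cardioriis import fem
from cardioriis.motion import (ExtensionOperator, MovingDomain, ale_velocities,
                               interp_displacement)


@pytest.fixture(scope="module")
def domain(coarse_mesh, coarse_motion):
    _, frames, times = coarse_motion
    return MovingDomain(mesh=coarse_mesh, frame_disp_m=frames * 1e-3,
                        frame_times=times, dt=2e-3)


class TestTimeInterpolation:
    def test_passes_through_frames(self, domain, coarse_motion):
        _, frames, times = coarse_motion
        for i, t in enumerate(times):
            d = domain.boundary_displacement(float(t))
            assert np.allclose(d, frames[i][domain.wall] * 1e-3, atol=1e-15)

    def test_cubic_reproduction(self):
        t = np.linspace(0, 1, 6)
        poly = lambda x: 2 + x - 3 * x**2 + 0.5 * x**3
        vals = poly(t)[:, None, None] * np.ones((6, 4, 3))
        sp = CubicSpline(t, vals, axis=0, bc_type="not-a-knot")
        for tq in [0.17, 0.43, 0.77]:
            out = interp_displacement(sp, tq, 1.0)
            assert np.allclose(out, poly(tq), atol=1e-12)

    def test_zero_frames_zero_everywhere(self):
        t = np.linspace(0, 1, 6)
        sp = CubicSpline(t, np.zeros((6, 5, 3)), axis=0)
        assert np.all(interp_displacement(sp, 0.5, 1.0) == 0.0)

    def test_out_of_window_rejected(self, domain):
        with pytest.raises(ValueError):
            domain.boundary_displacement(domain.t_end + 0.05)


class TestElasticExtension:
    def test_zero_data_zero_field(self, domain):
        d = domain.extend_harmonic(np.zeros((len(domain.wall), 3)))
        assert np.abs(d).max() == 0.0

    def test_atrial_outlet_fixed_exactly(self, domain):
        rng = np.random.default_rng(0)
        d = domain.extend_harmonic(1e-3 * rng.normal(size=(len(domain.wall), 3)))
        assert np.abs(d[domain.sigma1]).max() == 0.0

    def test_residual_below_tolerance(self, domain):
        rng = np.random.default_rng(1)
        wall_d = 1e-3 * rng.normal(size=(len(domain.wall), 3))
        d = domain.extend_harmonic(wall_d)
        assert domain._ext.residual(d) < 1e-10

    def test_matches_dense_direct_solve(self):
        # small mesh: sparse factorized solve vs plain dense linear algebra
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 3))
        from scipy.spatial import Delaunay

        tets = Delaunay(pts).simplices
        sv = fem.tet_volumes(pts, tets)
        tets[sv < 0] = tets[sv < 0][:, [0, 1, 3, 2]]
        bfaces, _ = fem.boundary_faces(tets)
        bnodes = np.unique(bfaces)
        pinned = bnodes[:3]
        presc = np.setdiff1d(bnodes, pinned)
        ext = ExtensionOperator(pts, tets, prescribed=presc, pinned=pinned)
        data = rng.normal(size=(len(presc), 3))
        d = ext.extend(data)

        n = len(pts)
        K = fem.elasticity_matrix(pts, tets, 0.4, 0.4).toarray()
        fixed = np.zeros(n, bool)
        fixed[presc] = True
        fixed[pinned] = True
        dof_fix = np.concatenate([np.where(fixed)[0] + k * n for k in range(3)])
        dof_free = np.concatenate([np.where(~fixed)[0] + k * n for k in range(3)])
        x = np.zeros(3 * n)
        full = np.zeros((n, 3))
        full[presc] = data
        for k in range(3):
            x[k * n : (k + 1) * n] = full[:, k]
        sol = np.linalg.solve(K[np.ix_(dof_free, dof_free)],
                              -K[np.ix_(dof_free, dof_fix)] @ x[dof_fix])
        x[dof_free] = sol
        dense = x.reshape(3, n).T
        assert np.abs(d - dense).max() < 1e-8 * max(np.abs(dense).max(), 1e-30)

    def test_nonfinite_data_rejected(self, domain):
        bad = np.full((len(domain.wall), 3), np.nan)
        with pytest.raises(ValueError):
            domain.extend_harmonic(bad)


class TestAleVelocities:
    def test_equal_displacements_zero(self):
        d = np.random.default_rng(0).normal(size=(10, 3))
        u, uw = ale_velocities(d, d, d[:4], d[:4], 1e-3)
        assert np.all(u == 0) and np.all(uw == 0)

    def test_linear_in_time_exact(self):
        c = np.array([1.0, -2.0, 0.5])
        d0 = 0.3 * c * np.ones((5, 3))
        d1 = 0.4 * c * np.ones((5, 3))
        u, _ = ale_velocities(d1, d0, d1, d0, 0.1)
        assert np.allclose(u, c, atol=1e-12)

    def test_matches_extended_precision_quotient(self):
        rng = np.random.default_rng(3)
        d0 = rng.normal(size=(20, 3))
        d1 = rng.normal(size=(20, 3))
        dt = 2.5e-4
        u, _ = ale_velocities(d1, d0, d1, d0, dt)
        oracle = ((d1.astype(np.longdouble) - d0.astype(np.longdouble)) / dt)
        assert np.abs(u - oracle.astype(float)).max() < 1e-9 * np.abs(oracle).max()

    def test_nonpositive_dt_rejected(self):
        z = np.zeros((2, 3))
        with pytest.raises(ValueError):
            ale_velocities(z, z, z, z, 0.0)


class TestGeometricConservation:
    def test_volume_rate_matches_wall_flux(self, domain, coarse_mesh):
        t0, dt = 0.10, 2e-3
        d0 = domain.displacement_at(t0)
        d1 = domain.displacement_at(t0 + dt)
        u = (d1 - d0) / dt
        nodes1 = domain.moved_nodes(d1)
        areas, normals = fem.face_areas_normals(nodes1, coarse_mesh.bfaces)
        uf = u[coarse_mesh.bfaces].mean(axis=1)
        flux = (np.einsum("fi,fi->f", uf, normals) * areas).sum()
        v0 = fem.mesh_volume_from_surface(domain.moved_nodes(d0),
                                          coarse_mesh.bfaces)
        v1 = fem.mesh_volume_from_surface(nodes1, coarse_mesh.bfaces)
        rate = (v1 - v0) / dt
        assert flux == pytest.approx(rate, rel=0.02)

    def test_mesh_stays_valid(self, domain, coarse_mesh):
        for t in np.linspace(0, domain.t_end, 9):
            assert domain.min_cell_volume(domain.displacement_at(float(t))) > 0
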