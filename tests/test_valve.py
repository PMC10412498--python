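import numpy as np
import pytest

from cardioriis.phantom import PhantomSpec, generate_valve_traces
from cardioriis.valve import (ImmersedValve, ValvePointCloud,
                              aortic_valve_templates, assemble_point_cloud,
                              attach_to_wall, build_surface, distance_and_delta,
                              fit_rings, make_scenario_valves, smoothed_delta,
                              ValveSurface)
from tests.conftest import COARSE


class TestAssemble:
    def test_row_count(self, healthy_traces):
        cloud = assemble_point_cloud(healthy_traces)
        assert cloud.raw.shape == (1152, 3)
        assert cloud.rings.shape == (32, 36, 3)

    def test_plane_permutation_normalized(self, healthy_traces):
        import copy

        perm = np.random.default_rng(0).permutation(18)
        tr2 = copy.deepcopy(healthy_traces)
        tr2.plane_azimuths_deg = tr2.plane_azimuths_deg[perm]
        tr2.anterior = tr2.anterior[perm]
        tr2.posterior = tr2.posterior[perm]
        c1 = assemble_point_cloud(healthy_traces)
        c2 = assemble_point_cloud(tr2)
        assert np.array_equal(c1.raw, c2.raw)

    def test_healthy_margin_ring_duplicated(self, healthy_traces):
        cloud = assemble_point_cloud(healthy_traces)
        ring = cloud.rings[-1]
        uniq = np.unique(np.round(ring, 9), axis=0)
        assert len(uniq) == 18  # every margin point appears twice

    def test_wrong_counts_fail(self, healthy_traces):
        with pytest.raises(ValueError):
            ValvePointCloud(raw=np.zeros((100, 3)),
                            profile_azimuths_deg=np.zeros(36))


class TestFitRings:
    def test_resampled_matrix_size(self, healthy_traces):
        cloud = fit_rings(assemble_point_cloud(healthy_traces))
        assert cloud.resampled_matrix.shape == (32000, 3)

    def test_circle_recovery(self):
        th = np.deg2rad(10.0 * np.arange(36))
        r = 5.0
        ring = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(36)])
        from cardioriis.valve import _fit_one_ring

        res, _ = _fit_one_ring(ring, 0.0)
        err = np.abs(np.linalg.norm(res[:, :2], axis=1) - r).max()
        assert err < 1e-3 * r

    def test_zero_smoothing_interpolates(self, noiseless_traces):
        cloud = fit_rings(assemble_point_cloud(noiseless_traces), smoothing=0.0)
        assert np.allclose(cloud.ring_grid, cloud.rings, atol=1e-8)

    def test_rotation_translation_equivariance(self, noiseless_traces):
        from scipy.spatial.transform import Rotation

        cloud = assemble_point_cloud(noiseless_traces)
        R = Rotation.from_euler("xyz", [0.3, -0.5, 1.1]).as_matrix()
        t = np.array([3.0, -2.0, 7.0])
        assert cloud.noise_sigma_mm == 0.0  # interpolation limit
        moved = ValvePointCloud(
            raw=cloud.raw @ R.T + t,
            profile_azimuths_deg=cloud.profile_azimuths_deg.copy(),
            noise_sigma_mm=cloud.noise_sigma_mm,
        )
        a = fit_rings(cloud).resampled
        b = fit_rings(moved).resampled
        rel = np.abs(b - (a @ R.T + t)).max() / np.abs(a).max()
        assert rel < 1e-9

    def test_degenerate_ring_fails(self):
        bad = np.zeros((1152, 3))
        bad[:, 0] = np.tile(np.linspace(0, 1, 36), 32)  # collinear rings
        cloud = ValvePointCloud(raw=bad.reshape(36, 32, 3).transpose(1, 0, 2)
                                .transpose(1, 0, 2).reshape(-1, 3),
                                profile_azimuths_deg=10.0 * np.arange(36))
        with pytest.raises(ValueError, match="degenerate"):
            fit_rings(cloud)


class TestSurface:
    def test_hemisphere_area(self, hemisphere_cloud):
        cloud, r = hemisphere_cloud
        surf = build_surface(cloud, target_edge_mm=1.5)
        assert surf.area() == pytest.approx(2 * np.pi * r**2, rel=0.02)
        assert surf.edge_length_cv() < 0.3

    def test_remesh_refinement_converges_area(self, hemisphere_cloud):
        cloud, _ = hemisphere_cloud
        a1 = build_surface(cloud, target_edge_mm=0.9).area()
        a2 = build_surface(cloud, target_edge_mm=0.45).area()
        assert abs(a2 - a1) / a1 < 0.005

    def test_structured_topology_is_annulus(self, hemisphere_cloud):
        cloud, _ = hemisphere_cloud
        surf = build_surface(cloud, target_edge_mm=1.5, remesh=False)
        V = len(surf.vertices)
        F = len(surf.faces)
        e = np.vstack([surf.faces[:, [0, 1]], surf.faces[:, [1, 2]],
                       surf.faces[:, [2, 0]]])
        E = len(np.unique(np.sort(e, axis=1), axis=0))
        assert V - E + F == 0  # cylinder-like (two boundary loops)

    def test_valve_surface_uniform_edges(self, noiseless_traces):
        cloud = fit_rings(assemble_point_cloud(noiseless_traces))
        surf = build_surface(cloud, target_edge_mm=2.0)
        assert surf.edge_length_cv() < 0.3


class TestAttach:
    @staticmethod
    def flat_valve_and_wall(gap_fn):
        # a small disk "valve" hovering above a triangulated plane "wall"
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        rings = np.stack(
            [
                np.column_stack(
                    [rr * np.cos(th), rr * np.sin(th), np.zeros_like(th)]
                )
                for rr in np.linspace(5.0, 1.0, 6)
            ]
        )
        surf = ValveSurface.from_grid(rings)
        g = np.linspace(-10, 10, 12)
        X, Y = np.meshgrid(g, g, indexing="ij")
        wall_v = np.column_stack(
            [X.ravel(), Y.ravel(), gap_fn(X.ravel(), Y.ravel())]
        )
        idx = np.arange(144).reshape(12, 12)
        f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], -1).reshape(-1, 3)
        f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], -1).reshape(-1, 3)
        return surf, wall_v, np.vstack([f1, f2])

    def test_zero_gap_identity(self):
        surf, wv, wf = self.flat_valve_and_wall(lambda x, y: 0.0 * x)
        warped = attach_to_wall(surf, wv, wf)
        assert np.allclose(warped.vertices, surf.vertices, atol=1e-9)

    def test_uniform_gap_uniform_translation(self):
        surf, wv, wf = self.flat_valve_and_wall(lambda x, y: 0.0 * x + 1.0)
        warped = attach_to_wall(surf, wv, wf)
        shift = warped.vertices - surf.vertices
        assert np.allclose(shift, [0, 0, 1.0], atol=1e-9)

    def test_maximum_principle(self):
        surf, wv, wf = self.flat_valve_and_wall(lambda x, y: 0.3 + 0.1 * x)
        warped = attach_to_wall(surf, wv, wf)
        shift_z = (warped.vertices - surf.vertices)[:, 2]
        ann = surf.annulus_vertex_ids()
        assert shift_z.min() >= shift_z[ann].min() - 1e-9
        assert shift_z.max() <= shift_z[ann].max() + 1e-9

    def test_excessive_gap_fails(self):
        surf, wv, wf = self.flat_valve_and_wall(lambda x, y: 0.0 * x + 50.0)
        with pytest.raises(ValueError, match="threshold"):
            attach_to_wall(surf, wv, wf)


class TestDelta:
    def test_peak_value(self):
        eps = 0.75e-3
        assert smoothed_delta(np.zeros(1), eps)[0] == pytest.approx(1 / eps)

    def test_compact_support(self):
        eps = 0.75e-3
        phi = np.array([-2 * eps, -1.01 * eps, 1.01 * eps, 5 * eps])
        assert np.all(smoothed_delta(phi, eps) == 0.0)

    def test_unit_integral(self):
        eps = 0.75e-3
        phi = np.linspace(-eps, eps, 20001)
        integral = np.trapezoid(smoothed_delta(phi, eps), phi)
        assert abs(integral - 1.0) < 1e-8

    def test_distance_is_exact_for_a_plane(self):
        # a large triangulated square at z=0: phi is |z|
        v = np.array([[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0.0]])
        f = np.array([[0, 1, 2], [0, 2, 3]])
        pts = np.array([[0.1, 0.2, 0.4], [0.0, 0.0, -0.3], [0.5, -0.5, 0.0]])
        phi, _ = distance_and_delta(v, f, pts, 1.0)
        assert np.allclose(phi, [0.4, 0.3, 0.0], atol=1e-12)


class TestScenarioValves:
    def test_scenarios(self, coarse_mesh, healthy_traces, prolapse_traces):
        mit, ao, _ = make_scenario_valves("H", coarse_mesh,
                                          traces_healthy=healthy_traces)
        assert mit.state == "closed"
        assert ao.state == "open"
        mit_r, ao_r, _ = make_scenario_valves(
            "R1", coarse_mesh, traces_regurgitant=prolapse_traces
        )
        assert ao_r.state == "closed"
        with pytest.raises(ValueError):
            make_scenario_valves("X", coarse_mesh)

    def test_open_and_closed_templates_exist(self, coarse_mesh):
        (cv, cf), (ov, of_) = aortic_valve_templates(coarse_mesh.primitives)
        assert len(cf) > 0 and len(of_) > 0
        # the closed disk spans the lumen; the open sleeve hugs the wall
        prim = coarse_mesh.primitives
        rel = ov - np.asarray(prim.aorta_origin)
        s = rel @ prim.aorta_dir
        perp = np.linalg.norm(rel - s[:, None] * prim.aorta_dir, axis=1)
        assert perp.min() > prim.aorta_radius - 0.5

    def test_r2_topology_matches_r1(self, coarse_mesh, prolapse_traces):
        from cardioriis.phantom import PhantomSpec, generate_geometry

        spec2 = PhantomSpec(dilation=1.25, valve_kind="prolapse",
                            trace_noise_mm=0.0, **COARSE)
        mesh2 = generate_geometry(spec2)
        m1, _, s1 = make_scenario_valves("R1", coarse_mesh,
                                         traces_regurgitant=prolapse_traces)
        m2, _, s2 = make_scenario_valves(
            "R2", mesh2, traces_regurgitant=prolapse_traces.scaled(1.25)
        )
        # scaling preserves the ring/trace structure fed into meshing
        assert prolapse_traces.anterior.shape == (18, 32, 3)
        assert np.allclose(
            prolapse_traces.scaled(1.25).anterior,
            prolapse_traces.anterior * 1.25,
        )


def test_immersed_valve_contracts():
    with pytest.raises(ValueError):
        ImmersedValve(name="m", vertices_m=np.zeros((3, 3)),
                      faces=np.array([[0, 1, 2]]), eps_m=-1.0)
    valve = ImmersedValve(name="m", vertices_m=np.zeros((3, 3)),
                          faces=np.array([[0, 1, 2]]), state="open")
    assert valve.active_surface() is None  # no open template -> no penalty
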