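"""Phantom generators: fiber fields, meshing networks, rendered maps."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

import walltomo as wt
from walltomo.angular import axial_separation_deg, circular_mean_axial
from walltomo.geometry import mean_menger_radius


class TestFiberField:
    def test_deterministic_for_fixed_seed(self):
        spec = wt.FiberFieldSpec(seed=3, fibers_per_layer=5)
        ts1, truth1 = wt.generate_fiber_field(spec)
        ts2, truth2 = wt.generate_fiber_field(spec)
        assert truth1.equals(truth2)
        for a, b in zip(ts1, ts2):
            np.testing.assert_array_equal(a.points, b.points)

    def test_truth_table_ids_unique_and_complete(self):
        ts, truth = wt.generate_fiber_field(wt.FiberFieldSpec(seed=1, fibers_per_layer=4))
        assert truth.fiber_id.is_unique
        assert set(truth.fiber_id) == {t.trace_id for t in ts}

    def test_circular_means_match_configured_modes(self):
        spec = wt.FiberFieldSpec(
            seed=2, pattern="staggered", mode_angles=(45.0, 135.0), angular_sd=8.0,
            n_layers=10, layer_thickness=40.0, fibers_per_layer=100,
        )
        _, truth = wt.generate_fiber_field(spec)
        for mode_idx, mode in enumerate((45.0, 135.0)):
            grp = truth[truth.mode_index == mode_idx]
            assert len(grp) >= 500
            got = circular_mean_axial(grp.true_angle_deg.to_numpy())
            assert axial_separation_deg(got, mode) < 1.0

    def test_zero_noise_unimodal_angles_exact(self):
        spec = wt.FiberFieldSpec(
            seed=4, pattern="unimodal", mode_angles=(90.0,), angular_sd=0.0,
            fibers_per_layer=5,
        )
        ts, truth = wt.generate_fiber_field(spec)
        assert (truth.true_angle_deg == 90.0).all()
        for t in ts:
            tc = wt.canonicalize_direction(t)
            assert wt.angle_to_axis(tc, (0.0, 1.0)) == pytest.approx(90.0, abs=1e-9)

    def test_point_spacing_at_most_2nm(self):
        ts, _ = wt.generate_fiber_field(wt.FiberFieldSpec(seed=5, fibers_per_layer=3))
        for t in ts:
            steps = np.linalg.norm(np.diff(t.points, axis=0), axis=1)
            assert steps.max() <= 2.0 + 1e-9

    def test_configured_curvature_recovered_by_menger(self):
        spec = wt.FiberFieldSpec(
            seed=6, curvature_radius=225.0, fibers_per_layer=10, angular_sd=5.0
        )
        ts, _ = wt.generate_fiber_field(spec)
        radii = [mean_menger_radius(t.points) for t in ts]
        assert abs(np.mean(radii) - 225.0) / 225.0 < 0.05

    def test_staggered_layers_alternate_modes(self):
        _, truth = wt.generate_fiber_field(
            wt.FiberFieldSpec(seed=7, pattern="staggered", fibers_per_layer=4)
        )
        per_layer = truth.groupby("layer_index").mode_index.nunique()
        assert (per_layer == 1).all()
        assert (truth.mode_index == truth.layer_index % 2).all()

    def test_overlapped_mixes_modes_at_all_heights(self):
        _, truth = wt.generate_fiber_field(
            wt.FiberFieldSpec(seed=8, pattern="overlapped", fibers_per_layer=40)
        )
        # both modes span the full stack
        for _, grp in truth.groupby("mode_index"):
            assert grp.z_center_nm.max() - grp.z_center_nm.min() > 300.0

    def test_box_too_small_raises(self):
        with pytest.raises(ValueError, match="box too small"):
            wt.FiberFieldSpec(box_dims=(200.0, 200.0, 400.0), fiber_length_range=(300, 400))

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            wt.FiberFieldSpec(pattern="helical")

    def test_generated_angles_recovered_by_mixture_fit(self):
        hits = 0
        for seed in range(10):
            spec = wt.FiberFieldSpec(
                seed=seed, n_layers=10, layer_thickness=40.0, fibers_per_layer=60,
                mode_angles=(45.0, 135.0), angular_sd=8.0,
            )
            _, truth = wt.generate_fiber_field(spec)
            m = wt.fit_axial_mixture(truth.true_angle_deg.to_numpy(), k=2, seed=seed)
            if (
                axial_separation_deg(m.modes_deg[0], 45.0) <= 3.0
                and axial_separation_deg(m.modes_deg[1], 135.0) <= 3.0
            ):
                hits += 1
        assert hits >= 9


class TestMeshingNetwork:
    def test_zero_density_gives_empty_graph(self):
        g = wt.generate_meshing_network(
            wt.MeshingSpec(density_at_surface=0.0, seed=1), (1000, 1000, 1000)
        )
        assert g.n_segments == 0

    def test_no_decay_depth_uniform(self):
        g = wt.generate_meshing_network(
            wt.MeshingSpec(
                density_at_surface=1300.0, depth_decay=math.inf,
                branch_probability=0.0, seed=2,
            ),
            (2000, 2000, 2000),
        )
        z = g.segment_midpoints()[:, 2]
        assert z.size >= 10000
        counts, _ = np.histogram(z, bins=np.linspace(0, 2000, 11))
        assert chisquare(counts).pvalue > 0.01

    def test_exponential_decay_ratio(self):
        g = wt.generate_meshing_network(
            wt.MeshingSpec(
                density_at_surface=2000.0, depth_decay=1000.0,
                branch_probability=0.0, seed=3,
            ),
            (2000, 2000, 2000),
        )
        z = g.segment_midpoints()[:, 2]
        shallow = ((z >= 0) & (z < 500)).sum()
        deep = ((z >= 1500) & (z < 2000)).sum()
        assert shallow / deep == pytest.approx(math.exp(1.5), rel=0.15)

    def test_orientations_isotropic_in_z(self):
        g = wt.generate_meshing_network(
            wt.MeshingSpec(
                density_at_surface=800.0, depth_decay=math.inf,
                branch_probability=0.0, seed=4,
            ),
            (2000, 2000, 2000),
        )
        d = g.nodes[g.edges[:, 1]] - g.nodes[g.edges[:, 0]]
        cosz = d[:, 2] / np.linalg.norm(d, axis=1)
        # cos of polar angle uniform on [-1, 1] for isotropic directions
        assert abs(cosz.mean()) < 0.03
        assert np.var(cosz) == pytest.approx(1.0 / 3.0, rel=0.1)

    def test_branching_adds_segments(self):
        base = dict(density_at_surface=500.0, depth_decay=1000.0, seed=5)
        g0 = wt.generate_meshing_network(
            wt.MeshingSpec(branch_probability=0.0, **base), (1000, 1000, 1000)
        )
        g1 = wt.generate_meshing_network(
            wt.MeshingSpec(branch_probability=0.5, **base), (1000, 1000, 1000)
        )
        assert g1.n_segments > g0.n_segments


class TestRendering:
    def test_empty_scene_renders_zero(self):
        fm, am = wt.render_probability_maps(
            [], None, wt.RenderSpec(noise_sd=0.0), (100, 100, 50)
        )
        assert not fm.data.any() and not am.data.any()

    def test_single_tube_argmax_on_axis(self):
        tr = np.array([[20.0, 100.0, 40.0], [180.0, 100.0, 40.0]])
        fm, _ = wt.render_probability_maps(
            [tr], None, wt.RenderSpec(voxel_size=2.0, fiber_radius=3.5, noise_sd=0.0),
            (200, 200, 80),
        )
        for ix in range(15, 86):
            sl = fm.data[:, :, ix]
            iz, iy = np.unravel_index(np.argmax(sl), sl.shape)
            assert abs(iz - 20) <= 1 and abs(iy - 50) <= 1

    def test_maps_clipped_to_unit_range_before_noise(self):
        tr = np.array([[20.0, 50.0, 20.0], [80.0, 50.0, 20.0]])
        fm, am = wt.render_probability_maps(
            [tr], None, wt.RenderSpec(voxel_size=2.0, noise_sd=0.0), (100, 100, 40)
        )
        for v in (fm, am):
            assert v.data.min() >= 0.0 and v.data.max() <= 1.0

    def test_noise_applied_after_clipping(self):
        tr = np.array([[20.0, 50.0, 20.0], [80.0, 50.0, 20.0]])
        fm, _ = wt.render_probability_maps(
            [tr], None, wt.RenderSpec(voxel_size=2.0, noise_sd=0.1, seed=9),
            (100, 100, 40),
        )
        assert fm.data.min() < 0.0  # additive noise may undershoot zero

    def test_memory_budget_enforced(self):
        with pytest.raises(MemoryError):
            wt.render_probability_maps(
                [], None, wt.RenderSpec(voxel_size=1.0, memory_budget_mb=10.0),
                (2000, 2000, 2000),
            )

    def test_render_deterministic(self):
        tr = np.array([[20.0, 50.0, 20.0], [80.0, 50.0, 20.0]])
        spec = wt.RenderSpec(voxel_size=2.0, noise_sd=0.05, seed=11)
        a, _ = wt.render_probability_maps([tr], None, spec, (100, 100, 40))
        b, _ = wt.render_probability_maps([tr], None, spec, (100, 100, 40))
        np.testing.assert_array_equal(a.data, b.data)


class TestPhantomBundle:
    def test_phantom_files_written(self, tmp_path, small_phantom):
        paths = wt.write_phantom(small_phantom, tmp_path / "ph")
        import os

        for p in paths.values():
            assert os.path.exists(p)
        back = wt.read_volume(paths["fiber_map"])
        np.testing.assert_allclose(back.data, small_phantom.fiber_map.data, atol=1e-6)

    def test_ground_truth_masks_cover_rendered_tubes(self, small_phantom):
        fibT, meshT = small_phantom.ground_truth_masks()
        fib = wt.binarize_map(small_phantom.fiber_map, 0.5)
        # half-max threshold recovers the nominal tube radius
        agree = (fib.grid == fibT).mean()
        assert agree > 0.99
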