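"""Leaflet surfaces, thickness maps, curvature and radial profiles."""

import numpy as np
import pytest

from memdeform.membrane import (GridField, GridSpec, average_leaflet_surfaces,
                                grid_leaflet_surface, mean_curvature,
                                midplane_height, radial_profile, thickness_map)
from memdeform.synthetic import (BilayerSpec, InclusionSpec,
                                 generate_trajectory, make_deformation_field)
from memdeform.trajio import Trajectory, assign_leaflets


def _full_field(values, spec):
    values = np.asarray(values, dtype=float)
    return GridField(values, np.ones(values.shape, bool),
                     np.ones(values.shape, int), spec)


class TestLeafletSurfaces:
    def test_flat_bilayer_surfaces(self, flat_bilayer):
        traj, _ = flat_bilayer
        frame = traj[0]
        spec = GridSpec(8.0, (150.0, 150.0))
        upper, lower = grid_leaflet_surface(frame, assign_leaflets(frame),
                                            "bead GL1", spec)
        assert np.all(upper.values[upper.mask] == pytest.approx(19.0))
        assert np.all(lower.values[lower.mask] == pytest.approx(-19.0))

    def test_boundary_bead_membership_is_deterministic(self):
        spec = GridSpec(10.0, (100.0, 100.0))
        # half-open cells: a bead exactly at x=10 belongs to the cell
        # starting at 10, i.e. index 1
        i, j = spec.cell_of(np.array([10.0]), np.array([0.0]))
        assert (i[0], j[0]) == (1, 0)
        i, j = spec.cell_of(np.array([100.0]), np.array([99.999]))
        assert (i[0], j[0]) == (0, 9)  # wraps periodically

    def test_grid_spec_rederives_cell_size(self):
        spec = GridSpec(7.0, (150.0, 150.0))
        assert spec.nx == 21
        assert spec.dx == pytest.approx(150.0 / 21)


class TestThicknessMap:
    def test_flat_noiseless_exact(self, flat_bilayer):
        traj, _ = flat_bilayer
        tmap = thickness_map(traj)
        assert tmap.n_frames == 1
        assert np.all(tmap.field.values[tmap.field.mask] == pytest.approx(38.0))

    def test_inclusion_masks_covered_cells(self):
        spec = BilayerSpec(n_frames=1, noise_sigma=0.0)
        inc = InclusionSpec(radius=15.0)
        traj, _ = generate_trajectory(spec, inc, seed=6)
        gs = GridSpec(4.0, (150.0, 150.0))
        tmap = thickness_map(traj, spec=gs)
        X, Y = np.meshgrid(gs.x_centers(), gs.y_centers(), indexing="ij")
        r = np.hypot(X - 75.0, Y - 75.0)
        covered = r < inc.radius - 0.5 * np.hypot(gs.dx, gs.dy)
        assert np.all(~tmap.field.mask[covered])
        assert (~tmap.field.mask[r < inc.radius]).sum() >= 20

    def test_z_translation_invariance(self, small_tilted_system):
        traj, _ = small_tilted_system
        shifted = Trajectory(traj.topology,
                             traj.coordinates + np.array([0.0, 0.0, 25.0]),
                             traj.boxes)
        a = thickness_map(traj, spec=GridSpec(15.0, (150.0, 150.0)))
        b = thickness_map(shifted, spec=GridSpec(15.0, (150.0, 150.0)))
        assert np.array_equal(a.field.mask, b.field.mask)
        assert np.allclose(a.field.values[a.field.mask],
                           b.field.values[b.field.mask], atol=1e-9)

    def test_midplane_reflection_symmetry(self, small_tilted_system):
        traj, _ = small_tilted_system
        reflected = Trajectory(traj.topology, traj.coordinates * np.array([1, 1, -1.0]),
                               traj.boxes)
        a = thickness_map(traj, spec=GridSpec(15.0, (150.0, 150.0)))
        b = thickness_map(reflected, spec=GridSpec(15.0, (150.0, 150.0)))
        assert np.array_equal(a.field.mask, b.field.mask)
        assert np.allclose(a.field.values[a.field.mask],
                           b.field.values[b.field.mask], atol=1e-9)

    def test_lateral_translation_equivariance(self, flat_bilayer):
        traj, _ = flat_bilayer
        gs = GridSpec(15.0, (150.0, 150.0))
        shift_cells = 3
        shifted = Trajectory(traj.topology,
                             traj.coordinates + np.array([shift_cells * gs.dx, 0.0, 0.0]),
                             traj.boxes)
        a = thickness_map(traj, spec=gs)
        b = thickness_map(shifted, spec=gs)
        assert np.array_equal(np.roll(a.field.mask, shift_cells, axis=0), b.field.mask)
        rolled = np.roll(a.field.values, shift_cells, axis=0)
        both = np.roll(a.field.mask, shift_cells, axis=0)
        assert np.allclose(rolled[both], b.field.values[both], atol=1e-9)

    def test_prescribed_field_recovery_noiseless(self, gaussian_well_field):
        spec = BilayerSpec(thickness_field=gaussian_well_field, n_frames=1)
        traj, truth = generate_trajectory(spec, seed=12)
        tmap = thickness_map(traj)
        gs = tmap.field.spec
        X, Y = np.meshgrid(gs.x_centers(), gs.y_centers(), indexing="ij")
        err = np.abs(tmap.field.values - truth.thickness_at(X, Y))[tmap.field.mask]
        # noiseless: only intra-cell variation of the prescribed field remains
        assert err.mean() < 0.5


class TestMidplane:
    @pytest.mark.parametrize("up,low,expect", [(19.0, -19.0, 0.0), (24.0, -14.0, 5.0)])
    def test_arithmetic(self, up, low, expect):
        spec = GridSpec(10.0, (30.0, 30.0))
        mid = midplane_height(_full_field(np.full((3, 3), up), spec),
                              _full_field(np.full((3, 3), low), spec))
        assert np.all(mid.values == pytest.approx(expect))

    def test_masked_propagates(self):
        spec = GridSpec(10.0, (30.0, 30.0))
        upper = _full_field(np.full((3, 3), 19.0), spec)
        upper.mask[1, 1] = False
        upper.values[1, 1] = np.nan
        mid = midplane_height(upper, _full_field(np.full((3, 3), -19.0), spec))
        assert not mid.mask[1, 1]
        assert mid.mask.sum() == 8

    def test_incongruent_grids_rejected(self):
        a = _full_field(np.zeros((3, 3)), GridSpec(10.0, (30.0, 30.0)))
        b = _full_field(np.zeros((4, 4)), GridSpec(10.0, (40.0, 40.0)))
        with pytest.raises(ValueError):
            midplane_height(a, b)


class TestMeanCurvature:
    def test_flat_field_is_zero(self):
        spec = GridSpec(4.0, (160.0, 160.0))
        h = _full_field(np.full((spec.nx, spec.ny), 7.5), spec)
        cm = mean_curvature(h, presmooth_sigma_cells=0.0)
        assert np.all(np.abs(cm.field.values[cm.field.mask]) < 1e-12)

    def test_affine_field_is_zero(self):
        spec = GridSpec(4.0, (160.0, 160.0), periodic=False)
        X, Y = np.meshgrid(spec.x_centers(), spec.y_centers(), indexing="ij")
        h = _full_field(3.0 + 0.04 * X - 0.02 * Y, spec)
        cm = mean_curvature(h, presmooth_sigma_cells=0.0)
        assert np.all(np.abs(cm.field.values[cm.field.mask]) < 1e-12)

    def test_sinusoid_matches_closed_form(self):
        A, L = 5.0, 75.0
        spec = GridSpec(1.0, (150.0, 150.0))
        X, _ = np.meshgrid(spec.x_centers(), spec.y_centers(), indexing="ij")
        cm = mean_curvature(_full_field(A * np.sin(2 * np.pi * X / L), spec),
                            presmooth_sigma_cells=0.0)
        k = 2 * np.pi / L
        i_crest = np.argmin(np.abs(spec.x_centers() - L / 4))
        # at a crest the surface bulges toward +z: positive H of magnitude Ak²/2
        expected = A * k * k / 2
        got = cm.field.values[i_crest, 5]
        assert got == pytest.approx(expected, rel=0.05)
        assert got > 0

    def test_spherical_cap_curvature(self):
        R = 200.0
        spec = GridSpec(2.0, (150.0, 150.0), periodic=False)
        X, Y = np.meshgrid(spec.x_centers(), spec.y_centers(), indexing="ij")
        r2 = (X - 75.0) ** 2 + (Y - 75.0) ** 2
        cm = mean_curvature(_full_field(np.sqrt(R * R - r2), spec),
                            presmooth_sigma_cells=0.0)
        center = cm.field.values[spec.nx // 2, spec.ny // 2]
        assert center == pytest.approx(1.0 / R, rel=0.05)
        assert center > 0

    def test_small_slope_half_laplacian_limit(self):
        spec = GridSpec(2.0, (150.0, 150.0))
        X, Y = np.meshgrid(spec.x_centers(), spec.y_centers(), indexing="ij")
        kx = ky = 2 * np.pi / 150.0
        h = 0.1 * np.sin(kx * X) * np.sin(ky * Y)  # max slope ≈ 0.004
        cm = mean_curvature(_full_field(h, spec), presmooth_sigma_cells=0.0)
        half_laplacian = -0.5 * (-(kx ** 2) - ky ** 2) * h  # −½∇²h, bulge-positive
        strong = np.abs(h) > 0.05
        rel = np.abs(cm.field.values[strong] - half_laplacian[strong]) \
            / np.abs(half_laplacian[strong])
        assert np.max(rel) < 0.01

    def test_masked_hole_masks_neighborhood(self):
        spec = GridSpec(4.0, (80.0, 80.0))
        h = _full_field(np.zeros((spec.nx, spec.ny)), spec)
        h.mask[10, 10] = False
        h.values[10, 10] = np.nan
        cm = mean_curvature(h, presmooth_sigma_cells=0.0)
        assert not cm.field.mask[9:12, 9:12].any()
        assert cm.field.mask[5, 5]

    def test_grid_too_small(self):
        spec = GridSpec(10.0, (20.0, 20.0))
        with pytest.raises(ValueError):
            mean_curvature(_full_field(np.zeros((2, 2)), spec))


class TestRadialProfile:
    def test_uniform_field(self):
        spec = GridSpec(4.0, (80.0, 80.0))
        prof = radial_profile(_full_field(np.full((20, 20), 38.0), spec),
                              (40.0, 40.0), 4.0)
        assert np.allclose(prof["mean_value"], 38.0)
        assert int(prof["n_cells"].sum()) == 400

    def test_gaussian_dip_profile_shape(self):
        well = make_deformation_field("radial_gaussian", amplitude=-12.0,
                                      width=30.0, center=(75.0, 75.0))
        spec = BilayerSpec(thickness_field=well, n_frames=1)
        traj, _ = generate_trajectory(spec, seed=13)
        tmap = thickness_map(traj)
        prof = radial_profile(tmap.field, (75.0, 75.0), 8.0)
        values = prof["mean_value"].to_numpy()
        assert np.argmin(values) == 0
        assert np.all(np.diff(values) > -0.6)  # non-decreasing within noise

    def test_center_outside_box_is_wrapped(self):
        spec = GridSpec(4.0, (80.0, 80.0))
        rng = np.random.default_rng(3)
        field = _full_field(rng.normal(38.0, 1.0, (20, 20)), spec)
        a = radial_profile(field, (10.0, 20.0), 4.0)
        b = radial_profile(field, (10.0 + 80.0, 20.0 - 160.0), 4.0)
        assert a.equals(b)


class TestAverageSurfaces:
    def test_matches_single_frame_surface(self, flat_bilayer):
        traj, _ = flat_bilayer
        upper, lower = average_leaflet_surfaces(traj)
        assert np.all(upper.values[upper.mask] == pytest.approx(19.0))
        assert np.all(lower.values[lower.mask] == pytest.approx(-19.0))
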