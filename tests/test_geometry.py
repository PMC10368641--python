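"""Helix axes, tilt angles, Kabsch superposition and displacement metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from memdeform.geometry import (HelixSelectionSpec, Superposition,
                                displacement_metrics, helix_axis,
                                superpose_rmsd, tilt_angle, tilt_series)
from memdeform.synthetic import BilayerSpec, InclusionSpec, generate_trajectory
from memdeform.trajio import BeadFrame, Trajectory


class TestHelixAxis:
    def test_collinear_along_z(self):
        p = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        assert np.allclose(helix_axis(p), [0, 0, 1], atol=1e-12)

    def test_collinear_diagonal(self):
        d = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        p = np.arange(8.0)[:, None] * d
        assert np.allclose(helix_axis(p), d, atol=1e-12)

    def test_n_to_c_sign_convention(self):
        p = np.column_stack([np.zeros(10), np.zeros(10), -np.arange(10.0)])
        assert np.allclose(helix_axis(p), [0, 0, -1], atol=1e-12)

    def test_ideal_alpha_helix_axis(self):
        # 29 residues, rise 1.5 Å/residue (pitch 5.4 Å / 3.6 res), radius 2.3 Å
        n = np.arange(29)
        theta = np.radians(100.0) * n
        p = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * n])
        axis = helix_axis(p)
        assert tilt_angle(axis) < 1.0

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            helix_axis(np.ones((5, 3)))


class TestTiltAngle:
    @pytest.mark.parametrize("v,expected", [
        ((0, 0, 1), 0.0),
        ((1, 0, 0), 90.0),
        ((1, 0, 1), 45.0),
        ((0, 0, -1), 0.0),
    ])
    def test_closed_forms(self, v, expected):
        assert tilt_angle(np.array(v, float)) == pytest.approx(expected)

    @given(st.tuples(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)).filter(
        lambda v: np.linalg.norm(v) > 1e-3))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_fold_symmetry(self, v):
        v = np.array(v)
        assert tilt_angle(v) == pytest.approx(tilt_angle(-v), abs=1e-9)
        assert 0.0 <= tilt_angle(v) <= 90.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            tilt_angle(np.zeros(3))


class TestTiltSeries:
    def test_recovery_with_jitter(self):
        spec = BilayerSpec(n_lipids_per_leaflet=40, n_frames=150)
        inc = InclusionSpec(prescribed_tilt=50.0, tilt_jitter_sigma=2.0)
        traj, truth = generate_trajectory(spec, inc, seed=21)
        series = tilt_series(traj, HelixSelectionSpec((106, 134), "BB"))
        assert series.mean == pytest.approx(truth.prescribed_tilt, abs=0.5)
        assert 1.0 < series.std < 3.0
        assert series.block_sem > 0

    def test_rigid_inclusion_zero_spread(self, small_tilted_system):
        traj, truth = small_tilted_system
        series = tilt_series(traj, HelixSelectionSpec((106, 134), "BB"))
        assert series.std <= 1e-9
        assert series.mean == pytest.approx(truth.prescribed_tilt, abs=1e-6)

    def test_invariant_under_z_rotation(self, small_tilted_system):
        traj, _ = small_tilted_system
        theta = np.radians(61.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = Trajectory(traj.topology, traj.coordinates @ rot.T, traj.boxes)
        a = tilt_series(traj, HelixSelectionSpec((106, 134), "BB"))
        b = tilt_series(rotated, HelixSelectionSpec((106, 134), "BB"))
        assert np.allclose(a.angles, b.angles, atol=1e-9)

    def test_missing_selection_rejected(self, flat_bilayer):
        traj, _ = flat_bilayer  # no helix in this system
        with pytest.raises(ValueError):
            tilt_series(traj, HelixSelectionSpec((106, 134), "BB"))


def _random_points(seed, n=10):
    return np.random.default_rng(seed).normal(scale=5.0, size=(n, 3))


class TestSuperposition:
    def test_identical_structures(self):
        P = _random_points(0)
        sup = superpose_rmsd(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_rigid_motion_recovered(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(scale=5.0, size=(8, 3))
        R = Rotation.random(random_state=int(seed)).as_matrix()
        t = rng.uniform(-20, 20, 3)
        sup = superpose_rmsd(P, P @ R.T + t)
        assert sup.rmsd < 1e-6
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_never_worse_than_unaligned(self):
        rng = np.random.default_rng(5)
        P, Q = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        unaligned = np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))
        assert superpose_rmsd(P, Q).rmsd <= unaligned + 1e-12

    def test_agrees_with_rotation_grid_search(self):
        # independent oracle: coarse Euler-angle grid, then local refinement
        rng = np.random.default_rng(17)
        P = rng.normal(scale=4.0, size=(4, 3))
        Q = P @ Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix().T \
            + np.array([3.0, -1.0, 2.0]) + rng.normal(scale=0.3, size=(4, 3))

        Pc, Qc = P - P.mean(0), Q - Q.mean(0)

        def rmsd_of(angles):
            R = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
            return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

        grid = [(a, b, c)
                for a in range(-180, 180, 15)
                for b in range(-90, 91, 15)
                for c in range(-180, 180, 15)]
        best = min(grid, key=rmsd_of)
        refined = minimize(rmsd_of, best, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12})
        kabsch = superpose_rmsd(P, Q)
        assert kabsch.rmsd <= refined.fun + 1e-9
        assert kabsch.rmsd == pytest.approx(refined.fun, abs=1e-3)

    def test_collinear_flagged_degenerate(self):
        P = np.arange(12.0).reshape(4, 3) * 0 + \
            np.arange(4.0)[:, None] * np.array([1.0, 1.0, 0.0])
        sup = superpose_rmsd(P, P)
        assert sup.degenerate

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


def _toy_model(probe_shift=np.zeros(3), probe2_shift=None):
    """Rigid scaffold (resids 1..12) + probe (20..24) + optional probe2 (30..34)."""
    rng = np.random.default_rng(99)
    scaffold = rng.normal(scale=8.0, size=(12, 3))
    probe = np.array([[40.0, 0, 0], [41, 1, 0], [39, -1, 0], [40, 0, 1], [40, 0, -1]])
    coords = [scaffold, probe + probe_shift]
    resids = list(range(1, 13)) + list(range(20, 25))
    if probe2_shift is not None:
        probe2 = probe + np.array([20.0, 0.0, 0.0])
        coords.append(probe2 + probe2_shift)
        resids += list(range(30, 35))
    pos = np.vstack(coords)
    n = len(pos)
    return BeadFrame(np.array(["A"] * n, object), np.array(resids),
                     np.array(["ALA"] * n, object), np.array(["CA"] * n, object),
                     pos, np.array([200.0, 200.0, 200.0]))


class TestDisplacementMetrics:
    def test_identical_models_zero(self):
        m = _toy_model()
        out = displacement_metrics(m, m, "resid 1-12", "resid 20-24")
        assert out["centroid_displacement"] == pytest.approx(0.0, abs=1e-9)
        assert out["per_residue_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_probe_translated_nine_angstrom_down(self):
        m_open = _toy_model()
        m_closed = _toy_model(probe_shift=np.array([0.0, 0.0, -9.0]))
        out = displacement_metrics(m_open, m_closed, "resid 1-12", "resid 20-24")
        assert out["centroid_displacement"] == pytest.approx(9.0, abs=1e-6)
        assert out["centroid_displacement_z"] == pytest.approx(-9.0, abs=1e-6)
        assert out["per_residue_mean"] == pytest.approx(9.0, abs=1e-6)

    def test_symmetric_approach_separation_change(self):
        m_open = _toy_model(probe2_shift=np.zeros(3))
        m_closed = _toy_model(probe_shift=np.array([2.0, 0, 0]),
                              probe2_shift=np.array([-2.0, 0, 0]))
        out = displacement_metrics(m_open, m_closed, "resid 1-12",
                                   "resid 20-24", "resid 30-34")
        assert out["separation_open"] == pytest.approx(20.0, abs=1e-6)
        assert out["separation_change"] == pytest.approx(4.0, abs=1e-6)
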