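import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mfskit import geometry, synthetic
from mfskit.geometry import (
    dccm, gate_selection, helix_axis_and_tilt, kink_analysis,
    pairwise_com_distance, pore_radius_profile, tilt_profile,
)
from mfskit.structures import Trajectory
from oracles import (
    brute_force_pore_radius, ca_structure, cone_structure,
    cylinder_structure, kinked_helix, single_frame_traj,
)


class TestTilt:
    @pytest.mark.parametrize("axis,expected", [
        ((0, 0, 1), 0.0),
        ((1, 0, 0), 90.0),
        ((np.sin(np.radians(25)), 0, np.cos(np.radians(25))), 25.0),
    ])
    def test_known_axes(self, axis, expected):
        h = synthetic.helix_trace(20, axis, (0, 0, 0))
        assert helix_axis_and_tilt(h) == pytest.approx(expected, abs=1.0)

    def test_direction_reversal_invariant(self):
        h = synthetic.helix_trace(20, (0.4, 0.2, 0.89), (0, 0, 0))
        h = h / np.linalg.norm([1])  # no-op, keep array
        assert helix_axis_and_tilt(h) == pytest.approx(
            helix_axis_and_tilt(h[::-1]), abs=1e-6)

    def test_degenerate_points_rejected(self):
        with pytest.raises(Exception):
            helix_axis_and_tilt(np.zeros((6, 3)))

    def test_static_structure_sd_zero(self, bundle_and_map):
        bundle, cmap = bundle_and_map
        traj = Trajectory(topology=bundle,
                          frames=np.repeat(bundle.coords[None], 10, axis=0))
        prof = tilt_profile(traj, cmap)
        assert np.all(prof.sd_tilt <= 1e-12)
        assert prof.frames_used == 10

    def test_pooled_replicas_frame_weighted(self, bundle_and_map):
        bundle, cmap = bundle_and_map
        t1 = Trajectory(topology=bundle, frames=bundle.coords[None])
        tilted = bundle.coords @ Rotation.from_euler(
            "y", 10, degrees=True).as_matrix().T
        t2 = Trajectory(topology=bundle,
                        frames=np.repeat(tilted[None], 3, axis=0))
        pooled = tilt_profile([t1, t2], cmap)
        a = tilt_profile(t1, cmap).mean_tilt
        b = tilt_profile(t2, cmap).mean_tilt
        assert np.allclose(pooled.mean_tilt, (a + 3 * b) / 4, atol=1e-9)

    def test_generator_tilt_recovery(self, bundle_and_map):
        bundle, cmap = bundle_and_map
        prof = tilt_profile(single_frame_traj(bundle), cmap)
        assert np.all(np.abs(prof.mean_tilt - 30.0) <= 2.0)


class TestKink:
    def test_straight_helix_no_kink(self):
        rep = kink_analysis(synthetic.helix_trace(24, (0, 0, 1), (0, 0, 0)))
        assert rep.evaluable and not rep.kink_present
        assert rep.kink_angle < 5.0

    def test_30_degree_junction_recovered(self):
        rep = kink_analysis(kinked_helix(30.0))
        assert rep.kink_present
        assert abs(rep.kink_angle - 30.0) <= 3.0
        assert abs(rep.kink_residue - 12) <= 1  # junction at residue 12

    def test_threshold_logic(self):
        rep = kink_analysis(kinked_helix(30.0), angle_threshold=45.0)
        assert not rep.kink_present

    def test_too_short_not_evaluable(self):
        rep = kink_analysis(synthetic.helix_trace(10, (0, 0, 1), (0, 0, 0)))
        assert not rep.evaluable


class TestComDistance:
    def test_two_single_atoms(self):
        st = ca_structure(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        d = pairwise_com_distance(single_frame_traj(st), [0], [1])
        assert d[0] == pytest.approx(5.000, abs=1e-9)

    def test_same_selection_zero(self, bundle_and_map):
        bundle, _ = bundle_and_map
        d = pairwise_com_distance(single_frame_traj(bundle),
                                  range(8), range(8))
        assert d[0] == 0.0

    def test_matches_hand_computed_centroids(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(16, 3))
        st = ca_structure(coords)
        d = pairwise_com_distance(single_frame_traj(st), range(8),
                                  range(8, 16))
        expected = np.linalg.norm(coords[:8].mean(0) - coords[8:].mean(0))
        assert d[0] == pytest.approx(expected, abs=1e-9)

    def test_empty_selection_rejected(self, bundle_and_map):
        bundle, _ = bundle_and_map
        with pytest.raises(ValueError):
            pairwise_com_distance(single_frame_traj(bundle), [], [0])


class TestPore:
    def test_cylinder_radius(self):
        st = cylinder_structure(inner_radius=5.0)
        prof = pore_radius_profile(single_frame_traj(st), z_step=2.0,
                                   n_snapshots=1, search_radius=4.0,
                                   z_range=(4.0, 16.0))
        assert np.all(np.abs(prof.mean_radius - 5.0) <= 0.1)
        assert not prof.capped.any()

    def test_cone_profile_linear(self):
        # the sphere-probe radius of a cone is linear in z (offset below the
        # 2-D slice radius because neighboring rings bulge into the cone)
        st = cone_structure(r0=3.0, r1=6.0, z_max=10.0)
        prof = pore_radius_profile(single_frame_traj(st), z_step=1.0,
                                   n_snapshots=1, search_radius=7.0,
                                   z_range=(1.0, 9.0))
        slope, intercept = np.polyfit(prof.z, prof.mean_radius, 1)
        residuals = prof.mean_radius - (slope * prof.z + intercept)
        assert np.abs(residuals).max() <= 0.2
        assert slope == pytest.approx(0.3, abs=0.05)

    def test_fine_grid_oracle_agreement(self):
        st = cylinder_structure(inner_radius=5.0)
        # one slice, deliberately off-center start
        prof = pore_radius_profile(single_frame_traj(st), z_step=1.0,
                                   n_snapshots=1, search_radius=4.0,
                                   axis_xy=(0.7, -0.4), z_range=(10.0, 10.0))
        oracle = brute_force_pore_radius(
            10.0, st.coords, np.array([a.vdw_radius for a in st.atoms]),
            np.array([0.7, -0.4]), 4.0, step=0.02)
        assert abs(prof.mean_radius[0] - oracle) <= 0.05

    def test_radius_shrinks_when_atoms_added(self):
        outer = cylinder_structure(inner_radius=6.0)
        inner = cylinder_structure(inner_radius=4.0)
        both_atoms = outer.atoms + [
            type(a)(serial=a.serial + outer.n_atoms, name=a.name,
                    element=a.element, residue_name=a.residue_name,
                    residue_id=a.residue_id + outer.n_atoms, chain=a.chain,
                    is_protein=a.is_protein, vdw_radius=a.vdw_radius)
            for a in inner.atoms]
        from mfskit.structures import Structure

        nested = Structure(atoms=both_atoms,
                           coords=np.vstack([outer.coords, inner.coords]))
        kw = dict(z_step=2.0, n_snapshots=1, search_radius=4.0,
                  z_range=(6.0, 14.0))
        r_outer = pore_radius_profile(single_frame_traj(outer), **kw).mean_radius
        r_nested = pore_radius_profile(single_frame_traj(nested), **kw).mean_radius
        assert np.all(r_nested <= r_outer + 1e-9)

    def test_empty_slab_capped(self):
        st = cylinder_structure(z_max=5.0)
        prof = pore_radius_profile(single_frame_traj(st), z_step=1.0,
                                   n_snapshots=1, search_radius=4.0,
                                   cap=15.0, z_range=(40.0, 40.0))
        assert prof.capped[0]
        assert prof.mean_radius[0] == 15.0


class TestDCCM:
    def _traj(self, disp_a, disp_b, base=None):
        n = len(disp_a)
        if base is None:
            base = np.array([[0.0, 0, 0], [20.0, 0, 0], [0, 20.0, 0],
                             [0, 0, 20.0]])
        frames = np.repeat(base[None], n, axis=0)
        frames[:, 0] += disp_a
        frames[:, 1] += disp_b
        return Trajectory(topology=ca_structure(base), frames=frames)

    def test_identical_displacements_plus_one(self):
        rng = np.random.default_rng(0)
        d = rng.normal(scale=0.01, size=(50, 3))
        m = dccm(self._traj(d, d), range(4), superpose=False)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_opposite_displacements_minus_one(self):
        rng = np.random.default_rng(1)
        d = rng.normal(scale=0.01, size=(50, 3))
        m = dccm(self._traj(d, -d), range(4), superpose=False)
        assert m.values[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_atom_flagged_not_propagated(self):
        rng = np.random.default_rng(2)
        d = rng.normal(scale=0.01, size=(50, 3))
        m = dccm(self._traj(d, np.zeros((50, 3))), range(4),
                 superpose=False)
        assert not m.defined[0, 1]
        # atoms 2,3 also static; the 0-0 diagonal stays defined
        assert m.defined[0, 0] and m.values[0, 0] == 1.0

    def test_independent_noise_bound(self):
        rng = np.random.default_rng(0)
        n_atoms, n_frames = 200, 5000
        base = rng.uniform(-40, 40, (n_atoms, 3))
        frames = base[None] + rng.normal(0, 0.1, (n_frames, n_atoms, 3))
        traj = Trajectory(topology=ca_structure(base), frames=frames)
        m = dccm(traj, range(n_atoms))
        off = m.values[~np.eye(n_atoms, dtype=bool)]
        assert np.abs(off).max() < 0.05
        assert np.allclose(np.diag(m.values), 1.0, atol=1e-9)
        assert np.allclose(m.values, m.values.T, atol=1e-12)

    def test_rigid_motion_invariance(self, bundle_and_map):
        bundle, _ = bundle_and_map
        rng = np.random.default_rng(3)
        frames = bundle.coords[None] + rng.normal(
            0, 0.2, (30, bundle.n_atoms, 3))
        traj = Trajectory(topology=bundle, frames=frames)
        m1 = dccm(traj, range(50))
        rot = Rotation.from_euler("xyz", [30, 40, 50], degrees=True).as_matrix()
        moved = np.einsum("fad,ed->fae", frames, rot) + np.array([4.0, 5, 6])
        m2 = dccm(Trajectory(topology=bundle, frames=moved), range(50))
        assert np.abs(m1.values - m2.values).max() <= 1e-6


def test_gate_selection_sides(bundle_and_map):
    bundle, cmap = bundle_and_map
    top = gate_selection(bundle, cmap, 1, side="extracellular")
    bottom = gate_selection(bundle, cmap, 1, side="intracellular")
    assert bundle.coords[top, 2].mean() > bundle.coords[bottom, 2].mean()
    assert len(top) == 8 and not set(top) & set(bottom)
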