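import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfskit import synthetic
from mfskit.interactions import (
    ConfigurationError, HBondCriteria, charge_relay_summary,
    classify_salt_bridges, contact_map, detect_hbonds_frame,
    find_donors_acceptors, interaction_fractions,
)
from mfskit.core import MotifHit
from mfskit.structures import AtomRecord, Structure, Trajectory
from mfskit.synthetic import _rec, hbond_triplet
from oracles import brute_force_contacts, brute_force_hbonds


def _triplet_structure(dist, angle):
    d, h, a = hbond_triplet(dist, angle)
    atoms = [_rec(1, "OG", "O", "SER", 1), _rec(2, "HG", "H", "SER", 1),
             _rec(3, "OE1", "O", "GLU", 2)]
    return Structure(atoms=atoms, coords=np.array([d, h, a]))


class TestHBondDetection:
    @pytest.mark.parametrize("dist,angle,expected", [
        (2.9, 170.0, 1),   # inside both cutoffs
        (3.1, 170.0, 0),   # distance cutoff violated
        (2.5, 120.0, 0),   # angle cutoff violated
        (3.0, 135.0, 1),   # exactly at both cutoffs (inclusive)
    ])
    def test_cutoff_decisions(self, dist, angle, expected):
        stx = _triplet_structure(dist, angle)
        events = detect_hbonds_frame(stx, [(0, 1)], [2])
        assert len(events) == expected

    def test_event_metadata(self):
        stx = _triplet_structure(2.8, 160.0)
        ev = detect_hbonds_frame(stx, [(0, 1)], [2], frame=7)[0]
        assert ev.donor == (1, "OG") and ev.acceptor == (2, "OE1")
        assert ev.hydrogen == "HG" and ev.frame == 7

    def test_hydrogen_acceptor_distance_mode(self):
        # D...A = 3.2 but H...A = 2.2: detected only in H-A mode
        stx = _triplet_structure(3.2, 180.0)
        assert not detect_hbonds_frame(stx, [(0, 1)], [2])
        crit = HBondCriteria(max_da_distance=3.0,
                             distance_mode="hydrogen-acceptor")
        assert len(detect_hbonds_frame(stx, [(0, 1)], [2], crit)) == 1

    def test_intra_residue_pairs_ignored(self):
        d, h, a = hbond_triplet(2.8, 170.0)
        atoms = [_rec(1, "OG", "O", "SER", 1), _rec(2, "HG", "H", "SER", 1),
                 _rec(3, "O", "O", "SER", 1)]
        stx = Structure(atoms=atoms, coords=np.array([d, h, a]))
        assert detect_hbonds_frame(stx, [(0, 1)], [2]) == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_matches_brute_force_on_random_geometries(self, seed):
        rng = np.random.default_rng(seed)
        n_d, n_a = 6, 8
        atoms = []
        coords = []
        donors, acceptors = [], []
        for k in range(n_d):
            d = rng.uniform(-6, 6, 3)
            h = d + rng.normal(size=3) * 0.0 + _unit(rng)
            atoms += [_rec(2 * k + 1, "NH1", "N", "ARG", k + 1),
                      _rec(2 * k + 2, "HH11", "H", "ARG", k + 1)]
            coords += [d, h]
            donors.append((2 * k, 2 * k + 1))
        for j in range(n_a):
            atoms.append(_rec(2 * n_d + j + 1, "OE1", "O", "GLU", 100 + j))
            coords.append(rng.uniform(-6, 6, 3))
            acceptors.append(2 * n_d + j)
        stx = Structure(atoms=atoms, coords=np.array(coords))
        events = detect_hbonds_frame(stx, donors, acceptors)
        got = set()
        for ev in events:
            d_idx = next(i for i, a in enumerate(stx.atoms)
                         if (a.residue_id, a.name) == ev.donor)
            a_idx = next(i for i, a in enumerate(stx.atoms)
                         if (a.residue_id, a.name) == ev.acceptor)
            got.add((d_idx, d_idx + 1, a_idx))
        same_res = lambda i, j: (stx.atoms[i].residue_id
                                 == stx.atoms[j].residue_id)
        expected = brute_force_hbonds(stx.coords, donors, acceptors,
                                      3.0, 135.0, same_res)
        assert got == expected


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestFractions:
    def test_seven_of_ten_frames(self):
        stx = _triplet_structure(2.8, 170.0)
        frames = np.repeat(stx.coords[None], 10, axis=0)
        frames[7:, 2, 2] += 10.0  # break the bond in the last 3 frames
        traj = Trajectory(topology=stx, frames=frames)
        table = interaction_fractions(traj, [(0, 1)], [2])
        assert table.fractions[(1, 2)] == pytest.approx(0.7)

    def test_salt_bridge_double_bond_fraction_two(self):
        traj, donors, acceptors = synthetic.build_charge_relay_fixture()
        table = interaction_fractions(traj, donors, acceptors)
        assert table.fractions[(162, 212)] == pytest.approx(2.0)
        assert table.fractions[(219, 447)] == pytest.approx(1.0)

    def test_threshold_drops_rare_pairs_from_report(self):
        traj, donors, acceptors = synthetic.build_charge_relay_fixture()
        table = interaction_fractions(traj, donors, acceptors, threshold=0.1)
        assert table.fractions[(218, 506)] == pytest.approx(0.05)
        assert (218, 506) not in table.reported()
        assert (162, 212) in table.reported()

    def test_indicator_mode_caps_at_one(self):
        traj, donors, acceptors = synthetic.build_charge_relay_fixture()
        table = interaction_fractions(traj, donors, acceptors,
                                      mode="indicator")
        assert table.fractions[(162, 212)] == pytest.approx(1.0)

    def test_frame_order_permutation_invariant(self):
        traj, donors, acceptors = synthetic.build_charge_relay_fixture()
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        shuffled = Trajectory(topology=traj.topology,
                              frames=traj.frames[perm])
        t1 = interaction_fractions(traj, donors, acceptors)
        t2 = interaction_fractions(shuffled, donors, acceptors)
        assert t1.fractions == t2.fractions


class TestSaltBridges:
    def test_arg_glu_flagged(self):
        traj, donors, acceptors = synthetic.build_charge_relay_fixture()
        table = interaction_fractions(traj, donors, acceptors)
        flags = classify_salt_bridges(table)
        assert flags[(162, 212)] is True    # Arg sidechain - Glu sidechain
        assert flags[(219, 447)] is True
        assert flags[(270, 271)] is False   # Ser donor: H-bond, not salt bridge

    def test_backbone_only_not_salt_bridge(self):
        d, h, a = hbond_triplet(2.8, 170.0)
        atoms = [_rec(1, "N", "N", "ARG", 10), _rec(2, "H", "H", "ARG", 10),
                 _rec(3, "O", "O", "GLU", 20)]
        stx = Structure(atoms=atoms, coords=np.array([d, h, a]))
        traj = Trajectory(topology=stx, frames=stx.coords[None])
        table = interaction_fractions(traj, [(0, 1)], [2])
        assert table.fractions[(10, 20)] == 1.0
        assert classify_salt_bridges(table)[(10, 20)] is False


class TestContacts:
    def _two_residue_traj(self, gap):
        atoms = [_rec(1, "CB", "C", "ALA", 1), _rec(2, "CB", "C", "ALA", 2)]
        stx = Structure(atoms=atoms,
                        coords=np.array([[0.0, 0, 0], [gap, 0, 0]]))
        return Trajectory(topology=stx,
                          frames=np.repeat(stx.coords[None], 4, axis=0))

    def test_contact_inside_cutoff(self):
        m, _, _ = contact_map(self._two_residue_traj(3.9), [1], [2])
        assert m[0, 0] == pytest.approx(1.0)

    def test_no_contact_outside_cutoff(self):
        m, _, _ = contact_map(self._two_residue_traj(4.1), [1], [2])
        assert m[0, 0] == 0.0

    def test_partial_fraction(self):
        traj = self._two_residue_traj(3.5)
        frames = traj.frames.copy()
        frames = np.repeat(frames[:1], 10, axis=0)
        frames[3:, 1, 0] = 50.0  # apart in 7 of 10 frames
        traj = Trajectory(topology=traj.topology, frames=frames)
        m, _, _ = contact_map(traj, [1], [2])
        assert m[0, 0] == pytest.approx(0.3)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(6)
        n_res, atoms_per = 20, 5
        atoms, coords = [], []
        serial = 0
        for r in range(1, n_res + 1):
            center = rng.uniform(-15, 15, 3)
            for k in range(atoms_per):
                serial += 1
                atoms.append(_rec(serial, f"C{k}", "C", "ALA", r))
                coords.append(center + rng.normal(scale=1.5, size=3))
        stx = Structure(atoms=atoms, coords=np.array(coords))
        traj = Trajectory(topology=stx, frames=stx.coords[None])
        group_a = list(range(1, 11))
        group_b = list(range(11, 21))
        m, _, _ = contact_map(traj, group_a, group_b, cutoff=4.0)
        for i, ra in enumerate(group_a):
            idx_a = [k for k, a in enumerate(atoms) if a.residue_id == ra]
            for j, rb in enumerate(group_b):
                idx_b = [k for k, a in enumerate(atoms) if a.residue_id == rb]
                expected = brute_force_contacts(stx.coords, idx_a, idx_b, 4.0)
                assert m[i, j] == (1.0 if expected else 0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            contact_map(self._two_residue_traj(3.0), [], [1])


N_HITS = [
    MotifHit("A-motif/N", 153, 162, "GYLADRLGRR"),
    MotifHit("EX6R/N", 212, 219, "EWMPIHTR"),
    MotifHit("PETL/N", 269, 275, "IESARWH"),
    MotifHit("A-motif/C", 390, 395, "NSLGRR"),
    MotifHit("EX6R/C", 447, 454, "ELYPTMIR"),
    MotifHit("PETL/C", 505, 508, "PETL"),
]


class TestChargeRelay:
    def _table(self, fractions):
        from mfskit.interactions import FractionTable

        return FractionTable(fractions=dict(fractions), n_frames=10,
                             pair_atoms={p: set() for p in fractions})

    def test_partition_intra_vs_inter(self):
        table = self._table({(162, 212): 2.0, (219, 447): 1.0})
        rep = charge_relay_summary(table, N_HITS)
        assert len(rep.intra_bundle) == 1 and len(rep.inter_bundle) == 1
        assert rep.intra_bundle[0]["residues"] == (162, 212)
        assert rep.inter_bundle[0]["residues"] == (219, 447)

    def test_empty_table_keeps_triads(self):
        rep = charge_relay_summary(self._table({}), N_HITS)
        assert rep.intra_bundle == [] and rep.inter_bundle == []
        assert set(rep.triads["N"]) == {"A-motif", "EX6R", "PETL"}
        assert rep.triads["C"]["PETL"] == (505, 508)

    def test_residue_outside_motifs_is_extension(self):
        table = self._table({(162, 300): 0.5})
        rep = charge_relay_summary(table, N_HITS)
        assert len(rep.tmh_extensions) == 1
        assert rep.intra_bundle == [] and rep.inter_bundle == []

    def test_missing_motif_raises(self):
        with pytest.raises(ConfigurationError, match="PETL"):
            charge_relay_summary(self._table({}), N_HITS[:5])

    def test_end_to_end_fixture_partition(self):
        traj, donors, acceptors = synthetic.build_charge_relay_fixture()
        table = interaction_fractions(traj, donors, acceptors)
        rep = charge_relay_summary(table, N_HITS)
        intra = {e["residues"] for e in rep.intra_bundle}
        inter = {e["residues"] for e in rep.inter_bundle}
        assert (162, 212) in intra and (270, 271) in intra
        assert inter == {(219, 447)}
        assert all(e["salt_bridge"] for e in rep.inter_bundle)


def test_find_donors_acceptors_full_atom():
    # a serine with hydroxyl hydrogen and backbone N-H / C=O
    atoms = [
        _rec(1, "N", "N", "SER", 1), _rec(2, "H", "H", "SER", 1),
        _rec(3, "CA", "C", "SER", 1), _rec(4, "C", "C", "SER", 1),
        _rec(5, "O", "O", "SER", 1), _rec(6, "OG", "O", "SER", 1),
        _rec(7, "HG", "H", "SER", 1),
    ]
    stx = Structure(atoms=atoms, coords=np.zeros((7, 3)) + np.arange(7)[:, None])
    donors, acceptors = find_donors_acceptors(stx)
    donor_heavies = {stx.atoms[d].name for d, _ in donors}
    assert donor_heavies == {"N", "OG"}
    assert {stx.atoms[a].name for a in acceptors} == {"O", "OG"}


def test_missing_hydrogen_is_configuration_error():
    atoms = [_rec(1, "OG", "O", "SER", 1)]  # hydroxyl without HG
    stx = Structure(atoms=atoms, coords=np.zeros((1, 3)))
    with pytest.raises(ConfigurationError, match="SER1:OG"):
        find_donors_acceptors(stx)
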