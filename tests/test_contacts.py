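import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import oracle_hbonds, oracle_salt_bridges, random_contact_system
from mdpost.contacts import (
    ContactTimeSeries,
    HBondCriteria,
    SaltBridgeCriteria,
    contact_timeseries,
    detect_hbonds,
    detect_salt_bridges,
)
from mdpost.io_structures import Atom, Topology, Trajectory


def _dha_system(da_dist, dha_angle_deg):
    """Donor-H...acceptor triple with exact distance and angle."""
    atoms = [
        Atom(index=0, name="N", element="N", residue_name="LIG", residue_index=1),
        Atom(index=1, name="H", element="H", residue_name="LIG", residue_index=1),
        Atom(index=2, name="O", element="O", residue_name="SER", residue_index=2),
    ]
    topo = Topology(atoms=atoms, bonds=[(0, 1)])
    topo.assign_donors_acceptors()
    d = np.zeros(3)
    h = np.array([0.1, 0.0, 0.0])
    # place acceptor so that the D-H-A angle is exactly dha_angle_deg and
    # |D-A| is exactly da_dist: solve on the H-centered triangle
    theta = np.radians(dha_angle_deg)
    u_hd = -np.array([1.0, 0.0, 0.0])  # H->D direction
    # rotate u_hd by theta in the xy-plane to get H->A direction
    u_ha = np.array([np.cos(theta) * u_hd[0] - np.sin(theta) * u_hd[1],
                     np.sin(theta) * u_hd[0] + np.cos(theta) * u_hd[1], 0.0])
    # distance from H along u_ha such that |D-A| = da_dist (law of cosines)
    hd = 0.1
    b = -2 * hd * np.cos(theta)
    ha = (-b + np.sqrt(b * b - 4 * (hd * hd - da_dist**2))) / 2
    a = h + ha * u_ha
    frame = np.array([d, h, a])
    assert np.linalg.norm(frame[2] - frame[0]) == pytest.approx(da_dist, abs=1e-12)
    return topo, frame


class TestHBondCriteria:
    def test_satisfying_geometry_detected(self):
        topo, frame = _dha_system(0.30, 170.0)
        assert detect_hbonds(frame, topo) == {(0, 1, 2)}

    def test_distance_beyond_cutoff_rejected(self):
        topo, frame = _dha_system(0.36, 170.0)
        assert detect_hbonds(frame, topo) == set()

    def test_boundary_strictness(self):
        # exactly 0.35 nm and exactly 150 deg both fail the strict criteria
        topo, frame = _dha_system(0.35, 170.0)
        assert detect_hbonds(frame, topo) == set()
        topo, frame = _dha_system(0.30, 150.0)
        assert detect_hbonds(frame, topo) == set()
        topo, frame = _dha_system(0.30, 150.0 + 1e-6)
        assert detect_hbonds(frame, topo) == {(0, 1, 2)}

    def test_empty_scope_distinguished_from_zero_contacts(self):
        atoms = [Atom(index=0, name="C1", element="C", residue_name="UNK", residue_index=1),
                 Atom(index=1, name="C2", element="C", residue_name="UNK", residue_index=2)]
        topo = Topology(atoms=atoms)
        topo.assign_donors_acceptors()
        with pytest.raises(ValueError, match="scope"):
            detect_hbonds(np.zeros((2, 3)), topo)

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_da_distance=1.5)
        with pytest.raises(ValueError):
            HBondCriteria(min_dha_angle=0.0)


def _pc_system(resname, atom_name, dist):
    atoms = [
        Atom(index=0, name="P", element="P", residue_name="LIG", residue_index=1),
        Atom(index=1, name=atom_name, element=atom_name[0], residue_name=resname, residue_index=122),
    ]
    frame = np.array([[0.0, 0.0, 0.0], [dist, 0.0, 0.0]])
    return Topology(atoms=atoms), frame


class TestSaltBridges:
    def test_lys_within_cutoff(self):
        topo, frame = _pc_system("LYS", "NZ", 0.69)
        assert detect_salt_bridges(frame, topo) == {(0, 1)}

    def test_arg_beyond_cutoff(self):
        topo, frame = _pc_system("ARG", "CZ", 0.71)
        assert detect_salt_bridges(frame, topo) == set()

    def test_cutoff_inclusive_at_exactly_0_7(self):
        topo, frame = _pc_system("LYS", "NZ", 0.7)
        assert detect_salt_bridges(frame, topo) == {(0, 1)}

    def test_unresolvable_atoms_raise(self):
        atoms = [Atom(index=0, name="CA", element="C", residue_name="GLY", residue_index=1)]
        with pytest.raises(ValueError, match="empty scope"):
            detect_salt_bridges(np.zeros((1, 3)), Topology(atoms=atoms))


class TestPlantedFixture:
    def test_planted_recovery_and_oracle(self, toy_complex_default):
        toy = toy_complex_default
        frame = toy.trajectory.coordinates[0]
        hb = detect_hbonds(frame, toy.topology, scope="ligand-all")
        assert len(hb) == toy.ledger["n_hbonds_per_frame"] == 7
        assert hb == {tuple(t) for t in toy.ledger["expected_hbond_triples"]}
        assert hb == oracle_hbonds(frame, toy.topology)
        sb = detect_salt_bridges(frame, toy.topology)
        assert len(sb) == toy.ledger["n_salt_bridges_per_frame"] == 4
        assert sb == oracle_salt_bridges(frame, toy.topology)


class TestPropertyOracleEquivalence:
    @pytest.mark.parametrize("seed", range(200))
    def test_matches_bruteforce_on_random_systems(self, seed):
        n_atoms = 300 if seed % 50 == 49 else None  # a few large systems, cap 300
        topo, frame = random_contact_system(seed, n_atoms)
        crit = HBondCriteria()
        assert detect_hbonds(frame, topo, crit) == oracle_hbonds(
            frame, topo, crit.max_da_distance, crit.min_dha_angle
        )
        assert detect_salt_bridges(frame, topo) == oracle_salt_bridges(frame, topo)

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_invariant_under_rigid_motion(self, seed):
        topo, frame = random_contact_system(seed)
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        moved = frame @ rot.T + np.array([1.0, -2.0, 0.5])
        assert detect_hbonds(frame, topo) == detect_hbonds(moved, topo)
        assert detect_salt_bridges(frame, topo) == detect_salt_bridges(moved, topo)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotonic_in_cutoffs(self, seed):
        topo, frame = random_contact_system(seed)
        loose_hb = HBondCriteria(max_da_distance=0.45)
        assert detect_hbonds(frame, topo) <= detect_hbonds(frame, topo, loose_hb)
        loose_sb = SaltBridgeCriteria(max_distance=0.9)
        assert detect_salt_bridges(frame, topo) <= detect_salt_bridges(frame, topo, loose_sb)


class TestContactTimeseries:
    def _static_traj(self, topo, frame, n):
        return Trajectory(np.repeat(frame[None], n, axis=0))

    def test_constant_series(self):
        topo, frame = _dha_system(0.30, 170.0)
        traj = self._static_traj(topo, frame, 10)
        ts = contact_timeseries(traj, topo, detect_hbonds)
        assert ts.mean_count == 1.0
        assert ts.error == 0.0
        assert list(ts.per_partner_occupancy.values()) == [1.0]

    def test_alternating_counts_mean(self):
        topo, frame_on = _dha_system(0.30, 170.0)
        _, frame_off = _dha_system(0.40, 170.0)
        frames = np.array([frame_on if i % 2 == 0 else frame_off for i in range(10)])
        ts = contact_timeseries(Trajectory(frames), topo, detect_hbonds)
        assert list(ts.per_frame_counts) == [1, 0] * 5
        assert ts.mean_count == pytest.approx(0.5)

    def test_planted_counts_match_direct_recount(self, toy_complex_default):
        toy = toy_complex_default
        ts = contact_timeseries(toy.trajectory, toy.topology, detect_hbonds, {"scope": "ligand-all"})
        expected = np.array(
            [len(oracle_hbonds(f, toy.topology)) for f in toy.trajectory.coordinates], dtype=float
        )
        assert np.array_equal(ts.per_frame_counts, expected)
        assert ts.mean_count == pytest.approx(expected.mean())

    def test_short_series_error_zero_with_warning(self, caplog):
        import logging

        topo, frame = _dha_system(0.30, 170.0)
        with caplog.at_level(logging.WARNING):
            ts = contact_timeseries(self._static_traj(topo, frame, 1), topo, detect_hbonds)
        assert ts.error == 0.0
        assert "too short" in caplog.text

    def test_occupancy_bounds_and_ranking(self, toy_complex_default):
        toy = toy_complex_default
        ts = contact_timeseries(toy.trajectory, toy.topology, detect_salt_bridges)
        assert isinstance(ts, ContactTimeSeries)
        for occ in ts.per_partner_occupancy.values():
            assert 0.0 <= occ <= 1.0
        ranked = ts.ranked_partners()
        assert sorted(ranked, key=lambda kv: (-kv[1], kv[0])) == ranked
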