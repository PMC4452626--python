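import math

import numpy as np
import pytest

from conftest import oracle_ligand_energy, oracle_pair, random_energy_system
from mdpost.energetics import (
    COULOMB_CONSTANT_KCAL,
    InteractionEnergySeries,
    LIEParameters,
    NonbondedParams,
    combine_poses,
    dissociation_ratio,
    lie_free_energy,
    ligand_environment_energy,
    pair_energy,
    pose_preference,
)
from mdpost.io_structures import Atom, Topology

RT298 = 1.9872e-3 * 298.0


def _atom(i, charge=0.0, eps=0.0, rmh=0.0):
    return Atom(index=i, name=f"A{i}", element="C", residue_name="UNK", residue_index=i + 1,
                charge=charge, lj_epsilon=eps, lj_rmin_half=rmh)


class TestPairEnergy:
    def test_zero_beyond_cutoff(self):
        a, b = _atom(0, charge=1.0, eps=0.2, rmh=0.2), _atom(1, charge=1.0, eps=0.2, rmh=0.2)
        assert pair_energy(a, b, 1.3) == (0.0, 0.0)
        assert pair_energy(a, b, 1.2) == (0.0, 0.0)

    def test_lj_root_at_sigma(self):
        a, b = _atom(0, eps=0.3, rmh=0.19), _atom(1, eps=0.12, rmh=0.21)
        rmin = 0.19 + 0.21
        sigma = rmin * 2 ** (-1 / 6)
        v_vdw, v_el = pair_energy(a, b, sigma)
        assert v_vdw == pytest.approx(0.0, abs=1e-12)
        assert v_el == 0.0

    def test_lj_minimum_depth_at_rmin(self):
        a, b = _atom(0, eps=0.25, rmh=0.2), _atom(1, eps=0.16, rmh=0.2)
        v_vdw, _ = pair_energy(a, b, 0.4)
        assert v_vdw == pytest.approx(-math.sqrt(0.25 * 0.16), rel=1e-12)

    def test_coulomb_direct_evaluation(self):
        a, b = _atom(0, charge=1.0), _atom(1, charge=1.0)
        _, v_el = pair_energy(a, b, 0.5)
        assert v_el == pytest.approx(33.2063711 / 0.5, rel=1e-12)
        assert v_el == pytest.approx(66.4127422, abs=1e-6)

    def test_zero_separation_raises(self):
        with pytest.raises(ValueError):
            pair_energy(_atom(0), _atom(1), 0.0)

    @pytest.mark.parametrize("r", [0.3, 0.7, 1.05, 1.15, 1.19])
    def test_matches_independent_formula(self, r):
        a, b = _atom(0, charge=0.7, eps=0.2, rmh=0.21), _atom(1, charge=-0.4, eps=0.05, rmh=0.17)
        got = pair_energy(a, b, r)
        ref = oracle_pair(0.7, -0.4, 0.2, 0.05, 0.21, 0.17, r)
        assert got[0] == pytest.approx(ref[0], rel=1e-12, abs=1e-12)
        assert got[1] == pytest.approx(ref[1], rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("r0", [1.0, 1.2])
    def test_switching_continuity(self, r0):
        a, b = _atom(0, charge=0.9, eps=0.3, rmh=0.22), _atom(1, charge=-0.8, eps=0.2, rmh=0.2)
        for dr in (-1e-6, 1e-6):
            e0 = np.array(pair_energy(a, b, r0))
            e1 = np.array(pair_energy(a, b, r0 + dr))
            assert np.all(np.abs(e1 - e0) < 1e-4)

    def test_invalid_switch_window(self):
        with pytest.raises(ValueError):
            NonbondedParams(cutoff=1.0, switch_on=1.2)


class TestLigandEnvironmentEnergy:
    def test_single_pair_system(self):
        topo = Topology(atoms=[_atom(0, charge=0.5, eps=0.2, rmh=0.2), _atom(1, charge=-0.5, eps=0.1, rmh=0.18)])
        frame = np.array([[0.0, 0.0, 0.0], [0.45, 0.0, 0.0]])
        assert ligand_environment_energy(frame, topo, [0]) == pytest.approx(
            pair_energy(topo.atoms[0], topo.atoms[1], 0.45)
        )

    def test_all_zero_parameters(self):
        topo = Topology(atoms=[_atom(i) for i in range(6)])
        frame = np.random.default_rng(0).uniform(0, 1, size=(6, 3))
        assert ligand_environment_energy(frame, topo, [0, 1]) == (0.0, 0.0)

    def test_empty_selections_raise(self):
        topo = Topology(atoms=[_atom(0), _atom(1)])
        frame = np.zeros((2, 3))
        with pytest.raises(ValueError):
            ligand_environment_energy(frame, topo, [])
        with pytest.raises(ValueError):
            ligand_environment_energy(frame, topo, [0, 1])

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_bruteforce_double_sum(self, seed):
        n_atoms = 300 if seed % 50 == 49 else None
        topo, frame, ligand = random_energy_system(seed, n_atoms)
        got = ligand_environment_energy(frame, topo, ligand)
        ref = oracle_ligand_energy(frame, topo, ligand)
        assert got[0] == pytest.approx(ref[0], abs=1e-9)
        assert got[1] == pytest.approx(ref[1], abs=1e-9)


class TestLIE:
    def _series(self, mean_vdw, mean_el, n=10):
        return InteractionEnergySeries(v_vdw=np.full(n, mean_vdw), v_el=np.full(n, mean_el))

    def test_direct_formula(self):
        bound = self._series(-40.0, -20.0)
        unbound = self._series(-30.0, -15.0)
        res = lie_free_energy(bound, unbound)
        assert res.dg_bind == pytest.approx(0.18 * -10 + 0.09 * -5, abs=1e-12)
        assert res.dg_bind == pytest.approx(-2.25)
        assert res.error == 0.0
        assert res.kd == pytest.approx(math.exp(-2.25 / RT298), rel=1e-9)
        assert res.kd < 1.0  # negative dG => sub-unity Kd ratio

    def test_identical_series_zero(self):
        s = self._series(-33.0, -12.0)
        assert lie_free_energy(s, s).dg_bind == 0.0

    def test_linearity_in_deltas(self):
        res1 = lie_free_energy(self._series(-40, -20), self._series(-30, -15))
        res2 = lie_free_energy(self._series(-50, -25), self._series(-30, -15))
        # scaling both deltas by 2 scales dG by 2
        assert res2.dg_bind == pytest.approx(2 * res1.dg_bind, rel=1e-12)

    def test_error_propagation_quadrature(self):
        rng = np.random.default_rng(0)
        bound = InteractionEnergySeries(v_vdw=rng.normal(-40, 1, 1000), v_el=rng.normal(-20, 1, 1000))
        unbound = InteractionEnergySeries(v_vdw=rng.normal(-30, 1, 1000), v_el=rng.normal(-15, 1, 1000))
        res = lie_free_energy(bound, unbound)
        expected = math.sqrt(
            0.18**2 * (bound.error_vdw**2 + unbound.error_vdw**2)
            + 0.09**2 * (bound.error_el**2 + unbound.error_el**2)
        )
        assert res.error == pytest.approx(expected, rel=1e-12)


class TestCombinePoses:
    def test_single_pose_identity(self):
        assert combine_poses({"A": -7.3}) == pytest.approx(-7.3, abs=1e-12)

    def test_equal_poses_return_common_value(self):
        assert combine_poses({"A": -5.0, "B": -5.0}) == pytest.approx(-5.0, abs=1e-12)

    def test_two_pose_direct_evaluation(self):
        g = {"A": -8.0, "B": -6.4}
        expected = -RT298 * math.log(0.5 * (math.exp(8.0 / RT298) + math.exp(6.4 / RT298)))
        got = combine_poses(g)
        assert got == pytest.approx(expected, rel=1e-12)
        # equal-prior exponential average lies between the best pose and
        # best pose + RT ln N
        assert -8.0 <= got <= -8.0 + RT298 * math.log(2) + 1e-12

    def test_permutation_invariance_and_bounds(self):
        g = {"A": -9.1, "B": -7.0, "C": -8.2}
        assert combine_poses(g) == pytest.approx(combine_poses(dict(reversed(list(g.items())))), rel=1e-12)
        best = min(g.values())
        assert best <= combine_poses(g) <= best + RT298 * math.log(len(g))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            combine_poses({})


class TestKdRatios:
    def test_equal_free_energies_unity(self):
        assert dissociation_ratio(-7.0, -7.0) == pytest.approx(1.0)

    def test_twenty_fold(self):
        gap = RT298 * math.log(20)
        assert gap == pytest.approx(1.7741, abs=1e-4)
        assert dissociation_ratio(-9.0, -9.0 + gap) == pytest.approx(20.0, rel=1e-9)

    def test_three_fold(self):
        gap = RT298 * math.log(3)
        assert dissociation_ratio(-9.0, -9.0 + gap) == pytest.approx(3.0, rel=1e-9)

    def test_direction(self):
        assert dissociation_ratio(-8.0, -7.0) > 1.0
        assert dissociation_ratio(-7.0, -8.0) < 1.0

    def test_roundtrip_with_pose_preference(self):
        ddg = pose_preference(-9.0, -7.4)
        assert ddg == pytest.approx(1.6, abs=1e-12)
        ratio = dissociation_ratio(-9.0, -7.4)
        assert RT298 * math.log(ratio) == pytest.approx(ddg, abs=1e-9)

    def test_pose_preference_antisymmetry(self):
        assert pose_preference(-9.0, -7.4) == -pose_preference(-7.4, -9.0)
        assert pose_preference(-5.0, -5.0) == 0.0


class TestGroundTruthRecovery:
    def test_noiseless_recovery_exact(self):
        from mdpost.synthetic import EnergySeriesSpec, make_energy_series

        spec = EnergySeriesSpec(noise_sd=0.0, n_frames=100)
        bound, unbound = make_energy_series(spec)
        res = lie_free_energy(bound, unbound)
        assert res.dg_bind == pytest.approx(spec.ground_truth_dg(), abs=1e-12)
        assert res.dg_bind == pytest.approx(-2.25)

    def test_monte_carlo_recovery_within_three_errors(self):
        from mdpost.synthetic import EnergySeriesSpec, make_energy_series

        hits = 0
        for seed in range(100):
            spec = EnergySeriesSpec(noise_sd=2.0, autocorrelation=0.3, n_frames=5000, seed=seed)
            bound, unbound = make_energy_series(spec)
            res = lie_free_energy(bound, unbound)
            if abs(res.dg_bind - spec.ground_truth_dg()) <= 3 * res.error:
                hits += 1
        assert hits >= 95
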