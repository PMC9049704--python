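"""Work-weighted observables: weighted averages, hydrogen-bond counting,
pair energies, Kabsch RMSD and representative structures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmdkit.constants import KB, COULOMB_K
from asmdkit.fixtures import (gen_hairpin_pathway, gen_planted_hbond_config,
                              gen_staged_work_ensemble)
from asmdkit.observables import (AtomGroup, HBondCriterion, count_hbonds,
                                 hairpin_intrapeptide_groups, hbond_series,
                                 kabsch_rmsd, pair_energy_series,
                                 pair_interaction_energy,
                                 representative_structure, weighted_average)
from asmdkit.systems import HairpinParams, make_hairpin_system


from oracles import brute_force_hbond_count, quaternion_rmsd


class TestWeightedAverage:
    def test_equal_works_give_arithmetic_mean(self):
        assert weighted_average([2.0, 4.0], [1.7, 1.7], 300.0) == pytest.approx(3.0)

    def test_dominant_weight(self):
        assert weighted_average([2.0, 4.0], [0.0, 1e6], 300.0) == pytest.approx(2.0)

    def test_three_point_matches_direct_sum(self):
        beta = 1.0 / (KB * 300.0)
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([0.5, 1.0, 1.5])
        expected = np.sum(v * np.exp(-beta * w)) / np.sum(np.exp(-beta * w))
        assert weighted_average(v, w, 300.0) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_average([], [], 300.0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-50, 50)),
                    min_size=1, max_size=20))
    def test_bounded_by_inputs(self, pairs):
        values = [p[0] for p in pairs]
        works = [p[1] for p in pairs]
        a = weighted_average(values, works, 300.0)
        assert min(values) - 1e-9 <= a <= max(values) + 1e-9


class TestCountHBonds:
    def _triple(self, dist, angle_deg):
        d = np.array([0.0, 0.0, 0.0])
        a = np.array([dist, 0.0, 0.0])
        h = d + np.array([np.cos(np.radians(angle_deg)),
                          np.sin(np.radians(angle_deg)), 0.0])
        positions = np.stack([d, h, a])
        donors = AtomGroup("d", [0], hydrogens=[1])
        acceptors = AtomGroup("a", [2])
        return positions, donors, acceptors

    def test_bonded_within_criterion(self):
        assert count_hbonds(*self._triple(2.9, 10.0)) == 1

    def test_distance_boundary_is_inclusive(self):
        assert count_hbonds(*self._triple(3.0, 0.0)) == 1
        assert count_hbonds(*self._triple(3.1, 0.0)) == 0

    def test_angle_boundary_is_inclusive(self):
        assert count_hbonds(*self._triple(2.5, 40.0)) == 1
        assert count_hbonds(*self._triple(2.5, 45.1)) == 0

    def test_missing_hydrogens_rejected(self):
        pos, _, acc = self._triple(2.9, 10.0)
        with pytest.raises(ValueError):
            count_hbonds(pos, AtomGroup("d", [0]), acc)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        positions = rng.uniform(0, 8, (n * 2, 3))
        donors = AtomGroup("d", np.arange(n), hydrogens=np.arange(n, 2 * n))
        acceptors = AtomGroup("a", rng.permutation(2 * n)[:n])
        crit = HBondCriterion()
        assert count_hbonds(positions, donors, acceptors, crit) == \
            brute_force_hbond_count(positions, donors, acceptors, crit)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_planted_truth(self, seed):
        cfg = gen_planted_hbond_config(3 + seed, 5, seed=seed)
        assert count_hbonds(cfg.positions, cfg.donors, cfg.acceptors) == cfg.true_count


class TestHBondSeries:
    def test_recovers_planted_step_profile(self):
        counts = [4, 2, 1]
        fx = gen_staged_work_ensemble(3, 6, spread=1.0, seed=3,
                                      planted_counts=counts)
        series = hbond_series(fx.ensembles, fx.hbond_groups, temperature=300.0)
        for ens, planted in zip(fx.ensembles, counts):
            mask = np.isin(series.stage_of_point, [ens.stage_index])
            np.testing.assert_allclose(series.values[mask], planted)

    def test_weighting_differs_from_plain_mean_when_works_spread(self):
        fx = gen_staged_work_ensemble(1, 8, spread=3.0, seed=4)
        ens = fx.ensembles[0]
        # plant counts anticorrelated with works via the scalar observables
        values = np.argsort(np.argsort(ens.final_works)).astype(float)
        works = ens.final_works
        wavg = weighted_average(values, works, 300.0)
        assert wavg != pytest.approx(values.mean())
        assert wavg < values.mean()  # low-work trajectories dominate

    def test_pathway_fixture_hbonds_decay_along_pull(self):
        fx = gen_hairpin_pathway(n_stages=6, n_traj=4, seed=2, jitter=0.02)
        groups = hairpin_intrapeptide_groups(fx.provider)
        series = hbond_series(fx.ensembles, groups, temperature=300.0)
        # native basin starts fully bonded, fully unzipped by the end
        assert series.values[0] == pytest.approx(5.0)
        assert series.values[-1] == 0.0
        # monotone trend (tolerance one bond for jitter)
        running_min = np.minimum.accumulate(series.values)
        assert np.all(series.values - running_min <= 1.0)


class TestPairEnergies:
    def test_unit_charges_coulomb_closed_form(self):
        params = HairpinParams(epsilon_r=1.0, repulsion_eps=0.0)
        system, provider = make_hairpin_system(params=params)
        # isolate residue 8 from every contact partner, then place its charged
        # sidechain bead at the reference separation from the Glu5 charge
        pos = system.positions.copy()
        for idx in system.residue_particles(8):
            pos[idx] += np.array([50.0, 0.0, 0.0])
        i5 = provider.sidechain_index[5]
        i8 = provider.sidechain_index[8]
        pos[i8] = pos[i5] + np.array([COULOMB_K / 100.0, 0.0, 0.0])
        e = pair_interaction_energy(pos, system, 5, 8, provider)
        assert e == pytest.approx(-100.0, rel=1e-9)

    def test_neutral_far_pair_is_negligible(self, hairpin):
        system, provider = hairpin
        pos = system.positions.copy()
        for idx in system.residue_particles(10):
            pos[idx] += np.array([50.0, 0.0, 0.0])
        e = pair_interaction_energy(pos, system, 3, 10, provider)
        assert abs(e) < 1e-4

    def test_symmetric_in_arguments(self, hairpin, rng):
        system, provider = hairpin
        pos = system.positions + rng.normal(0, 0.3, system.positions.shape)
        assert pair_interaction_energy(pos, system, 2, 11, provider) == \
            pytest.approx(pair_interaction_energy(pos, system, 11, 2, provider))

    def test_series_zeroed_pair_is_identically_zero(self):
        fx = gen_hairpin_pathway(mutations=["E5L"], n_stages=4, n_traj=3, seed=1,
                                 bridge=False)
        series = pair_energy_series(fx.ensembles, fx.system, (5, 7), fx.provider)
        # residues 5 and 7 share no contact or charge pair; only the soft
        # excluded-volume term remains, negligible at strand distances
        assert np.abs(series.values).max() < 0.1

    def test_single_trajectory_series_is_unweighted(self):
        fx = gen_hairpin_pathway(n_stages=2, n_traj=1, seed=6)
        series = pair_energy_series(fx.ensembles, fx.system, (5, 12), fx.provider)
        ens = fx.ensembles[0]
        direct = fx.provider.pair_energy(
            ens.trajectories[0].frames,
            fx.system.residue_particles(5), fx.system.residue_particles(12))
        np.testing.assert_allclose(series.values[:len(direct)], direct)

    def test_k8l_bridge_outcompetes_e5l(self):
        k8l = gen_hairpin_pathway(mutations=["K8L"], seed=5)
        e5l = gen_hairpin_pathway(mutations=["E5L"], seed=5)
        s_k8l = pair_energy_series(k8l.ensembles, k8l.system, (5, 12), k8l.provider)
        s_e5l = pair_energy_series(e5l.ensembles, e5l.system, (5, 12), e5l.provider)
        assert s_k8l.values.min() < s_e5l.values.min()
        # under K8L the 5–12 series is the most negative tracked pair early on
        early = s_k8l.r_grid <= 12.0
        for pair in [(2, 11), (4, 9), (5, 7), (5, 8), (8, 10)]:
            other = pair_energy_series(k8l.ensembles, k8l.system, pair, k8l.provider)
            assert s_k8l.values[early].min() <= other.values[early].min() + 1e-9


class TestKabschRMSD:
    def test_identical_structures(self, rng):
        x = rng.normal(0, 3, (10, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        x = rng.normal(0, 3, (12, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        y = x @ rot.T + np.array([5.0, -2.0, 1.0])
        assert kabsch_rmsd(x, y) < 1e-8

    def test_four_point_matches_quaternion_oracle(self):
        ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0.3, 0.4, 1.8]])
        mov = ref + np.array([[0.2, -0.1, 0.05], [0, 0.3, 0], [-0.2, 0, 0.1],
                              [0.1, 0.1, -0.3]])
        assert kabsch_rmsd(ref, mov) == pytest.approx(
            quaternion_rmsd(ref, mov), abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_pairs_match_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        ref = rng.normal(0, 5, (n, 3))
        mov = rng.normal(0, 5, (n, 3))
        assert kabsch_rmsd(ref, mov) == pytest.approx(
            quaternion_rmsd(ref, mov), abs=1e-8)

    def test_simultaneous_rigid_motion_and_permutation_invariance(self, rng):
        x = rng.normal(0, 4, (15, 3))
        y = rng.normal(0, 4, (15, 3))
        base = kabsch_rmsd(x, y)
        theta = 1.1
        rot = np.array([[1.0, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        shift = np.array([1.0, 2.0, -3.0])
        assert kabsch_rmsd(x @ rot.T + shift, y @ rot.T + shift) == \
            pytest.approx(base, abs=1e-8)
        perm = rng.permutation(15)
        assert kabsch_rmsd(x[perm], y[perm]) == pytest.approx(base, abs=1e-10)

    def test_degenerate_selection_rejected(self):
        line = np.stack([np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
                         np.array([2.0, 0, 0])])
        with pytest.raises(ValueError):
            kabsch_rmsd(line, line + 0.1)

    def test_selection_restricts_superposition(self, rng):
        x = rng.normal(0, 3, (20, 3))
        y = x.copy()
        y[10:] += rng.normal(0, 2, (10, 3))
        assert kabsch_rmsd(x, y, selection=range(10)) < 1e-10
        assert kabsch_rmsd(x, y) > 0.1


class TestRepresentativeStructure:
    def test_stage_boundary_gives_final_frame(self):
        fx = gen_staged_work_ensemble(1, 3, seed=2, planted_counts=[2])
        ens = fx.ensembles[0]
        sel = ens.trajectories[ens.selected_index]
        got = representative_structure(ens, ens.boundaries[1])
        np.testing.assert_array_equal(got, sel.frames[-1])

    def test_between_frames_picks_nearer(self):
        fx = gen_staged_work_ensemble(1, 1, seed=2, planted_counts=[1])
        ens = fx.ensembles[0]
        r = ens.je_r
        target = r[2] + 0.3 * (r[3] - r[2])
        got = representative_structure(ens, target)
        np.testing.assert_array_equal(got, ens.trajectories[0].frames[2])

    def test_outside_span_rejected(self):
        fx = gen_staged_work_ensemble(1, 1, seed=2, planted_counts=[1])
        with pytest.raises(ValueError):
            representative_structure(fx.ensembles[0], 1e6)
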