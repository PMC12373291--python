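"""Energy terms: bonded dual parameter sets, excluded volume, pairing,
stacking, coaxial stacking, additivity and incremental bookkeeping."""

import numpy as np
import pytest

from cgdna.cg_model import (BasePairSet, CGConformation, Sequence, ideal_helix,
                            init_conformation, loop_reference_chain,
                            parse_sequence, reverse_complement)
from cgdna.electrostatics import ChargeState, solve_charge_fractions
from cgdna.ensemble import detect_base_pairs
from cgdna.forcefield import (RegionMap, base_pair_energy, base_stack_energy,
                              bonded_energy, coaxial_stack_energy,
                              excluded_volume_energy, mechanical_energy,
                              stems_of, total_energy, _wca_energy)

from conftest import rigid_copy


@pytest.fixture()
def helix_pairs(duplex6):
    return detect_base_pairs(duplex6)


class TestBondedEnergy:
    def test_zero_at_loop_equilibria(self, params):
        ref = loop_reference_chain(parse_sequence("ACGTACGT"))
        e = bonded_energy(ref, params, RegionMap.all_loop(8))
        assert e == pytest.approx(0.0, abs=1e-8)

    def test_harmonic_bond_stretch_closed_form(self, params):
        ref = loop_reference_chain(parse_sequence("ACGT"))
        x = ref.coords.copy()
        # stretch the C0-N0 bond by delta along its own axis: only that
        # bond term changes (N0 is terminal in the bonded graph except for
        # its angle/dihedral terms, so move along the bond axis only)
        delta = 0.3
        axis = x[2] - x[1]
        axis /= np.linalg.norm(axis)
        x[2] = x[2] + delta * axis
        stretched = CGConformation(ref.sequence, x)
        e = bonded_energy(stretched, params, RegionMap.all_loop(4))
        k = params.bonded_loop.bonds["CN"][1]
        assert e == pytest.approx(k * delta ** 2, rel=1e-6, abs=1e-9)

    def test_helix_set_scores_ideal_duplex_lower_than_loop_set(
            self, duplex6, params, helix_pairs):
        all_helix = RegionMap.from_pairs(duplex6.n_nt, helix_pairs)
        all_loop = RegionMap.all_loop(duplex6.n_nt)
        assert bonded_energy(duplex6, params, all_helix) \
            < bonded_energy(duplex6, params, all_loop)

    def test_region_map_shape_mismatch_raises(self, duplex6, params):
        with pytest.raises(ValueError):
            bonded_energy(duplex6, params, RegionMap.all_loop(5))


class TestExcludedVolume:
    def test_zero_beyond_contact(self, params):
        seq = Sequence("AA")
        coords = np.zeros((6, 3))
        coords[0:3] = [[0, 0, 0], [3.7, 0, 0], [4.7, 2.9, 0]]
        coords[3:6] = coords[0:3] + [100.0, 0, 0]
        conf = CGConformation(seq, coords, chain_breaks=frozenset({0}))
        assert excluded_volume_energy(conf, params) == 0.0

    def test_value_at_exact_contact_equals_wca_closed_form(self, params):
        # two P beads at r = sigma: WCA gives exactly epsilon
        sigma = np.array([3.8])
        e = _wca_energy(np.array([3.8]), sigma, params.nonbonded.exc_epsilon)
        assert e[0] == pytest.approx(params.nonbonded.exc_epsilon)

    def test_monotone_nonincreasing_in_distance(self, params):
        sigma = np.full(50, 3.8)
        d = np.linspace(1.5, 6.0, 50)
        e = _wca_energy(d, sigma, params.nonbonded.exc_epsilon)
        assert np.all(np.diff(e) <= 1e-12)

    def test_ideal_duplex_carries_no_repulsion(self, duplex6, params):
        assert excluded_volume_energy(duplex6, params) == pytest.approx(0.0)


class TestBasePairEnergy:
    def test_ideal_gc_pair_reaches_full_well_depth(self, params):
        dup = ideal_helix(Sequence("G"), Sequence("C"))
        pairs = BasePairSet([(0, 1)], dup)
        e = base_pair_energy(dup, pairs, params)
        assert e == pytest.approx(-params.nonbonded.bp_depth["GC"], rel=1e-9)

    def test_ideal_at_pair_reaches_full_well_depth(self, params):
        dup = ideal_helix(Sequence("A"), Sequence("T"))
        pairs = BasePairSet([(0, 1)], dup)
        assert base_pair_energy(dup, pairs, params) == pytest.approx(
            -params.nonbonded.bp_depth["AT"], rel=1e-9)

    def test_pair_beyond_cutoff_contributes_zero(self, params):
        dup = ideal_helix(Sequence("G"), Sequence("C"))
        x = dup.coords.copy()
        x[3:] += np.array([28.0, 0.0, 0.0])  # pull the strands apart
        far = CGConformation(dup.sequence, x, dup.chain_breaks)
        assert base_pair_energy(far, BasePairSet([(0, 1)], far), params) == 0.0

    def test_non_wc_pair_rejected(self, params):
        conf = init_conformation(parse_sequence("AAAAAGGGGG"), 3)
        bad = BasePairSet([(0, 9)])  # A-G, constructed without validation
        with pytest.raises((ValueError, KeyError)):
            base_pair_energy(conf, bad, params)


class TestBaseStackEnergy:
    def test_single_isolated_pair_has_no_stacking(self, params):
        dup = ideal_helix(Sequence("G"), Sequence("C"))
        assert base_stack_energy(dup, BasePairSet([(0, 1)], dup), params) == 0.0

    def test_two_stacked_pairs_give_tabulated_step_value(self, params):
        dup = ideal_helix(Sequence("GC"), Sequence("GC"))
        pairs = BasePairSet([(0, 3), (1, 2)], dup)
        e = base_stack_energy(dup, pairs, params)
        assert e == pytest.approx(-params.nonbonded.bs_depth["GC"], rel=1e-6)

    def test_invariant_under_rigid_motion(self, duplex6, params, helix_pairs, rng):
        e0 = base_stack_energy(duplex6, helix_pairs, params)
        moved = rigid_copy(duplex6, rng)
        assert base_stack_energy(moved, helix_pairs, params) == \
            pytest.approx(e0, abs=1e-9)


class TestCoaxialStackEnergy:
    @staticmethod
    def _two_stem_junction(gap: float = 0.0):
        """Two 3-bp duplexes stacked end to end along one helix axis,
        indexed as a single 12-nt chain with breaks (a junction mimic)."""
        a = parse_sequence("GCG")
        s1 = ideal_helix(a, Sequence(reverse_complement(a)))
        s2 = ideal_helix(a, Sequence(reverse_complement(a)))
        shift = np.array([0.0, 0.0, 3 * 3.38 + gap])
        # continue the helical twist across the junction (3 x 36 degrees)
        ang = np.deg2rad(108.0)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        coords = np.vstack([s1.coords, s2.coords @ rot.T + shift])
        seq = Sequence(s1.sequence.residues + s2.sequence.residues)
        conf = CGConformation(seq, coords,
                              chain_breaks=frozenset({2, 5, 8}))
        pairs = BasePairSet([(0, 5), (1, 4), (2, 3),
                             (6, 11), (7, 10), (8, 9)], conf)
        return conf, pairs

    def test_single_continuous_stem_contributes_zero(self, duplex6, params,
                                                     helix_pairs):
        assert coaxial_stack_energy(duplex6, helix_pairs, params) == 0.0

    def test_abutting_stems_rewarded(self, params):
        conf, pairs = self._two_stem_junction()
        assert len(stems_of(pairs)) == 2
        e = coaxial_stack_energy(conf, pairs, params)
        assert e < -0.1

    def test_reward_decays_to_zero_as_stems_separate(self, params):
        values = []
        for gap in (0.0, 2.0, 5.0, 10.0, 25.0):
            conf, pairs = self._two_stem_junction(gap)
            values.append(coaxial_stack_energy(conf, pairs, params))
        assert values[0] < values[1] < values[2] <= values[3] <= 0.0
        assert values[-1] == 0.0


class TestTotalEnergy:
    def test_far_apart_neutralized_nucleotides_reduce_to_bonded_energy(
            self, params, ion):
        seq = Sequence("AT")
        coords = np.array([[0, 0, 0], [3.7, 0, 0], [4.7, 2.9, 0],
                           [200, 0, 0], [203.7, 0, 0], [204.7, 2.9, 0]],
                          dtype=float)
        conf = CGConformation(seq, coords, chain_breaks=frozenset({0}))
        regions = RegionMap.all_loop(2)
        charge = ChargeState.neutral(2)
        pairs = BasePairSet([])
        e = total_energy(conf, pairs, regions, params, ion, 25.0, charge)
        assert e == pytest.approx(bonded_energy(conf, params, regions), abs=1e-9)

    def test_additivity_of_components(self, duplex6, params, ion, helix_pairs):
        regions = RegionMap.from_pairs(duplex6.n_nt, helix_pairs)
        charge = solve_charge_fractions(duplex6, ion)
        from cgdna.electrostatics import electrostatic_energy
        total = total_energy(duplex6, helix_pairs, regions, params, ion,
                             25.0, charge)
        parts = (bonded_energy(duplex6, params, regions)
                 + excluded_volume_energy(duplex6, params)
                 + base_pair_energy(duplex6, helix_pairs, params)
                 + base_stack_energy(duplex6, helix_pairs, params)
                 + coaxial_stack_energy(duplex6, helix_pairs, params)
                 + electrostatic_energy(duplex6, charge, ion))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_every_term_invariant_under_rigid_motion(self, duplex6, params,
                                                     helix_pairs, rng):
        regions = RegionMap.from_pairs(duplex6.n_nt, helix_pairs)
        for _ in range(5):
            moved = rigid_copy(duplex6, rng)
            assert mechanical_energy(moved, helix_pairs, regions, params) == \
                pytest.approx(mechanical_energy(duplex6, helix_pairs, regions,
                                                params), abs=1e-8)

    def test_ideal_helix_is_near_a_local_minimum(self, duplex6, params, ion,
                                                 helix_pairs, rng):
        """Small random perturbations never lower the all-terms energy."""
        regions = RegionMap.from_pairs(duplex6.n_nt, helix_pairs)
        charge = solve_charge_fractions(duplex6, ion)
        e0 = total_energy(duplex6, helix_pairs, regions, params, ion, 25.0,
                          charge)
        for _ in range(20):
            noisy = CGConformation(
                duplex6.sequence,
                duplex6.coords + rng.normal(scale=0.05,
                                            size=duplex6.coords.shape),
                duplex6.chain_breaks)
            e = total_energy(noisy, helix_pairs, regions, params, ion, 25.0,
                             charge)
            assert e > e0 - 1e-6


class TestIncrementalBookkeeping:
    def test_delta_equals_full_recomputation_on_1000_random_moves(
            self, params, ion):
        from cgdna.forcefield import _exclusion_mask
        from cgdna.sampler import (base_twist_move, bead_displacement_move,
                                   incremental_delta, pivot_move)
        seq = parse_sequence("GCGCTTTTGCGC")
        conf = init_conformation(seq, 9)
        rng = np.random.default_rng(77)
        charge = solve_charge_fractions(conf, ion)
        regions = RegionMap.all_loop(conf.n_nt)
        mask = _exclusion_mask(conf)
        worst = 0.0
        def p_collision(c):
            p = c.beads_of_kind("P")
            d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
            iu = np.triu_indices(len(p), 1)
            return d[iu].min() < 1.05

        for k in range(1000):
            mv = (pivot_move, base_twist_move, bead_displacement_move)[k % 3]
            prop, moved = mv(conf, rng)
            if not moved.any() or p_collision(prop):
                continue
            pairs_old = detect_base_pairs(conf)
            pairs_new = detect_base_pairs(prop)
            du = incremental_delta(conf, prop, moved, pairs_old, pairs_new,
                                   regions, params, ion, 25.0, charge, mask)
            full = (total_energy(prop, pairs_new, regions, params, ion, 25.0,
                                 charge)
                    - total_energy(conf, pairs_old, regions, params, ion,
                                   25.0, charge))
            # relative to the move's own energy scale (overlapping proposals
            # reach ~1e8 kcal/mol, where double precision leaves ~1e-8 abs)
            worst = max(worst, abs(du - full) / max(1.0, abs(full)))
            # random-walk the reference through physically plausible states
            # (a deeply overlapping reference loses the comparison itself to
            # floating-point cancellation at ~1e5 kcal/mol state energies)
            if k % 5 == 0 and abs(full) < 50.0:
                conf = prop
        assert worst < 1e-9
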