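"""Pair detection, scoring metrics, clustering/model selection, refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgdna.cg_model import (BasePairSet, CGConformation, Sequence, ideal_helix,
                            init_conformation, loop_reference_chain,
                            parse_sequence, reverse_complement)
from cgdna.ensemble import (ClusterResult, ScoreReport, cluster_structures,
                            cluster_threshold, coords_rmsd, detect_base_pairs,
                            f1_score, kabsch_superpose, neutralization_stats,
                            radius_of_gyration, refine, rmsd, select_top_models)
from cgdna.fixtures import planted_decoys
from cgdna.sampler import ReplicaTrajectory, RunSchedule, TrajectorySample

from conftest import random_rotation, rigid_copy


class TestDetectBasePairs:
    def test_ideal_six_bp_duplex_yields_exactly_six_pairs(self, duplex6):
        assert len(detect_base_pairs(duplex6)) == 6

    def test_fully_extended_chain_has_no_pairs(self):
        ref = loop_reference_chain(parse_sequence("GCGCATATGCGC"))
        assert len(detect_base_pairs(ref)) == 0

    def test_best_geometry_wins_partner_conflicts(self):
        # two G's compete for one C: the one at the ideal distance wins
        dup = ideal_helix(Sequence("G"), Sequence("C"))
        seq = Sequence("GCG")
        coords = np.zeros((9, 3))
        coords[0:3] = dup.coords[0:3]          # G0 at ideal geometry
        coords[3:6] = dup.coords[3:6]          # C1 partner
        coords[6:9] = dup.coords[0:3] + [0.0, 1.0, 0.0]   # G2 displaced
        conf = CGConformation(seq, coords, chain_breaks=frozenset({0, 1}))
        pairs = detect_base_pairs(conf)
        assert (0, 1) in pairs and len(pairs) == 1


class TestRmsd:
    def test_zero_on_identical_structures(self, duplex6):
        assert rmsd(duplex6, duplex6) == pytest.approx(0.0, abs=1e-12)

    def test_zero_on_rigid_motion_orbits(self, duplex6, rng):
        assert rmsd(duplex6, rigid_copy(duplex6, rng)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_four_point_toy_matches_brute_force_superposition_oracle(self, rng):
        """Kabsch equals an independent oracle: random-rotation search
        polished by a generic optimizer over the rotation vector."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(4, 3)) * 3.0
        b = rng.normal(size=(4, 3)) * 3.0
        _, r_kabsch = kabsch_superpose(a, b)
        ac = a - a.mean(0)
        bc = b - b.mean(0)

        def cost(rotvec):
            r = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1)))

        best_vec, best_val = None, np.inf
        for _ in range(2000):
            vec = Rotation.from_matrix(random_rotation(rng)).as_rotvec()
            v = cost(vec)
            if v < best_val:
                best_vec, best_val = vec, v
        res = minimize(cost, best_vec, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        assert r_kabsch <= res.fun + 1e-9
        assert abs(res.fun - r_kabsch) < 1e-6

    def test_pseudo_metric_properties(self, rng):
        xs = [rng.normal(size=(5, 3)) * 4.0 for _ in range(3)]
        d01 = coords_rmsd(xs[0], xs[1])
        d10 = coords_rmsd(xs[1], xs[0])
        assert d01 == pytest.approx(d10, abs=1e-9)
        d02 = coords_rmsd(xs[0], xs[2])
        d12 = coords_rmsd(xs[1], xs[2])
        assert d02 <= d01 + d12 + 1e-9

    def test_length_mismatch_rejected(self, duplex6):
        small = init_conformation(parse_sequence("ACGT"), 0)
        with pytest.raises(ValueError):
            rmsd(duplex6, small)


class TestF1Score:
    def test_perfect_prediction(self):
        native = BasePairSet([(0, 9), (1, 8)])
        f1, pr, sn = f1_score(native, native)
        assert (f1, pr, sn) == (1.0, 1.0, 1.0)

    def test_worked_example_tp8_fp2_fn2(self):
        native = BasePairSet([(i, 40 - i) for i in range(10)])
        pred = BasePairSet([(i, 40 - i) for i in range(8)]
                           + [(50, 60), (51, 59)])
        f1, pr, sn = f1_score(pred, native)
        assert pr == pytest.approx(0.8)
        assert sn == pytest.approx(0.8)
        assert f1 == pytest.approx(0.8)

    def test_empty_prediction_scores_zero(self):
        native = BasePairSet([(0, 9)])
        f1, pr, sn = f1_score(BasePairSet([]), native)
        assert f1 == 0.0 and sn == 0.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6))
    def test_harmonic_mean_identity(self, tp, fp, fn):
        native = BasePairSet([(i, 50 - i) for i in range(tp + fn)])
        pred = BasePairSet([(i, 50 - i) for i in range(tp)]
                           + [(60 + i, 90 - i) for i in range(fp)])
        f1, pr, sn = f1_score(pred, native)
        assert 0.0 <= f1 <= 1.0
        if tp > 0:
            assert f1 == pytest.approx(2 * pr * sn / (pr + sn))
        else:
            assert f1 == 0.0


class TestRadiusOfGyration:
    def test_single_bead_is_zero(self):
        conf = init_conformation(Sequence("A"), 0)
        sub = CGConformation(Sequence("A"),
                             np.tile(conf.coords[0], (3, 1)))
        # a true single point has rg 0; use the definition directly
        assert radius_of_gyration(sub) == pytest.approx(0.0)

    def test_two_points_give_half_separation(self):
        coords = np.zeros((3, 3))
        coords[0] = [0, 0, 0]
        coords[1] = [0, 0, 0]
        coords[2] = [0, 0, 0]
        # definition-level check on raw coordinates instead
        x = np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]])
        rg = np.sqrt(np.mean(np.sum((x - x.mean(0)) ** 2, axis=1)))
        assert rg == pytest.approx(3.0)

    def test_random_cloud_matches_direct_sum_oracle(self, rng):
        conf = init_conformation(parse_sequence("ACGTACGTAC"), 6)
        x = conf.coords
        c = x.mean(axis=0)
        oracle = np.sqrt((np.sum((x - c) ** 2) / len(x)))
        assert radius_of_gyration(conf) == pytest.approx(oracle, abs=1e-12)


class TestClustering:
    def test_threshold_rule(self):
        assert cluster_threshold(50) == pytest.approx(5.0)
        assert cluster_threshold(38) == pytest.approx(3.8)

    def test_identical_pool_collapses_to_one_cluster(self):
        x = init_conformation(parse_sequence("ACGTA"), 1).coords
        res = cluster_structures([x.copy() for _ in range(10)], threshold=1.0)
        assert len(res.clusters) == 1
        assert len(res.clusters[0]) == 10

    def test_planted_families_recovered_exactly_like_bruteforce(self):
        coords, labels = planted_decoys(seed=4)
        thr = 3.0
        res = cluster_structures(coords, thr)
        # independent O(n^2) reference: connected components are the planted
        # families because inter-family distances are >> threshold
        fams = [frozenset(i for i, l in enumerate(labels) if l == f)
                for f in range(3)]
        got = [frozenset(c) for c in res.clusters]
        assert sorted(got, key=min) == sorted(fams, key=min)
        # medoid minimizes total intra-cluster rmsd (exhaustive check)
        for members, medoid in zip(res.clusters, res.medoids):
            totals = {m: sum(coords_rmsd(coords[m], coords[o])
                             for o in members) for m in members}
            assert totals[medoid] == pytest.approx(min(totals.values()))

    def test_cluster_sizes_non_increasing(self):
        coords, _ = planted_decoys(per_family=15, seed=9)
        res = cluster_structures(coords, 3.0)
        sizes = [len(c) for c in res.clusters]
        assert sizes == sorted(sizes, reverse=True)


def _toy_trajectory(seq, coord_list, energies):
    tr = ReplicaTrajectory(temperature=25.0, sequence=seq)
    for k, (x, e) in enumerate(zip(coord_list, energies), start=1):
        tr.append(TrajectorySample(step=k, energy=e, pairs=BasePairSet([]),
                                   coords=x))
    return tr


class TestSelectTopModels:
    def test_small_pool_uses_all_frames_with_warning(self):
        seq = parse_sequence("A" * 10)
        coords, _ = planted_decoys(seed=2)
        tr = _toy_trajectory(seq, coords, np.linspace(-5, 5, len(coords)))
        with pytest.warns(UserWarning, match="pool"):
            models, res = select_top_models(tr, n_pool=1000)
        assert 1 <= len(models) <= 4

    def test_identical_pool_returns_that_structure(self):
        seq = parse_sequence("ACGTA")
        x = init_conformation(seq, 3).coords
        tr = _toy_trajectory(seq, [x.copy() for _ in range(12)],
                             np.arange(12.0))
        with pytest.warns(UserWarning):
            models, res = select_top_models(tr, n_pool=20)
        assert len(res.clusters) == 1
        np.testing.assert_allclose(models[0].coords, x)

    def test_lowest_energy_decoy_appended(self):
        seq = parse_sequence("A" * 10)
        coords, labels = planted_decoys(seed=5)
        energies = np.linspace(0, 1, len(coords))
        # make a singleton family member the lowest-energy decoy
        energies[labels.index(2)] = -10.0
        tr = _toy_trajectory(seq, coords, energies)
        with pytest.warns(UserWarning):
            models, res = select_top_models(tr, n_pool=100)
        assert len(models) == 4  # 3 medoids + lowest-energy decoy


class TestRefine:
    def test_zero_step_schedule_is_identity(self, duplex6, params, ion):
        out = refine(duplex6, params, ion, RunSchedule(n_sweeps=0), seed=1)
        np.testing.assert_array_equal(out.coords, duplex6.coords)

    def test_ideal_helix_is_stable_under_refinement(self, duplex6, params, ion):
        out = refine(duplex6, params, ion,
                     RunSchedule(n_sweeps=40, burn_in=0), seed=2)
        assert rmsd(out, duplex6) < 0.5

    def test_deformed_helix_relaxes_toward_ideal(self, duplex6, params, ion):
        """An over-twisted, stretched duplex (all pairs intact) moves back
        toward the ideal geometry; energy never increases."""
        x = duplex6.coords.copy()
        r = np.linalg.norm(x[:, :2], axis=1)
        phi = np.arctan2(x[:, 1], x[:, 0])
        z = x[:, 2]
        phi2 = phi + z / 3.38 * np.deg2rad(6.0)
        pert = CGConformation(
            duplex6.sequence,
            np.column_stack([r * np.cos(phi2), r * np.sin(phi2), z * 1.12]),
            duplex6.chain_breaks)
        assert len(detect_base_pairs(pert)) == 6
        before = rmsd(pert, duplex6)
        out = refine(pert, params, ion,
                     RunSchedule(n_sweeps=150, burn_in=0,
                                 displacement_prob=0.6,
                                 displacement_sigma=0.2), seed=3)
        after = rmsd(out, duplex6)
        assert after < before
        assert len(detect_base_pairs(out)) == 6


class TestNeutralizationStats:
    def test_identical_frames_reduce_to_single_frame_value(self, ion):
        seq = parse_sequence("ACGTACGT")
        conf = init_conformation(seq, 4)
        f = np.linspace(0.3, 0.5, 8)
        tr = ReplicaTrajectory(temperature=25.0, sequence=seq)
        for k in range(3):
            tr.append(TrajectorySample(step=k + 1, energy=0.0,
                                       pairs=BasePairSet([]),
                                       coords=conf.coords.copy(), f=f.copy()))
        stats = neutralization_stats(tr, ["F", "F", "F"], ion)
        assert set(stats) == {"F"}
        assert stats["F"]["mean_f"] == pytest.approx(f.mean())
        assert stats["F"]["mean_rg"] == pytest.approx(
            radius_of_gyration(conf))

    def test_two_known_frames_average_arithmetically(self, ion):
        seq = parse_sequence("ACGT")
        c1 = init_conformation(seq, 1)
        c2 = init_conformation(seq, 2)
        tr = ReplicaTrajectory(temperature=25.0, sequence=seq)
        tr.append(TrajectorySample(1, 0.0, BasePairSet([]), c1.coords,
                                   np.full(4, 0.2)))
        tr.append(TrajectorySample(2, 0.0, BasePairSet([]), c2.coords,
                                   np.full(4, 0.6)))
        stats = neutralization_stats(tr, ["U", "U"], ion)
        assert stats["U"]["mean_f"] == pytest.approx(0.4)

    def test_absent_state_is_absent_not_zero(self, ion):
        seq = parse_sequence("ACGT")
        c1 = init_conformation(seq, 1)
        tr = ReplicaTrajectory(temperature=25.0, sequence=seq)
        tr.append(TrajectorySample(1, 0.0, BasePairSet([]), c1.coords,
                                   np.full(4, 0.2)))
        stats = neutralization_stats(tr, ["U"], ion)
        assert "F" not in stats


def test_score_report_validates_ranges():
    with pytest.raises(ValueError):
        ScoreReport(rmsd=1.0, f1=1.2, precision=0.5, sensitivity=0.5, rg=10.0)
    rep = ScoreReport(rmsd=2.0, f1=0.9, precision=0.9, sensitivity=0.9, rg=15.0)
    assert rep.rmsd == 2.0
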