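"""Winner-take-all maps, cluster-constrained null, Jaccard, voxel counts."""

import numpy as np
import pytest
from scipy import stats as sps

from crossrep import (GroupSpec, LabelMap, cluster_decomposition,
                      constrained_null, generate_group_dataset,
                      generate_subject, group_map, jaccard,
                      make_planted_truth, map_group_correlation,
                      n_cluster_assignments, selective_voxel_counts,
                      subject_map, winner_take_all)
from crossrep.selectivity import InsufficientClustersError, _relabel


def _map(labels, grid=(6, 1, 1), granularity=4):
    labels = np.asarray(labels)
    return LabelMap(labels, np.arange(labels.size), grid, granularity)


class TestWinnerTakeAll:
    def test_argmax_forced(self):
        betas = np.array([[1.0], [0.5], [-0.2], [0.1]])
        m = winner_take_all(betas, [0], (1, 1, 1))
        assert m.labels[0] == 0

    def test_exact_tie_goes_to_lowest_index(self):
        betas = np.array([[1.0], [1.0], [0.2], [0.1]])
        m = winner_take_all(betas, [0], (1, 1, 1))
        assert m.labels[0] == 0

    def test_nan_beta_identifies_location(self):
        betas = np.array([[1.0, 0.0], [np.nan, 0.2]])
        with pytest.raises(ValueError, match="condition 1, mask voxel 0"):
            winner_take_all(betas, [0, 1], (2, 1, 1))

    def test_noiseless_planted_dataset_recovers_truth(self, design):
        tr = make_planted_truth(design, noise_sd=1e-9, seed=9)
        g = GroupSpec("G", 1, {"VOTC": 1.0})
        d = generate_subject(design, tr, g, 0, 2)
        m = subject_map(d, "VOTC", 4)
        assert np.array_equal(m.labels, tr.true_label_maps["VOTC"][4])


class TestGroupMap:
    def test_single_subject_group_equals_subject_map(self, hi_snr_group):
        d = hi_snr_group[0]
        assert np.array_equal(group_map([d], "VOTC", 4).labels,
                              subject_map(d, "VOTC", 4).labels)

    def test_identical_subjects_give_same_map(self, hi_snr_group):
        d = hi_snr_group[0]
        assert np.array_equal(group_map([d, d, d], "VOTC", 4).labels,
                              subject_map(d, "VOTC", 4).labels)

    def test_high_snr_group_recovers_planted_map(self, design, truth, hi_snr_group):
        gm = group_map(hi_snr_group, "VOTC", 4)
        assert np.mean(gm.labels == truth.true_label_maps["VOTC"][4]) > 0.95

    def test_mismatched_grids_rejected(self, design, truth, hi_snr_group):
        other = generate_subject(design, make_planted_truth(design, grid_shape=(12, 10, 10), seed=3),
                                 GroupSpec("G", 1, {"VOTC": 1.0}), 0, 3)
        with pytest.raises(ValueError, match="common grid"):
            group_map([hi_snr_group[0], other], "VOTC", 4)


class TestClusters:
    def test_decomposition_partitions_mask_with_uniform_labels(self, hi_snr_group):
        m = subject_map(hi_snr_group[0], "VOTC", 4)
        dec = cluster_decomposition(m, connectivity=6)
        seen = np.concatenate(dec.clusters)
        assert sorted(seen) == list(range(m.labels.size))
        for lab, idx in zip(dec.labels, dec.clusters):
            assert np.all(m.labels[idx] == lab)

    def test_seven_clusters_four_conditions_give_16384_assignments(self):
        # 7 alternating blocks along one axis -> 7 connected clusters
        labels = np.repeat([0, 1, 2, 3, 0, 1, 2], 2)
        m = _map(labels, grid=(14, 1, 1))
        dec = cluster_decomposition(m)
        assert dec.n_clusters == 7
        assert n_cluster_assignments(dec, 4) == 16384

    def test_relabeling_preserves_cluster_count_and_sizes(self, rng):
        labels = np.repeat([0, 1, 2, 3, 0, 1, 2], 2)
        m = _map(labels, grid=(14, 1, 1))
        dec = cluster_decomposition(m)
        new = _relabel(dec, labels.size, 4, rng)
        dec2 = cluster_decomposition(_map(new, grid=(14, 1, 1)))
        # relabeled map's clusters can only merge at shared borders; every
        # original cluster keeps a single label
        for idx in dec.clusters:
            assert len(set(new[idx])) == 1

    def test_insufficient_clusters_is_explicit(self):
        m = _map([2, 2, 2, 2, 2, 2])
        with pytest.raises(InsufficientClustersError, match="assignments"):
            constrained_null(m, np.array([0, 1, 2, 3, 0, 1]), n_perm=10000)


class TestMapGroupCorrelation:
    def test_identical_groups_correlate_perfectly(self, hi_snr_group):
        maps = [subject_map(d, "VOTC", 4) for d in hi_snr_group]
        gm = group_map(hi_snr_group, "VOTC", 4)
        res = map_group_correlation((maps, gm), (maps, gm), n_perm=100, seed=0)
        assert res.observed > 0.9       # subject maps vs their own group map

    def test_hand_computed_three_step_statistic(self):
        """Two 2-subject groups of 6-voxel maps vs a direct computation."""
        a1, a2 = np.array([0, 1, 2, 3, 0, 1]), np.array([0, 1, 2, 2, 0, 1])
        b1, b2 = np.array([0, 1, 2, 3, 3, 1]), np.array([1, 1, 2, 3, 0, 1])
        mean_a, mean_b = np.array([0, 1, 2, 3, 0, 1]), np.array([0, 1, 2, 3, 1, 1])
        maps_a = [_map(x) for x in (a1, a2)]
        maps_b = [_map(x) for x in (b1, b2)]
        res = map_group_correlation((maps_a, _map(mean_a)), (maps_b, _map(mean_b)),
                                    n_perm=50, seed=0)
        s1 = np.mean([sps.spearmanr(x, mean_b).statistic for x in (a1, a2)])
        s2 = np.mean([sps.spearmanr(x, mean_a).statistic for x in (b1, b2)])
        assert res.observed == pytest.approx(0.5 * (s1 + s2))

    def test_invariant_to_subject_order(self, hi_snr_group, noise_group):
        maps_a = [subject_map(d, "VOTC", 4) for d in hi_snr_group]
        maps_b = [subject_map(d, "VOTC", 4) for d in noise_group]
        gm_a = group_map(hi_snr_group, "VOTC", 4)
        gm_b = group_map(noise_group, "VOTC", 4)
        r1 = map_group_correlation((maps_a, gm_a), (maps_b, gm_b),
                                   n_perm=20, seed=1).observed
        r2 = map_group_correlation((maps_a[::-1], gm_a), (maps_b[::-1], gm_b),
                                   n_perm=20, seed=1).observed
        assert r1 == pytest.approx(r2)

    def test_low_cluster_subjects_excluded_with_warning(self, hi_snr_group):
        maps = [subject_map(d, "VOTC", 4) for d in hi_snr_group]
        gm = group_map(hi_snr_group, "VOTC", 4)
        uniform = _map(np.zeros(maps[0].labels.size, dtype=int),
                       grid=maps[0].grid_shape)
        uniform.mask = maps[0].mask
        with pytest.warns(UserWarning, match="excluded"):
            res = map_group_correlation((maps + [uniform], gm), (maps, gm),
                                        n_perm=100, seed=0)
        assert res.extra["excluded"] == 1
        with pytest.raises(ValueError, match="empty"):
            map_group_correlation(([uniform], gm), (maps, gm), n_perm=100, seed=0)

    def test_planted_signal_beats_constrained_null(self, design, truth, hi_snr_group):
        """Shared planted topography: observed exceeds the 99th percentile."""
        half_a, half_b = hi_snr_group[:3], hi_snr_group[3:]
        res = map_group_correlation(
            ([subject_map(d, "VOTC", 4) for d in half_a], group_map(half_a, "VOTC", 4)),
            ([subject_map(d, "VOTC", 4) for d in half_b], group_map(half_b, "VOTC", 4)),
            n_perm=500, seed=2)
        assert res.observed > np.percentile(res.null_values, 99)
        assert res.p < 0.01


class TestConstrainedNull:
    def test_null_calibration_under_its_own_null(self, rng):
        """Relabeling-generated maps give uniform p within binomial bounds.

        Clusters are separated by unmasked gap voxels so a random
        relabeling can never merge neighbors (which would change the
        cluster decomposition between draws).
        """
        grid = (31, 1, 1)
        mask = np.concatenate([np.arange(4 * k, 4 * k + 3) for k in range(8)])
        base = np.repeat([0, 1, 2, 3, 0, 1, 2, 3], 3)   # 8 isolated clusters
        m0 = LabelMap(base, mask, grid, 4)
        dec = cluster_decomposition(m0)
        assert dec.n_clusters == 8
        other = rng.integers(0, 4, base.size)
        ps = []
        for k in range(200):
            labels = _relabel(dec, base.size, 4, rng)
            lm = LabelMap(labels, mask, grid, 4)
            ps.append(constrained_null(lm, other, n_perm=99,
                                       seed=int(rng.integers(2**31))).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestJaccardAndCounts:
    def test_identical_disjoint_and_half_overlap(self):
        a = _map([0, 0, 0, 1, 1, 2])
        b = _map([1, 0, 0, 0, 1, 2])
        assert jaccard(a, a, 0).score == 1.0
        # voxels preferring 0: A={0,1,2}, B={1,2,3} -> 2/4
        assert jaccard(a, b, 0).score == 0.5
        assert jaccard(a, b, 3).score == 0.0 and jaccard(a, b, 3).degenerate

    def test_symmetry(self, rng):
        a = _map(rng.integers(0, 4, 6))
        b = _map(rng.integers(0, 4, 6))
        for c in range(4):
            assert jaccard(a, b, c).score == jaccard(b, a, c).score

    def test_counts_partition_the_mask(self, hi_snr_group, truth):
        m = subject_map(hi_snr_group[0], "VOTC", 4)
        counts = selective_voxel_counts(m)
        assert counts.sum() == m.labels.size
        uniform = _map(np.zeros(6, dtype=int))
        assert selective_voxel_counts(uniform).tolist() == [6, 0, 0, 0]

    def test_planted_map_counts_match_cluster_sizes(self, design):
        tr = make_planted_truth(design, noise_sd=1e-9, seed=5)
        g = GroupSpec("G", 1, {"VOTC": 1.0})
        d = generate_subject(design, tr, g, 0, 4)
        counts = selective_voxel_counts(subject_map(d, "VOTC", 4))
        planted = np.bincount(tr.rois["VOTC"].cluster_super, minlength=4)
        assert np.array_equal(counts, planted)
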