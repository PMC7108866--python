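"""Group DSM correlation, partial model correlation, inter-subject matrix,
hierarchical clustering."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.cluster import hierarchy

from crossrep import (DSM, StudyDesign, group_dsm_correlation,
                      hierarchical_clusters, intersubject_matrix,
                      pair_difference_test, partial_model_correlation,
                      partial_spearman, spearman, square_from_vector,
                      two_way_group_stat, vectorize_dsm)


def _vecs(rng, n, m=28, loc=0.0):
    return rng.normal(loc, 1.0, (n, m))


class TestGroupDSMCorrelation:
    def test_identical_groups_give_r_one(self, rng):
        v = _vecs(rng, 1)
        res = group_dsm_correlation([v[0]] * 3, [v[0]] * 3, n_perm=50, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_independent_random_dsms_near_zero(self, rng):
        rs = [group_dsm_correlation(_vecs(rng, 4), _vecs(rng, 4),
                                    n_perm=10, seed=k).observed
              for k in range(40)]
        assert abs(np.mean(rs)) < 0.1

    def test_hand_computed_three_step_scheme(self, rng):
        """Two 3-subject groups of 6-entry DSM vectors (4 categories):
        the statistic equals the manual step-1/2/3 computation."""
        a = _vecs(rng, 3, m=6)
        b = _vecs(rng, 3, m=6)
        s1 = np.mean([sps.spearmanr(x, b.mean(axis=0)).statistic for x in a])
        s2 = np.mean([sps.spearmanr(x, a.mean(axis=0)).statistic for x in b])
        res = group_dsm_correlation(list(a), list(b), n_categories=4,
                                    n_perm=20, seed=0)
        assert res.observed == pytest.approx(0.5 * (s1 + s2))

    def test_symmetric_in_group_order(self, rng):
        a, b = _vecs(rng, 4), _vecs(rng, 5)
        r1 = group_dsm_correlation(list(a), list(b), n_perm=10, seed=0).observed
        r2 = group_dsm_correlation(list(b), list(a), n_perm=10, seed=0).observed
        assert r1 == pytest.approx(r2)

    def test_shared_planted_geometry_is_significant(self, truth, hi_snr_dsms):
        half_a = hi_snr_dsms[:6]
        half_b = hi_snr_dsms[6:]
        res = group_dsm_correlation(half_a, half_b, n_perm=500, seed=1)
        assert res.observed > 0.5
        assert res.p < 0.01

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            group_dsm_correlation([rng.normal(size=28)], [rng.normal(size=21)])


class TestPairDifference:
    def test_antisymmetric_in_group_swap(self, rng):
        f, g1, g2 = _vecs(rng, 3), _vecs(rng, 4), _vecs(rng, 4)
        d12 = pair_difference_test(list(f), list(g1), list(g2),
                                   n_perm=50, seed=0).observed
        d21 = pair_difference_test(list(f), list(g2), list(g1),
                                   n_perm=50, seed=0).observed
        assert d12 == pytest.approx(-d21)

    def test_planted_difference_detected(self, rng):
        """g1 shares the fixed group's geometry, g2 is noise."""
        base = rng.normal(0, 1, 28)
        fixed = [base + rng.normal(0, 0.3, 28) for _ in range(6)]
        g1 = [base + rng.normal(0, 0.3, 28) for _ in range(6)]
        g2 = [rng.normal(0, 1, 28) for _ in range(6)]
        res = pair_difference_test(fixed, g1, g2, n_perm=500, seed=3)
        assert res.observed > 0
        assert res.p < 0.05

    def test_null_calibration(self, rng):
        """g1 and g2 drawn from the same process: p uniform over repetitions."""
        ps = []
        for k in range(200):
            f = _vecs(rng, 3)
            g1, g2 = _vecs(rng, 3), _vecs(rng, 3)
            ps.append(pair_difference_test(list(f), list(g1), list(g2),
                                           n_perm=99, seed=k).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestPartialCorrelation:
    def test_orthogonal_nuisance_leaves_full_spearman(self, rng):
        x, y = rng.normal(size=200), rng.normal(size=200)
        nuis = rng.normal(size=200)       # independent of both
        full = spearman(x, y)
        assert partial_spearman(x, y, nuis) == pytest.approx(full, abs=0.05)

    def test_target_equal_nuisance_partials_to_zero(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.5, 50)
        assert abs(partial_spearman(x, y, y)) < 1e-10

    def test_matches_rank_regression_oracle(self, rng):
        """6-entry example vs an independent residual-rank computation."""
        x, y, z = rng.normal(size=6), rng.normal(size=6), rng.normal(size=6)
        rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))

        def resid(a, b):
            onez = np.column_stack([np.ones_like(b), b])
            beta, *_ = np.linalg.lstsq(onez, a, rcond=None)
            return a - onez @ beta

        expect = np.corrcoef(resid(rx, rz), resid(ry, rz))[0, 1]
        assert partial_spearman(x, y, z) == pytest.approx(expect)

    def test_matches_pingouin_cross_check(self, rng):
        import pandas as pd
        import pingouin as pg

        x, y, z = rng.normal(size=28), rng.normal(size=28), rng.normal(size=28)
        ours = partial_spearman(x, y, z)
        theirs = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                                 x="x", y="y", covar="z",
                                 method="spearman")["r"].iloc[0]
        assert ours == pytest.approx(float(theirs), abs=1e-10)

    def test_bounded_by_one(self, rng):
        for _ in range(20):
            x, y, z = (rng.normal(size=12) for _ in range(3))
            assert abs(partial_spearman(x, y, z)) <= 1 + 1e-12

    def test_constant_vector_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(10), rng.normal(size=10), rng.normal(size=10))

    def test_negative_observed_never_significant_one_tailed(self, rng):
        """One-tailed testing targets the positive tail only."""
        x = rng.normal(size=28)
        y = -x + rng.normal(0, 0.1, 28)
        nuis = rng.normal(size=28)
        res = partial_model_correlation(x, y, nuis, n_perm=200, seed=0)
        assert res.observed < 0
        assert res.p >= 0.5

    def test_planted_model_correlation_significant(self, truth, hi_snr_dsms, rng):
        mean_vec = np.mean([vectorize_dsm(d.matrix) for d in hi_snr_dsms], axis=0)
        target = vectorize_dsm(truth.true_dsm)
        nuis = rng.normal(size=28)
        res = partial_model_correlation(mean_vec, target, nuis,
                                        n_perm=500, seed=0)
        assert res.observed > 0.5
        assert res.p < 0.01


class TestInterSubject:
    def test_shape_matches_group_sizes(self, rng):
        vecs = _vecs(rng, 49)
        labels = np.repeat([0, 1, 2], [16, 16, 17])
        res = intersubject_matrix(list(vecs), labels,
                                  group_names=["SCv", "EBa", "SCa"],
                                  n_perm=50, seed=0)
        assert res.matrix.shape == (49, 49)
        assert np.allclose(res.matrix, res.matrix.T)
        assert len(res.within) == 3 and len(res.between) == 3

    def test_identical_subjects_give_unit_blocks(self, rng):
        v = rng.normal(size=28)
        res = intersubject_matrix([v] * 6, np.repeat([0, 1], 3),
                                  group_names=["a", "b"], n_perm=20, seed=0)
        assert all(m == pytest.approx(1.0) for m in res.within.values())
        assert all(m == pytest.approx(1.0) for m in res.between.values())

    def test_block_means_invariant_to_subject_order(self, rng):
        vecs = _vecs(rng, 9)
        labels = np.repeat([0, 1, 2], 3)
        r1 = intersubject_matrix(list(vecs), labels, n_perm=10, seed=0)
        perm = rng.permutation(9)
        r2 = intersubject_matrix(list(vecs[perm]), labels[perm], n_perm=10, seed=0)
        for k in r1.within:
            assert r1.within[k] == pytest.approx(r2.within[k])

    def test_distinct_geometry_group_has_higher_within_than_between(self, rng):
        base1, base2 = rng.normal(size=28), rng.normal(size=28)
        g1 = [base1 + rng.normal(0, 0.5, 28) for _ in range(8)]
        g2 = [base2 + rng.normal(0, 0.5, 28) for _ in range(8)]
        res = intersubject_matrix(g1 + g2, np.repeat([0, 1], 8),
                                  group_names=["a", "b"], n_perm=100, seed=0)
        assert res.within["a"] > res.between[("a", "b")]
        assert res.within["b"] > res.between[("a", "b")]

    def test_singleton_group_flagged(self, rng):
        vecs = _vecs(rng, 4)
        res = intersubject_matrix(list(vecs), np.array([0, 0, 0, 1]),
                                  group_names=["a", "b"], n_perm=10, seed=0)
        assert np.isnan(res.within["b"])
        assert "b" in res.extra["singletons"]


class TestHierarchicalClustering:
    def _block_dsm(self):
        """Two well-separated 4-category blocks."""
        m = np.full((8, 8), 10.0)
        for i in range(4):
            for j in range(4):
                m[i, j] = abs(i - j) * 0.1
                m[4 + i, 4 + j] = abs(i - j) * 0.1
        np.fill_diagonal(m, 0)
        return DSM(m, StudyDesign().category_names)

    def test_two_planted_blocks_recovered_at_k2(self):
        labels = hierarchical_clusters(self._block_dsm(), 2)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_k_equals_n_gives_singletons(self):
        labels = hierarchical_clusters(self._block_dsm(), 8)
        assert len(set(labels)) == 8

    def test_partitions_nested_as_k_grows(self, hi_snr_dsms):
        d = hi_snr_dsms[0]
        parts = {k: hierarchical_clusters(d, k) for k in (2, 3, 4)}
        for k in (2, 3):
            finer, coarser = parts[k + 1], parts[k]
            for c in set(finer):
                members = np.flatnonzero(finer == c)
                assert len(set(coarser[members])) == 1

    def test_ultrametric_toy_tree_reproduced_exactly(self):
        """An ultrametric DSM is a fixed point of agglomerative linkage."""
        m = square_from_vector(np.array([1.0, 4, 4, 4, 4, 2]))
        labels = ("a", "b", "c", "d")
        for method in ("single", "average", "complete"):
            z = hierarchy.linkage(vectorize_dsm(m), method=method)
            heights = sorted(z[:, 2])
            assert heights == [1.0, 2.0, 4.0]

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_clusters(self._block_dsm(), 9)
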