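import numpy as np
import pandas as pd
import pytest

from seroscreen import (characterize_strata, cluster_profiles,
                        count_distribution, stratify_counts)
from seroscreen.counts import characterize_group, dendrogram_json
from seroscreen.cutoffs import CutoffRecord, SeroCallSet

from oracles import complete_linkage_enum, fisher_p_enum


def callset_from(frame: pd.DataFrame) -> SeroCallSet:
    recs = [CutoffRecord(antigen_id=a, peak_x=0.0, direction="up", cutoff=0.1)
            for a in frame.columns]
    return SeroCallSet(cutoffs=recs, calls=frame)


class TestCountDistribution:
    def test_identity_matrix(self):
        n = 8
        frame = pd.DataFrame(np.eye(n, dtype=int))
        s = count_distribution(callset_from(frame))
        assert s.per_individual["mean"] == 1
        assert s.per_antigen["mean"] == 1

    def test_all_positive_antigen(self):
        frame = pd.DataFrame({"a": np.ones(30, dtype=int),
                              "b": np.zeros(30, dtype=int)})
        s = count_distribution(callset_from(frame))
        assert s.per_antigen["range"] == (30, 30)  # only detected antigens

    def test_cohort_count_center(self, cohort, calls):
        # per-individual truth counts are ~normal around spike_rate*n_antigens
        cfg = cohort.config
        center = cfg.spike_rate * cfg.n_antigens
        truth_counts = cohort.truth.sum(axis=1)
        se = truth_counts.std() / np.sqrt(len(truth_counts))
        assert abs(truth_counts.mean() - center) < 3 * se + 1.0


class TestStratify:
    def test_order_statistics_1_to_100(self):
        counts = pd.Series(np.arange(1, 101))
        s = stratify_counts(counts, 5, 95)
        assert all(counts[i] < s.low_threshold for i in s.low_ids)
        assert all(counts[i] > s.high_threshold for i in s.high_ids)
        assert len(s.low_ids) <= 5 and len(s.high_ids) <= 5
        assert set(s.low_ids).isdisjoint(s.high_ids)

    def test_strict_inequality_excludes_boundary_ties(self):
        counts = pd.Series([1, 1, 2, 2, 3, 3, 3, 9, 9, 9])
        s = stratify_counts(counts, 20, 80)
        assert all(counts[i] < s.low_threshold for i in s.low_ids)
        assert all(counts[i] > s.high_threshold for i in s.high_ids)

    def test_zero_low_percentile_empty_low(self):
        s = stratify_counts(pd.Series([1, 2, 3, 4]), 0, 95)
        assert s.low_ids == []

    def test_widening_percentiles_never_shrinks(self):
        rng = np.random.default_rng(5)
        counts = pd.Series(rng.poisson(25, 300))
        narrow = stratify_counts(counts, 5, 95)
        wide = stratify_counts(counts, 10, 90)
        assert set(narrow.low_ids) <= set(wide.low_ids)
        assert set(narrow.high_ids) <= set(wide.high_ids)

    def test_constant_counts_warns_empty(self, caplog):
        s = stratify_counts(pd.Series([7] * 20), 5, 95)
        assert s.low_ids == [] and s.high_ids == []


class TestCharacterize:
    def test_perfect_association_infinite_or(self):
        clin = pd.DataFrame({"v": [1] * 5 + [0] * 15},
                            index=[f"i{k}" for k in range(20)])
        res = characterize_group([f"i{k}" for k in range(5)], clin, ["v"])
        assert np.isinf(res.loc[0, "odds_ratio"])
        assert res.loc[0, "p"] < 0.01

    def test_p_matches_hypergeometric_enumeration_small_margins(self):
        rng = np.random.default_rng(6)
        ids = [f"i{k}" for k in range(30)]
        for _ in range(25):
            member = rng.choice(ids, size=8, replace=False)
            clin = pd.DataFrame({"v": rng.integers(0, 2, 30)}, index=ids)
            res = characterize_group(member, clin, ["v"])
            t = res.loc[0, ["n11", "n10", "n01", "n00"]].to_numpy(int)
            expected = fisher_p_enum(((t[0], t[1]), (t[2], t[3])))
            assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_constant_variable_skipped(self):
        clin = pd.DataFrame({"v": [1.0] * 10}, index=[f"i{k}" for k in range(10)])
        res = characterize_group(["i0", "i1"], clin, ["v"])
        assert res.empty

    def test_continuous_variable_median_dichotomized(self):
        ids = [f"i{k}" for k in range(8)]
        clin = pd.DataFrame({"cyt": [1.0, 2, 3, 4, 5, 6, 7, 8]}, index=ids)
        res = characterize_group(ids[4:], clin, ["cyt"])
        # group == above-median exactly -> perfect association
        assert np.isinf(res.loc[0, "odds_ratio"])

    def test_type_one_error_calibrated_under_permutation(self, cohort, calls):
        rng = np.random.default_rng(7)
        strata = stratify_counts(calls.counts, 5, 95)
        member = strata.high_ids
        clin = cohort.clinical
        rejections = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = pd.DataFrame(
                {"v": rng.permutation(clin["female"].to_numpy())},
                index=clin.index)
            res = characterize_group(member, perm, ["v"])
            rejections += int(res.loc[0, "p"] < 0.05)
        # exact tests are conservative; type-I error at most ~alpha
        assert rejections / n_perm < 0.08


class TestCluster:
    def test_identical_profiles_merge_at_zero(self):
        x = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        Z, _ = cluster_profiles(x)
        assert Z[0, 2] == 0.0

    def test_three_point_hand_linkage(self):
        # mutual distances 1, 1, 2: the distance-1 pair merges first, the
        # third point joins at the maximum distance 2
        pts = pd.DataFrame([[0.0], [1.0], [2.0]])
        Z, _ = cluster_profiles(pts)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(2.0)

    def test_heights_match_brute_force(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(15, 4))
        Z, _ = cluster_profiles(pd.DataFrame(pts))
        assert np.allclose(sorted(Z[:, 2]), sorted(complete_linkage_enum(pts)))

    def test_permutation_invariant_heights(self):
        rng = np.random.default_rng(9)
        pts = pd.DataFrame(rng.normal(size=(12, 3)))
        Z1, _ = cluster_profiles(pts)
        Z2, _ = cluster_profiles(pts.iloc[::-1])
        assert np.allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]))

    def test_dendrogram_json_nests_all_leaves(self):
        pts = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 2)),
                           index=list("abcdef"))
        Z, _ = cluster_profiles(pts)
        tree = dendrogram_json(Z, list(pts.index))
        flat = []

        def walk(node):
            if isinstance(node, list):
                walk(node[0]), walk(node[1])
            else:
                flat.append(node)
        walk(tree)
        assert sorted(flat) == list("abcdef")
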