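"""Dichotomization, Fisher-z differential-correlation scoring and ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from ccrscan import (
    BetaMatrix,
    CCRScorer,
    ccr_score,
    dichotomize,
    group_correlation_matrix,
    pairwise_correlation,
    score_all_candidates,
    score_consistency,
    split_train_test,
)
from ccrscan.correlation import FISHER_EPS
from ccrscan.modules import module_set_from_assignments
from ccrscan.reference import score_candidates_reference
from ccrscan.simulate import generate, marker_recovery_spec


def matrix_of(rows, probes=None):
    rows = np.asarray(rows, dtype=float)
    probes = probes or [f"p{i}" for i in range(rows.shape[0])]
    return BetaMatrix(
        pd.DataFrame(rows, index=probes,
                     columns=[f"s{j + 1}" for j in range(rows.shape[1])])
    )


class TestDichotomize:
    def test_direct_thresholding(self):
        m = matrix_of([[0.05, 0.30, 0.90, 0.15]])
        split = dichotomize(m, "p0", threshold=0.2)
        assert set(split.unmethylated_samples) == {"s1", "s4"}
        assert set(split.methylated_samples) == {"s2", "s3"}
        assert split.minority_fraction == 0.5

    def test_imbalance_guard_15_percent(self):
        m = matrix_of([[0.9] * 19 + [0.1]])
        split = dichotomize(m, "p0")
        assert split.minority_fraction == pytest.approx(0.05)
        assert not split.valid

    def test_missing_sample_excluded(self):
        m = matrix_of([[0.1, np.nan, 0.8]])
        split = dichotomize(m, "p0")
        assert split.excluded_samples == ["s2"]
        assert split.n_methylated == 1 and split.n_unmethylated == 1

    def test_exact_threshold_counts_as_methylated(self):
        m = matrix_of([[0.2, 0.1, 0.9]])
        split = dichotomize(m, "p0")
        assert "s1" in split.methylated_samples

    def test_partition_of_samples(self):
        m = matrix_of([[0.1, np.nan, 0.8, 0.3, 0.05]])
        split = dichotomize(m, "p0")
        all_back = (set(split.methylated_samples)
                    | set(split.unmethylated_samples)
                    | set(split.excluded_samples))
        assert all_back == set(m.sample_ids)

    def test_unknown_probe_raises(self):
        m = matrix_of([[0.1, 0.9, 0.5]])
        with pytest.raises(KeyError):
            dichotomize(m, "nope")


class TestGroupCorrelationMatrix:
    def test_identical_meta_profiles_give_unit_offdiagonal(self):
        meta = pd.DataFrame([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9]],
                            columns=["s1", "s2", "s3"])
        corr = group_correlation_matrix(meta, ["s1", "s2", "s3"])
        assert corr[0, 1] == pytest.approx(1.0)

    def test_brute_force_all_pairs(self, rng):
        meta = pd.DataFrame(rng.random((3, 10)),
                            columns=[f"s{j}" for j in range(10)])
        subset = [f"s{j}" for j in range(2, 9)]
        corr = group_correlation_matrix(meta, subset)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = pairwise_correlation(
                    meta.loc[i, subset], meta.loc[j, subset]
                )
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_samples_rejected(self):
        meta = pd.DataFrame([[0.1, 0.5]], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            group_correlation_matrix(meta, ["s1", "s2"])


class TestCCRScore:
    def test_identical_groups_score_zero(self, rng):
        values = rng.random((3, 12))
        m = matrix_of(np.vstack([np.tile([0.1, 0.9], 6), values[1:]]))
        split = dichotomize(m, "p0")
        meta = pd.DataFrame(np.tile(values[1], (2, 1)), columns=m.sample_ids)
        # both groups see the same duplicated meta-profiles -> z1 == z2
        assert ccr_score(split, meta) == 0.0

    def test_opposite_perfect_correlation_single_pair(self):
        # group 1 (unmethylated, candidate < 0.2): modules exactly equal;
        # group 2 (methylated): modules exactly opposite
        candidate = [0.1, 0.1, 0.1, 0.9, 0.9, 0.9]
        a = [0.2, 0.5, 0.8, 0.3, 0.6, 0.9]
        b = [0.2, 0.5, 0.8, 0.7, 0.4, 0.1]
        m = matrix_of([candidate, a, b])
        split = dichotomize(m, "p0", min_minority_fraction=0.15)
        meta = m.data.loc[["p1", "p2"]].set_axis([0, 1])
        expected = 2 * math.atanh(1 - FISHER_EPS)
        assert ccr_score(split, meta) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(14.5086, abs=1e-3)

    def test_brute_force_three_modules(self, rng):
        values = rng.random((4, 30))
        values[0] = np.tile([0.1, 0.9], 15)  # balanced dichotomy
        m = matrix_of(values)
        split = dichotomize(m, "p0")
        meta = pd.DataFrame(values[1:], columns=m.sample_ids)
        z = lambda r: math.atanh(max(-1 + FISHER_EPS, min(1 - FISHER_EPS, r)))
        expected = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                r1 = pairwise_correlation(
                    meta.loc[i, split.unmethylated_samples],
                    meta.loc[j, split.unmethylated_samples],
                )
                r2 = pairwise_correlation(
                    meta.loc[i, split.methylated_samples],
                    meta.loc[j, split.methylated_samples],
                )
                expected += abs(z(r1) - z(r2))
        assert ccr_score(split, meta) == pytest.approx(expected, abs=1e-12)

    def test_invalid_split_raises(self):
        m = matrix_of([[0.9] * 19 + [0.1]])
        split = dichotomize(m, "p0")
        meta = pd.DataFrame(np.random.default_rng(0).random((2, 20)),
                            columns=m.sample_ids)
        with pytest.raises(ValueError, match="imbalance"):
            ccr_score(split, meta)

    def test_group_swap_symmetry(self, rng):
        values = rng.random((5, 24))
        values[0] = np.tile([0.1, 0.9], 12)
        m = matrix_of(values)
        split = dichotomize(m, "p0")
        meta = pd.DataFrame(values[1:], columns=m.sample_ids)
        swapped = dichotomize(m, "p0")
        swapped.methylated_samples, swapped.unmethylated_samples = (
            swapped.unmethylated_samples,
            swapped.methylated_samples,
        )
        assert ccr_score(split, meta) == ccr_score(swapped, meta)

    def test_full_matrix_sum_would_exactly_double(self, rng):
        from ccrscan.scoring import _score_from_matrices
        from ccrscan.correlation import fisher_z

        values = rng.random((4, 20))
        values[0] = np.tile([0.1, 0.9], 10)
        m = matrix_of(values)
        split = dichotomize(m, "p0")
        meta = pd.DataFrame(values[1:], columns=m.sample_ids)
        r1 = group_correlation_matrix(meta, split.unmethylated_samples)
        r2 = group_correlation_matrix(meta, split.methylated_samples)
        s = _score_from_matrices(r1, r2)
        full = np.abs(fisher_z(r1) - fisher_z(r2)).sum()
        assert full == pytest.approx(2 * s, abs=1e-12)


class TestScoreAllCandidates:
    def small_instance(self, seed=0):
        import dataclasses

        spec = dataclasses.replace(
            marker_recovery_spec(seed), n_samples=60, n_modules=3,
            probes_per_module=4, n_noise_probes=4,
        )
        m, _, truth = generate(spec)
        from ccrscan.simulate import ground_truth_module_labels
        labels = ground_truth_module_labels(truth)
        return m, module_set_from_assignments(m, labels), labels

    def test_oracle_equivalence_random_instances(self):
        for seed in [0, 1, 2]:
            m, modules, labels = self.small_instance(seed)
            table = score_all_candidates(m, modules, m.probe_ids)
            ref = score_candidates_reference(m.data, labels.to_numpy())
            merged = table.merge(ref, on="candidate_probe", suffixes=("", "_ref"))
            assert (merged["valid"] == merged["valid_ref"]).all()
            valid = merged[merged["valid"]]
            assert np.allclose(
                valid["score_s"], valid["score_s_ref"], atol=1e-10
            )
            assert (valid["rank"] == valid["rank_ref"]).all()

    def test_constant_candidate_unscored(self, rng):
        values = np.vstack([np.full(30, 0.9), rng.random((4, 30))])
        m = matrix_of(values)
        labels = pd.Series([0, 1, 2, 3, 4], index=m.probe_ids)
        modules = module_set_from_assignments(m, labels)
        table = score_all_candidates(m, modules, m.probe_ids)
        row = table.set_index("candidate_probe").loc["p0"]
        assert not row["valid"]
        assert np.isnan(row["score_s"])
        assert np.isnan(row["rank"])

    def test_identical_dichotomies_share_scores(self, rng):
        base = np.tile([0.1, 0.9], 15)
        jitter = base + rng.normal(0, 0.03, 30)
        values = np.vstack([base, np.clip(jitter, 0, 1), rng.random((3, 30))])
        # p0 and p1 dichotomize identically (same side of 0.2 everywhere)
        assert ((values[0] >= 0.2) == (values[1] >= 0.2)).all()
        m = matrix_of(values)
        labels = pd.Series(range(5), index=m.probe_ids)
        modules = module_set_from_assignments(m, labels)
        table = score_all_candidates(m, modules, m.probe_ids).set_index(
            "candidate_probe"
        )
        assert table.loc["p0", "score_s"] == table.loc["p1", "score_s"]

    def test_rank_dense_descending_with_id_tiebreak(self):
        table = pd.DataFrame(
            {
                "candidate_probe": ["a", "b", "c", "d"],
                "score_s": [3.0, 5.0, 3.0, np.nan],
                "n_methylated": [10, 10, 10, 20],
                "n_unmethylated": [10, 10, 10, 0],
                "valid": [True, True, True, False],
            }
        )
        from ccrscan.markers import select_top_markers

        panel = select_top_markers(table, 3)
        assert panel.probe_ids == ["b", "a", "c"]

    def test_empty_candidate_list_raises(self, small_matrix):
        labels = pd.Series(range(4), index=small_matrix.probe_ids)
        modules = module_set_from_assignments(small_matrix, labels)
        with pytest.raises(ValueError, match="empty"):
            score_all_candidates(small_matrix, modules, [])


class TestCCRScorerEstimator:
    def test_fit_transform_selects_top_markers(self):
        import dataclasses

        spec = dataclasses.replace(
            marker_recovery_spec(0), n_samples=80, n_modules=4,
            probes_per_module=5, n_noise_probes=5,
        )
        m, _, truth = generate(spec)
        X = m.data.T
        est = CCRScorer(n_markers=3, random_state=0).fit(X)
        Xt = est.transform(X)
        assert Xt.shape == (80, 3)
        assert list(Xt.columns) == est.top_markers_
        ranked = est.score_table_.dropna(subset=["rank"]).sort_values("rank")
        assert est.top_markers_ == ranked["candidate_probe"].head(3).tolist()

    def test_get_params_clone_roundtrip(self):
        from sklearn.base import clone

        est = CCRScorer(beta_threshold=0.25, n_markers=10)
        c = clone(est)
        assert c.get_params()["beta_threshold"] == 0.25


class TestSplitTrainTest:
    def test_sizes_disjoint_exhaustive(self):
        ids = [f"s{i}" for i in range(10)]
        train, test = split_train_test(ids, 6, seed=0)
        assert len(train) == 6 and len(test) == 4
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    def test_deterministic_same_seed(self):
        ids = [f"s{i}" for i in range(20)]
        assert split_train_test(ids, 12, 7) == split_train_test(ids, 12, 7)

    def test_different_seeds_differ_with_high_probability(self):
        ids = [f"s{i}" for i in range(20)]
        base = split_train_test(ids, 10, 0)
        distinct = sum(
            split_train_test(ids, 10, seed) != base for seed in range(1, 101)
        )
        assert distinct >= 99

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            split_train_test(["a", "b"], 2, 0)


class TestScoreConsistency:
    def table(self, scores, valid=None):
        n = len(scores)
        return pd.DataFrame(
            {
                "candidate_probe": [f"p{i}" for i in range(n)],
                "score_s": scores,
                "n_methylated": [10] * n,
                "n_unmethylated": [10] * n,
                "valid": valid or [True] * n,
            }
        )

    def test_identical_tables(self):
        t = self.table([1.0, 2.0, 3.0, 4.0])
        assert score_consistency(t, t) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = self.table([1.0, 2.0, 3.0, 5.0])
        b = self.table([2.0, 4.0, 6.0, 10.0])
        assert score_consistency(a, b) == pytest.approx(1.0)

    def test_only_commonly_valid_candidates_used(self):
        a = self.table([1.0, 2.0, 3.0, 99.0], valid=[True, True, True, False])
        b = self.table([2.0, 4.0, 6.0, -99.0])
        assert score_consistency(a, b) == pytest.approx(1.0)

    def test_insufficient_overlap_raises(self):
        a = self.table([1.0, 2.0], valid=[True, False])
        b = self.table([1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            score_consistency(a, b)
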