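"""Coherence-constrained agglomerative clustering of probes."""

import numpy as np
import pandas as pd
import pytest

from ccrscan import (
    BetaMatrix,
    CoherenceClustering,
    agglomerate,
    cluster_coherence,
    cluster_similarity,
    pairwise_correlation,
)
from ccrscan.modules import module_meta_profiles, module_set_from_assignments


def matrix_from(values, prefix="p"):
    values = np.asarray(values, dtype=float)
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        )
    )


class TestClusterCoherence:
    def test_identical_profiles(self):
        prof = np.tile([0.1, 0.5, 0.9, 0.3], (2, 1))
        assert cluster_coherence(prof) == pytest.approx(1.0)

    def test_singleton_convention(self):
        assert cluster_coherence([[0.2, 0.4, 0.8]]) == 1.0

    def test_matches_brute_force_mean_of_member_mean_correlations(self, rng):
        profiles = rng.random((3, 15))
        profiles[0, 3] = np.nan
        mean = np.nanmean(profiles, axis=0)
        expected = np.mean(
            [pairwise_correlation(p, mean) for p in profiles]
        )
        assert cluster_coherence(profiles) == pytest.approx(expected, abs=1e-12)

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            cluster_coherence(np.empty((0, 5)))


class TestClusterSimilarity:
    def test_identical_singletons(self):
        a = [[0.1, 0.5, 0.9]]
        assert cluster_similarity(a, a) == pytest.approx(1.0)

    def test_singleton_vs_pair_is_mean_of_cross_correlations(self, rng):
        a = rng.random((1, 10))
        b = rng.random((2, 10))
        expected = np.mean(
            [pairwise_correlation(a[0], b[0]), pairwise_correlation(a[0], b[1])]
        )
        assert cluster_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self, rng):
        a = rng.random((2, 12))
        b = rng.random((3, 12))
        assert cluster_similarity(a, b) == pytest.approx(
            cluster_similarity(b, a), abs=1e-12
        )


def two_block_matrix(rng, n_per_block=4, n_samples=40):
    """Two blocks of identical profiles, anti-correlated across blocks.

    Exactly-uncorrelated blocks would NOT stay separate: the union of two
    equal-size uncorrelated clusters has coherence 1/sqrt(2) ~ 0.707,
    which passes the 0.7 floor.  Anti-correlation makes the cross-block
    merge impossible for every merge order."""
    base = rng.random(n_samples)
    a = np.clip(base, 0, 1)
    b = 0.62 - 0.24 * base  # decreasing in base -> cross-correlation -1
    values = np.vstack([np.tile(a, (n_per_block, 1)), np.tile(b, (n_per_block, 1))])
    return matrix_from(values)


class TestAgglomerate:
    def test_two_block_fixture_any_seed(self, rng):
        m = two_block_matrix(rng)
        cross = pairwise_correlation(m.data.iloc[0], m.data.iloc[-1])
        assert cross < 0  # fixture construction: blocks anti-correlated
        for seed in range(10):
            ms = agglomerate(m, coherence_threshold=0.7, seed=seed)
            assert ms.n_modules == 2
            assert np.allclose(ms.coherences, 1.0)
            labels = ms.module_assignments
            assert len(set(labels.iloc[:4])) == 1
            assert len(set(labels.iloc[4:])) == 1

    def test_single_probe(self):
        ms = agglomerate(matrix_from([[0.1, 0.9, 0.4]]), seed=0)
        assert ms.n_modules == 1
        assert ms.coherences[0] == 1.0

    def test_default_threshold(self):
        assert CoherenceClustering().coherence_threshold == 0.7

    def test_invalid_threshold_raises(self):
        m = matrix_from([[0.1, 0.9, 0.4]])
        for bad in [0.0, -1.0, np.nan, np.inf]:
            with pytest.raises(ValueError):
                agglomerate(m, coherence_threshold=bad, seed=0)

    def test_coherence_invariant_recomputed_from_members(self, rng):
        values = rng.random((30, 25))
        m = matrix_from(values)
        ms = agglomerate(m, coherence_threshold=0.7, seed=1)
        for k in range(ms.n_modules):
            members = ms.members(k)
            coh = cluster_coherence(m.data.loc[members].to_numpy())
            assert coh >= 0.7 or len(members) == 1
            assert coh == pytest.approx(ms.coherences[k], abs=1e-12)

    def test_first_iteration_halves_fully_correlated_input(self):
        n = 17
        profile = np.linspace(0.1, 0.9, 24)
        m = matrix_from(np.tile(profile, (n, 1)))
        est = CoherenceClustering(coherence_threshold=0.7, random_state=3)
        est.fit(m.data.T)
        assert est.n_clusters_per_iteration_[0] <= int(np.ceil(n / 2))
        assert est.n_modules_ == 1  # everything eventually merges

    def test_cluster_count_non_increasing_and_terminates(self, rng):
        values = rng.random((25, 20))
        est = CoherenceClustering(coherence_threshold=0.7, random_state=0)
        est.fit(pd.DataFrame(values).T)
        counts = est.n_clusters_per_iteration_
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == est.n_modules_

    def test_deterministic_under_seed(self, rng):
        values = rng.random((20, 15))
        m = matrix_from(values)
        a = agglomerate(m, seed=42)
        b = agglomerate(m, seed=42)
        assert (a.module_assignments == b.module_assignments).all()
        assert np.array_equal(a.coherences, b.coherences)
        pd.testing.assert_frame_equal(a.meta_profiles, b.meta_profiles)

    def test_meta_profile_is_member_mean(self, rng):
        values = rng.random((12, 10))
        values[rng.random(values.shape) < 0.1] = np.nan
        m = matrix_from(values)
        ms = agglomerate(m, seed=5)
        for k in range(ms.n_modules):
            block = m.data.loc[ms.members(k)].to_numpy()
            expected = np.nanmean(block, axis=0)
            got = ms.meta_profiles.iloc[k].to_numpy()
            mask = ~np.isnan(expected)
            assert np.allclose(got[mask], expected[mask], atol=1e-12)
            assert np.isnan(got[~mask]).all()

    def test_all_members_missing_meta_entry_is_missing(self):
        values = np.array([[0.1, np.nan, 0.5], [0.2, np.nan, 0.6]])
        meta = module_meta_profiles(values, np.array([0, 0]))
        assert np.isnan(meta[0, 1])
        assert meta[0, 0] == pytest.approx(0.15)

    def test_transform_pools_modules(self, rng):
        values = rng.random((8, 12))
        X = pd.DataFrame(values).T
        est = CoherenceClustering(random_state=0).fit(X)
        pooled = est.transform(X)
        assert pooled.shape == (12, est.n_modules_)
        k = est.labels_[0]
        members = np.flatnonzero(est.labels_ == k)
        assert np.allclose(
            pooled[k].to_numpy(), values[members].mean(axis=0), atol=1e-12
        )


class TestModuleSetFromAssignments:
    def test_builds_meta_and_coherence(self, rng):
        values = rng.random((6, 10))
        m = matrix_from(values)
        labels = pd.Series([0, 0, 1, 1, 2, 2], index=m.probe_ids)
        ms = module_set_from_assignments(m, labels)
        assert ms.n_modules == 3
        assert np.allclose(
            ms.meta_profiles.iloc[0].to_numpy(), values[:2].mean(axis=0)
        )

    def test_non_contiguous_labels_rejected(self, rng):
        values = rng.random((4, 8))
        m = matrix_from(values)
        labels = pd.Series([0, 0, 2, 2], index=m.probe_ids)
        with pytest.raises(ValueError, match="contiguous"):
            module_set_from_assignments(m, labels)
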