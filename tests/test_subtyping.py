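"""Consensus clustering, cluster metrics, drug-response groups, robustness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import phenomap as pm
from phenomap.data_io import Covariate, PhenotypeTable
from phenomap.selection import SignificanceCall


class TestUnitScale:
    def test_already_standardized_column_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(50)
        col = (col - col.mean()) / col.std(ddof=1)
        out = pm.unit_scale(col[:, None])
        np.testing.assert_allclose(out[:, 0], col, atol=1e-12)

    def test_two_point_column(self):
        out = pm.unit_scale(np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(out[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)

    def test_contract_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        out = pm.unit_scale(rng.uniform(-5, 100, size=(30, 4)))
        assert np.abs(out.mean(axis=0)).max() < 1e-12
        assert np.abs(out.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_constant_column_named_in_error(self):
        M = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="flatcol"):
            pm.unit_scale(M, column_names=["ok", "flatcol"])


def _planted_clouds(k, n_per, d, sep, seed):
    """Well-separated unit-variance clouds: centers equally spaced on a
    circle with adjacent separation `sep` times the within-cluster SD."""
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(k) / k
    radius = sep / (2 * np.sin(np.pi / k))
    centers = np.zeros((k, d))
    centers[:, 0] = radius * np.cos(theta)
    centers[:, 1] = radius * np.sin(theta)
    M = np.vstack([c + rng.standard_normal((n_per, d)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return M, labels


class TestConsensusKmeans:
    def test_perfectly_separated_clouds_give_binary_consensus(self):
        rng = np.random.default_rng(3)
        M = np.vstack([rng.standard_normal((10, 2)) * 0.01,
                       rng.standard_normal((10, 2)) * 0.01 + 5.0])
        res = pm.consensus_kmeans(M, k_grid=[2], reps=100, seed=0)
        C = res.consensus[2]
        within = np.concatenate([C[:10, :10].ravel(), C[10:, 10:].ravel()])
        between = C[:10, 10:].ravel()
        assert within.min() == 1.0 and between.max() == 0.0
        assert res.cophenetic[2] == pytest.approx(1.0)

    def test_recovers_planted_three_clusters(self):
        M, truth = _planted_clouds(k=3, n_per=20, d=2, sep=5, seed=4)
        res = pm.consensus_kmeans(M, k_grid=range(2, 8), reps=150, seed=1)
        assert res.selected_k == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_recovers_planted_k_across_sizes(self, k):
        M, truth = _planted_clouds(k=k, n_per=12, d=3, sep=6, seed=10 + k)
        res = pm.consensus_kmeans(M, k_grid=range(2, 8), reps=120, seed=2)
        assert res.selected_k == k
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_consensus_matrix_invariants(self):
        M, _ = _planted_clouds(k=2, n_per=12, d=2, sep=3, seed=5)
        res = pm.consensus_kmeans(M, k_grid=[2, 3], reps=60, seed=3)
        for k, C in res.consensus.items():
            assert np.allclose(C, C.T)
            assert np.allclose(np.diag(C), 1.0)
            assert C.min() >= 0 and C.max() <= 1

    def test_consensus_stable_in_rep_count(self):
        M, _ = _planted_clouds(k=3, n_per=15, d=2, sep=7, seed=6)
        a = pm.consensus_kmeans(M, k_grid=[3], reps=500, seed=7).consensus[3]
        b = pm.consensus_kmeans(M, k_grid=[3], reps=1000, seed=8).consensus[3]
        assert np.abs(a - b).max() < 0.05

    def test_defaults_follow_published_protocol(self):
        from phenomap.subtyping import DEFAULT_K_GRID, DEFAULT_REPS, DEFAULT_SUBSAMPLE_FRACTION
        assert DEFAULT_REPS == 1000
        assert tuple(DEFAULT_K_GRID) == (2, 3, 4, 5, 6, 7)
        assert DEFAULT_SUBSAMPLE_FRACTION == 0.8

    def test_k_too_large_for_subsample_rejected(self):
        M, _ = _planted_clouds(k=2, n_per=5, d=2, sep=3, seed=9)
        with pytest.raises(ValueError):
            pm.consensus_kmeans(M, k_grid=[9], reps=10, seed=0)


class TestCopheneticCoefficient:
    def test_block_diagonal_consensus_is_one(self):
        C = np.zeros((6, 6))
        C[:3, :3] = 1.0
        C[3:, 3:] = 1.0
        assert pm.cophenetic_coefficient(C) == pytest.approx(1.0)

    def test_matches_brute_force_merge_heights(self):
        # brute-force cophenetic distances by explicit agglomeration on 6 samples
        rng = np.random.default_rng(11)
        C = np.clip(0.5 + 0.4 * rng.standard_normal((6, 6)), 0, 1)
        C = 0.5 * (C + C.T)
        np.fill_diagonal(C, 1.0)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)

        # average-linkage agglomeration tracked by hand
        clusters = {i: [i] for i in range(6)}
        coph = np.zeros((6, 6))
        active = list(clusters)
        while len(active) > 1:
            best = None
            for a, b in itertools.combinations(active, 2):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
            d, a, b = best
            for i in clusters[a]:
                for j in clusters[b]:
                    coph[i, j] = coph[j, i] = d
            clusters[a] = clusters[a] + clusters[b]
            active.remove(b)
        iu = np.triu_indices(6, 1)
        expected = np.corrcoef(D[iu], coph[iu])[0, 1]
        assert pm.cophenetic_coefficient(C) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(12)
        C = np.clip(0.5 + 0.3 * rng.standard_normal((8, 8)), 0, 1)
        C = 0.5 * (C + C.T)
        np.fill_diagonal(C, 1.0)
        perm = rng.permutation(8)
        assert pm.cophenetic_coefficient(C[np.ix_(perm, perm)]) == pytest.approx(
            pm.cophenetic_coefficient(C), abs=1e-12)

    def test_degenerate_matrix_flagged_undefined(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        assert np.isnan(pm.cophenetic_coefficient(C))


class TestSilhouetteWidth:
    def test_tight_far_clusters_near_one(self):
        rng = np.random.default_rng(13)
        M = np.vstack([rng.standard_normal((10, 2)) * 0.01,
                       rng.standard_normal((10, 2)) * 0.01 + 10])
        labels = np.repeat([0, 1], 10)
        assert pm.silhouette_width(M, labels) > 0.9

    def test_matches_textbook_double_loop(self):
        rng = np.random.default_rng(14)
        M = rng.standard_normal((8, 3))
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        D = np.linalg.norm(M[:, None] - M[None, :], axis=2)
        expected = []
        for i in range(8):
            own = [j for j in range(8) if labels[j] == labels[i] and j != i]
            a = np.mean([D[i, j] for j in own])
            b = min(np.mean([D[i, j] for j in range(8) if labels[j] == other])
                    for other in set(labels) - {labels[i]})
            expected.append((b - a) / max(a, b))
        assert pm.silhouette_width(M, labels) == pytest.approx(np.mean(expected), abs=1e-12)

    def test_random_labels_on_noise_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            M = rng.standard_normal((40, 3))
            labels = rng.integers(0, 3, 40)
            if len(np.unique(labels)) < 2:
                continue
            vals.append(pm.silhouette_width(M, labels))
        assert abs(np.mean(vals)) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            pm.silhouette_width(np.zeros((5, 2)), np.zeros(5))


def _calls(cov_rows):
    return SignificanceCall(
        feature_calls=pd.DataFrame(columns=["feature", "cmv", "z", "mean", "sign"]),
        covariate_calls=pd.DataFrame(cov_rows, columns=["covariate", "cmv", "z", "mean", "sign"]),
        feature_threshold=3.89, covariate_threshold=1.96, n_undefined=0)


class TestBuildSubtypeInput:
    def _pheno(self, n=12, seed=15):
        rng = np.random.default_rng(seed)
        return PhenotypeTable(
            sample_ids=[f"s{i}" for i in range(n)],
            covariates=[Covariate("drug1", "quantitative", rng.standard_normal(n)),
                        Covariate("drug2", "quantitative", rng.standard_normal(n))])

    def test_universal_mode_two_cmvs_two_drugs_gives_four_columns(self):
        rng = np.random.default_rng(16)
        U = rng.standard_normal((2, 12))
        calls = _calls([("drug1", 0, 3.0, 1.0, 1), ("drug2", 1, -2.5, -1.0, -1)])
        M = pm.build_subtype_input(U, calls, self._pheno(), mode="universal")
        assert list(M.columns) == ["CMV1", "CMV2", "drug1", "drug2"]
        assert M.shape == (12, 4)

    def test_per_cmv_without_significant_covariates_is_cmv_alone(self):
        rng = np.random.default_rng(17)
        U = rng.standard_normal((2, 12))
        calls = _calls([("drug1", 0, 3.0, 1.0, 1)])
        M = pm.build_subtype_input(U, calls, self._pheno(), mode="per_cmv", cmv=1)
        assert list(M.columns) == ["CMV2"]

    def test_output_is_unit_scaled(self):
        rng = np.random.default_rng(18)
        U = 7 + 3 * rng.standard_normal((2, 12))
        M = pm.build_subtype_input(U, _calls([]), self._pheno(), mode="universal")
        assert np.abs(M.to_numpy().mean(axis=0)).max() < 1e-12
        assert np.abs(M.to_numpy().std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_missing_phenotype_column_rejected(self):
        rng = np.random.default_rng(19)
        U = rng.standard_normal((1, 12))
        calls = _calls([("drugX", 0, 3.0, 1.0, 1)])
        with pytest.raises(KeyError, match="drugX"):
            pm.build_subtype_input(U, calls, self._pheno(), mode="per_cmv", cmv=0)


class TestDrugResponseGroups:
    def test_separable_triples(self):
        labels = pm.drug_response_groups([0, 0, 0, 5, 5, 5, 10, 10, 10])
        assert list(labels) == ["L"] * 3 + ["M"] * 3 + ["H"] * 3

    def test_optimal_among_all_three_partitions(self):
        # exhaustive oracle over every 3-part set partition (incl. non-contiguous)
        rng = np.random.default_rng(20)
        v = rng.standard_normal(9)
        x = pm.unit_scale(v)[:, 0]
        ours = pm.drug_response_groups(v)
        codes = {"L": 0, "M": 1, "H": 2}
        ours_ss = sum(((x[np.array([codes[l] for l in ours]) == g]
                        - x[np.array([codes[l] for l in ours]) == g].mean()) ** 2).sum()
                      for g in range(3))
        best = np.inf
        for assign in itertools.product(range(3), repeat=9):
            assign = np.array(assign)
            if len(set(assign)) < 3:
                continue
            ss = sum(((x[assign == g] - x[assign == g].mean()) ** 2).sum() for g in range(3))
            best = min(best, ss)
        assert ours_ss == pytest.approx(best, abs=1e-10)

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=12))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_groups_contiguous_in_sorted_order(self, vals):
        v = np.asarray(vals)
        if len(np.unique(v)) < 3 or v.std(ddof=1) == 0:
            return
        labels = pm.drug_response_groups(v)
        order = np.argsort(v, kind="stable")
        seq = "".join(labels[order])
        # sorted ascending must read as L...M...H blocks
        assert seq == "L" * seq.count("L") + "M" * seq.count("M") + "H" * seq.count("H")

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(21)
        v = rng.standard_normal(15)
        a = pm.drug_response_groups(v)
        b = pm.drug_response_groups(3.7 * v + 11.0)
        assert list(a) == list(b)

    def test_per_drug_independence(self):
        v = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8])
        assert list(pm.drug_response_groups(v)) == list(pm.drug_response_groups(v))

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            pm.drug_response_groups([1.0, 1.0, 2.0, 2.0])


class TestPermutationRobustness:
    def test_random_subset_of_homogeneous_cloud_not_robust(self):
        rng = np.random.default_rng(22)
        M = pm.unit_scale(rng.standard_normal((60, 3)))
        labels = np.zeros(60, dtype=int)
        labels[rng.choice(60, 20, replace=False)] = 1
        tab = pm.permutation_robustness(M, labels, n_perm=300, seed=0)
        assert not tab["robust"].any()
        assert tab["score"].max() < 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_displaced_cluster_always_robust(self, seed):
        rng = np.random.default_rng(200 + seed)
        M = rng.standard_normal((50, 3))
        labels = np.zeros(50, dtype=int)
        labels[:12] = 1
        M[:12] += 5.0  # displaced by 5 unit-scaled units
        tab = pm.permutation_robustness(M, labels, n_perm=150, seed=seed)
        assert bool(tab.loc[tab["subtype"] == 1, "robust"].iloc[0])

    def test_default_threshold_is_one(self):
        from phenomap.subtyping import ROBUSTNESS_THRESHOLD
        assert ROBUSTNESS_THRESHOLD == 1.0

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            pm.permutation_robustness(np.zeros((10, 2)), np.zeros(10), n_perm=10)
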