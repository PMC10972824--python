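import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from depresist import perturbcluster, synthetic


class TestZTransform:
    def test_row_mean_zero_sd_one(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"], columns=list("abc"))
        z = perturbcluster.z_transform(m)
        assert z.loc["g0"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.loc["g0"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_row_dropped(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                         index=["flat", "ok"], columns=list("abc"))
        z = perturbcluster.z_transform(m)
        assert list(z.index) == ["ok"]
        with pytest.raises(ValueError):
            perturbcluster.z_transform(m, drop_constant=False)

    def test_idempotence(self, rng):
        m = pd.DataFrame(rng.standard_normal((20, 8)))
        z1 = perturbcluster.z_transform(m)
        z2 = perturbcluster.z_transform(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


class TestHierarchicalClusters:
    def test_two_separated_blobs(self, rng):
        a = rng.standard_normal((10, 4)) * 0.1
        b = rng.standard_normal((10, 4)) * 0.1 + 10
        m = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(20)])
        assign = perturbcluster.hierarchical_clusters(m, k=2)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, assign.labels) == 1.0

    def test_planted_five_cluster_recovery(self, perturbation):
        m, truth = perturbation
        z = perturbcluster.z_transform(m)
        assign = perturbcluster.hierarchical_clusters(z, k=5)
        ari = adjusted_rand_score(truth["labels"].loc[assign.labels.index], assign.labels)
        assert ari > 0.9

    def test_merge_heights_non_decreasing(self, rng):
        m = pd.DataFrame(rng.standard_normal((30, 5)))
        assign = perturbcluster.hierarchical_clusters(m, k=3)
        heights = assign.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_row_permutation_invariance_up_to_relabel(self, rng):
        m = pd.DataFrame(rng.standard_normal((25, 4)),
                         index=[f"g{i}" for i in range(25)])
        a1 = perturbcluster.hierarchical_clusters(m, k=4)
        perm = rng.permutation(25)
        a2 = perturbcluster.hierarchical_clusters(m.iloc[perm], k=4)
        merged = pd.concat([a1.labels.rename("l1"), a2.labels.rename("l2")], axis=1)
        assert adjusted_rand_score(merged["l1"], merged["l2"]) == 1.0

    def test_fewer_rows_than_k_errors(self, rng):
        m = pd.DataFrame(rng.standard_normal((3, 4)))
        with pytest.raises(ValueError):
            perturbcluster.hierarchical_clusters(m, k=5)


class TestClusterEnrichment:
    def test_cluster_equal_to_set_minimal_p(self, rng):
        a = rng.standard_normal((10, 4)) * 0.1
        b = rng.standard_normal((10, 4)) * 0.1 + 10
        genes = [f"g{i}" for i in range(20)]
        m = pd.DataFrame(np.vstack([a, b]), index=genes)
        assign = perturbcluster.hierarchical_clusters(m, k=2)
        cluster1 = assign.members(1)
        coll = {"EXACT": cluster1, "OTHER": genes[5:15]}
        enr = perturbcluster.cluster_enrichment(assign, coll)
        c1 = enr[enr["cluster"] == 1].set_index("set")
        assert c1["p"].idxmin() == "EXACT"

    def test_reversed_cluster_enriched_for_its_planted_set(self, perturbation):
        m, truth = perturbation
        z = perturbcluster.z_transform(m)
        assign = perturbcluster.hierarchical_clusters(z, k=5)
        enr = perturbcluster.cluster_enrichment(assign, truth["cluster_sets"])
        planted = f"CLUSTER_SET_{truth['reversed_cluster']}"
        best = enr[enr["set"] == planted].sort_values("p").iloc[0]
        assert best["FDR"] < 0.05

    def test_random_assignment_null_p_uniform(self, rng):
        genes = [f"g{i}" for i in range(100)]
        pvals = []
        for _ in range(100):
            labels = pd.Series(rng.integers(1, 3, size=100), index=genes)
            assign = perturbcluster.ClusterAssignment(
                labels=labels, linkage=np.empty((0, 4)), k=2)
            coll = {"S": list(rng.choice(genes, 20, replace=False))}
            enr = perturbcluster.cluster_enrichment(assign, coll)
            pvals.extend(enr["p"].tolist())
        # hypergeometric p under the null is super-uniform (discrete)
        assert np.mean(np.array(pvals) < 0.05) <= 0.08


class TestPca:
    def test_rank_one_first_component_explains_all(self, rng):
        u = rng.standard_normal(20)
        v = rng.standard_normal(6)
        m = pd.DataFrame(np.outer(u, v), columns=[f"s{i}" for i in range(6)])
        _, explained = perturbcluster.pca_projection(m, 1)
        assert explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_preserves_pairwise_distances(self, rng):
        m = pd.DataFrame(rng.standard_normal((10, 5)),
                         columns=[f"s{i}" for i in range(5)])
        coords, _ = perturbcluster.pca_projection(m, 5)
        x = m.to_numpy().T
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(coords.to_numpy()), pdist(x), atol=1e-9)

    def test_deterministic_sign_convention(self, rng):
        m = pd.DataFrame(rng.standard_normal((15, 6)),
                         columns=[f"s{i}" for i in range(6)])
        c1, _ = perturbcluster.pca_projection(m, 2)
        c2, _ = perturbcluster.pca_projection(m.copy(), 2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_too_many_components_errors(self, rng):
        m = pd.DataFrame(rng.standard_normal((4, 3)))
        with pytest.raises(ValueError):
            perturbcluster.pca_projection(m, 5)


def test_reversed_cluster_profile_pattern(perturbation):
    """The recovered 'reversed' cluster goes up on drug and back down on the
    drug+inhibitor combination."""
    m, truth = perturbation
    z = perturbcluster.z_transform(m)
    assign = perturbcluster.hierarchical_clusters(z, k=5)
    profiles = perturbcluster.condition_profiles(z, assign, truth["conditions"])
    # identify the recovered analogue by majority overlap with planted truth
    planted = set(truth["cluster_sets"][f"CLUSTER_SET_{truth['reversed_cluster']}"])
    overlaps = {cid: len(planted & set(assign.members(cid))) for cid in range(1, 6)}
    cid = max(overlaps, key=overlaps.get)
    prof = profiles.loc[cid]
    assert prof["drug"] > prof["vehicle"]
    assert prof["drug"] > prof["drug_inhibitor"]
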