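"""Spearman/centroid hierarchical clustering and the two-cluster cut."""

import numpy as np
import pandas as pd
import pytest

from breastmarker import clustering, decall, qpcr
from breastmarker import synthetic as syn


def _profiles(cols):
    return pd.DataFrame(cols)


class TestSpearmanSimilarity:
    def test_self_similarity_is_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        sim = clustering.spearman_similarity(m)
        assert np.allclose(np.diag(sim), 1.0)
        assert np.allclose(sim, sim.T)

    def test_monotone_profiles_perfectly_similar(self):
        m = _profiles({"a": [1, 2, 3], "b": [10, 20, 30]})
        sim = clustering.spearman_similarity(m)
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_ranked_pair(self):
        # ranks (1,2,3) vs (3,1,2): rho = 1 - 6*(4+1+1)/(3*8) = -0.5
        m = _profiles({"a": [1, 2, 3], "b": [3, 1, 2]})
        sim = clustering.spearman_similarity(m)
        assert sim.loc["a", "b"] == pytest.approx(-0.5)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        m = _profiles({"a": x, "b": np.exp(x)})
        sim = clustering.spearman_similarity(m)
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_item_flagged(self):
        m = _profiles({"a": [1, 2, 3], "b": [5, 5, 5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            sim = clustering.spearman_similarity(m)
        assert np.isnan(sim.loc["a", "b"])


class TestClusterTree:
    def test_duplicated_item_merges_with_twin_first(self, rng):
        base = rng.normal(size=12)
        m = _profiles({
            "x": base, "y": base.copy(), "z": rng.normal(size=12),
        })
        dendro = clustering.cluster(m)
        first = dendro.merges[0]
        assert first[2] == pytest.approx(1.0)
        assert {dendro.items[first[0]], dendro.items[first[1]]} == {"x", "y"}

    def test_input_order_permutation_same_topology(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(15, 6)),
            columns=[f"T{j}" for j in range(6)],
        )
        d1 = clustering.cluster(m)
        d2 = clustering.cluster(m[list(reversed(m.columns))])

        def splits(node, acc):
            if node.is_leaf:
                return
            acc.add(frozenset(node.leaves()))
            splits(node.left, acc)
            splits(node.right, acc)

        s1, s2 = set(), set()
        splits(d1.root, s1)
        splits(d2.root, s2)
        assert s1 == s2

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            clustering.cluster(pd.DataFrame({"only": [1.0, 2.0]}))

    def test_two_items_cut_into_singletons(self, rng):
        m = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        assign = clustering.cut_two(clustering.cluster(m))
        assert set(assign.labels) == {"A", "B"}

    def test_newick_export_contains_all_leaves(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 5)),
                         columns=[f"T{j}" for j in range(5)])
        nwk = clustering.cluster(m).to_newick()
        assert nwk.endswith(";")
        for j in range(5):
            assert f"T{j}" in nwk

    def test_gene_axis_clustering_separates_anticorrelated_blocks(self, rng):
        base = rng.normal(size=12)
        rows = [base + rng.normal(0, 0.05, 12) for _ in range(5)]
        rows += [-base + rng.normal(0, 0.05, 12) for _ in range(5)]
        m = pd.DataFrame(rows, index=[f"G{i}" for i in range(10)],
                         columns=[f"T{j}" for j in range(12)])
        assign = clustering.cut_two(clustering.cluster(m, axis="genes"))
        groups = {assign.labels[f"G{i}"] for i in range(5)}
        assert len(groups) == 1  # positively correlated block stays together
        assert assign.labels["G0"] != assign.labels["G5"]


class TestCohortSeparation:
    def _strong_cohort(self, seed=11, frac_cl=0.2, n_ipsi=40):
        de = tuple((i, "over" if i % 2 else "under", 4.0) for i in range(10))
        cfg = syn.CohortConfig(
            n_cancer=12, n_ipsi=n_ipsi, n_contra=0, n_mamm=14, n_genes=30,
            de_genes=de, frac_cancerlike_ipsi=frac_cl, noise_sd=0.3,
            n_subtype_groups=2, subtype_effect=4.0, seed=seed,
        )
        matrix, ann = syn.gen_cohort(cfg)
        centered = qpcr.median_center(matrix, center="mean")
        return centered, ann

    def test_root_split_recovers_ground_truth_classes(self):
        centered, ann = self._strong_cohort(frac_cl=0.0)
        assign = clustering.cut_two(clustering.cluster(centered))
        report = clustering.classify_normals(assign, ann)
        assert report.loc["cancer", "in_cancer_cluster"] == 12
        assert report.loc["mammaplasty", "in_control_cluster"] == 14
        assert report.loc["ipsilateral", "in_cancer_cluster"] == 0

    def test_planted_cancer_like_fraction_flagged_exactly(self):
        centered, ann = self._strong_cohort(frac_cl=0.2, n_ipsi=40)
        assign = clustering.cut_two(clustering.cluster(centered))
        report = clustering.classify_normals(assign, ann)
        assert report.loc["ipsilateral", "in_cancer_cluster"] == 8
        flagged_truth = set(ann.loc[ann["cancer_like"], "tissue"])
        cancer_label = next(k for k, v in assign.enrichment.items() if v == "cancer")
        in_cancer = set(assign.members(cancer_label))
        assert flagged_truth <= in_cancer

    def test_error_rate_falls_with_effect_size(self):
        errors = []
        for effect in (0.5, 2.0, 4.0):
            de = tuple((i, "over", effect) for i in range(10))
            cfg = syn.CohortConfig(
                n_cancer=10, n_ipsi=0, n_contra=0, n_mamm=12, n_genes=25,
                de_genes=de, noise_sd=1.0, n_subtype_groups=1, seed=5,
            )
            matrix, ann = syn.gen_cohort(cfg)
            centered = qpcr.median_center(matrix, center="mean")
            assign = clustering.cut_two(clustering.cluster(centered))
            report = clustering.classify_normals(assign, ann)
            err = (report.loc["cancer", "in_control_cluster"]
                   + report.loc["mammaplasty", "in_cancer_cluster"])
            errors.append(int(err))
        assert errors[-1] == 0
        assert errors[0] >= errors[-1]

    def test_unannotated_item_rejected(self):
        centered, ann = self._strong_cohort()
        assign = clustering.cut_two(clustering.cluster(centered))
        with pytest.raises(KeyError):
            clustering.classify_normals(assign, ann.iloc[:-1])

    def test_subcluster_summary_purity_with_planted_subtypes(self):
        centered, ann = self._strong_cohort(frac_cl=0.0)
        dendro = clustering.cluster(centered)
        assign = clustering.cut_two(dendro)
        clustering.classify_normals(assign, ann)
        table = clustering.subcluster_summary(dendro, assign, ann)
        assert table["n"].sum() == 12  # all cancers, no normals
        purities = []
        for _, row in table.iterrows():
            counts = [row.get("subtype=luminal", 0), row.get("subtype=basal", 0)]
            purities.append(max(counts) / row["n"])
        assert min(purities) >= 0.8

    def test_subcluster_summary_without_outcome_column(self):
        centered, ann = self._strong_cohort(frac_cl=0.0)
        dendro = clustering.cluster(centered)
        assign = clustering.cut_two(dendro)
        clustering.classify_normals(assign, ann)
        table = clustering.subcluster_summary(
            dendro, assign, ann.drop(columns=["outcome"])
        )
        assert not any(c.startswith("outcome=") for c in table.columns)


class TestPipelineIntegration:
    def test_discriminating_genes_cluster_study_cohort(self, study_cohort):
        """End-to-end: DE call then clustering on the called genes."""
        cfg, matrix, ann = study_cohort
        centered = qpcr.median_center(matrix)
        cancers = ann.loc[ann["tissue_class"] == "cancer", "tissue"].tolist()
        controls = ann.loc[ann["tissue_class"] == "mammaplasty", "tissue"].tolist()
        calls = decall.call_de(centered, cancers, controls)
        called = decall.called_genes(calls)
        sub = qpcr.median_center(matrix.loc[called], center="mean")
        assign = clustering.cut_two(clustering.cluster(sub))
        report = clustering.classify_normals(assign, ann)
        assert report.loc["cancer", "in_cancer_cluster"] == cfg.n_cancer
        n_cl = int(round(cfg.frac_cancerlike_ipsi * cfg.n_ipsi))
        assert report.loc["ipsilateral", "in_cancer_cluster"] == n_cl
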