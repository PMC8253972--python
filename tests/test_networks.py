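"""Atlas masks, per-network tables and covariate splits."""

import numpy as np
import pandas as pd
import pytest

from dyadprint import (
    ALL_LABEL,
    SyntheticSpec,
    ValidationError,
    between_network_edge_mask,
    build_comb_cohort,
    compare_timepoints,
    covariate_split_analysis,
    make_atlas,
    network_node_mask,
    per_network_analysis,
    similarity_matrix,
    simulate_cohort,
    within_network_edge_mask,
)


@pytest.fixture(scope="module")
def atlas():
    return make_atlas(30)  # 3 nodes per network


class TestMasks:
    def test_within_mask_combinatorics(self, small_study):
        atlas33 = small_study.atlas
        edges33 = small_study.fc["age11"].feature_ids
        for net in atlas33.networks:
            k = len(atlas33.nodes_in_network(net))
            mask = within_network_edge_mask(atlas33, net, edges33)
            assert len(mask) == k * (k - 1) // 2

    def test_all_mask_keeps_everything(self, small_study):
        edges = small_study.fc["age11"].feature_ids
        assert within_network_edge_mask(small_study.atlas, ALL_LABEL, edges) == edges

    def test_within_plus_between_partition_edges(self, small_study):
        atlas = small_study.atlas
        edges = small_study.fc["age11"].feature_ids
        nets = atlas.networks
        seen: list[str] = []
        for i, a in enumerate(nets):
            seen += within_network_edge_mask(atlas, a, edges)
            for b in nets[i + 1 :]:
                seen += between_network_edge_mask(atlas, a, b, edges)
        assert sorted(seen) == sorted(edges)
        assert len(seen) == len(set(seen))

    def test_between_mask_symmetric_and_product_count(self, small_study):
        atlas = small_study.atlas
        edges = small_study.fc["age11"].feature_ids
        a, b = atlas.networks[:2]
        mab = between_network_edge_mask(atlas, a, b, edges)
        mba = between_network_edge_mask(atlas, b, a, edges)
        assert sorted(mab) == sorted(mba)
        ka = len(atlas.nodes_in_network(a))
        kb = len(atlas.nodes_in_network(b))
        assert len(mab) == ka * kb

    def test_identical_labels_rejected(self, atlas):
        with pytest.raises(ValidationError, match="distinct"):
            between_network_edge_mask(atlas, "MF", "MF", [])

    def test_unknown_label_lists_valid(self, atlas):
        with pytest.raises(ValidationError, match="MF"):
            within_network_edge_mask(atlas, "nope", [])

    def test_node_masks_partition_node_set(self, atlas):
        nodes: list[str] = []
        for net in atlas.networks:
            nodes += network_node_mask(atlas, net)
        assert sorted(nodes) == sorted(atlas.node_ids)
        assert network_node_mask(atlas, ALL_LABEL) == atlas.node_ids

    def test_masking_commutes_with_similarity(self, small_study):
        cohort = small_study.fc["age11"]
        atlas = small_study.atlas
        mask = within_network_edge_mask(atlas, "MF", cohort.feature_ids)
        a = similarity_matrix(cohort, mask)
        b = similarity_matrix(cohort.mask_features(mask))
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestPerNetwork:
    def test_perfect_transmission_saturates_every_cell(self):
        study = simulate_cohort(
            SyntheticSpec(n_dyads=8, n_nodes=33, alpha=1.0, noise_sd=0.0, seed=2)
        )
        table = per_network_analysis(
            study.fc["age11"], study.gmv["age11"], study.atlas,
            n_boot=30, n_perm=0, seed=0,
        )
        computable = table.dropna(subset=["accuracy"])
        assert len(computable) > 0
        assert np.allclose(computable["accuracy"], 1.0)
        assert np.allclose(computable["ci_lo"], 1.0)
        assert np.allclose(computable["ci_hi"], 1.0)

    def test_transmission_planted_in_one_network_localizes(self):
        study = simulate_cohort(
            SyntheticSpec(n_dyads=30, n_nodes=60, alpha=0.0,
                          alpha_by_network={"FP": 0.9}, seed=4)
        )
        table = per_network_analysis(
            study.fc["age11"], None, study.atlas, modalities=("FC",),
            networks=study.atlas.networks, n_boot=0, n_perm=0, seed=0,
        )
        table = table.dropna(subset=["accuracy"]).set_index("network")
        best = table["accuracy"].idxmax()
        assert best == "FP"
        others = table.drop("FP")["accuracy"]
        assert (table.loc["FP", "accuracy"] > others).all()

    def test_small_network_cell_marked_not_computable(self):
        study = simulate_cohort(SyntheticSpec(n_dyads=6, n_nodes=12, alpha=0.5, seed=1))
        table = per_network_analysis(
            study.fc["age11"], study.gmv["age11"], study.atlas,
            n_boot=0, n_perm=0, seed=0,
        )
        # 12 nodes over 10 networks -> most networks have <3 features
        assert table["accuracy"].isna().any()
        assert table["accuracy"].notna().any()  # run continued

    def test_all_accuracy_is_not_network_mean(self):
        # documented non-property: whole-brain accuracy need not equal the
        # average of per-network accuracies
        study = simulate_cohort(
            SyntheticSpec(n_dyads=15, n_nodes=33, alpha=0.0,
                          alpha_by_network={"MF": 0.8}, seed=6)
        )
        table = per_network_analysis(
            study.fc["age11"], None, study.atlas, modalities=("FC",),
            n_boot=0, n_perm=0, seed=0,
        ).set_index("network")
        per_net = table.drop(ALL_LABEL)["accuracy"].dropna()
        assert table.loc[ALL_LABEL, "accuracy"] != pytest.approx(per_net.mean(), abs=1e-6)

    def test_identity_subset_reproduces_table(self, small_study):
        fc = small_study.fc["age11"]
        gmv = small_study.gmv["age11"]
        whole = per_network_analysis(fc, gmv, small_study.atlas,
                                     n_boot=10, n_perm=10, seed=3)
        again = per_network_analysis(
            fc.subset_dyads(range(fc.n_dyads)),
            gmv.subset_dyads(range(gmv.n_dyads)),
            small_study.atlas, n_boot=10, n_perm=10, seed=3,
        )
        pd.testing.assert_frame_equal(whole, again)

    def test_comb_concatenates_network_masks(self, small_study):
        fc = small_study.fc["age11"]
        gmv = small_study.gmv["age11"]
        comb = build_comb_cohort(fc, gmv)
        assert comb.children.n_features == fc.children.n_features + gmv.children.n_features


class TestSplits:
    def test_planted_sex_difference_recovered(self):
        study = simulate_cohort(
            SyntheticSpec(n_dyads=60, n_nodes=110, alpha=0.2,
                          subgroup_effects={"F": 0.5}, seed=8)
        )
        res = covariate_split_analysis(
            None, study.gmv["age11"], study.atlas, split="sex",
            modalities=("GMV",), n_boot=0, n_perm=0, seed=0,
        )
        f = res.tables["F"].set_index("network")["accuracy"]
        m = res.tables["M"].set_index("network")["accuracy"]
        common = [n for n in f.index if n in m.index]
        n_higher = int((f[common] > m[common]).sum())
        assert n_higher >= 10  # of the 10 networks + ALL
        assert res.comparisons["GMV"].p_value < 0.05

    def test_median_split_analysis_runs(self, small_study):
        gmv = small_study.gmv["age11"]
        scores = gmv.covariates.column("cbcl")
        res = covariate_split_analysis(
            None, gmv, small_study.atlas, split="median", scores=scores,
            modalities=("GMV",), n_boot=0, n_perm=0, seed=0,
        )
        assert set(res.tables) == {"lower", "upper"}

    def test_subgroup_too_small_names_group(self):
        study = simulate_cohort(
            SyntheticSpec(n_dyads=8, n_nodes=33, alpha=0.3, female_frac=0.25, seed=9)
        )
        with pytest.raises(ValidationError, match="'F'"):
            covariate_split_analysis(
                None, study.gmv["age11"], study.atlas, split="sex",
                modalities=("GMV",), n_boot=0, n_perm=0, seed=0,
            )

    def test_full_pool_strangers_variant(self, small_study):
        gmv = small_study.gmv["age11"]
        res = covariate_split_analysis(
            None, gmv, small_study.atlas, split="sex",
            modalities=("GMV",), n_boot=0, n_perm=0, seed=0, strangers="all",
        )
        for table in res.tables.values():
            assert table["accuracy"].between(0, 1).all()

    def test_compare_timepoints_paired_over_networks(self):
        study = simulate_cohort(
            SyntheticSpec(n_dyads=20, n_nodes=33, alpha=0.4,
                          timepoints=("age11", "age13"),
                          alpha_by_timepoint={"age13": 0.7}, seed=10)
        )
        t11 = per_network_analysis(None, study.gmv["age11"], study.atlas,
                                   modalities=("GMV",), n_boot=0, n_perm=0, seed=0)
        t13 = per_network_analysis(None, study.gmv["age13"], study.atlas,
                                   modalities=("GMV",), n_boot=0, n_perm=0, seed=0)
        res = compare_timepoints(t11, t13, "GMV")
        assert res.t_stat < 0  # age-13 cohort was planted more similar
        assert res.df == len(t11.dropna(subset=["accuracy"])) - 1
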