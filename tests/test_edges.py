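"""Products, empirical probability, differential power, group consistency."""

import numpy as np
import pytest

from dyadprint import (
    SyntheticSpec,
    ValidationError,
    differential_power,
    edge_measures,
    empirical_probability,
    group_consistency,
    lobe_normalized_counts,
    make_atlas,
    product_vectors,
    similarity_matrix,
    simulate_cohort,
    simulate_feature_cohort,
    top_percentile,
    zscore_subject_vectors,
)
from dyadprint.edges import EdgeProducts


def brute_force_p_i(zc: np.ndarray, zp: np.ndarray) -> np.ndarray:
    """Exhaustive enumeration of both comparison directions."""
    n, m = zc.shape
    out = np.zeros((n, m))
    for i in range(n):
        for f in range(m):
            dyad = zc[i, f] * zp[i, f]
            count = 0
            for j in range(n):
                if j == i:
                    continue
                if zc[j, f] * zp[i, f] > dyad:  # stranger child, dyad parent
                    count += 1
                if zc[i, f] * zp[j, f] > dyad:  # dyad child, stranger parent
                    count += 1
            out[i, f] = count / (2 * (n - 1))
    floor = 1 / (2 * (n - 1))
    return np.maximum(out, floor)


class TestZScore:
    def test_affine_standardization(self):
        cohort = simulate_feature_cohort(3, 3, seed=0)
        cohort.children.values[0] = [1.0, 2.0, 3.0]
        z = zscore_subject_vectors(cohort.children)
        assert np.allclose(z.values[0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        cohort = simulate_feature_cohort(4, 10, seed=1)
        z1 = zscore_subject_vectors(cohort.children)
        z2 = zscore_subject_vectors(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_product_sum_recovers_pearson(self):
        """Σ_f z_c z_p / (M−1) equals the similarity-engine correlation."""
        cohort = simulate_feature_cohort(5, 40, alpha=0.5, seed=2)
        products = product_vectors(cohort)
        sim = similarity_matrix(cohort)
        m = cohort.children.n_features
        implied = products.dyad_products.sum(axis=1) / (m - 1)
        assert np.allclose(implied, np.diag(sim.values), atol=1e-10)

    def test_zero_variance_subject_rejected(self):
        cohort = simulate_feature_cohort(3, 5, seed=0)
        cohort.children.values[2] = 1.5
        with pytest.raises(ValidationError, match="child002"):
            zscore_subject_vectors(cohort.children)


class TestProducts:
    def test_brute_force_all_pairs(self):
        cohort = simulate_feature_cohort(3, 5, alpha=0.4, seed=9)
        products = product_vectors(cohort)
        for i in range(3):
            for j in range(3):
                expected = products.child_values[i] * products.parent_values[j]
                assert np.allclose(products.phi(i, j), expected, atol=1e-12)
        assert np.allclose(
            products.dyad_products,
            np.vstack([products.phi(i, i) for i in range(3)]),
            atol=1e-12,
        )

    def test_zero_child_value_annihilates(self):
        zc = np.array([[0.0, 1.0, -1.0], [1.0, 0.5, 2.0], [0.2, 0.3, 0.4]])
        zp = np.abs(np.random.default_rng(0).normal(size=(3, 3))) + 1
        prod = EdgeProducts(["a", "b", "c"], zc, zp, True)
        assert prod.phi(0, 1)[0] == 0.0

    def test_identical_standardized_vectors_square_positive(self):
        cohort = simulate_feature_cohort(4, 8, alpha=1.0, noise_sd=0.0, seed=3)
        products = product_vectors(cohort)
        assert np.all(products.dyad_products >= 0)


class TestEmpiricalProbability:
    def test_matches_exhaustive_enumeration(self):
        cohort = simulate_feature_cohort(3, 5, alpha=0.4, seed=9)
        products = product_vectors(cohort)
        p = empirical_probability(products)
        expected = brute_force_p_i(products.child_values, products.parent_values)
        assert np.allclose(p, expected, atol=1e-12)

    def test_clean_sweep_floored(self):
        # dyad product 4 beats every stranger product -> raw 0, floored
        zc = np.array([[2.0, 1.0, 1.0], [0.1, 1.0, -1.0], [0.1, -2.0, 0.5]])
        zp = np.array([[2.0, 1.0, 1.0], [0.1, 0.5, -1.0], [0.1, -2.0, 0.5]])
        p = empirical_probability(EdgeProducts(["a", "b", "c"], zc, zp, True))
        assert p[0, 0] == 1 / 4  # floor = 1/(2(N-1)) with N=3

    def test_strictly_smallest_dyad_product_gives_one(self):
        zc = np.array([[-3.0, 1.0, 1.0], [1.0, 1.0, -1.0], [2.0, -2.0, 0.5]])
        zp = np.array([[3.0, 1.0, 1.0], [1.0, 0.5, -1.0], [1.0, -2.0, 0.5]])
        # dyad 0, feature 0: product -9; strangers: 1*3=3, 2*3=6, -3*1=-3, -3*1=-3 all > -9
        p = empirical_probability(EdgeProducts(["a", "b", "c"], zc, zp, True))
        assert p[0, 0] == 1.0

    def test_chunking_is_transparent(self):
        cohort = simulate_feature_cohort(6, 50, alpha=0.3, seed=5)
        products = product_vectors(cohort)
        assert np.array_equal(
            empirical_probability(products, chunk=7),
            empirical_probability(products, chunk=1000),
        )


class TestDifferentialPower:
    def test_all_ones_give_zero(self):
        assert np.allclose(differential_power(np.ones((4, 3))), 0.0)

    def test_direct_evaluation(self):
        p = np.full((3, 2), 0.25)
        assert np.allclose(differential_power(p), 3 * np.log(4))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            differential_power(np.array([[0.5, 0.0]]))

    def test_planted_discriminative_features_rank_higher(self):
        # transmission only inside the MF network: its edges should carry
        # the identification signal
        spec = SyntheticSpec(
            n_dyads=20, n_nodes=30, alpha=0.0,
            alpha_by_network={"MF": 0.9}, seed=21,
        )
        study = simulate_cohort(spec)
        cohort = study.fc["age11"]
        res = edge_measures(cohort)
        alpha_fc = study.ground_truth["alpha"]["age11"]["fc"]
        planted = alpha_fc > 0
        assert planted.sum() >= 3
        assert res.dp[planted].mean() > res.dp[~planted].mean()

    def test_permuting_parents_destroys_dp_advantage(self, rng):
        spec = SyntheticSpec(
            n_dyads=20, n_nodes=30, alpha=0.0,
            alpha_by_network={"MF": 0.9}, seed=22,
        )
        study = simulate_cohort(spec)
        cohort = study.fc["age11"]
        alpha_fc = study.ground_truth["alpha"]["age11"]["fc"]
        planted = alpha_fc > 0
        res = edge_measures(cohort)
        advantage = res.dp[planted].mean() - res.dp[~planted].mean()
        # break the dyad mapping
        perm = rng.permutation(cohort.n_dyads)
        shuffled = cohort.parents.subset_subjects([cohort.parent_ids[i] for i in perm])
        from dyadprint.cohort import DyadCohort
        null_cohort = DyadCohort(
            cohort.children, shuffled,
            list(zip(cohort.child_ids, shuffled.subject_ids)),
        )
        null_res = edge_measures(null_cohort)
        null_advantage = null_res.dp[planted].mean() - null_res.dp[~planted].mean()
        assert abs(null_advantage) < 0.25 * advantage


class TestGroupConsistency:
    def test_mean_of_dyad_products(self):
        zc = np.array([[1.0, 2.0], [0.5, 1.0], [1.5, 0.0]])
        zp = np.array([[0.5, 1.0], [3.0, 2.0], [1.0, 0.0]])
        prod = EdgeProducts(["a", "b"], zc, zp, True)
        assert np.allclose(group_consistency(prod), [(0.5 + 1.5 + 1.5) / 3, (2 + 2 + 0) / 3])

    def test_all_zero_feature(self):
        zc = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, -1.0]])
        zp = np.ones((3, 2))
        assert group_consistency(EdgeProducts(["a", "b"], zc, zp, True))[0] == 0.0

    def test_planted_consistent_features_have_high_phi_low_dp(self):
        # features with a large shared population mean and no transmission
        spec = SyntheticSpec(
            n_dyads=24, n_nodes=30, alpha=0.0,
            consistent_mean=4.0, consistent_frac=0.1, seed=30,
        )
        study = simulate_cohort(spec)
        cohort = study.gmv["age11"]
        consistent = np.isin(cohort.feature_ids, study.ground_truth["consistent_gmv"])
        assert consistent.sum() >= 2
        res = edge_measures(cohort)
        assert res.phi_bar[consistent].mean() > res.phi_bar[~consistent].mean()
        # group-consistent features do not help identification
        assert res.dp[consistent].mean() < res.dp[~consistent].mean() + 1.0


class TestSelection:
    def test_top_quarter_percent_of_400(self, rng):
        vals = rng.permutation(400).astype(float)
        sel = top_percentile(vals, [f"f{i}" for i in range(400)], 99.75)
        assert len(sel) == 1

    def test_near_zero_percentile_selects_all(self, rng):
        vals = rng.normal(size=50)
        assert len(top_percentile(vals, [f"f{i}" for i in range(50)], 1e-9)) == 50

    def test_full_edge_set_count(self, rng):
        m = 35778
        vals = rng.permutation(m).astype(float)
        sel = top_percentile(vals, [f"f{i}" for i in range(m)], 99.75)
        assert 89 <= len(sel) <= 91  # about 0.25% of 35,778 edges

    def test_ties_at_cut_included(self):
        vals = np.array([1.0, 2.0, 3.0, 3.0])
        assert len(top_percentile(vals, list("abcd"), 75)) == 2


class TestLobeCounts:
    def test_full_lobe_selected(self):
        atlas = make_atlas(20)
        lobe = atlas.lobes[0]
        members = [n for n in atlas.node_ids if atlas.lobe_of[n] == lobe]
        fracs = lobe_normalized_counts(members, atlas)
        assert fracs[lobe] == 1.0

    def test_empty_selection(self):
        atlas = make_atlas(20)
        assert all(v == 0.0 for v in lobe_normalized_counts([], atlas).values())

    def test_partial_ratio(self):
        atlas = make_atlas(40)
        lobe = atlas.lobes[0]
        members = [n for n in atlas.node_ids if atlas.lobe_of[n] == lobe]
        fracs = lobe_normalized_counts(members[: len(members) // 2], atlas)
        assert fracs[lobe] == pytest.approx(0.5)

    def test_unknown_node_rejected(self):
        atlas = make_atlas(10)
        with pytest.raises(ValidationError, match="ghost"):
            lobe_normalized_counts(["ghost"], atlas)
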