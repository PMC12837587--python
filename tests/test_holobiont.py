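"""Holobiont selection, fitness decomposition, information partition,
T-term diagnostics and the association permutation test."""

import numpy as np
import pytest

from infofolds import (
    FrequencyDistribution,
    HolobiontFitness,
    JointTable,
    association_information_direct,
    compose_fitness,
    decompose_fitness,
    holobiont_select,
    independence_reference,
    marginalize,
    partition,
    permutation_test_association,
    t_terms,
    toy_model,
)

from conftest import product_table_step, random_simplex, random_table_pair

TOY_W = np.array([[1.0, 0.7], [0.7, 2.0]])


class TestComposeDecompose:
    def test_pure_product_fitness(self):
        spec = HolobiontFitness((1.0, 2.0), [(1.0, 1.0)], np.ones((2, 2)))
        assert np.allclose(compose_fitness(spec), [[1.0, 1.0], [2.0, 2.0]])

    def test_all_ones(self):
        spec = HolobiontFitness((1.0, 1.0), [(1.0, 1.0)], np.ones((2, 2)))
        assert np.allclose(compose_fitness(spec), 1.0)

    def test_multiplicative_fitness_recovers_unit_association(self, rng):
        W = np.outer(np.exp(rng.normal(0, 1, 3)), np.exp(rng.normal(0, 1, 4)))
        assert np.allclose(decompose_fitness(W).association, 1.0, atol=1e-12)

    def test_round_trip_random(self, rng):
        for shape in [(2, 2), (3, 4), (2, 3, 2)]:
            W = np.exp(rng.normal(0, 1, shape))
            assert np.allclose(compose_fitness(decompose_fitness(W)), W, atol=1e-12)

    def test_toy_fitness_has_interaction(self):
        a = decompose_fitness(TOY_W).association
        assert not np.allclose(a, 1.0, atol=1e-3)

    def test_effects_mean_centered(self, rng):
        spec = decompose_fitness(np.exp(rng.normal(0, 1, (3, 4))))
        assert np.log(spec.w_components[0]).mean() == pytest.approx(0.0, abs=1e-12)
        assert np.log(spec.association).sum() == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            decompose_fitness([[1.0, -1.0], [1.0, 1.0]])


class TestHolobiontSelect:
    def test_toy_mean_fitness(self, toy):
        q, W, _, _ = toy
        _, wbar = holobiont_select(q, W)
        assert wbar == pytest.approx(1.1, abs=1e-12)

    def test_toy_post_state(self, toy):
        _, _, q_post, _ = toy
        assert np.allclose(
            q_post.values, [[0.2273, 0.1591], [0.1591, 0.4545]], atol=5e-4
        )

    def test_constant_fitness_identity(self, rng):
        q, _ = random_table_pair(rng)
        out, wbar = holobiont_select(q, np.full(q.shape, 3.0))
        assert np.allclose(out.values, q.values)
        assert wbar == pytest.approx(3.0)


class TestMarginals:
    def test_toy_marginals(self, toy):
        _, _, q_post, _ = toy
        host, (m1,) = marginalize(q_post)
        assert np.allclose(host.values, [0.3864, 0.6136], atol=5e-4)
        assert np.allclose(m1.values, host.values)

    def test_product_table_recovers_factors(self, rng):
        f = random_simplex(rng, 3)
        g = random_simplex(rng, 2)
        q = JointTable.product(
            [FrequencyDistribution(("a", "b", "c"), f), FrequencyDistribution(("x", "y"), g)]
        )
        host, (m1,) = marginalize(q)
        assert np.allclose(host.values, f)
        assert np.allclose(m1.values, g)

    def test_uniform(self):
        q = JointTable.uniform(("host", "M1"), (("a", "b"), ("x", "y")))
        host, (m1,) = marginalize(q)
        assert np.allclose(host.values, 0.5)
        assert np.allclose(m1.values, 0.5)


class TestIndependenceReference:
    def test_product_is_its_own_reference(self, rng):
        q, _, _ = product_table_step(rng)
        r = independence_reference(q)
        assert np.allclose(r.values, q.values, atol=1e-12)

    def test_toy_reference_values(self, toy):
        _, _, q_post, _ = toy
        r = independence_reference(q_post)
        assert np.allclose(
            r.values.reshape(-1), [0.14928, 0.23709, 0.23709, 0.37655], atol=5e-5
        )

    def test_reference_shares_marginals(self, rng):
        _, q_post = random_table_pair(rng, (3, 3))
        r = independence_reference(q_post)
        for axis in range(2):
            assert np.allclose(
                r.marginal(axis).values, q_post.marginal(axis).values, atol=1e-12
            )


class TestTTerms:
    def test_no_change_on_product_all_zero(self, rng):
        """With q' = q and q on the independence manifold, r = q and every
        term vanishes; off the manifold only the sum is zero."""
        q, _, _ = product_table_step(rng)
        assert np.allclose(t_terms(q, q), 0.0, atol=1e-12)
        q2, _ = random_table_pair(rng)
        assert sum(t_terms(q2, q2)) == pytest.approx(0.0, abs=1e-12)

    def test_toy_t4_is_association(self, toy):
        q, _, q_post, _ = toy
        T1, T2, T3, T4 = t_terms(q, q_post)
        assert T4 == pytest.approx(0.1097, abs=5e-4)
        assert T3 == pytest.approx(0.0, abs=1e-12)  # uniform q is a product

    def test_sum_identity_random(self, rng):
        from infofolds import jeffreys_divergence

        for _ in range(100):
            q, qp = random_table_pair(rng, (2, 3))
            T = t_terms(q, qp)
            J = jeffreys_divergence(qp.flatten(), q.flatten())
            assert sum(T) == pytest.approx(J, abs=1e-12)

    def test_t3_zero_on_product_initial(self, rng):
        for _ in range(50):
            q, q_post, _ = product_table_step(rng, (3, 2))
            _, _, T3, _ = t_terms(q, q_post)
            assert T3 == pytest.approx(0.0, abs=1e-12)


class TestPartition:
    def test_toy_printed_values(self, toy):
        _, _, _, part = toy
        assert part.J_total == pytest.approx(0.2066, abs=5e-4)
        assert part.J_H == pytest.approx(0.0526, abs=5e-4)
        assert part.J_M[0] == pytest.approx(0.0526, abs=5e-4)
        assert part.J_assoc == pytest.approx(0.1097, abs=5e-4)
        assert part.E == pytest.approx(-0.0082, abs=5e-4)

    def test_association_nonnegative_random(self, rng):
        for _ in range(200):
            q, qp = random_table_pair(rng, (2, 2))
            assert partition(q, qp).J_assoc >= 0

    def test_components_close_by_construction(self, rng):
        q, qp = random_table_pair(rng, (3, 3))
        part = partition(q, qp)
        assert part.J_H + sum(part.J_M) + part.J_assoc + part.E == pytest.approx(
            part.J_total, abs=1e-12
        )
        assert part.T1 + part.T2 + part.T3 + part.T4 == pytest.approx(
            part.J_total, abs=1e-12
        )

    def test_multiplicative_selection_preserves_independence(self, rng):
        """Product q with a == 1 keeps q' on the product manifold:
        J_assoc = 0 and E = 0."""
        for _ in range(50):
            names = ("host", "M1")
            labels = (("H0", "H1"), ("m0", "m1", "m2"))
            margs = [
                FrequencyDistribution(lab, random_simplex(rng, len(lab)))
                for lab in labels
            ]
            q = JointTable.product(margs, axis_names=names)
            W = np.outer(np.exp(rng.normal(0, 1, 2)), np.exp(rng.normal(0, 1, 3)))
            q_post, _ = holobiont_select(q, W)
            part = partition(q, q_post)
            assert part.J_assoc == pytest.approx(0.0, abs=1e-12)
            assert part.E == pytest.approx(0.0, abs=1e-12)

    def test_three_axis_uniform_neutral(self):
        """K = 2 components, no fitness differences: every component 0."""
        q = JointTable.uniform(
            ("host", "M1", "M2"), (("a", "b"), ("x", "y"), ("u", "v"))
        )
        part = partition(q, q)
        assert part.J_total == 0.0
        assert all(v == pytest.approx(0.0, abs=1e-15) for v in part.as_dict().values())

    def test_k2_partition_sums(self, rng):
        names = ("host", "M1", "M2")
        labels = (("a", "b"), ("x", "y"), ("u", "v"))
        v1 = random_simplex(rng, 8).reshape(2, 2, 2)
        v2 = random_simplex(rng, 8).reshape(2, 2, 2)
        q, qp = JointTable(names, labels, v1), JointTable(names, labels, v2)
        part = partition(q, qp)
        assert len(part.J_M) == 2
        assert part.J_H + sum(part.J_M) + part.J_assoc + part.E == pytest.approx(
            part.J_total, abs=1e-12
        )


class TestAssociationDirect:
    def test_unit_association_gives_zero(self, rng):
        q, q_post, W = product_table_step(rng)
        spec = HolobiontFitness(
            np.ones(q.shape[0]), [np.ones(q.shape[1])], W / 1.0
        )
        # gauge with a == W: value equals J_total; with a == 1 it is 0
        unit = HolobiontFitness(np.ones(q.shape[0]), [np.ones(q.shape[1])], np.ones(q.shape))
        assert association_information_direct(q, q_post, unit) == 0.0

    def test_pure_association_gauge_equals_total(self, toy):
        """With W_H = W_M = 1 and a = W, sum (q'-q) ln a = J_total because
        ln a = ln(q'/q) + ln wbar and sum(q'-q) = 0."""
        q, W, q_post, part = toy
        spec = HolobiontFitness(np.ones(2), [np.ones(2)], W)
        val = association_information_direct(q, q_post, spec)
        assert val == pytest.approx(part.J_total, abs=1e-12)

    def test_decomposed_gauge_reported_not_asserted(self, toy):
        """ANOVA-gauge value is finite and of the same order as I_assoc;
        exact equality is gauge-dependent and not asserted."""
        q, W, q_post, part = toy
        val = association_information_direct(q, q_post, decompose_fitness(W))
        assert np.isfinite(val)
        assert abs(val - part.I_assoc) < 0.1


class TestPermutationTest:
    def test_flat_table_p_is_one(self):
        counts = np.full((2, 2), 100)
        _, _, p = permutation_test_association(counts, n_perm=99, seed=1)
        assert p == 1.0

    def test_diagonal_table_is_significant(self):
        counts = np.array([[200, 0], [0, 200]])
        obs, null, p = permutation_test_association(counts, n_perm=199, seed=7)
        assert p <= 0.01
        assert obs > null.max()

    def test_degenerate_margin_warns_p_one(self):
        counts = np.array([[100, 50], [0, 0]])
        with pytest.warns(UserWarning, match="degenerate"):
            _, _, p = permutation_test_association(counts, n_perm=99, seed=1)
        assert p == 1.0

    def test_rejects_non_integer(self):
        with pytest.raises(ValueError, match="integer"):
            permutation_test_association(np.array([[0.5, 0.5], [0.5, 0.5]]), seed=1)

    def test_margins_preserved_under_null(self):
        """The re-pairing scheme keeps both margins: the null statistic of a
        product table concentrates near zero."""
        rng = np.random.default_rng(3)
        counts = rng.multinomial(500, np.outer([0.4, 0.6], [0.3, 0.7]).ravel()).reshape(2, 2)
        obs, null, p = permutation_test_association(counts, n_perm=199, seed=5)
        assert null.max() < 0.1  # small association statistics only


class TestToyModel:
    def test_returns_consistent_bundle(self):
        q, W, q_post, part = toy_model()
        q2, wbar = holobiont_select(q, W)
        assert np.allclose(q2.values, q_post.values)
        assert wbar == pytest.approx(1.1)
        assert part.as_dict() == partition(q, q_post).as_dict()
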