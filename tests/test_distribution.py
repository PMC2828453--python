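"""Truncated polynomial algebra and the three exact-distribution routes."""

import numpy as np
import pytest
from scipy import stats

from pattstat import (
    CountDistribution,
    HomogeneousModel,
    TruncPoly,
    algorithm1,
    algorithm2,
    algorithm3,
    brute_force_distribution,
    compile_dfa,
    embed,
    embed_heterogeneous,
    expected_count,
    make_alphabet,
    mgf_single,
    parse_words,
    poly_mul,
    select_algorithm,
    simulate,
    tail_pvalues,
)
from pattstat.distribution import DistributionError
from pattstat.oracle import make_fixture
from tests.conftest import TOY_G1, TOY_G2, TOY_G3, TOY_LENGTHS, TOY_STARTS


def _dist_from(bf, n_top):
    ref = np.zeros(n_top + 1)
    for k, v in bf.items():
        ref[min(k, n_top)] += v
    return ref


class TestTruncPoly:
    def test_one_is_identity(self):
        rng = np.random.default_rng(0)
        b = TruncPoly(rng.dirichlet(np.ones(6)))
        np.testing.assert_allclose(poly_mul(TruncPoly.one(5), b).c, b.c)

    def test_binomial_fold_saturates(self):
        half = TruncPoly.from_coeffs([0.5, 0.5], n_top=1)
        prod = poly_mul(half, half)
        np.testing.assert_allclose(prod.c, [0.25, 0.75])

    def test_commutative_associative_under_saturation(self):
        rng = np.random.default_rng(1)
        a, b, c = (TruncPoly(rng.dirichlet(np.ones(5))) for _ in range(3))
        np.testing.assert_allclose(poly_mul(a, b).c, poly_mul(b, a).c, atol=1e-15)
        np.testing.assert_allclose(
            poly_mul(poly_mul(a, b), c).c, poly_mul(a, poly_mul(b, c)).c, atol=1e-15
        )

    def test_toy_product_tail(self, toy_chain):
        g1 = mgf_single(toy_chain, "a", 9, 5)
        g2 = mgf_single(toy_chain, "b", 6, 5)
        g3 = mgf_single(toy_chain, "a", 8, 5)
        g = poly_mul(poly_mul(g1, g2), g3)
        assert 100 * (g.c[4] + g.c[5]) == pytest.approx(0.333, abs=5e-4)


class TestMgfSingle:
    @pytest.mark.parametrize(
        "start,length,printed",
        [("a", 9, TOY_G1), ("b", 6, TOY_G2), ("a", 8, TOY_G3)],
    )
    def test_toy_printed_coefficients(self, toy_chain, start, length, printed):
        g = mgf_single(toy_chain, start, length, n_top=6)
        for k, coef in enumerate(printed):
            assert g.c[k] == pytest.approx(coef, abs=5e-8)
        assert g.total() == pytest.approx(1.0, abs=1e-12)

    def test_length_d_no_occurrence(self, toy_chain):
        g = mgf_single(toy_chain, "a", 1, n_top=3)
        np.testing.assert_allclose(g.c, [1, 0, 0, 0])

    def test_length_below_order_errors(self, toy_chain):
        with pytest.raises(DistributionError):
            mgf_single(toy_chain, "a", 0, n_top=2)


class TestAlgorithmsOnToy:
    def test_all_three_reproduce_the_reference_pvalue(self, toy_chain):
        n_top = 5
        outs = {
            "alg1": algorithm1([toy_chain] * 3, TOY_STARTS, TOY_LENGTHS, n_top),
            "alg2": algorithm2(toy_chain, TOY_STARTS, TOY_LENGTHS, n_top)[0],
            "alg3": algorithm3(toy_chain, TOY_STARTS, TOY_LENGTHS, n_top)[0],
        }
        for name, g in outs.items():
            dist = CountDistribution.from_mgf(g)
            _, p_ge = tail_pvalues(dist, 4)
            assert 100 * p_ge == pytest.approx(0.333, abs=5e-4), name

    def test_per_sequence_mgfs_in_input_order(self, toy_chain):
        _, per = algorithm2(toy_chain, TOY_STARTS, TOY_LENGTHS, 6)
        for g, printed in zip(per, [TOY_G1, TOY_G2, TOY_G3]):
            for k, coef in enumerate(printed):
                assert g.c[k] == pytest.approx(coef, abs=5e-8)

    def test_single_sequence_reduces_to_mgf_single(self, toy_chain):
        g = algorithm1([toy_chain], ["a"], [9], 5)
        np.testing.assert_allclose(g.c, mgf_single(toy_chain, "a", 9, 5).c, atol=1e-15)


class TestCrossAlgorithmAgreement:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_homogeneous_instances(self, seed):
        fx = make_fixture(seed, n_symbols=2 + (seed % 2) * 2, order=1,
                          n_words=2, word_len=(2, 4), lengths=(15, 40, 26))
        dfa = compile_dfa(fx.expr, fx.alphabet, 1)
        ch = embed(dfa, fx.model)
        n_top = 6
        g1 = algorithm1([ch] * 3, list(fx.starts), list(fx.lengths), n_top)
        g2, _ = algorithm2(ch, list(fx.starts), list(fx.lengths), n_top)
        g3, _ = algorithm3(ch, list(fx.starts), list(fx.lengths), n_top)
        np.testing.assert_allclose(g1.c, g2.c, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(g1.c, g3.c, rtol=1e-12, atol=1e-14)

    def test_long_sequence_binary_powers(self, toy_chain):
        n_top = 4
        g2, _ = algorithm2(toy_chain, ["a"], [4096 + 1], n_top)
        g3, _ = algorithm3(toy_chain, ["a"], [4096 + 1], n_top)
        np.testing.assert_allclose(g2.c, g3.c, rtol=1e-10)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_homogeneous_small_instances(self, seed):
        fx = make_fixture(100 + seed, n_symbols=2, order=1, lengths=(5, 6, 4))
        dfa = compile_dfa(fx.expr, fx.alphabet, 1)
        ch = embed(dfa, fx.model)
        bf = brute_force_distribution(fx.model, fx.expr, fx.lengths, fx.starts)
        n_top = max(bf) + 1
        for g in (
            algorithm1([ch] * 3, list(fx.starts), list(fx.lengths), n_top),
            algorithm2(ch, list(fx.starts), list(fx.lengths), n_top)[0],
            algorithm3(ch, list(fx.starts), list(fx.lengths), n_top)[0],
        ):
            np.testing.assert_allclose(g.c, _dist_from(bf, n_top), atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_heterogeneous_small_instances(self, seed):
        fx = make_fixture(200 + seed, heterogeneous=True, lengths=(4, 5))
        dfa = compile_dfa(fx.expr, fx.alphabet, 1)
        ch = embed_heterogeneous(dfa, fx.model)
        bf = brute_force_distribution(fx.model, fx.expr, fx.lengths, fx.starts)
        n_top = max(bf) + 1
        g = algorithm1([ch] * 2, list(fx.starts), list(fx.lengths), n_top)
        np.testing.assert_allclose(g.c, _dist_from(bf, n_top), atol=1e-12)


class TestBinomialLimit:
    def test_single_symbol_iid_is_binomial(self, ab2):
        p = 0.3
        model = HomogeneousModel(
            alphabet=ab2, order=0, trans=np.array([[p, 1 - p]])
        )
        dfa = compile_dfa(parse_words(["a"], ab2), ab2, 0)
        ch = embed(dfa, model)
        lengths = [7, 5]
        n_top = sum(lengths) + 1
        g, _ = algorithm2(ch, [() for _ in lengths], lengths, n_top)
        ref = stats.binom.pmf(np.arange(n_top), sum(lengths), p)
        np.testing.assert_allclose(g.c[:-1], ref, atol=1e-12)
        _, p_ge = tail_pvalues(CountDistribution.from_mgf(g), 4)
        assert p_ge == pytest.approx(stats.binom.sf(3, sum(lengths), p), abs=1e-12)


class TestTailPvalues:
    def test_full_mass_at_zero(self, toy_chain):
        g = algorithm1([toy_chain] * 3, TOY_STARTS, TOY_LENGTHS, 5)
        dist = CountDistribution.from_mgf(g)
        p_le, p_ge = tail_pvalues(dist, 0)
        assert p_ge == pytest.approx(1.0, abs=1e-12)
        assert p_le + p_ge - dist.probs[0] == pytest.approx(1.0, abs=1e-12)

    def test_monotonicity(self, toy_chain):
        g = algorithm1([toy_chain] * 3, TOY_STARTS, TOY_LENGTHS, 5)
        dist = CountDistribution.from_mgf(g)
        ge = [tail_pvalues(dist, n)[1] for n in range(5)]
        le = [tail_pvalues(dist, n)[0] for n in range(5)]
        assert all(a >= b for a, b in zip(ge, ge[1:]))
        assert all(a <= b for a, b in zip(le, le[1:]))

    def test_unresolved_count_errors(self, toy_chain):
        g = algorithm1([toy_chain] * 3, TOY_STARTS, TOY_LENGTHS, 3)
        with pytest.raises(DistributionError, match="n_top"):
            tail_pvalues(CountDistribution.from_mgf(g), 3)


class TestSaturation:
    def test_bucket_equals_exact_tail_at_larger_truncation(self, toy_chain):
        small = algorithm1([toy_chain] * 3, TOY_STARTS, TOY_LENGTHS, 3)
        large = algorithm1([toy_chain] * 3, TOY_STARTS, TOY_LENGTHS, 12)
        assert small.c[3] == pytest.approx(large.c[3:].sum(), abs=1e-14)

    def test_distribution_normalized_nonnegative(self, toy_chain):
        for n_top in (1, 2, 5, 9):
            g = algorithm1([toy_chain] * 3, TOY_STARTS, TOY_LENGTHS, n_top)
            assert (g.c >= 0).all()
            assert g.total() == pytest.approx(1.0, abs=1e-12)


class TestExpectedCount:
    def test_periodic_deterministic_chain(self, ab2):
        model = HomogeneousModel(
            alphabet=ab2, order=1, trans=np.array([[0.0, 1.0], [1.0, 0.0]])
        )
        dfa = compile_dfa(parse_words(["ab"], ab2), ab2, 1)
        ch = embed(dfa, model)
        k = 7
        assert expected_count(ch, ["a"], [2 * k]) == pytest.approx(k)

    def test_matches_mgf_derivative(self, toy_chain):
        n_top = 12  # high enough that the bucket is empty
        g = algorithm1([toy_chain] * 3, TOY_STARTS, TOY_LENGTHS, n_top)
        e = expected_count(toy_chain, TOY_STARTS, TOY_LENGTHS)
        assert e == pytest.approx(g.mean(), abs=1e-10)

    def test_matches_monte_carlo(self, toy_chain, toy_model, toy_dfa):
        from pattstat import scan

        n_sim = 5000
        rng_counts = []
        seqs = simulate(toy_model, [9] * n_sim, starts=["a"] * n_sim, seed=21)
        counts = np.array([scan(toy_dfa, s)[0] for s in seqs])
        exact = expected_count(toy_chain, ["a"], [9])
        se = counts.std() / np.sqrt(n_sim)
        assert abs(counts.mean() - exact) < 3 * se


class TestGuardsAndSelection:
    def test_algorithm2_rejects_heterogeneous(self):
        fx = make_fixture(5, heterogeneous=True, lengths=(5, 5))
        dfa = compile_dfa(fx.expr, fx.alphabet, 1)
        ch = embed_heterogeneous(dfa, fx.model)
        with pytest.raises(DistributionError, match="algorithm1"):
            algorithm2(ch, list(fx.starts), list(fx.lengths), 3)

    def test_algorithm3_complexity_guard(self, toy_chain):
        with pytest.raises(DistributionError, match="high complexity"):
            algorithm3(toy_chain, ["a"], [10], 3, l_guard=5)

    def test_auto_selection(self, toy_chain):
        fx = make_fixture(5, heterogeneous=True, lengths=(5, 5))
        dfa = compile_dfa(fx.expr, fx.alphabet, 1)
        het = embed_heterogeneous(dfa, fx.model)
        assert select_algorithm(het, [5, 5]) == "alg1"
        assert select_algorithm(toy_chain, [100]) == "alg2"
        assert select_algorithm(toy_chain, [100_000]) == "alg3"
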