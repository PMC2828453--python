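"""Markov model fitting, simulation and spectral diagnostics."""

import numpy as np
import pytest

from pattstat import (
    HomogeneousModel,
    fit_heterogeneous_window,
    fit_homogeneous,
    make_alphabet,
    marginal_profile,
    model_from_json,
    model_to_json,
    simulate,
    spectral_diagnostics,
    stationary_distribution,
)
from pattstat.markov import ModelError


class TestFitHomogeneous:
    def test_single_observed_transition(self, ab2):
        model = fit_homogeneous(["aaaa"], ab2, 1, pseudocount=1e-9)
        assert model.prob("a", ab2.index("a")) == pytest.approx(1.0)

    def test_deterministic_alternation(self, ab2):
        model = fit_homogeneous(["abab", "abab"], ab2, 1, pseudocount=1e-12)
        assert model.prob("a", ab2.index("b")) == pytest.approx(1.0)
        assert model.prob("b", ab2.index("a")) == pytest.approx(1.0)

    def test_unseen_context_is_hard_error(self, ab2):
        with pytest.raises(ModelError, match="b"):
            fit_homogeneous(["aaaa"], ab2, 1, pseudocount=0.0)

    def test_start_distribution_is_empirical(self, ab2):
        model = fit_homogeneous(["ab", "ba", "ab"], ab2, 1)
        np.testing.assert_allclose(model.start, [2 / 3, 1 / 3])

    def test_parameter_recovery_two_sample_sizes(self, ab2):
        truth = HomogeneousModel(
            alphabet=ab2, order=1, trans=np.array([[0.8, 0.2], [0.35, 0.65]]),
            start=np.array([0.5, 0.5]),
        )
        errors = []
        for n_seq, length in [(20, 100), (500, 100)]:
            seqs = simulate(truth, [length] * n_seq, seed=5)
            fit = fit_homogeneous(seqs, ab2, 1)
            errors.append(np.abs(fit.trans - truth.trans).max())
            # within 3 binomial standard errors of the truth
            se = np.sqrt(0.8 * 0.2 / (n_seq * length / 2))
            assert errors[-1] < 3 * se + 0.02
        assert errors[1] < errors[0]  # error shrinks with sample size


class TestFitHeterogeneousWindow:
    def test_full_window_equals_homogeneous(self, ab2):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(["a", "b"], 20)) for _ in range(5)]
        hom = fit_homogeneous(seqs, ab2, 1)
        het = fit_heterogeneous_window(seqs, ab2, 1, window=100)
        for i in range(het.trans.shape[0]):
            np.testing.assert_allclose(het.trans[i], hom.trans)

    def test_two_positions_degenerate_window(self, ab2):
        het = fit_heterogeneous_window(["ab", "ab", "ba"], ab2, 1, window=2)
        hom = fit_homogeneous(["ab", "ab", "ba"], ab2, 1)
        np.testing.assert_allclose(het.trans[0], hom.trans)

    def test_change_point_recovered(self, ab2):
        # regime switch in pi at mid-sequence; windowed profile must move
        # from one regime to the other around the change point
        ell, w = 120, 30
        a1 = np.array([[0.9, 0.1], [0.9, 0.1]])
        a2 = np.array([[0.1, 0.9], [0.1, 0.9]])
        trans = np.stack([a1 if i < ell // 2 else a2 for i in range(ell - 1)])
        from pattstat import HeterogeneousModel

        truth = HeterogeneousModel(
            alphabet=ab2, order=1, trans=trans, start=np.array([0.5, 0.5])
        )
        seqs = simulate(truth, [ell] * 400, seed=11)
        fit = fit_heterogeneous_window(seqs, ab2, 1, window=w)
        early = fit.trans[10, 0, 0]  # pi_i(a,a) in regime 1
        late = fit.trans[ell - 12, 0, 0]
        assert early > 0.8 and late < 0.2

    def test_unequal_lengths_error(self, ab2):
        with pytest.raises(ModelError, match="equal"):
            fit_heterogeneous_window(["ab", "aba"], ab2, 1, window=4)


class TestStationary:
    def test_uniform_two_state(self, ab2):
        model = HomogeneousModel(alphabet=ab2, order=1, trans=np.full((2, 2), 0.5))
        np.testing.assert_allclose(stationary_distribution(model), [0.5, 0.5])

    def test_doubly_stochastic_is_uniform(self):
        ab = make_alphabet("dna")
        row = [0.4, 0.3, 0.2, 0.1]
        m = np.array([np.roll(row, k) for k in range(4)])  # circulant
        model = HomogeneousModel(alphabet=ab, order=1, trans=m)
        np.testing.assert_allclose(stationary_distribution(model), np.full(4, 0.25))

    def test_matches_power_iteration(self):
        ab = make_alphabet("dna")
        rng = np.random.default_rng(7)
        m = rng.dirichlet(np.ones(4), 4)
        model = HomogeneousModel(alphabet=ab, order=1, trans=m)
        v = np.full(4, 0.25)
        for _ in range(3000):
            v = v @ m
        np.testing.assert_allclose(stationary_distribution(model), v, atol=1e-10)

    def test_reducible_chain_errors(self, ab2):
        model = HomogeneousModel(alphabet=ab2, order=1, trans=np.eye(2))
        with pytest.raises(ModelError, match="reducible|classes"):
            stationary_distribution(model)


class TestSpectral:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.45])
    def test_symmetric_two_state_mu(self, ab2, p):
        model = HomogeneousModel(
            alphabet=ab2, order=1, trans=np.array([[1 - p, p], [p, 1 - p]])
        )
        diag = spectral_diagnostics(model)
        assert diag.second_eigenvalue_magnitude == pytest.approx(abs(1 - 2 * p))

    def test_mu_matches_dense_eigendecomposition(self):
        ab = make_alphabet("dna")
        rng = np.random.default_rng(9)
        m = rng.dirichlet(np.ones(4), 4)
        model = HomogeneousModel(alphabet=ab, order=1, trans=m)
        mu = spectral_diagnostics(model).second_eigenvalue_magnitude
        ref = np.sort(np.abs(np.linalg.eigvals(m)))[-2]
        assert mu == pytest.approx(ref, rel=1e-12)

    def test_horizon_shrinks_with_mixing(self, ab2):
        slow = HomogeneousModel(alphabet=ab2, order=1,
                                trans=np.array([[0.95, 0.05], [0.05, 0.95]]))
        fast = HomogeneousModel(alphabet=ab2, order=1,
                                trans=np.array([[0.5, 0.5], [0.55, 0.45]]))
        assert (
            spectral_diagnostics(slow, 1e-12).convergence_horizon
            > spectral_diagnostics(fast, 1e-12).convergence_horizon
        )


class TestMarginalProfile:
    def test_stationary_start_is_constant(self, toy_model):
        v = stationary_distribution(toy_model)
        prof = marginal_profile(toy_model, start=v, length=20)
        for row in prof[1:]:
            np.testing.assert_allclose(row, prof[0], atol=1e-12)

    def test_point_start_approaches_stationary(self, toy_model):
        prof = marginal_profile(toy_model, start=np.array([1.0, 0.0]), length=40)
        from pattstat import stationary_symbol_distribution

        stat = stationary_symbol_distribution(toy_model)
        d1 = np.abs(prof[0] - stat).max()
        d30 = np.abs(prof[29] - stat).max()
        assert d30 <= d1

    def test_length_d_is_start_marginal(self, toy_model):
        prof = marginal_profile(toy_model, start=np.array([0.0, 1.0]), length=1)
        np.testing.assert_allclose(prof[0], [0.0, 1.0])

    def test_rows_sum_to_one(self, toy_model):
        prof = marginal_profile(toy_model, length=15)
        np.testing.assert_allclose(prof.sum(axis=1), np.ones(15), atol=1e-12)


class TestSimulate:
    def test_deterministic_given_seed(self, toy_model):
        a = simulate(toy_model, [50, 30], seed=42)
        b = simulate(toy_model, [50, 30], seed=42)
        assert a == b

    def test_deterministic_chain(self, ab2):
        model = HomogeneousModel(
            alphabet=ab2, order=1, trans=np.array([[0.0, 1.0], [1.0, 0.0]])
        )
        (seq,) = simulate(model, [6], starts=["a"], seed=0)
        assert "".join(ab2.decode(seq)) == "ababab"

    def test_empirical_transitions_converge(self, toy_model):
        (seq,) = simulate(toy_model, [100_000], starts=["a"], seed=3)
        pairs = np.zeros((2, 2))
        for x, y in zip(seq, seq[1:]):
            pairs[x, y] += 1
        emp = pairs / pairs.sum(axis=1, keepdims=True)
        assert np.abs(emp - toy_model.trans).max() < 0.01

    def test_bad_start_word_length(self, toy_model):
        with pytest.raises(ModelError, match="length"):
            simulate(toy_model, [5], starts=["ab"], seed=0)


def test_model_json_round_trip_lossless(toy_model):
    again = model_from_json(model_to_json(toy_model))
    np.testing.assert_array_equal(again.trans, toy_model.trans)
    np.testing.assert_array_equal(again.start, toy_model.start)
    assert again.order == toy_model.order
    assert again.alphabet.symbols == toy_model.alphabet.symbols
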