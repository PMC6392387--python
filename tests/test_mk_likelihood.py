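"""Mk transition probabilities, discrete-gamma rates and pruning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from morphoclock.mk_likelihood import (
    CONDITION_ON_VARIABLE,
    MkPartitionedLikelihood,
    SiteRateModel,
    discrete_gamma_rates,
    matrix_loglik,
    mk_transition_matrix,
    prob_variable,
    prune_character_loglik,
)
from morphoclock.morph_matrix_io import MISSING, CharacterMatrix, PartitionScheme
from morphoclock.trees import TimeTree

from conftest import brute_force_loglik


class TestTransitionMatrix:
    def test_zero_length_is_identity(self):
        assert np.allclose(mk_transition_matrix(2, 0.0), np.eye(2))

    def test_saturation_limit_is_uniform(self):
        for k in (2, 3, 7):
            assert np.allclose(mk_transition_matrix(k, 1e3), np.full((k, k), 1 / k))

    def test_matches_matrix_exponential(self):
        # independent oracle: expm of the k-state equal-rates generator
        from scipy.linalg import expm

        for k, nu in [(2, 0.5), (3, 0.17), (5, 1.3)]:
            q = np.full((k, k), 1.0 / (k - 1))
            np.fill_diagonal(q, -1.0)
            assert np.allclose(
                mk_transition_matrix(k, nu), expm(q * nu), atol=1e-12
            )

    def test_known_binary_value(self):
        p = mk_transition_matrix(2, 0.5)
        assert p[0, 0] == pytest.approx(0.5 + 0.5 * np.exp(-1), abs=1e-9)

    @given(
        k=st.integers(2, 10),
        nu=st.floats(0.0, 50.0, allow_nan=False),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_rows_sum_to_one_and_entries_in_unit_interval(self, k, nu):
        p = mk_transition_matrix(k, nu)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all() and (p <= 1).all()
        assert np.allclose(p, p.T)

    def test_p_same_monotone_decreasing_in_nu(self):
        nus = np.linspace(0, 5, 40)
        psame = [mk_transition_matrix(3, v)[0, 0] for v in nus]
        assert np.all(np.diff(psame) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mk_transition_matrix(1, 0.1)
        with pytest.raises(ValueError):
            mk_transition_matrix(2, -0.1)


class TestDiscreteGamma:
    def test_single_category(self):
        assert discrete_gamma_rates(0.5, 1).tolist() == [1.0]

    def test_large_alpha_limit(self):
        r = discrete_gamma_rates(100.0, 4)
        assert (r > 0.75).all() and (r < 1.25).all()
        assert r.mean() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("alpha,n", [(1.0, 4), (0.3, 4), (2.5, 6)])
    def test_bin_means_match_quadrature(self, alpha, n):
        # oracle: numerical integration of x f(x) over each quantile bin
        dist = stats.gamma(alpha, scale=1 / alpha)
        edges = np.concatenate(([0], dist.ppf(np.arange(1, n) / n), [np.inf]))
        expected = []
        for a, b in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(lambda x: x * dist.pdf(x), a, min(b, 1e3))
            expected.append(val * n)
        got = discrete_gamma_rates(alpha, n)
        assert np.allclose(got, expected, rtol=1e-6)
        assert got.mean() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(got) > 0).all()

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)


class TestPruning:
    def test_all_missing_cherry_is_certain(self, cherry4):
        bl = np.full(cherry4.n_nodes, 0.3)
        col = np.full(4, MISSING, dtype=np.int16)
        assert prune_character_loglik(cherry4, bl, col, 2) == pytest.approx(0.0)

    def test_single_observed_tip_is_stationary(self, cherry4):
        bl = np.full(cherry4.n_nodes, 0.7)
        col = np.array([0, MISSING, MISSING, MISSING], dtype=np.int16)
        ll = prune_character_loglik(cherry4, bl, col, 2)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_enumeration(self, caterpillar5, k):
        rng = np.random.default_rng(7)
        rates = discrete_gamma_rates(0.8, 4)
        for _ in range(8):
            bl = rng.uniform(0.05, 1.2, caterpillar5.n_nodes)
            col = rng.integers(-1, k, caterpillar5.n_tips).astype(np.int16)
            got = prune_character_loglik(caterpillar5, bl, col, k, rates)
            want = brute_force_loglik(caterpillar5, bl, col, k, rates)
            assert got == pytest.approx(want, abs=1e-10)

    def test_state_out_of_range_rejected(self, cherry4):
        bl = np.ones(cherry4.n_nodes)
        with pytest.raises(ValueError):
            prune_character_loglik(cherry4, bl, np.array([0, 1, 2, 0]), 2)

    def test_relabeling_invariance(self, cherry4):
        # uniform equilibrium: permuting state labels leaves the likelihood
        bl = np.full(cherry4.n_nodes, 0.4)
        col = np.array([0, 1, 2, 0], dtype=np.int16)
        perm = np.array([2, 0, 1])
        ll1 = prune_character_loglik(cherry4, bl, col, 3)
        ll2 = prune_character_loglik(cherry4, bl, perm[col], 3)
        assert ll1 == pytest.approx(ll2, abs=1e-12)


class TestProbVariable:
    def test_two_tip_closed_form(self):
        tree = TimeTree.from_newick("(A:1,B:1);")
        bl = np.full(tree.n_nodes, 0.25)
        # P(same tip states) = sum_s P(s)*[P(s->a)P(s->b) summed] with
        # nu = 0.25 per branch: 0.5 (1 + e^-1)
        expect = 0.5 * (1 + np.exp(-1))
        assert prob_variable(tree, bl, 2) == pytest.approx(1 - expect, abs=1e-12)

    def test_saturation_limit(self):
        tree = TimeTree.from_newick("(A:1,B:1);")
        bl = np.full(tree.n_nodes, 1e3)
        assert prob_variable(tree, bl, 2) == pytest.approx(0.5, abs=1e-9)

    def test_zero_lengths_give_zero(self, cherry4):
        assert prob_variable(cherry4, np.zeros(cherry4.n_nodes), 3) == 0.0

    def test_conditional_likelihoods_normalise(self, cherry4):
        bl = np.full(cherry4.n_nodes, 0.35)
        rates = discrete_gamma_rates(1.2, 4)
        pv = prob_variable(cherry4, bl, 2, rates)
        total = 0.0
        for pat in itertools.product(range(2), repeat=4):
            if len(set(pat)) < 2:
                continue
            ll = prune_character_loglik(
                cherry4, bl, np.array(pat, dtype=np.int16), 2, rates
            )
            total += np.exp(ll - np.log(pv))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestMatrixLoglik:
    def _matrix(self):
        states = np.array(
            [[0, 1, 0], [1, MISSING, 0], [0, 2, 1], [1, 0, MISSING]],
            dtype=np.int16,
        )
        return CharacterMatrix(
            ["A", "B", "C", "D"], states, np.array([2, 3, 2]),
            ["p1", "p2", "p1"], ["c1", "c2", "c3"],
        )

    def test_single_character_consistency(self, cherry4):
        m = self._matrix().select(np.array([0]))
        scheme = PartitionScheme.unpartitioned(m)
        rates = {"all": np.full(cherry4.n_nodes, 0.3)}
        total, per = matrix_loglik(
            m, scheme, cherry4, rates, {"all": SiteRateModel(0.9, 4)}
        )
        bl = 0.3 * cherry4.branch_durations()
        ref = prune_character_loglik(
            cherry4, bl, m.states[:, 0], 2, discrete_gamma_rates(0.9, 4)
        )
        assert total == pytest.approx(ref, abs=1e-9)

    def test_identical_partitions_symmetric(self, cherry4):
        states = np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=np.int16)
        m = CharacterMatrix(["A", "B", "C", "D"], states, np.array([2, 2]),
                            ["p1", "p2"], ["c1", "c2"])
        scheme = PartitionScheme.from_labels(m)
        r = np.full(cherry4.n_nodes, 0.2)
        _, per = matrix_loglik(
            m, scheme, cherry4, {"p1": r, "p2": r},
            {"p1": SiteRateModel(1, 4), "p2": SiteRateModel(1, 4)},
        )
        assert per["p1"] == pytest.approx(per["p2"], abs=1e-12)

    def test_engine_matches_reference_with_correction(self, cherry4):
        m = self._matrix()
        scheme = PartitionScheme.from_labels(m)
        eng = MkPartitionedLikelihood(
            m, cherry4, scheme, n_categories=4,
            ascertainment=CONDITION_ON_VARIABLE,
        )
        r = np.full(cherry4.n_nodes, 0.4)
        got = eng.partition_loglik("p1", cherry4.ages, r, 1.1)
        rates = discrete_gamma_rates(1.1, 4)
        bl = 0.4 * cherry4.branch_durations()
        pv = prob_variable(cherry4, bl, 2, rates)
        want = (
            prune_character_loglik(cherry4, bl, m.states[:, 0], 2, rates)
            + prune_character_loglik(cherry4, bl, m.states[:, 2], 2, rates)
            - 2 * np.log(pv)
        )
        assert got == pytest.approx(want, abs=1e-9)

    def test_random_trees_match_enumeration(self):
        # property sweep over random small trees and parameters
        rng = np.random.default_rng(42)
        newicks = [
            "((A:1,B:1):1,C:2);",
            "((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);",
            "((((A:1,B:1):1,C:2):1,D:3):1,E:4);",
        ]
        for nw in newicks:
            tree = TimeTree.from_newick(nw)
            for k in (2, 3):
                bl = rng.uniform(0.01, 2.0, tree.n_nodes)
                col = rng.integers(0, k, tree.n_tips).astype(np.int16)
                rates = discrete_gamma_rates(rng.uniform(0.3, 3.0), 3)
                got = prune_character_loglik(tree, bl, col, k, rates)
                want = brute_force_loglik(tree, bl, col, k, rates)
                assert got == pytest.approx(want, abs=1e-10)
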