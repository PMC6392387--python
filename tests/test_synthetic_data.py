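"""Forward simulator: trees, rates, characters, ascertainment, replicas."""

import numpy as np
import pytest
from scipy import stats

from morphoclock.mk_likelihood import prob_variable
from morphoclock.morph_matrix_io import MISSING
from morphoclock.synthetic_data import (
    PartitionSimSpec,
    STUDY_PARTITION_SIZES,
    ascertainment_filter,
    default_study_spec,
    draw_branch_rates,
    make_study_replica,
    simulate_characters,
    simulate_timetree,
)
from morphoclock.time_tree_priors import BirthDeathParams, _bd_quantile
from morphoclock.trees import TimeTree


class TestSimulateTimetree:
    def test_minimal_tree_arithmetic(self):
        t = simulate_timetree(3, 10.0, 0.1, rng=1)
        assert t.n_tips == 3
        assert t.n_nodes - t.n_tips == 2
        assert t.ages[t.root] == pytest.approx(10.0)

    def test_same_seed_same_newick(self):
        a = simulate_timetree(9, 50.0, 0.05, 0.01, 0.5, rng=7)
        b = simulate_timetree(9, 50.0, 0.05, 0.01, 0.5, rng=7)
        assert a.to_newick() == b.to_newick()

    def test_valid_timetree_invariants(self):
        t = simulate_timetree(20, 120.0, 0.04, 0.02, 0.1, rng=3)
        for v in t.postorder_internal:
            c0, c1 = t.children_of(int(v))
            assert t.ages[v] > max(t.ages[c0], t.ages[c1])
        assert np.all(t.ages[: t.n_tips] == 0)

    def test_yule_age_distribution(self):
        # KS against the closed-form conditioned Yule age density: with
        # mu=0, rho=1 the non-root ages are iid truncated exponentials
        lam, T = 0.05, 60.0
        rng = np.random.default_rng(11)
        ages = []
        for _ in range(400):
            t = simulate_timetree(5, T, lam, 0.0, 1.0, rng)
            ages.extend(t.ages[t.n_tips : t.root])
        z = 1 - np.exp(-lam * T)

        def cdf(x):
            return (1 - np.exp(-lam * np.asarray(x))) / z

        assert stats.kstest(ages, cdf).pvalue > 0.01


class TestDrawBranchRates:
    def test_strict_clock_limit(self):
        t = simulate_timetree(6, 30.0, 0.1, rng=0)
        r = draw_branch_rates(t, np.log(0.01), 0.0, rng=0)
        assert np.allclose(r, 0.01)

    def test_lognormal_moments(self):
        t = simulate_timetree(3, 10.0, 0.1, rng=0)
        m, s = -2.0, 0.5
        rng = np.random.default_rng(1)
        draws = np.concatenate(
            [draw_branch_rates(t, m, s, rng)[: t.n_nodes - 1] for _ in range(3000)]
        )
        want = np.exp(m + s * s / 2)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - want) < 2 * se + 1e-12

    def test_seed_reproducible(self):
        t = simulate_timetree(6, 30.0, 0.1, rng=0)
        assert np.array_equal(
            draw_branch_rates(t, -2, 0.3, rng=5), draw_branch_rates(t, -2, 0.3, rng=5)
        )


class TestSimulateCharacters:
    def test_zero_rates_all_invariant(self):
        t = simulate_timetree(6, 30.0, 0.1, rng=0)
        mat, _ = simulate_characters(
            t, np.zeros(t.n_nodes), [PartitionSimSpec("p", 50, 1.0, {3: 1.0}, None)],
            0.0, rng=1,
        )
        for c in range(mat.n_chars):
            assert len(np.unique(mat.states[:, c])) == 1

    def test_saturation_uniform_tips(self):
        t = simulate_timetree(4, 30.0, 0.1, rng=0)
        mat, _ = simulate_characters(
            t, np.full(t.n_nodes, 100.0),
            [PartitionSimSpec("p", 4000, 1.0, {4: 1.0}, None)], 0.0, rng=2,
        )
        counts = np.bincount(mat.states.ravel(), minlength=4)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_single_branch_transition_frequency(self):
        # two-tip tree = two independent branches from the root; the
        # fraction of identical tip pairs matches the closed form
        t = TimeTree.from_newick("(A:10,B:10);")
        rate = 0.03
        n = 50_000
        mat, _ = simulate_characters(
            t, np.full(t.n_nodes, rate),
            [PartitionSimSpec("p", n, 1.0, {2: 1.0}, None)], 0.0, rng=3,
        )
        same = (mat.states[0] == mat.states[1]).mean()
        # both tips evolve nu = 0.3 from the root: P(equal) = sum over the
        # root state of the chance both copies match
        e = np.exp(-2 * 0.3)
        p_same_branch = 0.5 + 0.5 * e
        p_equal = p_same_branch**2 + (1 - p_same_branch) ** 2
        se = np.sqrt(p_equal * (1 - p_equal) / n)
        assert abs(same - p_equal) < 3 * se

    def test_missing_fraction_applied(self):
        t = simulate_timetree(8, 40.0, 0.05, rng=0)
        mat, _ = simulate_characters(
            t, np.full(t.n_nodes, 0.01),
            [PartitionSimSpec("p", 2000, 1.0, {2: 1.0}, 1.0)], 0.3, rng=4,
        )
        frac = (mat.states == MISSING).mean()
        assert frac == pytest.approx(0.3, abs=0.02)


class TestAscertainmentFilter:
    def _matrix(self, rng, n=300, rate=0.004):
        t = simulate_timetree(8, 60.0, 0.05, rng=rng)
        mat, _ = simulate_characters(
            t, np.full(t.n_nodes, rate),
            [PartitionSimSpec("p", n, 1.0, {2: 1.0}, None)], 0.0, rng=rng,
        )
        return t, mat

    def test_no_invariant_columns_is_identity(self):
        rng = np.random.default_rng(5)
        t, mat = self._matrix(rng, rate=0.5)
        out, discarded = ascertainment_filter(mat)
        assert out.n_chars == mat.n_chars
        assert discarded == 0.0

    def test_invariant_columns_dropped(self):
        rng = np.random.default_rng(6)
        t, mat = self._matrix(rng)
        out, discarded = ascertainment_filter(mat)
        assert out.n_chars < mat.n_chars
        assert discarded == pytest.approx(1 - out.n_chars / mat.n_chars)
        for c in range(out.n_chars):
            assert len(np.unique(out.states[:, c])) >= 2

    def test_discard_rate_matches_prob_variable(self):
        # oracle: the likelihood module's variable-character probability
        rng = np.random.default_rng(7)
        t = simulate_timetree(6, 50.0, 0.05, rng=rng)
        rate = 0.005
        mat, _ = simulate_characters(
            t, np.full(t.n_nodes, rate),
            [PartitionSimSpec("p", 20_000, 1.0, {2: 1.0}, None)], 0.0, rng=rng,
        )
        _, discarded = ascertainment_filter(mat)
        bl = rate * t.branch_durations()
        pvar = prob_variable(t, bl, 2)
        se = np.sqrt(pvar * (1 - pvar) / 20_000)
        assert abs((1 - discarded) - pvar) < 3 * se

    def test_top_up_reaches_target(self):
        rng = np.random.default_rng(8)
        t, mat = self._matrix(rng, n=100)

        def resim(n, r):
            m, _ = simulate_characters(
                t, np.full(t.n_nodes, 0.004),
                [PartitionSimSpec("p", n, 1.0, {2: 1.0}, None)], 0.0, rng=rng,
            )
            return m

        out, _ = ascertainment_filter(
            mat, target_count=100, top_up=True, resimulate=resim, rng=rng
        )
        assert out.n_chars == 100

    def test_degenerate_top_up_raises(self):
        rng = np.random.default_rng(9)
        t = simulate_timetree(5, 10.0, 0.1, rng=rng)
        mat, _ = simulate_characters(
            t, np.zeros(t.n_nodes),
            [PartitionSimSpec("p", 10, 1.0, {2: 1.0}, None)], 0.0, rng=rng,
        )

        def resim(n, r):
            m, _ = simulate_characters(
                t, np.zeros(t.n_nodes),
                [PartitionSimSpec("p", n, 1.0, {2: 1.0}, None)], 0.0, rng=rng,
            )
            return m

        with pytest.raises(RuntimeError, match="variable characters"):
            ascertainment_filter(mat, target_count=10, top_up=True,
                                 resimulate=resim, rng=rng, max_attempts=5)


class TestStudyReplica:
    def test_partition_sizes_scale(self):
        rep = make_study_replica(1, scale=0.1, n_taxa=10)
        sizes = {k: len(v) for k, v in rep.scheme.mapping.items()}
        assert sizes == {name: round(0.1 * n)
                         for name, n in STUDY_PARTITION_SIZES.items()}

    def test_full_scale_character_total(self):
        spec = default_study_spec(0, scale=1.0, n_taxa=40)
        assert sum(p.n_characters for p in spec.partitions) == 4541

    def test_seed_reproducible_nexus(self, tmp_path):
        from morphoclock.morph_matrix_io import write_nexus_matrix

        a = make_study_replica(3, scale=0.02, n_taxa=8)
        b = make_study_replica(3, scale=0.02, n_taxa=8)
        pa, pb = tmp_path / "a.nex", tmp_path / "b.nex"
        write_nexus_matrix(a.matrix, pa)
        write_nexus_matrix(b.matrix, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.tree.to_newick() == b.tree.to_newick()

    def test_calibrations_resolve_on_tree(self):
        rep = make_study_replica(2, scale=0.02, n_taxa=10)
        assert rep.calibrations[0].mean == 183.2  # crown prior on the root
        for cal in rep.calibrations:
            node = rep.tree.mrca(cal.taxa)
            assert node >= rep.tree.n_tips

    def test_scale_too_small_raises(self):
        with pytest.raises(ValueError, match="empty"):
            default_study_spec(0, scale=1e-4)

    def test_likelihood_prefers_truth_over_perturbation(self):
        # simulator -> likelihood consistency sweep
        from morphoclock.mk_likelihood import MkPartitionedLikelihood, NONE
        rep = make_study_replica(4, scale=0.03, n_taxa=8)
        lik = MkPartitionedLikelihood(
            rep.matrix, rep.tree, rep.scheme, n_categories=4,
            ascertainment="condition_on_variable",
        )
        def total(factor):
            return sum(
                lik.partition_loglik(p, rep.tree.ages,
                                     rep.truth.rates[p] * factor, 1.0)
                for p in lik.partitions
            )
        at_truth = total(1.0)
        assert at_truth > total(4.0)
        assert at_truth > total(0.25)
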