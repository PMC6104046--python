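"""Substitution models: rate matrices, gamma categories, pruning
likelihoods against brute-force enumeration, ascertainment correction."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from tipdating.models import (
    LikelihoodError, SiteModel, build_rate_matrix, constant_pattern_log_prob,
    discrete_gamma_rates, morph_tip_partials, partition_log_likelihood,
    transition_probs, variable_coding_correction,
)
from tests.conftest import brute_force_pattern_prob


def indicator_partials(states, k):
    """(n_tips, 1, k) partials for one character; entries may be state
    ints or sets."""
    out = np.zeros((len(states), 1, k))
    for i, s in enumerate(states):
        members = [s] if np.isscalar(s) else list(s)
        for m in members:
            out[i, 0, m] = 1.0
    return out


class TestRateMatrices:
    def test_mk_unordered_symmetric(self):
        Q = build_rate_matrix(SiteModel(family="mk", k=2))
        off = Q[~np.eye(2, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(Q.sum(axis=1), 0)

    def test_mk_ordered_stepwise(self):
        Q = build_rate_matrix(SiteModel(family="mk", k=3, ordered=True))
        assert Q[0, 2] == 0 and Q[2, 0] == 0
        assert Q[0, 1] > 0

    def test_gtr_equal_rates_equals_mk4(self):
        gtr = build_rate_matrix(SiteModel(family="gtr"))
        mk4 = build_rate_matrix(SiteModel(family="mk", k=4))
        assert np.allclose(gtr, mk4, atol=1e-12)

    def test_gtr_detailed_balance(self):
        m = SiteModel(family="gtr",
                      exchangeabilities=[1, 2, 0.5, 1.5, 3, 1],
                      base_freqs=[0.1, 0.2, 0.3, 0.4])
        Q = build_rate_matrix(m)
        pi = m.base_freqs
        flows = pi[:, None] * Q
        assert np.allclose(flows, flows.T, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(LikelihoodError):
            SiteModel(family="mk", k=1)
        with pytest.raises(LikelihoodError):
            SiteModel(family="mk", gamma_shape=-1)


class TestTransitionProbs:
    def test_zero_branch_is_identity(self):
        Q = build_rate_matrix(SiteModel(family="mk", k=3))
        assert np.allclose(transition_probs(Q, 0.0), np.eye(3))

    def test_mk_closed_form(self):
        k, t = 4, 0.5
        Q = build_rate_matrix(SiteModel(family="mk", k=k))
        P = transition_probs(Q, t)
        stay = 1 / k + ((k - 1) / k) * math.exp(-(k / (k - 1)) * t)
        assert P[0, 0] == pytest.approx(stay, abs=1e-12)
        assert np.allclose(P.sum(axis=1), 1)

    def test_long_branch_reaches_stationarity(self):
        Q = build_rate_matrix(SiteModel(family="mk", k=4))
        P = transition_probs(Q, 500.0)
        assert np.allclose(P, 0.25, atol=1e-9)

    def test_invalid_time(self):
        Q = build_rate_matrix(SiteModel(family="mk", k=2))
        with pytest.raises(LikelihoodError):
            transition_probs(Q, float("nan"))


class TestGammaRates:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 5.0])
    def test_mean_one(self, alpha):
        assert discrete_gamma_rates(alpha, 4).mean() == \
            pytest.approx(1.0, abs=1e-12)

    def test_large_shape_limit(self):
        assert np.allclose(discrete_gamma_rates(1e5, 4), 1.0, atol=1e-2)

    def test_category_means_match_quadrature(self):
        alpha, n = 0.5, 4
        bounds = stats.gamma.ppf(np.arange(1, n) / n, alpha,
                                 scale=1 / alpha)
        bounds = np.concatenate([[0], bounds, [np.inf]])
        expected = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mass, _ = integrate.quad(
                lambda x: x * stats.gamma.pdf(x, alpha, scale=1 / alpha),
                lo, min(hi, 1e3))
            expected.append(mass * n)
        assert np.allclose(discrete_gamma_rates(alpha, n), expected,
                           atol=1e-6)

    def test_invalid(self):
        with pytest.raises(LikelihoodError):
            discrete_gamma_rates(0.5, 0)
        with pytest.raises(LikelihoodError):
            discrete_gamma_rates(-1.0)


class TestPruningOracle:
    @pytest.mark.parametrize("model_kw, states", [
        (dict(family="mk", k=2), [0, 1, 1, 0]),
        (dict(family="mk", k=3, ordered=True), [0, 2, 1, 1]),
        (dict(family="mk", k=2, gamma_shape=0.5), [0, 1, 0, 0]),
        (dict(family="gtr"), [0, 3, 2, 1]),
        (dict(family="gtr", exchangeabilities=[1, 2, 0.5, 1.5, 3, 1],
              base_freqs=[0.1, 0.2, 0.3, 0.4], gamma_shape=0.7),
         [2, 2, 0, 1]),
    ])
    def test_matches_brute_force(self, quartet_tree, model_kw, states):
        model = SiteModel(**model_kw)
        bl = quartet_tree.durations() * 0.3
        partials = indicator_partials(states, model.k)
        res = partition_log_likelihood(quartet_tree, partials, model, bl)
        Q = build_rate_matrix(model)
        rates = (discrete_gamma_rates(model.gamma_shape, 4)
                 if model.gamma_shape else [1.0])
        tip_states = dict(zip(sorted(quartet_tree.tip_names()), states))
        expected = np.mean([
            brute_force_pattern_prob(quartet_tree, Q, bl * r, tip_states,
                                     model.stationary_freqs)
            for r in rates])
        assert res.total == pytest.approx(math.log(expected), abs=1e-10)

    def test_pattern_probabilities_sum_to_one(self, triplet_tree):
        import itertools
        model = SiteModel(family="mk", k=2)
        bl = triplet_tree.durations() * 0.4
        total = 0.0
        for pat in itertools.product(range(2), repeat=3):
            partials = indicator_partials(list(pat), 2)
            res = partition_log_likelihood(triplet_tree, partials, model, bl)
            total += math.exp(res.total)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_character_doubles_contribution(self, quartet_tree):
        model = SiteModel(family="mk", k=2)
        bl = quartet_tree.durations() * 0.2
        one = indicator_partials([0, 1, 1, 0], 2)
        two = np.concatenate([one, one], axis=1)
        r1 = partition_log_likelihood(quartet_tree, one, model, bl)
        r2 = partition_log_likelihood(quartet_tree, two, model, bl)
        assert r2.total == pytest.approx(2 * r1.total, abs=1e-12)

    def test_full_polymorphism_equals_missing(self, quartet_tree):
        model = SiteModel(family="mk", k=2)
        bl = quartet_tree.durations() * 0.2
        poly = indicator_partials([{0, 1}, 0, 1, 1], 2)
        miss = indicator_partials([0, 1, 1, 0], 2)
        miss[0, 0, :] = 1.0
        miss[1:, 0, :] = poly[1:, 0, :]
        ra = partition_log_likelihood(quartet_tree, poly, model, bl)
        rb = partition_log_likelihood(quartet_tree, miss, model, bl)
        assert ra.total == pytest.approx(rb.total, abs=1e-12)

    def test_taxon_and_character_order_invariance(self, quartet_tree, rng):
        from tipdating.treemodel import TimeTree
        model = SiteModel(family="mk", k=2, gamma_shape=1.0)
        bl = quartet_tree.durations() * 0.3
        pats = [[0, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 1]]
        partials = np.concatenate(
            [indicator_partials(p, 2) for p in pats], axis=1)
        base = partition_log_likelihood(quartet_tree, partials, model,
                                        bl).total
        # permute characters
        perm = rng.permutation(3)
        shuffled = partials[:, perm, :]
        assert partition_log_likelihood(
            quartet_tree, shuffled, model, bl).total == \
            pytest.approx(base, abs=1e-12)
        # rotated newick (same tree, different written order)
        rot = TimeTree.from_newick("((D:1.5,C:1.5):0.5,(B:1,A:1):1);")
        bl2 = rot.durations() * 0.3
        assert partition_log_likelihood(rot, partials, model, bl2).total \
            == pytest.approx(base, abs=1e-10)

    def test_one_gamma_category_equals_homogeneous(self, quartet_tree):
        bl = quartet_tree.durations() * 0.3
        partials = indicator_partials([0, 1, 1, 0], 2)
        hom = partition_log_likelihood(
            quartet_tree, partials, SiteModel(family="mk", k=2), bl)
        g1 = partition_log_likelihood(
            quartet_tree, partials,
            SiteModel(family="mk", k=2, gamma_shape=0.7, n_categories=1), bl)
        assert g1.total == pytest.approx(hom.total, abs=1e-12)

    def test_all_missing_character_contributes_zero(self, quartet_tree):
        model = SiteModel(family="mk", k=2, ascertainment="variable")
        bl = quartet_tree.durations() * 0.3
        partials = np.ones((4, 1, 2))
        res = partition_log_likelihood(quartet_tree, partials, model, bl)
        assert res.total == 0.0


class TestVariableCoding:
    def test_constant_probability_matches_brute_force(self, triplet_tree):
        model = SiteModel(family="mk", k=2)
        bl = triplet_tree.durations() * 0.2
        log_pc = constant_pattern_log_prob(triplet_tree, model, bl)
        expected = sum(
            brute_force_pattern_prob(
                triplet_tree, build_rate_matrix(model), bl,
                dict(zip(sorted(triplet_tree.tip_names()), [s] * 3)))
            for s in (0, 1))
        assert log_pc == pytest.approx(math.log(expected), abs=1e-10)

    def test_corrected_variable_probs_sum_to_one(self, triplet_tree):
        import itertools
        model = SiteModel(family="mk", k=2, ascertainment="variable")
        bl = triplet_tree.durations() * 0.4
        total = 0.0
        for pat in itertools.product(range(2), repeat=3):
            if len(set(pat)) == 1:
                continue
            partials = indicator_partials(list(pat), 2)
            res = partition_log_likelihood(triplet_tree, partials, model, bl)
            total += math.exp(res.total)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_zero_length_tree_reports_divergence(self, triplet_tree):
        model = SiteModel(family="mk", k=2)
        bl = np.zeros(triplet_tree.n_nodes)
        with pytest.raises(LikelihoodError, match="diverg"):
            variable_coding_correction(triplet_tree, model, bl)

    def test_long_tree_independent_tips_limit(self, triplet_tree):
        # saturated branches: tips independent uniform, so
        # P(constant) = k * (1/k)^n and the correction follows
        model = SiteModel(family="mk", k=2)
        bl = np.full(triplet_tree.n_nodes, 200.0)
        corr = variable_coding_correction(triplet_tree, model, bl)
        n = triplet_tree.n_tips
        assert corr == pytest.approx(math.log(1 - 2 * 0.5 ** n), abs=1e-8)


class TestMorphPartials:
    def test_missing_taxon_row_is_all_ones(self):
        from tests.test_characters import make_matrix, S
        m = make_matrix([[S([0])], [S([1])]], n_states=[2],
                        taxa=["a", "b"])
        partials = morph_tip_partials(m, np.array([0]), ["a", "b", "c"], 2)
        assert (partials[2] == 1).all()
        assert partials[0, 0, 0] == 1 and partials[0, 0, 1] == 0
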