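"""MCMC engine: heating ladder, diagnostics, burn-in rule, allcompat
summaries, reproducibility, prior recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

from tipdating.mcmc import (
    ExtendRunSignal, InferenceModel, McmcError, RunConfig, chain_heat,
    compute_asdsf, compute_ess, diagnose, run_mcmcmc, select_burnin,
    summarize_allcompat,
)
from tipdating.simulate import SimulationConfig, simulate_dataset
from tipdating.treemodel import TimeTree


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SimulationConfig(seed=5, n_morph=20, n_sites=0, origin_age=12.0,
                           speciation=0.3, fossilization=0.05,
                           min_tips=5, max_tips=9)
    data, tree, truth = simulate_dataset(cfg)
    return data, tree, truth


class TestChainHeat:
    def test_cold_chain_is_one(self):
        assert chain_heat(0, 0.02) == 1.0

    def test_incremental_ladder(self):
        assert chain_heat(1, 0.02) == pytest.approx(1 / 1.02)
        assert chain_heat(3, 0.1) == pytest.approx(1 / 1.3)

    def test_zero_heat_all_cold(self):
        assert all(chain_heat(i, 0.0) == 1.0 for i in range(4))

    def test_negative_heat_rejected(self):
        with pytest.raises(McmcError):
            chain_heat(1, -0.1)


class TestAsdsf:
    trees_a = [TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")] * 4
    trees_b = [TimeTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")] * 4

    def test_identical_samples_zero(self):
        assert compute_asdsf(self.trees_a, list(self.trees_a)) == 0.0

    def test_fully_disagreeing_split(self):
        # split at frequency 1 in run A, 0 in run B: population-sd
        # convention gives sd 0.5 per conflicting split
        assert compute_asdsf(self.trees_a, self.trees_b) == \
            pytest.approx(0.5)

    def test_symmetry_and_order_invariance(self, rng):
        mixed = self.trees_a[:2] + self.trees_b[:2]
        shuffled = [mixed[i] for i in rng.permutation(4)]
        assert compute_asdsf(mixed, self.trees_a) == \
            pytest.approx(compute_asdsf(self.trees_a, mixed))
        assert compute_asdsf(mixed, shuffled) == \
            pytest.approx(compute_asdsf(mixed, mixed))

    def test_too_few_trees(self):
        with pytest.raises(McmcError):
            compute_asdsf(self.trees_a[:1], self.trees_b)


class TestEss:
    def test_iid_normal(self, rng):
        x = rng.normal(size=10_000)
        assert compute_ess(x) == pytest.approx(10_000, rel=0.10)

    def test_ar1_closed_form(self, rng):
        phi, n = 0.5, 100_000
        x = lfilter([1.0], [1.0, -phi], rng.normal(size=n))
        assert compute_ess(x) == pytest.approx(n * (1 - phi) / (1 + phi),
                                               rel=0.10)

    def test_bounded_by_n(self, rng):
        x = rng.permutation(10).astype(float)
        assert compute_ess(x) <= 10

    def test_agrees_with_arviz_on_ar1(self, rng):
        # independent-implementation cross-check
        arviz = pytest.importorskip("arviz")
        x = lfilter([1.0], [1.0, -0.5], rng.normal(size=100_000))
        ours = compute_ess(x)
        theirs = float(arviz.ess(x))
        assert ours == pytest.approx(theirs, rel=0.15)

    def test_constant_series_flagged(self):
        with pytest.raises(McmcError):
            compute_ess(np.ones(100))

    def test_short_series(self):
        with pytest.raises(McmcError):
            compute_ess(np.arange(5.0))


class TestBurninRule:
    def test_applies_stated_rule(self):
        table = {5: (0.02, 800), 10: (0.009, 300), 15: (0.008, 500)}
        assert select_burnin(table) == 15

    def test_single_qualifier(self):
        assert select_burnin({5: (0.05, 10), 10: (0.004, 40)}) == 10

    def test_no_qualifier_signals_extend(self):
        with pytest.raises(ExtendRunSignal):
            select_burnin({5: (0.02, 800), 10: (0.03, 900)})

    def test_empty_table(self):
        with pytest.raises(McmcError):
            select_burnin({})


class TestAllcompat:
    def test_identical_samples_full_support(self):
        trees = [TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")] * 5
        summary, support = summarize_allcompat(trees)
        assert set(support.values()) == {1.0}
        assert summary.is_monophyletic(["A", "B"])
        assert summary.root.age == pytest.approx(2.0)

    def test_majority_resolution_wins(self):
        a = TimeTree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        b = TimeTree.from_newick("(((A:1,C:1):1,B:2):1,D:3);")
        summary, support = summarize_allcompat([a] * 6 + [b] * 4)
        ab = frozenset(["A", "B"])
        assert support[ab] == pytest.approx(0.6)
        assert summary.is_monophyletic(["A", "B"])

    def test_plurality_added_as_compatible_group(self):
        # 45/35/20 conflict on one quartet: the 45% resolution enters
        a = TimeTree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        b = TimeTree.from_newick("(((A:1,C:1):1,B:2):1,D:3);")
        c = TimeTree.from_newick("(((B:1,C:1):1,A:2):1,D:3);")
        trees = [a] * 45 + [b] * 35 + [c] * 20
        summary, support = summarize_allcompat(trees)
        assert summary.is_monophyletic(["A", "B"])
        assert support[frozenset(["A", "B"])] == pytest.approx(0.45)

    def test_every_majority_split_present(self, small_dataset):
        data, tree, _ = small_dataset
        cfg = RunConfig(n_generations=400, n_runs=1, n_chains=1,
                        sample_every=5, seed=3)
        res = run_mcmcmc(data, InferenceModel(), cfg)
        trees = res.pooled_trees()
        summary, support = summarize_allcompat(trees)
        from tipdating.mcmc import _clade_frequencies
        freqs = _clade_frequencies(trees)
        present = {summary.clade_names(n) for n in summary.postorder()
                   if not n.is_leaf}
        for clade, f in freqs.items():
            if f > 0.5:
                assert clade in present

    def test_node_ages_are_means_over_containing_samples(self):
        t1 = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        t2 = TimeTree.from_newick("((A:2,B:2):2,C:4);")
        summary, _ = summarize_allcompat([t1, t2])
        node = summary.mrca(["A", "B"])
        assert node.age == pytest.approx(1.5)
        assert summary.root.age == pytest.approx(3.0)


class TestEngine:
    def test_seed_reproducibility(self, small_dataset):
        data, _, _ = small_dataset
        cfg = RunConfig(n_generations=200, n_runs=2, n_chains=2,
                        sample_every=10, heat=0.05, seed=9)
        r1 = run_mcmcmc(data, InferenceModel(), cfg)
        r2 = run_mcmcmc(data, InferenceModel(), cfg)
        for a, b in zip(r1.runs, r2.runs):
            pd.testing.assert_frame_equal(a.params, b.params)
            assert [t.to_newick() for t in a.trees] == \
                [t.to_newick() for t in b.trees]

    def test_equal_temperature_swaps_always_accepted(self, small_dataset):
        data, _, _ = small_dataset
        cfg = RunConfig(n_generations=150, n_runs=1, n_chains=2,
                        sample_every=10, heat=0.0, seed=2)
        res = run_mcmcmc(data, InferenceModel(), cfg)
        assert res.runs[0].swap_acceptance == 1.0

    def test_prior_only_recovers_exact_prior_marginals(self, small_dataset):
        # clock rate, IGR variance and gamma shape have marginals equal
        # to their priors under prior-only sampling (the FBD parameters
        # do not: conditioning on a fixed taxon set tilts them)
        data, _, _ = small_dataset
        cfg = RunConfig(n_generations=40_000, n_runs=1, n_chains=1,
                        sample_every=20, seed=11)
        model = InferenceModel(prior_only=True,
                               clock_rate_prior=("exponential", 1.0))
        res = run_mcmcmc(data, model, cfg)
        df = res.runs[0].params.iloc[200:]
        for param, mean in [("clock_rate", 1.0), ("igr_variance", 0.1),
                            ("morph_alpha", 1.0)]:
            x = df[param].to_numpy()
            se = x.std() / math.sqrt(max(compute_ess(x), 4))
            assert abs(x.mean() - mean) < 3.5 * se, param

    def test_diagnose_produces_burnin_table(self, small_dataset):
        data, _, _ = small_dataset
        cfg = RunConfig(n_generations=600, n_runs=2, n_chains=1,
                        sample_every=5, seed=4)
        res = run_mcmcmc(data, InferenceModel(), cfg)
        rep = diagnose(res, burnin_fracs=(0.1, 0.25, 0.5))
        assert rep.burnin_table.shape[0] == 3
        assert (rep.burnin_table["asdsf"] >= 0).all()
        assert rep.min_ess > 0

    def test_invalid_config(self):
        with pytest.raises(McmcError):
            RunConfig(n_generations=0)
        with pytest.raises(McmcError):
            RunConfig(heat=-1)
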