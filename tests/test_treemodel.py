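"""Tree priors: FBD density oracles, IGR clock, calibrations, tip-age
windows, and the empirical clock-rate-prior derivation."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from tipdating.characters import TaxonRecord
from tipdating.treemodel import (
    Calibration, FBDParams, TimeTree, TreeError, calibration_log_density,
    derive_clock_rate_prior, fbd_log_density, igr_log_prior,
    path_lengths_from_newick, propose_fossil_tip_age, random_dated_tree,
    sample_igr_multipliers, yule_log_density, _fbd_constants, _log_q, _p0,
)


def edgewise_fbd_log_density(tree, p, fossil_names=frozenset()):
    """Independent product-form FBD evaluation: one q-ratio factor per
    edge plus per-event factors (cross-check implementation)."""
    lam, mu, psi, rho, c1, c2 = _fbd_constants(p)
    logf = 0.0
    for node in tree.postorder():
        if node.parent is not None:
            logf += _log_q(node.parent.age, c1, c2) - _log_q(node.age, c1, c2)
        if not node.is_leaf:
            logf += math.log(lam)
        elif node.name in fossil_names or node.age > 0:
            logf += math.log(psi) + math.log(
                _p0(node.age, lam, mu, psi, c1, c2))
        else:
            logf += math.log(rho)
    return logf


class TestTimeTree:
    def test_newick_round_trip_preserves_ages(self):
        t = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        back = TimeTree.from_newick(t.to_newick())
        assert back.root.age == pytest.approx(t.root.age)
        assert sorted(back.tip_names()) == ["A", "B", "C", "D"]

    def test_validate_rejects_negative_durations(self):
        t = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        t.root.age = 0.5
        with pytest.raises(TreeError):
            t.validate()

    def test_prune_taxa(self):
        t = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        pruned = t.prune_taxa(["A"])
        assert sorted(pruned.tip_names()) == ["B", "C", "D"]
        assert pruned.root.age == pytest.approx(t.root.age)

    def test_mrca_and_monophyly(self):
        t = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        assert t.is_monophyletic(["A", "B"])
        assert not t.is_monophyletic(["A", "C"])

    def test_random_dated_tree_respects_fossil_ages(self, rng):
        ages = {"f1": 5.0, "f2": 8.0}
        t = random_dated_tree(["a", "b", "c", "f1", "f2"], rng,
                              root_age=20.0, tip_ages=ages)
        t.validate()
        tips = {n.name: n.age for n in t.tips}
        assert tips["f1"] == 5.0 and tips["f2"] == 8.0
        assert t.root.age == pytest.approx(20.0)


class TestFBD:
    def test_yule_limit_matches_closed_form(self, rng):
        p = FBDParams(speciation=0.7, turnover=0.0, sampling_prop=0.0,
                      rho=1.0)
        for seed in range(5):
            t = random_dated_tree(list("ABCDEF"),
                                  np.random.default_rng(seed), root_age=3.0)
            assert fbd_log_density(t, p) == pytest.approx(
                yule_log_density(t, 0.7), abs=1e-8)

    def test_matches_independent_edgewise_evaluation(self):
        # two-implementation cross-check on 50 random trees with fossils
        p = FBDParams(speciation=0.5, turnover=0.4, sampling_prop=0.3,
                      rho=0.6)
        for seed in range(50):
            r = np.random.default_rng(seed)
            ages = {"f1": float(r.uniform(0.5, 2)),
                    "f2": float(r.uniform(0.5, 2))}
            t = random_dated_tree(["a", "b", "c", "f1", "f2"], r,
                                  root_age=float(r.uniform(4, 8)),
                                  tip_ages=ages)
            assert fbd_log_density(t, p, fossil_names=set(ages)) == \
                pytest.approx(edgewise_fbd_log_density(t, p, set(ages)),
                              abs=1e-9)

    def test_density_decreases_with_fossilization_when_no_fossils(self, rng):
        t = random_dated_tree(list("ABCDE"), rng, root_age=4.0)
        dens = [fbd_log_density(
            t, FBDParams(0.5, 0.3, s, rho=1.0))
            for s in (0.0, 0.2, 0.4, 0.6)]
        assert all(a > b for a, b in zip(dens, dens[1:]))

    def test_finite_at_prior_means(self, rng):
        ages = {"f1": 1.0}
        t = random_dated_tree(["a", "b", "c", "f1"], rng, root_age=5.0,
                              tip_ages=ages)
        p = FBDParams(speciation=0.1, turnover=0.5, sampling_prop=0.5,
                      rho=0.5)
        assert math.isfinite(fbd_log_density(t, p, fossil_names={"f1"}))

    def test_fossils_with_zero_fossilization_rate(self, rng):
        ages = {"f1": 1.0}
        t = random_dated_tree(["a", "b", "f1"], rng, root_age=5.0,
                              tip_ages=ages)
        p = FBDParams(speciation=0.2, turnover=0.0, sampling_prop=0.0)
        assert fbd_log_density(t, p, fossil_names={"f1"}) == -math.inf

    def test_simulated_trees_have_finite_density(self):
        from tipdating.simulate import SimulationConfig, simulate_fbd_tree
        cfg = SimulationConfig(speciation=0.3, extinction=0.1,
                               fossilization=0.05, origin_age=15.0, rho=0.8)
        p = FBDParams(0.3, 1 / 3, 0.05 / 0.15, rho=0.8)
        for seed in range(10):
            tree, truth = simulate_fbd_tree(cfg, seed=seed)
            d = fbd_log_density(tree, p, origin_age=cfg.origin_age)
            assert math.isfinite(d)

    def test_parameterization_roundtrip(self):
        p = FBDParams(speciation=0.4, turnover=0.5, sampling_prop=0.25)
        assert p.extinction == pytest.approx(0.2)
        # psi/(mu+psi) = 0.25  =>  psi = mu/3
        assert p.fossilization == pytest.approx(0.2 / 3)
        with pytest.raises(TreeError):
            FBDParams(speciation=-1, turnover=0.5, sampling_prop=0.5)


class TestIGR:
    def test_density_matches_gamma_oracle(self):
        # one branch, duration d: multiplier ~ Gamma(d/v, scale v/d)
        d, v, m = 2.0, 0.5, 1.2
        expected = stats.gamma.logpdf(m, a=d / v, scale=v / d)
        assert igr_log_prior(np.array([m]), v, np.array([d])) == \
            pytest.approx(expected, abs=1e-12)

    def test_small_variance_concentrates_at_one(self):
        d = np.array([1.0])
        lp_near = igr_log_prior(np.array([1.0]), 1e-4, d)
        lp_far = igr_log_prior(np.array([1.5]), 1e-4, d)
        assert lp_near > lp_far + 100

    def test_sampled_multipliers_have_mean_one(self, rng):
        durations = np.full(10_000, 2.0)
        m = sample_igr_multipliers(0.5, durations, rng)
        se = m.std() / math.sqrt(len(m))
        assert abs(m.mean() - 1.0) < 3 * se

    def test_nonpositive_multiplier(self):
        assert igr_log_prior(np.array([-0.1]), 0.5, np.array([1.0])) \
            == -math.inf


class TestCalibrations:
    cal = Calibration(frozenset(["a", "b"]), 55.8, 55.8, 1.0, "Primates")

    def test_truncation_below_minimum(self):
        assert calibration_log_density(55.0, self.cal) == -math.inf

    def test_argmax_at_mean(self):
        ages = np.linspace(55.8, 60.0, 400)
        dens = [calibration_log_density(a, self.cal) for a in ages]
        assert ages[int(np.argmax(dens))] == pytest.approx(55.8, abs=0.02)

    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda a: math.exp(calibration_log_density(a, self.cal)),
            55.8, 80.0)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestTipAgeProposal:
    songhor = TaxonRecord("F", False, (18.5, 20.0))   # Songhor-like bracket

    def test_uniform_mean_over_window(self, rng):
        draws = [propose_fossil_tip_age(self.songhor, 19.0, rng)
                 for _ in range(10_000)]
        se = np.std(draws) / math.sqrt(len(draws))
        assert abs(np.mean(draws) - 19.25) < 3 * se
        assert min(draws) >= 18.5 and max(draws) <= 20.0

    def test_degenerate_window(self, rng):
        rec = TaxonRecord("F", False, (10.0, 10.0))
        assert propose_fossil_tip_age(rec, 10.0, rng) == 10.0

    def test_extant_taxon_rejected(self, rng):
        with pytest.raises(TreeError):
            propose_fossil_tip_age(TaxonRecord("X", True), 0.0, rng)


class TestClockRatePrior:
    def test_rate_arithmetic(self):
        fit = derive_clock_rate_prior(
            {"a": 0.652, "b": 0.6, "c": 0.7}, {}, root_age=65.2)
        assert fit.rates[0] == pytest.approx(0.01)

    def test_lognormal_recovery(self):
        # n=125 tips with lognormal rates: BIC picks lognormal and
        # recovers the parameters within 10%
        mu, sd = -4.0, 0.5
        rates = np.random.default_rng(1).lognormal(mu, sd, size=125)
        root_age = 65.2
        pls = {f"t{i}": r * root_age for i, r in enumerate(rates)}
        fit = derive_clock_rate_prior(pls, {}, root_age)
        assert fit.best == "lognormal"
        assert fit.best_params["log_mean"] == pytest.approx(mu, rel=0.10)
        assert fit.best_params["log_sd"] == pytest.approx(sd, rel=0.10)
        table = fit.bic_table()
        assert table.iloc[0]["family"] == "lognormal"

    def test_invariance_to_tip_order_and_rotation(self):
        nwk_a = "((a:0.3,b:0.4):0.2,(c:0.5,d:0.1):0.3);"
        nwk_b = "((d:0.1,c:0.5):0.3,(b:0.4,a:0.3):0.2);"
        ages = {"c": 5.0}
        fits = [derive_clock_rate_prior(path_lengths_from_newick(n), ages,
                                        root_age=20.0) for n in (nwk_a,
                                                                 nwk_b)]
        assert np.allclose(sorted(fits[0].rates), sorted(fits[1].rates))
        assert fits[0].best == fits[1].best

    def test_errors(self):
        with pytest.raises(TreeError):
            derive_clock_rate_prior({"a": 0.1, "b": 0.2}, {}, 10.0)
        with pytest.raises(TreeError):
            derive_clock_rate_prior({"a": 0.1, "b": 0.2, "c": 0.3},
                                    {"a": 12.0}, 10.0)
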