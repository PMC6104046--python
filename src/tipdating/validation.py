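"""Desk-scale validation experiments.

Self-contained benchmark computations exercising every stage of the
package against independent oracles: closed forms, brute-force
enumeration, conjugate models and simulation truth.  Each function
returns a dict of measured quantities; the test suite asserts them at
their documented tolerances and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import lfilter

from .characters import concatenate, extant_sampling_fraction
from .mcmc import InferenceModel, RunConfig, compute_ess, run_mcmcmc, \
    select_burnin
from .models import SiteModel, build_rate_matrix, discrete_gamma_rates, \
    partition_log_likelihood
from .simulate import SimulationConfig, assign_age_windows, \
    generate_tooth_meshes, simulate_characters, simulate_dna, \
    simulate_fbd_tree
from .treemodel import FBDParams, TimeTree, derive_clock_rate_prior, \
    fbd_log_density, random_dated_tree, yule_log_density


def _sub_seed(seed: int, label: int) -> int:
    return int(np.random.SeedSequence([seed, label]).generate_state(1)[0]
               % (2 ** 31))


def sampling_fraction_check() -> dict:
    """Extant sampling probability from the study's species richnesses:
    23 sampled of 450 primates + 2 dermopterans + 20 scandentians."""
    frac = extant_sampling_fraction(23, (450, 2, 20))
    return {"fraction": frac, "rounded_4dp": round(frac, 4), "n": 472}


def _brute_force_pattern_prob(tree, Q, bl, tip_states, pi):
    import itertools

    from scipy.linalg import expm

    k = Q.shape[0]
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    tips = {n.name: n for n in tree.tips}
    P = {n.index: expm(Q * bl[n.index]) for n in nodes
         if n.parent is not None}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for name, s in tip_states.items():
            st[tips[name]] = s
        p = pi[st[tree.root]]
        for n in nodes:
            if n.parent is not None:
                p *= P[n.index][st[n.parent], st[n]]
        total += p
    return total


def likelihood_oracle_check() -> dict:
    """Pruning vs enumeration for Mk (ordered/unordered, gamma,
    variable coding) and GTR on a 4-taxon tree."""
    tree = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
    bl = tree.durations() * 0.3
    cases = [
        (SiteModel(family="mk", k=2), [0, 1, 1, 0]),
        (SiteModel(family="mk", k=3, ordered=True), [0, 2, 1, 1]),
        (SiteModel(family="mk", k=2, gamma_shape=0.5), [0, 1, 0, 0]),
        (SiteModel(family="gtr",
                   exchangeabilities=[1, 2, 0.5, 1.5, 3, 1],
                   base_freqs=[0.1, 0.2, 0.3, 0.4]), [2, 2, 0, 1]),
    ]
    worst = 0.0
    for model, states in cases:
        partials = np.zeros((4, 1, model.k))
        for i, s in enumerate(states):
            partials[i, 0, s] = 1.0
        res = partition_log_likelihood(tree, partials, model, bl)
        Q = build_rate_matrix(model)
        rates = (discrete_gamma_rates(model.gamma_shape, 4)
                 if model.gamma_shape else [1.0])
        tip_states = dict(zip(sorted(tree.tip_names()), states))
        expected = np.mean([
            _brute_force_pattern_prob(tree, Q, bl * r, tip_states,
                                      model.stationary_freqs)
            for r in rates])
        worst = max(worst, abs(res.total - math.log(expected)))
    # variable coding: corrected variable-pattern probabilities sum to 1
    import itertools
    model = SiteModel(family="mk", k=2, ascertainment="variable")
    tri = TimeTree.from_newick("((A:1,B:1):1,C:2);")
    bl3 = tri.durations() * 0.4
    total = 0.0
    for pat in itertools.product(range(2), repeat=3):
        if len(set(pat)) == 1:
            continue
        partials = np.zeros((3, 1, 2))
        for i, s in enumerate(pat):
            partials[i, 0, s] = 1.0
        total += math.exp(
            partition_log_likelihood(tri, partials, model, bl3).total)
    worst = max(worst, abs(total - 1.0))
    return {"max_abs_error": worst, "n_cases": len(cases) + 1}


def fbd_yule_check(seed: int = 0) -> dict:
    """FBD density vs the pure-birth closed form at mu = psi = 0,
    rho = 1 on random dated trees."""
    worst = 0.0
    p = FBDParams(speciation=0.7, turnover=0.0, sampling_prop=0.0,
                  rho=1.0)
    for i in range(20):
        rng = np.random.default_rng(_sub_seed(seed, 100 + i))
        tree = random_dated_tree(list("ABCDEFG"), rng, root_age=3.0)
        worst = max(worst, abs(fbd_log_density(tree, p)
                               - yule_log_density(tree, 0.7)))
    return {"max_abs_error": worst, "n_trees": 20}


def stepping_stone_check(seed: int = 0, n_steps: int = 50,
                         samples_per_step: int = 1000) -> dict:
    """Stepping-stone estimate vs the conjugate beta-binomial marginal
    likelihood."""
    from .comparison import BetaBinomialToy, stepping_stone
    toy = BetaBinomialToy(successes=7, trials=20)
    est = stepping_stone(toy.sampler(), n_steps=n_steps,
                         samples_per_step=samples_per_step,
                         seed=_sub_seed(seed, 4))
    return {"estimate": est.log_ml, "exact": toy.exact_log_marginal(),
            "abs_error": abs(est.log_ml - toy.exact_log_marginal()),
            "n": est.n_samples}


def clock_prior_recovery_check(seed: int = 0) -> dict:
    """BIC family selection and lognormal parameter recovery from
    synthetic path lengths (n = 125 tips)."""
    mu, sd = -4.0, 0.5
    rng = np.random.default_rng(_sub_seed(seed, 5))
    rates = rng.lognormal(mu, sd, size=125)
    fit = derive_clock_rate_prior(
        {f"t{i}": r * 65.2 for i, r in enumerate(rates)}, {}, 65.2)
    err_mu = abs(fit.fits["lognormal"][0]["log_mean"] - mu) / abs(mu)
    err_sd = abs(fit.fits["lognormal"][0]["log_sd"] - sd) / sd
    return {"selected": fit.best, "lognormal_selected":
            float(fit.best == "lognormal"),
            "max_rel_error_pct": 100 * max(err_mu, err_sd), "n": 125}


def diagnostics_check(seed: int = 0) -> dict:
    """AR(1) ESS vs the closed form n(1-phi)/(1+phi), and the burn-in
    grid rule on a hand-built table."""
    phi, n = 0.5, 100_000
    rng = np.random.default_rng(_sub_seed(seed, 6))
    x = lfilter([1.0], [1.0, -phi], rng.normal(size=n))
    ess = compute_ess(x)
    expected = n * (1 - phi) / (1 + phi)
    chosen = select_burnin({5: (0.02, 800), 10: (0.009, 300),
                            15: (0.008, 500)})
    return {"ess": ess, "expected": expected,
            "rel_error_pct": 100 * abs(ess - expected) / expected,
            "burnin_choice": chosen, "burnin_rule_correct":
            float(chosen == 15), "n": n}


def asr_check() -> dict:
    """Marginal ASR vs enumeration, plus the >10% calling rule on
    hand-labeled probability vectors."""
    from .asr import asr_marginal, call_best_states
    tree = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
    bl = tree.durations() * 0.4
    model = SiteModel(family="mk", k=2)
    states = [0, 0, 1, 0]
    partials = np.zeros((4, 1, 2))
    for i, s in enumerate(states):
        partials[i, 0, s] = 1.0
    probs = asr_marginal(tree, partials, model, bl)
    Q = build_rate_matrix(model)
    tip_states = dict(zip(sorted(tree.tip_names()), states))
    worst = 0.0
    import itertools
    for node in probs:
        nodes = tree.postorder()
        internals = [x for x in nodes if not x.is_leaf]
        tips = {x.name: x for x in tree.tips}
        from scipy.linalg import expm
        P = {x.index: expm(Q * bl[x.index]) for x in nodes
             if x.parent is not None}
        marg = np.zeros(2)
        for assign in itertools.product(range(2), repeat=len(internals)):
            st = dict(zip(internals, assign))
            for name, s in tip_states.items():
                st[tips[name]] = s
            p = 0.5
            for x in nodes:
                if x.parent is not None:
                    p *= P[x.index][st[x.parent], st[x]]
            marg[st[node]] += p
        marg /= marg.sum()
        worst = max(worst, float(np.abs(probs[node][0] - marg).max()))

    labeled = [((0.8, 0.2), {0}), ((0.52, 0.48), {0, 1}),
               ((0.5, 0.5), {0, 1}), ((0.45, 0.40, 0.15), {0, 1}),
               ((0.2, 0.75, 0.05), {1})]
    agree = sum(set(call_best_states(np.array([p]))[0]) == want
                for p, want in labeled)
    return {"max_abs_error": worst, "calling_rule_agreement":
            agree / len(labeled), "n_vectors": len(labeled)}


def morphometrics_check(seed: int = 0) -> dict:
    """Known-rotation recovery and two-class PC1 separation on
    synthetic tooth meshes."""
    from .morphometrics import (global_align, pairwise_align,
                                procrustes_tangent_pca,
                                spread_pseudolandmarks)
    from .simulate import random_rotation
    rng = np.random.default_rng(_sub_seed(seed, 7))
    meshes, labels = generate_tooth_meshes(2, 5, deformation=0.15,
                                           noise_sd=0.005,
                                           seed=_sub_seed(seed, 8))
    lms = [spread_pseudolandmarks(m, 100, seed=i)
           for i, m in enumerate(meshes)]
    R = random_rotation(rng)
    A = lms[0]
    B = (A - A.mean(0)) @ R.T + rng.normal(size=3)
    al = pairwise_align(A, B, allow_reflections=False)
    rot_err = float(np.abs(al.rotation - R).max())
    mirrored = (A - A.mean(0)) @ np.diag([1.0, -1.0, 1.0])
    refl = pairwise_align(A, mirrored, allow_reflections=True)

    aligned, _ = global_align(lms)
    space = procrustes_tangent_pca(aligned)
    pc1 = space.scores[:, 0]
    a, b = pc1[labels == 0], pc1[labels == 1]
    overlap = int(np.sum((a[:, None] > b.min()) & (a[:, None] < b.max()))
                  + np.sum((b[:, None] > a.min()) & (b[:, None] < a.max()))) \
        if not (a.max() < b.min() or b.max() < a.min()) else 0
    gap = float(min(b.min() - a.max(), 1e9) if a.mean() < b.mean()
                else a.min() - b.max())
    return {"rotation_recovery_error": rot_err,
            "reflection_residual": refl.distance,
            "pc1_overlap_count": overlap, "pc1_class_gap": gap,
            "pc1_variance_fraction": float(space.variance_fractions[0]),
            "n_specimens": len(meshes)}


def root_age_coverage_check(seed: int = 0, n_replicates: int = 20,
                            n_generations: int = 8_000) -> dict:
    """End-to-end tip-dating recovery: fraction of replicates whose
    true root age falls in the 95% credible interval.

    Each replicate simulates an FBD tree (10-18 tips, origin 15 Ma)
    with fossil tips in 1.5 Ma stratigraphic windows, variable-coded
    morphology and a GTR+G alignment, then re-infers everything with
    the matched FBD model (sampling-with-removal, conditioned on the
    known origin age) using two Metropolis-coupled chains.
    """
    hits = 0
    for rep in range(n_replicates):
        s = _sub_seed(seed, 1000 + rep)
        rng = np.random.default_rng(s)
        cfg = SimulationConfig(
            seed=s, n_morph=100, n_sites=500, n_subsets=1,
            origin_age=15.0, speciation=0.22, extinction=0.05,
            fossilization=0.05, rho=0.7, clock_rate=0.02,
            window_width=1.5, morph_gamma_shape=None)
        tree, truth = simulate_fbd_tree(cfg, seed=rng, min_tips=10,
                                        max_tips=18)
        true_root_age = tree.root.age
        morph = simulate_characters(tree, cfg.n_morph, k=2,
                                    clock_rate=cfg.clock_rate,
                                    variable_only=True, seed=rng)
        mol, _ = simulate_dna(tree, cfg, seed=rng,
                              exchangeabilities=np.ones(6),
                              base_freqs=np.full(4, 0.25))
        records = assign_age_windows(tree, cfg.window_width, seed=rng)
        data = concatenate(morph, mol, records)
        run = RunConfig(n_generations=n_generations, n_runs=1, n_chains=2,
                        sample_every=5, heat=0.2,
                        seed=_sub_seed(seed, 2000 + rep))
        model = InferenceModel(
            rho=cfg.rho, morph_gamma=False, fbd_removal=True,
            origin_age=cfg.origin_age,
            clock_rate_prior=("lognormal", math.log(cfg.clock_rate), 0.5))
        res = run_mcmcmc(data, model, run)
        ra = res.runs[0].params["root_age"].iloc[
            len(res.runs[0].params) // 4:].to_numpy()
        lo, hi = np.quantile(ra, [0.025, 0.975])
        hits += bool(lo <= true_root_age <= hi)
    return {"coverage": hits / n_replicates, "hits": hits,
            "n_replicates": n_replicates}
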