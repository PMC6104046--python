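"""Metropolis-coupled MCMC over dated trees, with convergence
diagnostics and tree summarization.

One chain's state is the full model: topology and node ages, fossil
tip ages, relaxed-clock base rate and branch multipliers, FBD
parameters, and per-partition gamma shapes.  Heated chains follow the
incremental-heating ladder beta_i = 1/(1 + i*T); a random pair of
chains attempts a state swap each generation.  Diagnostics are the
average standard deviation of split frequencies (ASDSF) between
independent runs and autocorrelation-based effective sample sizes
(ESS), combined by the grid burn-in selection rule.  Posterior tree
samples are summarized as a majority-rule-plus-compatible-groups
("allcompat") tree with mean node ages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .characters import CombinedDataset
from .models import SiteModel, dna_tip_partials, morph_tip_partials, \
    partition_log_likelihood
from .treemodel import (FBDParams, Node, TimeTree, igr_log_prior,
                        random_dated_tree, CalibrationSet)

logger = logging.getLogger(__name__)


class McmcError(RuntimeError):
    pass


class ExtendRunSignal(RuntimeError):
    """No burn-in candidate reached the convergence target."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    """MCMCMC run settings (study defaults: 2 runs x 4 chains, sampling
    every 1000 generations, heating temperature 0.02)."""

    n_generations: int = 10_000
    n_runs: int = 2
    n_chains: int = 4
    sample_every: int = 1000
    heat: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.n_generations, self.n_runs, self.n_chains,
               self.sample_every) < 1:
            raise McmcError("run settings must be positive")
        if self.heat < 0:
            raise McmcError("heating temperature must be non-negative")


@dataclass
class InferenceModel:
    """Model specification for a run.

    ``tree_prior`` is "fbd" (tip dating) or "uniform" (non-clock style:
    flat prior on node ages, no calibrations).  ``prior_only`` ignores
    the data, which samples the joint prior.  ``clock_rate_prior`` is
    ("lognormal", log_mean, log_sd) or ("exponential", rate).
    """

    tree_prior: str = "fbd"
    rho: float = 1.0
    root_age_max: float = 300.0
    morph_gamma: bool = True
    morph_ascertainment: str = "variable"
    clock_rate_prior: tuple = ("exponential", 1.0)
    igr_variance_rate: float = 10.0       # exponential prior rate
    speciation_rate: float = 10.0         # exponential prior rate
    alpha_prior_rate: float = 1.0         # exponential prior on gamma shapes
    calibrations: CalibrationSet | None = None
    prior_only: bool = False
    sample_topology: bool = True
    relaxed_clock: bool = True
    fbd_removal: bool = False   # fossils terminate their lineage
    origin_age: float | None = None   # condition the FBD on a known origin


_LOG_2PI = math.log(2 * math.pi)


def _expon_logpdf(x: float, rate: float) -> float:
    if x < 0:
        return -math.inf
    return math.log(rate) - rate * x


def _lognorm_logpdf(x: float, log_mean: float, log_sd: float) -> float:
    if x <= 0:
        return -math.inf
    z = (math.log(x) - log_mean) / log_sd
    return -math.log(x) - math.log(log_sd) - 0.5 * (_LOG_2PI + z * z)


def chain_heat(i: int, heat: float) -> float:
    """Inverse temperature of chain i: beta = 1/(1 + i*heat)."""
    if heat < 0:
        raise McmcError("negative heating temperature")
    return 1.0 / (1.0 + i * heat)


# ---------------------------------------------------------------------------
# Chain state


@dataclass
class ChainState:
    tree: TimeTree
    speciation: float
    turnover: float
    sampling_prop: float
    clock_rate: float
    igr_variance: float
    morph_alpha: float
    subset_alphas: np.ndarray
    log_like: float = np.nan
    log_prior: float = np.nan

    def clone(self) -> "ChainState":
        return ChainState(
            tree=self.tree.copy(), speciation=self.speciation,
            turnover=self.turnover, sampling_prop=self.sampling_prop,
            clock_rate=self.clock_rate, igr_variance=self.igr_variance,
            morph_alpha=self.morph_alpha,
            subset_alphas=self.subset_alphas.copy(),
            log_like=self.log_like, log_prior=self.log_prior)


class _Posterior:
    """Precompiled likelihood + prior evaluator for one dataset."""

    def __init__(self, data: CombinedDataset | None, model: InferenceModel):
        self.model = model
        self.data = data
        self.morph_groups = []
        self.dna_blocks = []
        self.fossil_windows = {}
        self.constraints = []
        if data is not None:
            names = sorted(data.taxon_names)
            self.tip_order = names
            for rec in data.taxa:
                if not rec.extant:
                    self.fossil_windows[rec.name] = rec.age_window
            self.constraints = list(data.constraints)
            if data.morph is not None and data.morph.n_chars:
                groups: dict = {}
                for j in range(data.morph.n_chars):
                    key = (int(data.morph.n_states[j]),
                           bool(data.morph.ordered[j]))
                    groups.setdefault(key, []).append(j)
                from .models import _Decomposed, build_rate_matrix
                for (k, ordered), chars in sorted(groups.items()):
                    partials = morph_tip_partials(
                        data.morph, np.asarray(chars), names, k)
                    sm = SiteModel(family="mk", k=k, ordered=ordered)
                    dec = _Decomposed(build_rate_matrix(sm),
                                      sm.stationary_freqs)
                    self.morph_groups.append((k, ordered, partials, dec))
            if data.mol is not None and data.mol.n_sites:
                from .models import _Decomposed, build_rate_matrix
                gtr = SiteModel(family="gtr")
                gtr_dec = _Decomposed(build_rate_matrix(gtr),
                                      gtr.stationary_freqs)
                for subset in sorted(set(data.mol.subset_scheme.values())):
                    cols = data.mol.subset_sites(subset)
                    partials, weights = dna_tip_partials(
                        data.mol.sites[:, cols], data.mol.taxa, names)
                    tag = data.mol.subset_models[subset]
                    self.dna_blocks.append((subset, tag, partials, weights,
                                            gtr_dec))

    # -- likelihood

    def log_likelihood(self, st: ChainState) -> float:
        if self.model.prior_only or self.data is None:
            return 0.0
        tree = st.tree
        bl = np.zeros(tree.n_nodes)
        for node in tree.postorder():
            if node.parent is not None:
                bl[node.index] = ((node.parent.age - node.age)
                                  * node.rate * st.clock_rate)
        total = 0.0
        gamma = st.morph_alpha if self.model.morph_gamma else None
        for k, ordered, partials, dec in self.morph_groups:
            sm = SiteModel(family="mk", k=k, ordered=ordered,
                           gamma_shape=gamma,
                           ascertainment=self.model.morph_ascertainment)
            total += partition_log_likelihood(tree, partials, sm, bl,
                                              dec=dec).total
        for i, (subset, tag, partials, weights, dec) in \
                enumerate(self.dna_blocks):
            sm = SiteModel(family="gtr", gamma_shape=st.subset_alphas[i],
                           p_invariant=0.1 if "I" in tag.split("+") else 0.0)
            total += partition_log_likelihood(tree, partials, sm, bl,
                                              weights, dec=dec).total
        return total

    # -- prior

    def log_prior(self, st: ChainState) -> float:
        from .treemodel import fbd_log_density
        m = self.model
        tree = st.tree
        lp = 0.0
        try:
            tree.validate()
        except Exception:
            return -math.inf
        if tree.root.age > m.root_age_max:
            return -math.inf
        for label, clade in self.constraints:
            if not tree.is_monophyletic(clade):
                return -math.inf
        tips_by_name = {t.name: t for t in tree.tips}
        for name, (lo, hi) in self.fossil_windows.items():
            age = tips_by_name[name].age
            if not (lo <= age <= hi):
                return -math.inf
            if hi > lo:
                lp -= math.log(hi - lo)

        if m.tree_prior == "fbd":
            fbd = FBDParams(st.speciation, st.turnover, st.sampling_prop,
                            m.rho)
            dens = fbd_log_density(tree, fbd,
                                   fossil_names=set(self.fossil_windows),
                                   removal=m.fbd_removal,
                                   origin_age=m.origin_age)
            if not math.isfinite(dens):
                return -math.inf
            lp += dens + fbd.log_prior(m.speciation_rate)
        # "uniform" tree prior contributes a constant

        if m.calibrations is not None:
            lp += m.calibrations.log_density(tree)
            if not math.isfinite(lp):
                return -math.inf

        if m.relaxed_clock:
            nodes = [n for n in tree.postorder() if n.parent is not None]
            mult = np.array([n.rate for n in nodes])
            dur = np.array([n.parent.age - n.age for n in nodes])
            lp += igr_log_prior(mult, st.igr_variance, dur)
            lp += _expon_logpdf(st.igr_variance, m.igr_variance_rate)

        kind, *pars = m.clock_rate_prior
        if kind == "lognormal":
            lp += _lognorm_logpdf(st.clock_rate, pars[0], pars[1])
        else:
            lp += _expon_logpdf(st.clock_rate, pars[0])

        lp += _expon_logpdf(st.morph_alpha, m.alpha_prior_rate)
        for a in st.subset_alphas:
            lp += _expon_logpdf(a, m.alpha_prior_rate)
        return float(lp)

    def evaluate(self, st: ChainState) -> ChainState:
        st.log_prior = self.log_prior(st)
        st.log_like = (self.log_likelihood(st)
                       if math.isfinite(st.log_prior) else -math.inf)
        return st


# ---------------------------------------------------------------------------
# Proposals (each returns (new_state, log_hastings) or None to auto-reject)


def _scale(value, rng, factor=1.3):
    f = math.exp(rng.uniform(-1, 1) * math.log(factor))
    return value * f, math.log(f)


def _propose(st: ChainState, post: _Posterior, rng) -> tuple | None:
    m = post.model
    moves = ["node_age", "clock_rate", "morph_alpha"]
    if m.tree_prior == "fbd":
        moves += ["fbd"]
    if m.relaxed_clock:
        moves += ["branch_rate", "igr_variance"]
    if post.fossil_windows:
        moves += ["tip_age"]
    if m.sample_topology and st.tree.n_tips > 3:
        moves += ["topology", "topology"]
    if len(st.subset_alphas):
        moves += ["subset_alpha"]
    moves += ["tree_scale", "tree_scale", "ridge_scale", "ridge_scale"]
    move = moves[rng.integers(len(moves))]
    new = st.clone()
    lh = 0.0

    if move == "ridge_scale":
        # scale ages and inversely scale the clock rate: moves along the
        # (time x rate) ridge where effective branch lengths are constant
        f = math.exp(rng.uniform(-1, 1) * math.log(1.3))
        internals = new.tree.internal_nodes()
        for node in internals:
            node.age *= f
        new.clock_rate /= f
        for tip in new.tree.tips:
            if tip.parent.age <= tip.age:
                return None
        lh = (len(internals) - 1) * math.log(f)
    elif move == "tree_scale":
        # scale every internal node age (tips fixed): the critical move
        # for node-age/rate deconfounding in dating
        f = math.exp(rng.uniform(-1, 1) * math.log(1.15))
        internals = new.tree.internal_nodes()
        for node in internals:
            node.age *= f
        for tip in new.tree.tips:
            if tip.parent.age <= tip.age:
                return None
        lh = len(internals) * math.log(f)
    elif move == "node_age":
        internals = new.tree.internal_nodes()
        node = internals[rng.integers(len(internals))]
        lo = max(c.age for c in node.children)
        if node.parent is None:
            # root: multiplicative slide of the stem above oldest child
            span = node.age - lo
            span_new, lh = _scale(max(span, 1e-8), rng)
            node.age = lo + span_new
        else:
            node.age = rng.uniform(lo, node.parent.age)
    elif move == "tip_age":
        name = list(post.fossil_windows)[
            rng.integers(len(post.fossil_windows))]
        lo, hi = post.fossil_windows[name]
        tip = next(t for t in new.tree.tips if t.name == name)
        tip.age = rng.uniform(lo, hi) if hi > lo else lo
        if tip.age >= tip.parent.age:
            return None
    elif move == "clock_rate":
        new.clock_rate, lh = _scale(new.clock_rate, rng)
    elif move == "igr_variance":
        new.igr_variance, lh = _scale(new.igr_variance, rng)
    elif move == "morph_alpha":
        new.morph_alpha, lh = _scale(new.morph_alpha, rng)
    elif move == "subset_alpha":
        i = rng.integers(len(new.subset_alphas))
        new.subset_alphas[i], lh = _scale(new.subset_alphas[i], rng)
    elif move == "branch_rate":
        nodes = [n for n in new.tree.postorder() if n.parent is not None]
        node = nodes[rng.integers(len(nodes))]
        node.rate, lh = _scale(node.rate, rng)
    elif move == "fbd":
        which = rng.integers(3)
        if which == 0:
            new.speciation, lh = _scale(new.speciation, rng)
        elif which == 1:
            new.turnover = _reflect(new.turnover + rng.normal(0, 0.1))
        else:
            new.sampling_prop = _reflect(
                new.sampling_prop + rng.normal(0, 0.1))
    elif move == "topology":
        if not _exchange_move(new.tree, rng):
            return None
    return new, lh


def _reflect(x: float) -> float:
    # reflect into the open unit interval
    x = x % 2.0
    x = 2.0 - x if x > 1.0 else x
    return min(max(x, 1e-9), 1 - 1e-9)


def _exchange_move(tree: TimeTree, rng) -> bool:
    """Dated narrow/wide exchange: swap two subtrees whose ages permit
    attachment under each other's parent.  Symmetric."""
    nodes = [n for n in tree.postorder() if n.parent is not None]
    wide = rng.random() < 0.3
    if wide:
        a = nodes[rng.integers(len(nodes))]
        b = nodes[rng.integers(len(nodes))]
    else:
        # narrow: node and its "aunt"
        cand = [n for n in nodes
                if n.parent.parent is not None]
        if not cand:
            return False
        a = cand[rng.integers(len(cand))]
        g = a.parent.parent
        b = next(c for c in g.children if c is not a.parent)
    if a is b or a.parent is b.parent:
        return False
    # neither may be an ancestor of the other
    for x, y in ((a, b), (b, a)):
        node = y
        while node is not None:
            if node is x:
                return False
            node = node.parent
    if a.age >= b.parent.age or b.age >= a.parent.age:
        return False
    pa, pb = a.parent, b.parent
    pa.children[pa.children.index(a)] = b
    pb.children[pb.children.index(b)] = a
    a.parent, b.parent = pb, pa
    tree.reindex()
    return True


# ---------------------------------------------------------------------------
# Engine


@dataclass
class RunTrace:
    params: pd.DataFrame
    trees: list            # TimeTree cold-chain samples
    swap_acceptance: float


@dataclass
class McmcResult:
    runs: list
    config: RunConfig

    def pooled_trees(self, burnin_frac=0.0):
        out = []
        for run in self.runs:
            n = len(run.trees)
            out.extend(run.trees[int(burnin_frac * n):])
        return out


def _init_state(data, model: InferenceModel, rng,
                init_tree: TimeTree | None = None) -> ChainState:
    if init_tree is not None:
        tree = init_tree.copy()
    else:
        names = sorted(data.taxon_names) if data is not None else \
            [f"t{i}" for i in range(5)]
        tip_ages = {}
        if data is not None:
            for rec in data.taxa:
                tip_ages[rec.name] = 0.0 if rec.extant else rec.midpoint_age
        oldest = max(list(tip_ages.values()) + [1.0])
        root_age = oldest * 1.5 + 5.0
        if model.origin_age is not None:
            # start strictly inside the fixed-origin bound
            root_age = oldest + 0.9 * (model.origin_age - oldest)
            if root_age <= oldest:
                raise McmcError("origin age does not exceed the oldest tip")
        constraints = list(data.constraints) if data is not None else []
        for _ in range(2000):
            tree = random_dated_tree(names, rng, root_age=root_age,
                                     tip_ages=tip_ages)
            if all(tree.is_monophyletic(c) for _, c in constraints):
                break
        else:
            raise McmcError("could not initialize a constraint-satisfying "
                            "tree; check constraints")
    return ChainState(
        tree=tree, speciation=float(rng.exponential(0.1)) + 0.05,
        turnover=0.5, sampling_prop=0.5,
        clock_rate=0.05, igr_variance=0.1, morph_alpha=1.0,
        subset_alphas=np.ones(0))


def run_mcmcmc(data: CombinedDataset | None, model: InferenceModel,
               config: RunConfig,
               init_tree: TimeTree | None = None) -> McmcResult:
    """Run the full Metropolis-coupled sampler.

    Returns one :class:`RunTrace` per independent run, each holding the
    cold-chain parameter trace (sampled every ``sample_every``
    generations) and the matching tree samples.  Bit-reproducible for a
    given ``config.seed``.
    """
    runs = []
    n_subsets = 0
    if data is not None and data.mol is not None and data.mol.n_sites:
        n_subsets = data.mol.n_subsets
    for run_idx in range(config.n_runs):
        rng = np.random.default_rng([config.seed, run_idx])
        post = _Posterior(data, model)
        chains = []
        for _ in range(config.n_chains):
            st = _init_state(data, model, rng, init_tree)
            st.subset_alphas = np.ones(n_subsets)
            post.evaluate(st)
            tries = 0
            while not math.isfinite(st.log_prior + st.log_like):
                tries += 1
                if tries > 50:
                    raise McmcError("could not find a finite-posterior "
                                    "starting state")
                st = _init_state(data, model, rng, init_tree)
                st.subset_alphas = np.ones(n_subsets)
                post.evaluate(st)
            chains.append(st)
        betas = [chain_heat(i, config.heat) for i in range(config.n_chains)]

        rows, trees = [], []
        swaps = accepted_swaps = 0
        for gen in range(1, config.n_generations + 1):
            for ci, st in enumerate(chains):
                prop = _propose(st, post, rng)
                if prop is None:
                    continue
                new, lh = prop
                post.evaluate(new)
                if not math.isfinite(new.log_prior):
                    continue
                delta = ((new.log_like + new.log_prior)
                         - (st.log_like + st.log_prior))
                if math.log(rng.random() + 1e-300) < betas[ci] * delta + lh:
                    chains[ci] = new
            if config.n_chains > 1:
                i, j = rng.choice(config.n_chains, size=2, replace=False)
                swaps += 1
                pi = chains[i].log_like + chains[i].log_prior
                pj = chains[j].log_like + chains[j].log_prior
                if math.log(rng.random() + 1e-300) < \
                        (betas[i] - betas[j]) * (pj - pi):
                    chains[i], chains[j] = chains[j], chains[i]
                    accepted_swaps += 1
            if gen % config.sample_every == 0:
                cold = chains[0]
                rows.append({
                    "gen": gen,
                    "log_likelihood": cold.log_like,
                    "log_prior": cold.log_prior,
                    "speciation": cold.speciation,
                    "turnover": cold.turnover,
                    "sampling_prop": cold.sampling_prop,
                    "clock_rate": cold.clock_rate,
                    "igr_variance": cold.igr_variance,
                    "morph_alpha": cold.morph_alpha,
                    "root_age": cold.tree.root.age,
                    "tree_length": cold.tree.total_length(),
                })
                trees.append(cold.tree.copy())
        runs.append(RunTrace(pd.DataFrame(rows), trees,
                             accepted_swaps / max(swaps, 1)))
        logger.info("run %d: %d samples, swap acceptance %.2f",
                    run_idx, len(rows), runs[-1].swap_acceptance)
    return McmcResult(runs, config)


# ---------------------------------------------------------------------------
# Diagnostics


def _clade_frequencies(trees) -> dict:
    counts: dict = {}
    for tree in trees:
        for node in tree.postorder():
            if node.is_leaf or node is tree.root:
                continue
            counts[tree.clade_names(node)] = \
                counts.get(tree.clade_names(node), 0) + 1
    n = len(trees)
    return {c: k / n for c, k in counts.items()}


def compute_asdsf(trees_a, trees_b, min_split_freq: float = 0.1) -> float:
    """Average (population) standard deviation of split frequencies
    between two independent runs, over splits whose pooled frequency
    reaches ``min_split_freq``."""
    if len(trees_a) < 2 or len(trees_b) < 2:
        raise McmcError("need at least 2 trees per run")
    fa = _clade_frequencies(trees_a)
    fb = _clade_frequencies(trees_b)
    sds = []
    for clade in set(fa) | set(fb):
        pa, pb = fa.get(clade, 0.0), fb.get(clade, 0.0)
        if (pa + pb) / 2 >= min_split_freq:
            mean = (pa + pb) / 2
            sds.append(math.sqrt(((pa - mean) ** 2 + (pb - mean) ** 2) / 2))
    if not sds:
        logger.warning("no splits reach pooled frequency %g", min_split_freq)
        return 0.0
    return float(np.mean(sds))


def compute_ess(series) -> float:
    """Effective sample size from the initial-positive-sequence
    autocorrelation sum (Geyer)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise McmcError("series too short for an ESS estimate")
    if np.allclose(x, x[0]):
        raise McmcError("constant series: ESS undefined")
    x = x - x.mean()
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs while positive
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        tau += 2 * pair
    return float(min(n, n / max(tau, 1e-12)))


@dataclass
class DiagnosticsReport:
    asdsf: float
    ess: dict
    min_ess: float
    burnin_table: pd.DataFrame | None = None
    chosen_burnin: int | None = None

    def to_dict(self):
        d = {"asdsf": self.asdsf, "min_ess": self.min_ess,
             "ess": self.ess, "chosen_burnin": self.chosen_burnin}
        if self.burnin_table is not None:
            d["burnin_table"] = self.burnin_table.to_dict("records")
        return d


def select_burnin(candidates: dict, asdsf_target: float = 0.01,
                  ess_target: float = 100.0) -> int:
    """Grid burn-in selection: among candidates meeting the ASDSF
    target, pick the one whose least-sampled parameter most exceeds the
    minESS target.  Raises :class:`ExtendRunSignal` when none
    qualifies."""
    if not candidates:
        raise McmcError("empty candidate table")
    qualifying = {b: v for b, v in candidates.items()
                  if v[0] <= asdsf_target}
    if not qualifying:
        raise ExtendRunSignal(
            f"no burn-in candidate reached ASDSF <= {asdsf_target}; "
            "extend the run")
    best = max(qualifying, key=lambda b: qualifying[b][1])
    if qualifying[best][1] < ess_target:
        logger.warning("best candidate minESS %.1f below target %.0f",
                       qualifying[best][1], ess_target)
    return best


def diagnose(result: McmcResult, burnin_fracs=(0.0, 0.1, 0.25, 0.5),
             params=None, asdsf_target=0.01, ess_target=100.0
             ) -> DiagnosticsReport:
    """Run the full burn-in grid over both runs and assemble a report."""
    if len(result.runs) < 2:
        raise McmcError("diagnostics require two independent runs")
    df0 = result.runs[0].params
    if params is None:
        params = [c for c in df0.columns if c != "gen"
                  and df0[c].nunique() > 1]
    rows, table = [], {}
    for frac in burnin_fracs:
        cut = int(frac * len(df0))
        trees = [run.trees[cut:] for run in result.runs]
        if min(len(t) for t in trees) < 2:
            continue
        asdsf = compute_asdsf(trees[0], trees[1])
        esses = []
        for run in result.runs:
            sub = run.params.iloc[cut:]
            for p in params:
                try:
                    esses.append(compute_ess(sub[p].to_numpy()))
                except McmcError:
                    pass
        min_ess = min(esses) if esses else 0.0
        table[cut] = (asdsf, min_ess)
        rows.append({"burnin_samples": cut, "asdsf": asdsf,
                     "min_ess": min_ess})
    try:
        chosen = select_burnin(table, asdsf_target, ess_target)
    except ExtendRunSignal:
        chosen = None
    burnin_df = pd.DataFrame(rows)
    cut = chosen if chosen is not None else 0
    full = pd.concat([run.params.iloc[cut:] for run in result.runs])
    ess = {}
    for p in params:
        try:
            ess[p] = compute_ess(full[p].to_numpy())
        except McmcError:
            ess[p] = float("nan")
    finite = [v for v in ess.values() if np.isfinite(v)]
    return DiagnosticsReport(
        asdsf=table.get(cut, (float("nan"), 0))[0], ess=ess,
        min_ess=min(finite) if finite else float("nan"),
        burnin_table=burnin_df, chosen_burnin=chosen)


# ---------------------------------------------------------------------------
# allcompat summary


def summarize_allcompat(trees) -> tuple[TimeTree, dict]:
    """Majority-rule-plus-compatible-groups consensus of rooted dated
    trees.

    All clades with frequency > 0.5 are included; remaining clades are
    added in decreasing frequency order when compatible (nested or
    disjoint) with the tree so far, until fully resolved.  Node ages
    are means across the samples containing the clade; returns the
    summary tree and a {clade: posterior probability} map.
    """
    if not trees:
        raise McmcError("no tree samples")
    freqs = _clade_frequencies(trees)
    names = sorted(trees[0].tip_names())
    full = frozenset(names)

    def compatible(c, chosen):
        return all(c <= d or d <= c or not (c & d) for d in chosen)

    chosen = []
    order = sorted(freqs.items(), key=lambda kv: (-kv[1], -len(kv[0]),
                                                  sorted(kv[0])))
    # clades with frequency > 0.5 are mutually compatible and always
    # enter first; lower-frequency clades enter only when compatible
    for clade, f in order:
        if compatible(clade, chosen):
            chosen.append(clade)

    # mean ages per clade (over samples containing it) and per tip
    age_sum = {c: 0.0 for c in chosen}
    age_n = {c: 0 for c in chosen}
    root_ages, tip_ages = [], {n: [] for n in names}
    for tree in trees:
        clades = {tree.clade_names(n): n.age for n in tree.postorder()
                  if not n.is_leaf and n is not tree.root}
        for c in chosen:
            if c in clades:
                age_sum[c] += clades[c]
                age_n[c] += 1
        root_ages.append(tree.root.age)
        for tip in tree.tips:
            tip_ages[tip.name].append(tip.age)

    support = {c: freqs[c] for c in chosen}
    nested = sorted(chosen + [full], key=len)
    node_of = {}
    for c in nested:
        node = Node(None, 0.0)
        node_of[c] = node
    for name in names:
        node_of[frozenset([name])] = Node(name, float(np.mean(
            tip_ages[name])))
    units = [frozenset([n]) for n in names] + nested
    for c in units:
        if c == full:
            continue
        parent = min((d for d in nested if c < d), key=len)
        node_of[parent].add_child(node_of[c])
    for c in nested:
        if c == full:
            node_of[c].age = float(np.mean(root_ages))
        else:
            node_of[c].age = age_sum[c] / max(age_n[c], 1)
    root = node_of[full]

    # enforce parent > child ages (low-support clades can conflict)
    def fix(node):
        for ch in node.children:
            fix(ch)
        if node.children:
            top = max(ch.age for ch in node.children)
            if node.age <= top:
                node.age = top + 1e-6
        return node

    tree = TimeTree(fix(root))
    return tree, support
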