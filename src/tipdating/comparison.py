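"""Stepping-stone marginal likelihoods and Bayes-factor hypothesis tests.

The hypothesis design compares alternative placements of two focal
fossil taxa on a fixed backbone tree (the dated summary tree with the
focals pruned): H1 allows any placement, H2 forbids a focal+reference
pair clade, H3 forbids stem placements next to the reference taxon,
and H4 additionally forces the focals inside a named crown clade.
Marginal likelihoods are estimated by stepping-stone sampling along a
ladder of power posteriors; Bayes factors are interpreted with the
conventional >10 "strong" and >100 "decisive" thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

from .mcmc import ChainState, InferenceModel, _Posterior, _propose
from .treemodel import Node, TimeTree


class ComparisonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Topology constraints


@dataclass(frozen=True)
class TopologyConstraint:
    """One topological restriction.

    kind "backbone": relationships among the backbone taxa are fixed;
    other (focal) taxa may attach anywhere.  kind "negative": no clade
    may contain exactly/only ``taxa`` while excluding every member of
    ``excluding`` (with ``excluding`` empty the forbidden clade is
    ``taxa`` exactly).  kind "positive": the clade spanned by ``taxa``
    must contain every taxon in ``within``.
    """

    kind: str
    taxa: frozenset = frozenset()
    excluding: frozenset = frozenset()
    within: frozenset = frozenset()
    backbone_clades: frozenset = frozenset()   # frozenset of frozensets
    hypothesis: str = ""

    def satisfied(self, tree: TimeTree) -> bool:
        clades = {tree.clade_names(n) for n in tree.postorder()
                  if not n.is_leaf}
        if self.kind == "backbone":
            extras = set(tree.tip_names()) - set(self.taxa)
            restricted = tree.prune_taxa(extras) if extras else tree
            rc = {restricted.clade_names(n)
                  for n in restricted.postorder()
                  if not n.is_leaf and n is not restricted.root}
            return self.backbone_clades <= rc
        if self.kind == "negative":
            for c in clades:
                if self.taxa <= c and not (c & self.excluding):
                    if self.excluding or c == self.taxa:
                        return False
            return True
        if self.kind == "positive":
            # smallest clade containing `taxa` must also contain `within`
            host = min((c for c in clades if self.taxa <= c), key=len,
                       default=None)
            return host is not None and self.within <= host
        raise ComparisonError(f"unknown constraint kind {self.kind!r}")


def satisfies_all(tree: TimeTree, constraints) -> bool:
    return all(c.satisfied(tree) for c in constraints)


def backbone_constraint(backbone: TimeTree, hypothesis="") \
        -> TopologyConstraint:
    clades = frozenset(
        backbone.clade_names(n) for n in backbone.postorder()
        if not n.is_leaf and n is not backbone.root)
    return TopologyConstraint(kind="backbone",
                              taxa=frozenset(backbone.tip_names()),
                              backbone_clades=clades, hypothesis=hypothesis)


def build_hypothesis_constraints(backbone: TimeTree, hypothesis: str,
                                 focal_taxa, reference_taxon: str,
                                 crown_clade) -> list:
    """Constraint sets for the four placement hypotheses.

    ``backbone`` is the dated tree pruned of the focal taxa;
    ``reference_taxon`` is the extant taxon whose stem lineage the
    focals may or may not join (e.g. the aye-aye when testing
    chiromyiform placements);
    ``crown_clade`` is the taxon set of the crown group used by H3/H4.
    H1: backbone only.  H2: backbone + no (focal2, reference) pair
    clade.  H3: backbone + no focal on the reference stem (no clade
    holding a focal with the reference taxon but no other crown
    member).  H4: H3 + focals inside the crown clade.
    """
    focal_taxa = list(focal_taxa)
    names = set(backbone.tip_names())
    if reference_taxon not in names:
        raise ComparisonError(f"backbone lacks {reference_taxon!r}")
    missing = set(crown_clade) - names
    if missing:
        raise ComparisonError(f"backbone lacks crown taxa {missing}")
    cons = [backbone_constraint(backbone, hypothesis)]
    others = frozenset(set(crown_clade) - {reference_taxon})
    if hypothesis == "H1":
        return cons
    if hypothesis == "H2":
        cons.append(TopologyConstraint(
            kind="negative",
            taxa=frozenset([focal_taxa[-1], reference_taxon]),
            hypothesis=hypothesis))
        return cons
    if hypothesis in ("H3", "H4"):
        for f in focal_taxa:
            cons.append(TopologyConstraint(
                kind="negative", taxa=frozenset([f, reference_taxon]),
                excluding=others, hypothesis=hypothesis))
        if hypothesis == "H4":
            cons.append(TopologyConstraint(
                kind="positive", taxa=frozenset(crown_clade),
                within=frozenset(focal_taxa), hypothesis=hypothesis))
        return cons
    raise ComparisonError(f"unknown hypothesis {hypothesis!r}")


# ---------------------------------------------------------------------------
# Stepping-stone estimator


def stepping_stone_schedule(n_steps: int = 50, alpha: float = 0.4
                            ) -> np.ndarray:
    """Powers descending from 1 toward 0 at quantiles of Beta(alpha, 1)."""
    k = np.arange(n_steps, -1, -1)
    return (k / n_steps) ** (1.0 / alpha)


@dataclass
class MarginalLikelihoodEstimate:
    log_ml: float
    schedule: np.ndarray
    per_step: pd.DataFrame
    n_samples: int
    seed: int


def stepping_stone(sample_at_power, n_steps: int = 50,
                   samples_per_step: int = 1000,
                   alpha: float = 0.4, burnin_frac: float = 0.25,
                   seed: int = 0) -> MarginalLikelihoodEstimate:
    """Generic stepping-stone driver.

    ``sample_at_power(beta, n, rng, state)`` must return
    ``(loglikes, state)``: post-burn-in log-likelihood draws from the
    power posterior prior x likelihood^beta, plus carry-over state for
    the next (colder) step.  The estimator sums, over adjacent powers
    b_k > b_{k+1}, the log mean importance ratio
    ``log mean exp((b_k - b_{k+1}) * ll)`` with samples drawn at the
    lower power.
    """
    betas = stepping_stone_schedule(n_steps, alpha)
    rng = np.random.default_rng(seed)
    state = None
    log_ml = 0.0
    rows = []
    n_keep = max(int(samples_per_step * (1 - burnin_frac)), 1)
    for k in range(len(betas) - 1):
        b_hi, b_lo = betas[k], betas[k + 1]
        lls, state = sample_at_power(b_lo, samples_per_step, rng, state)
        lls = np.asarray(lls)[-n_keep:]
        if np.allclose(lls, lls[0]):
            contrib = (b_hi - b_lo) * lls[0]
        else:
            contrib = float(logsumexp((b_hi - b_lo) * lls)
                            - math.log(len(lls)))
        log_ml += contrib
        rows.append({"beta_high": b_hi, "beta_low": b_lo,
                     "log_ratio": contrib,
                     "mean_ll": float(np.mean(lls))})
    return MarginalLikelihoodEstimate(
        log_ml=float(log_ml), schedule=betas,
        per_step=pd.DataFrame(rows),
        n_samples=(len(betas) - 1) * samples_per_step, seed=seed)


# -- conjugate calibration target


@dataclass
class BetaBinomialToy:
    """Conjugate beta-binomial target with closed-form marginal
    likelihood, used to calibrate the stepping-stone estimator."""

    successes: int
    trials: int
    a: float = 1.0
    b: float = 1.0

    def exact_log_marginal(self) -> float:
        y, n = self.successes, self.trials
        return float(math.lgamma(n + 1) - math.lgamma(y + 1)
                     - math.lgamma(n - y + 1)
                     + betaln(self.a + y, self.b + n - y)
                     - betaln(self.a, self.b))

    def log_likelihood(self, theta: float) -> float:
        y, n = self.successes, self.trials
        return float(math.lgamma(n + 1) - math.lgamma(y + 1)
                     - math.lgamma(n - y + 1)
                     + y * math.log(theta) + (n - y) * math.log1p(-theta))

    def sampler(self, step_sd: float = 0.2):
        from scipy import stats

        def sample_at_power(beta, n_samples, rng, theta):
            if theta is None:
                theta = rng.beta(self.a, self.b)
            lls = np.empty(n_samples)
            lp = (stats.beta.logpdf(theta, self.a, self.b)
                  + beta * self.log_likelihood(theta))
            for i in range(n_samples):
                prop = theta + rng.normal(0, step_sd)
                if 0 < prop < 1:
                    lp_new = (stats.beta.logpdf(prop, self.a, self.b)
                              + beta * self.log_likelihood(prop))
                    if math.log(rng.random() + 1e-300) < lp_new - lp:
                        theta, lp = prop, lp_new
                lls[i] = self.log_likelihood(theta)
            return lls, theta

        return sample_at_power


# -- morphological-partition tree target


def attach_taxon(tree: TimeTree, name: str, tip_age: float, rng
                 ) -> TimeTree:
    """Attach a new tip to a random branch at a random valid height."""
    new = tree.copy()
    nodes = [n for n in new.postorder()
             if n.parent is not None and n.parent.age > tip_age]
    nodes.append(new.root)
    node = nodes[rng.integers(len(nodes))]
    lo = max(tip_age, node.age if node is not new.root else node.age)
    hi = node.parent.age if node is not new.root else node.age * 1.3 + 1.0
    if hi <= lo:
        hi = lo + 1.0
    h = rng.uniform(lo, hi)
    if h <= lo:
        h = lo + 1e-6
    joint = Node(None, h)
    tip = Node(name, tip_age)
    if node is new.root:
        joint.add_child(node)
        node.parent = joint
        joint.add_child(tip)
        new.root = joint
    else:
        parent = node.parent
        parent.children[parent.children.index(node)] = joint
        joint.parent = parent
        joint.add_child(node)
        joint.add_child(tip)
    new.reindex()
    new.validate()
    return new


def constrained_start_tree(backbone: TimeTree, focal_ages: dict,
                           constraints, rng, max_tries: int = 500
                           ) -> TimeTree:
    for _ in range(max_tries):
        tree = backbone
        for name, age in focal_ages.items():
            tree = attach_taxon(tree, name, age, rng)
        if satisfies_all(tree, constraints):
            return tree
    raise ComparisonError("no focal attachment satisfies the constraints")


def stepping_stone_lnML(data, model: InferenceModel, constraints,
                        backbone: TimeTree, focal_ages: dict,
                        n_steps: int = 50, samples_per_step: int = 1000,
                        alpha: float = 0.4, seed: int = 0,
                        thin: int = 1) -> MarginalLikelihoodEstimate:
    """Stepping-stone marginal likelihood of one morphological-partition
    hypothesis.

    The sampler is a single-chain MH over the focal taxa's placements,
    node ages and model parameters at each power, with backbone and
    clade constraints enforced by rejection.
    """
    post = _Posterior(data, model)

    def sample_at_power(beta, n_samples, rng, st):
        if st is None:
            tree = constrained_start_tree(backbone, focal_ages,
                                          constraints, rng)
            st = ChainState(tree=tree, speciation=0.1, turnover=0.5,
                            sampling_prop=0.5, clock_rate=0.05,
                            igr_variance=0.1, morph_alpha=1.0,
                            subset_alphas=np.zeros(0))
            post.evaluate(st)
            if not math.isfinite(st.log_prior + st.log_like):
                raise ComparisonError("infinite posterior at start")
        lls = np.empty(n_samples)
        for i in range(n_samples):
            for _ in range(thin):
                prop = _propose(st, post, rng)
                if prop is None:
                    continue
                new, lh = prop
                if not satisfies_all(new.tree, constraints):
                    continue
                post.evaluate(new)
                if not math.isfinite(new.log_prior):
                    continue
                delta = (beta * (new.log_like - st.log_like)
                         + new.log_prior - st.log_prior)
                if math.log(rng.random() + 1e-300) < delta + lh:
                    st = new
            lls[i] = st.log_like
        return lls, st

    return stepping_stone(sample_at_power, n_steps=n_steps,
                          samples_per_step=samples_per_step, alpha=alpha,
                          seed=seed)


# ---------------------------------------------------------------------------
# Bayes factors


@dataclass(frozen=True)
class BayesFactor:
    log_bf: float

    @property
    def value(self) -> float:
        return math.exp(self.log_bf)

    @property
    def category(self) -> str:
        # strict > thresholds, compared on the log scale
        if self.log_bf > math.log(100):
            return "decisive"
        if self.log_bf > math.log(10):
            return "strong"
        return "not strong"


def bayes_factor(log_ml_h1: float, log_ml_alt: float) -> BayesFactor:
    """BF = exp(lnML_H1 - lnML_alt); >10 strong, >100 decisive
    (strict inequalities) in favor of H1."""
    if not (math.isfinite(log_ml_h1) and math.isfinite(log_ml_alt)):
        raise ComparisonError("non-finite marginal likelihoods")
    return BayesFactor(log_bf=log_ml_h1 - log_ml_alt)


def comparison_table(estimates: dict) -> pd.DataFrame:
    """Hypothesis table: lnML, BF vs H1, category."""
    if "H1" not in estimates:
        raise ComparisonError("need an H1 estimate as reference")
    ref = estimates["H1"].log_ml
    rows = []
    for h, est in sorted(estimates.items()):
        bf = bayes_factor(ref, est.log_ml)
        rows.append({"hypothesis": h, "log_ml": est.log_ml,
                     "bf_vs_h1": bf.value if h != "H1" else 1.0,
                     "category": bf.category if h != "H1" else ""})
    return pd.DataFrame(rows)
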