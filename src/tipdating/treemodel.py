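"""Dated trees and their priors.

Implements the prior machinery of Bayesian tip dating: the
fossilized-birth-death (FBD) tree prior with terminal fossil tips and
fixed extant sampling probability, uniform stratigraphic tip-age
windows, the independent-gamma-rates (IGR) relaxed clock, truncated
normal node-age calibrations, and the empirical derivation of a clock
base-rate prior from a non-clock tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from .characters import TaxonRecord

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TimeTree


class Node:
    __slots__ = ("children", "parent", "name", "age", "index", "rate")

    def __init__(self, name=None, age=0.0, rate=1.0):
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.name = name
        self.age = float(age)
        self.index = -1
        self.rate = float(rate)  # relaxed-clock branch multiplier

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"<Node {self.name or self.index} age={self.age:.3g}>"


class TimeTree:
    """Rooted binary tree with node ages in Ma (present = 0).

    Branch duration of a node is ``parent.age - node.age``.  Node
    indices are assigned tips-first in sorted-name order so likelihood
    code can address flat arrays; :meth:`reindex` must be called after
    any topology change.
    """

    def __init__(self, root: Node):
        self.root = root
        self.reindex()

    # -- construction and indexing

    def reindex(self) -> None:
        tips = sorted(self.leaves(), key=lambda n: n.name)
        for i, tip in enumerate(tips):
            tip.index = i
        i = len(tips)
        for node in self.postorder():
            if not node.is_leaf:
                node.index = i
                i += 1
        self._tips = tips
        self._n_nodes = i

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def n_nodes(self) -> int:
        return self._n_nodes

    @property
    def tips(self) -> list[Node]:
        return self._tips

    def tip_names(self) -> list[str]:
        return [t.name for t in self._tips]

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def preorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def internal_nodes(self):
        return [n for n in self.postorder() if not n.is_leaf]

    def validate(self) -> None:
        for node in self.postorder():
            if node.parent is not None and node.parent.age <= node.age:
                raise TreeError(
                    f"parent age {node.parent.age} <= child age {node.age}")
            if not node.is_leaf and len(node.children) != 2:
                raise TreeError("tree must be binary")

    def copy(self) -> "TimeTree":
        mapping = {}

        def clone(node):
            c = Node(node.name, node.age, node.rate)
            c.index = node.index
            mapping[node] = c
            for ch in node.children:
                c.add_child(clone(ch))
            return c

        t = TimeTree(clone(self.root))
        return t

    # -- quantities

    def durations(self) -> np.ndarray:
        """Branch duration per node index (root entry = 0)."""
        d = np.zeros(self.n_nodes)
        for node in self.postorder():
            if node.parent is not None:
                d[node.index] = node.parent.age - node.age
        return d

    def total_length(self) -> float:
        return float(self.durations().sum())

    def node_ages(self) -> np.ndarray:
        ages = np.zeros(self.n_nodes)
        for node in self.postorder():
            ages[node.index] = node.age
        return ages

    def mrca(self, names) -> Node:
        target = set(names)
        for node in self.postorder():
            if target.issubset(self.clade_names(node)):
                return node
        raise TreeError(f"no MRCA found for {sorted(target)}")

    def clade_names(self, node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def is_monophyletic(self, names) -> bool:
        return self.clade_names(self.mrca(names)) == frozenset(names)

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the tip-name side not
        containing the alphabetically first tip."""
        all_names = frozenset(self.tip_names())
        anchor = min(all_names)
        out = set()
        for node in self.postorder():
            if node.is_leaf or node is self.root:
                continue
            clade = self.clade_names(node)
            side = clade if anchor not in clade else all_names - clade
            if 1 < len(side) < len(all_names):
                out.add(side)
        return out

    def prune_taxa(self, names) -> "TimeTree":
        """Copy of the tree with the given tips removed (unary nodes
        suppressed, ages kept)."""
        drop = set(names)
        keep = [t for t in self.tip_names() if t not in drop]
        if len(keep) < 2:
            raise TreeError("pruning would leave fewer than 2 tips")
        tree = self.copy()

        def prune(node):
            if node.is_leaf:
                return node if node.name not in drop else None
            kept = [c for c in (prune(ch) for ch in node.children)
                    if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            node.children = []
            for c in kept:
                node.add_child(c)
            return node

        root = prune(tree.root)
        root.parent = None
        return TimeTree(root)

    # -- I/O

    def to_newick(self, ages_as_lengths=True) -> str:
        def fmt(node):
            if node.is_leaf:
                label = node.name
            else:
                label = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is not None and ages_as_lengths:
                label += f":{node.parent.age - node.age:.10g}"
            return label

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, tip_ages: dict | None = None
                    ) -> "TimeTree":
        """Build a dated tree from newick branch lengths (durations).

        Tip ages are taken from ``tip_ages`` when given; otherwise the
        deepest tip is placed at age 0 and every node age follows from
        the root-to-node path lengths.
        """
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree, tip_ages=tip_ages)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree",
                      tip_ages: dict | None = None) -> "TimeTree":
        depth = {}
        root_d = dtree.seed_node

        def walk(dn, d):
            depth[dn] = d
            for ch in dn.child_nodes():
                walk(ch, d + (ch.edge.length or 0.0))

        walk(root_d, 0.0)
        max_depth = max(depth[l] for l in dtree.leaf_node_iter())

        def build(dn):
            if dn.is_leaf():
                name = dn.taxon.label.replace(" ", "_")
                age = (tip_ages or {}).get(name, max_depth - depth[dn])
                node = Node(name, age)
            else:
                node = Node(None, 0.0)
                for ch in dn.child_nodes():
                    node.add_child(build(ch))
            return node

        root = build(root_d)

        # internal ages from durations, bottom-up: parent = child age +
        # child's edge length
        def set_ages(dn, node):
            for dch, ch in zip(dn.child_nodes(), node.children):
                set_ages(dch, ch)
            if not node.is_leaf:
                ages = [ch.age + (dch.edge.length or 0.0)
                        for dch, ch in zip(dn.child_nodes(), node.children)]
                node.age = float(np.mean(ages))

        set_ages(root_d, root)
        tree = cls(root)
        return tree


def random_dated_tree(names, rng, root_age=10.0,
                      tip_ages: dict | None = None) -> TimeTree:
    """Random dated topology over ``names`` with the root at
    ``root_age`` (utility for initialization and tests).

    Built top-down: each internal node splits its taxon set at random
    and children ages are drawn uniformly between the oldest contained
    tip and the parent age, so the tree is valid for any fossil ages
    below ``root_age``."""
    tip_ages = tip_ages or {}
    names = list(names)
    if root_age <= max((tip_ages.get(n, 0.0) for n in names), default=0.0):
        raise TreeError("root age must exceed every tip age")

    def build(subset, age):
        if len(subset) == 1:
            return Node(subset[0], tip_ages.get(subset[0], 0.0))
        node = Node(None, age)
        cut = int(rng.integers(1, len(subset)))
        perm = list(rng.permutation(subset))
        for part in (perm[:cut], perm[cut:]):
            oldest = max(tip_ages.get(n, 0.0) for n in part)
            child_age = (rng.uniform(oldest + 0.5 * (age - oldest), age)
                         if len(part) > 1 else 0.0)
            child = build(part, child_age)
            node.add_child(child)
        return node

    tree = TimeTree(build(names, root_age))
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# FBD prior


@dataclass
class FBDParams:
    """FBD rates in the (speciation, turnover, sampling-proportion,
    extant-sampling) parameterization.

    turnover = mu/lambda and sampling_prop = psi/(mu+psi) live on (0,1)
    so flat Beta(1,1) priors apply directly; the raw extinction and
    fossilization rates are derived.
    """

    speciation: float            # lambda, events/lineage/Ma
    turnover: float              # mu / lambda
    sampling_prop: float         # psi / (mu + psi)
    rho: float = 1.0             # extant sampling probability (fixed)

    def __post_init__(self):
        if self.speciation <= 0:
            raise TreeError("speciation rate must be positive")
        if not (0 <= self.turnover < 1):
            raise TreeError("turnover must lie in [0,1)")
        if not (0 <= self.sampling_prop < 1):
            raise TreeError("sampling proportion must lie in [0,1)")
        if not (0 < self.rho <= 1):
            raise TreeError("rho must lie in (0,1]")

    @property
    def extinction(self) -> float:
        return self.speciation * self.turnover

    @property
    def fossilization(self) -> float:
        mu = self.extinction
        s = self.sampling_prop
        return 0.0 if s == 0 else mu * s / (1 - s)

    def log_prior(self, speciation_rate_prior=10.0) -> float:
        """Exponential(rate 10) on speciation; Beta(1,1) on the two
        (0,1) quantities (log density 0)."""
        if self.speciation < 0:
            return -math.inf
        return (math.log(speciation_rate_prior)
                - speciation_rate_prior * self.speciation)


def _fbd_constants(p: FBDParams):
    lam, mu, psi, rho = (p.speciation, p.extinction, p.fossilization, p.rho)
    c1 = abs(math.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi))
    if c1 == 0:
        c1 = 1e-300
    c2 = -(lam - mu - 2 * lam * rho - psi) / c1
    return lam, mu, psi, rho, c1, c2


def _log_q(t, c1, c2):
    # q(t) = 4 e^{-c1 t} / (e^{-c1 t}(1-c2) + (1+c2))^2
    e = math.exp(-c1 * t)
    denom = e * (1 - c2) + (1 + c2)
    return math.log(4) - c1 * t - 2 * math.log(abs(denom))


def _p0(t, lam, mu, psi, c1, c2):
    e = math.exp(-c1 * t)
    frac = (e * (1 - c2) - (1 + c2)) / (e * (1 - c2) + (1 + c2))
    return (lam + mu + psi + c1 * frac) / (2 * lam)


def fbd_log_density(tree: TimeTree, p: FBDParams,
                    condition: str = "origin",
                    origin_age: float | None = None,
                    survival: bool = False,
                    fossil_names: set | None = None,
                    removal: bool = False) -> float:
    """Log prior density of a dated tree under the FBD process.

    Fossils are terminal sampled tips (age > 0); extant tips sit at
    age 0 and are sampled with probability rho.  ``condition`` selects
    the time the process is anchored on: "origin" (default; the origin
    defaults to the root age, i.e. a zero-length stem) or "root"
    (conditions on the root divergence, dropping the stem factor).
    ``survival`` additionally conditions on at least one sampled lineage.
    ``removal=True`` uses the sampling-with-removal variant, where a
    lineage terminates at fossil sampling, so the no-sampled-descendants
    factor p0(y) at each fossil is dropped (the p0 and q functions
    themselves are unchanged between the variants).
    """
    lam, mu, psi, rho, c1, c2 = _fbd_constants(p)
    tips = tree.tips
    if fossil_names is None:
        fossil_names = {t.name for t in tips if t.age > 0}
    fossils = [t for t in tips if t.name in fossil_names]
    n_extant = len(tips) - len(fossils)
    m = len(fossils)
    if m > 0 and psi == 0:
        logger.warning("tree has fossil tips but fossilization rate is 0")
        return -math.inf

    internals = tree.internal_nodes()
    x0 = tree.root.age if origin_age is None else float(origin_age)
    if x0 < tree.root.age:
        return -math.inf

    logf = 0.0
    if condition == "origin":
        logf += _log_q(x0, c1, c2)
    elif condition == "root":
        pass  # stem factor dropped; root handled with the internals below
    else:
        raise TreeError(f"unknown conditioning {condition!r}")

    for node in internals:
        logf += math.log(lam) + _log_q(node.age, c1, c2)
    if condition == "root":
        # conditioning on the root divergence removes one speciation factor
        logf -= math.log(lam)

    for f in fossils:
        logf += math.log(psi) - _log_q(f.age, c1, c2)
        if not removal:
            p0 = _p0(f.age, lam, mu, psi, c1, c2)
            if p0 <= 0:
                return -math.inf
            logf += math.log(p0)

    if n_extant:
        logf += n_extant * math.log(rho)

    if survival:
        t_cond = x0 if condition == "origin" else tree.root.age
        p0_cond = _p0(t_cond, lam, mu, psi, c1, c2)
        if p0_cond >= 1:
            return -math.inf
        logf -= math.log1p(-p0_cond)
        if condition == "root":
            logf -= math.log1p(-p0_cond)  # both root children must survive
    return logf


def yule_log_density(tree: TimeTree, lam: float,
                     origin_age: float | None = None) -> float:
    """Closed-form pure-birth density (oracle limit of the FBD)."""
    x0 = tree.root.age if origin_age is None else origin_age
    total = tree.total_length() + (x0 - tree.root.age)
    n_internal = len(tree.internal_nodes())
    return n_internal * math.log(lam) - lam * total


# ---------------------------------------------------------------------------
# IGR relaxed clock


def igr_log_prior(multipliers: np.ndarray, v: float,
                  durations: np.ndarray) -> float:
    """Log prior of independent gamma branch-rate multipliers.

    Each branch of duration d carries an independent multiplier with
    mean 1 and variance v/d, i.e. Gamma(shape=d/v, rate=d/v); longer
    branches have tighter rates, so the variance of the branch-length
    deviation is proportional to v.
    """
    if v <= 0:
        raise TreeError("IGR variance must be positive")
    multipliers = np.asarray(multipliers, dtype=float)
    durations = np.asarray(durations, dtype=float)
    mask = durations > 0
    m = multipliers[mask]
    if np.any(m <= 0):
        return -math.inf
    a = durations[mask] / v
    # Gamma(a, rate a) log pdf in closed form (hot path)
    from scipy.special import gammaln
    return float(np.sum(a * np.log(a) - gammaln(a)
                        + (a - 1) * np.log(m) - a * m))


def sample_igr_multipliers(v, durations, rng) -> np.ndarray:
    durations = np.asarray(durations, dtype=float)
    out = np.ones_like(durations)
    mask = durations > 0
    a = durations[mask] / v
    out[mask] = rng.gamma(shape=a, scale=1.0 / a)
    return out


# ---------------------------------------------------------------------------
# Calibrations


@dataclass(frozen=True)
class Calibration:
    """Truncated-normal node age calibration: zero below ``min_age``,
    normal(mean, sd) above, renormalized."""

    clade: frozenset
    min_age: float
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.sd <= 0:
            raise TreeError("calibration sd must be positive")
        if self.mean < self.min_age:
            raise TreeError("calibration mean below its minimum")


def calibration_log_density(age: float, cal: Calibration) -> float:
    if age < cal.min_age:
        return -math.inf
    z = 1.0 - stats.norm.cdf(cal.min_age, loc=cal.mean, scale=cal.sd)
    return float(stats.norm.logpdf(age, loc=cal.mean, scale=cal.sd)
                 - math.log(z))


@dataclass
class CalibrationSet:
    calibrations: list[Calibration] = field(default_factory=list)

    def log_density(self, tree: TimeTree) -> float:
        total = 0.0
        for cal in self.calibrations:
            node = tree.mrca(cal.clade)
            total += calibration_log_density(node.age, cal)
        return total


def study_calibrations(primates: frozenset, euarchonta: frozenset
                       ) -> CalibrationSet:
    """The two calibrations used for crown Primates (oldest fossil
    *Teilhardina*, 55.8 Ma) and Euarchonta (*Purgatorius*, 65.2 Ma),
    both with minimum = mean and 1 Ma sd."""
    return CalibrationSet([
        Calibration(primates, 55.8, 55.8, 1.0, "Primates"),
        Calibration(euarchonta, 65.2, 65.2, 1.0, "Euarchonta"),
    ])


# ---------------------------------------------------------------------------
# Fossil tip ages


def propose_fossil_tip_age(record: TaxonRecord, current: float,
                           rng) -> float:
    """Independent uniform draw of a fossil tip age inside its
    stratigraphic window (symmetric proposal: Hastings ratio 1)."""
    if record.extant:
        raise TreeError(f"{record.name} is extant; its age is fixed at 0")
    lo, hi = record.age_window
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


def tip_age_log_prior(age: float, record: TaxonRecord) -> float:
    lo, hi = record.age_window
    if lo == hi:
        return 0.0 if age == lo else -math.inf
    if lo <= age <= hi:
        return -math.log(hi - lo)
    return -math.inf


# ---------------------------------------------------------------------------
# Clock-rate prior derivation


@dataclass
class ClockRatePriorFit:
    """Result of fitting rate distributions to per-tip path-length rates.

    ``fits`` maps family name -> (params dict, lnL, BIC); ``best`` names
    the BIC-selected family.  For the lognormal, params are the mean and
    sd of log rate.
    """

    rates: np.ndarray
    fits: dict
    best: str

    @property
    def best_params(self) -> dict:
        return self.fits[self.best][0]

    def bic_table(self):
        import pandas as pd
        rows = [{"family": k, "lnL": v[1], "BIC": v[2], **v[0]}
                for k, v in self.fits.items()]
        return pd.DataFrame(rows).sort_values("BIC").reset_index(drop=True)


def derive_clock_rate_prior(path_lengths: dict[str, float],
                            tip_ages: dict[str, float],
                            root_age: float) -> ClockRatePriorFit:
    """Derive an empirical clock base-rate prior from a non-clock tree.

    Each tip's root-to-tip path length (expected substitutions/site) is
    scaled by the time elapsed (root age minus tip age: 0 for extant
    taxa, the age-window midpoint for fossils), giving per-tip rates in
    substitutions/site/Ma.  Normal, lognormal and gamma families are fit
    by maximum likelihood and ranked by BIC = k ln(n) - 2 lnL.
    """
    names = sorted(path_lengths)
    if len(names) < 3:
        raise TreeError("need at least 3 tips to fit a rate distribution")
    rates = []
    for name in names:
        t = root_age - tip_ages.get(name, 0.0)
        if t <= 0:
            raise TreeError(f"{name}: tip age >= root age")
        r = path_lengths[name] / t
        if r <= 0:
            raise TreeError(f"{name}: non-positive rate")
        rates.append(r)
    rates = np.asarray(rates)
    n = len(rates)
    log_n = math.log(n)

    fits = {}
    mu, sd = float(np.mean(rates)), float(np.std(rates))
    lnl = float(np.sum(stats.norm.logpdf(rates, mu, sd)))
    fits["normal"] = ({"mean": mu, "sd": sd}, lnl, 2 * log_n - 2 * lnl)

    lr = np.log(rates)
    lmu, lsd = float(np.mean(lr)), float(np.std(lr))
    lnl = float(np.sum(stats.lognorm.logpdf(rates, s=lsd,
                                            scale=math.exp(lmu))))
    fits["lognormal"] = ({"log_mean": lmu, "log_sd": lsd}, lnl,
                         2 * log_n - 2 * lnl)

    a, _, scale = stats.gamma.fit(rates, floc=0)
    lnl = float(np.sum(stats.gamma.logpdf(rates, a=a, scale=scale)))
    fits["gamma"] = ({"shape": float(a), "scale": float(scale)}, lnl,
                     2 * log_n - 2 * lnl)

    best = min(fits, key=lambda k: fits[k][2])
    logger.info("clock-rate prior: best family %s (BIC %.2f) on %d rates",
                best, fits[best][2], n)
    return ClockRatePriorFit(rates=rates, fits=fits, best=best)


def path_lengths_from_newick(newick: str) -> dict[str, float]:
    """Root-to-tip path lengths (substitution units) from a non-clock
    tree."""
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    out = {}
    for leaf in dtree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label.replace(" ", "_")] = d
    return out
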