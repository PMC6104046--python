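"""Substitution models and likelihoods on dated trees.

Morphological partitions use the Mk model (symmetric k-state CTMC),
optionally with an ordered (stepwise) rate matrix, discrete-gamma rate
heterogeneity and the variable-coding ascertainment correction that
conditions each character's likelihood on being variable.  Molecular
partitions use GTR with discrete-gamma rates and an optional invariant
class.  Likelihoods are computed by Felsenstein pruning with per-node
rescaling, vectorized over site patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import expm

from .characters import MISSING, INAPPLICABLE, MorphMatrix
from .treemodel import TimeTree


class LikelihoodError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Site models


@dataclass
class SiteModel:
    """Specification of one partition's substitution process.

    family: "mk" (set ``k`` and ``ordered``) or "gtr" (set
    ``exchangeabilities`` in AC,AG,AT,CG,CT,GT order and
    ``base_freqs``).  ``gamma_shape=None`` disables rate heterogeneity;
    ``n_categories`` discrete-gamma classes use category means.
    ``p_invariant`` adds an invariant-site class (GTR+I+G).
    ``ascertainment="variable"`` switches on variable coding.
    """

    family: str = "mk"
    k: int = 2
    ordered: bool = False
    exchangeabilities: np.ndarray | None = None
    base_freqs: np.ndarray | None = None
    gamma_shape: float | None = None
    n_categories: int = 4
    p_invariant: float = 0.0
    ascertainment: str = "none"

    def __post_init__(self):
        if self.family not in ("mk", "gtr"):
            raise LikelihoodError(f"unknown model family {self.family!r}")
        if self.family == "mk" and self.k < 2:
            raise LikelihoodError("Mk needs at least 2 states")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise LikelihoodError("gamma shape must be positive")
        if not (0 <= self.p_invariant < 1):
            raise LikelihoodError("p_invariant must lie in [0,1)")
        if self.family == "gtr":
            self.k = 4
            if self.exchangeabilities is None:
                self.exchangeabilities = np.ones(6)
            if self.base_freqs is None:
                self.base_freqs = np.full(4, 0.25)
            self.exchangeabilities = np.asarray(self.exchangeabilities,
                                                dtype=float)
            self.base_freqs = np.asarray(self.base_freqs, dtype=float)
            self.base_freqs = self.base_freqs / self.base_freqs.sum()

    @property
    def stationary_freqs(self) -> np.ndarray:
        if self.family == "gtr":
            return self.base_freqs
        return np.full(self.k, 1.0 / self.k)


def build_rate_matrix(model: SiteModel) -> np.ndarray:
    """Instantaneous rate matrix, normalized to one expected event per
    unit branch length at stationarity."""
    if model.family == "mk":
        k = model.k
        if model.ordered:
            Q = np.zeros((k, k))
            for i in range(k - 1):
                Q[i, i + 1] = Q[i + 1, i] = 1.0
        else:
            Q = np.ones((k, k))
            np.fill_diagonal(Q, 0.0)
        pi = np.full(k, 1.0 / k)
    else:
        r = model.exchangeabilities
        pi = model.base_freqs
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(r, pairs):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(Q)))
    if mean_rate <= 0:
        raise LikelihoodError("degenerate rate matrix")
    return Q / mean_rate


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1."""
    if not np.isfinite(t) or t < 0:
        raise LikelihoodError(f"invalid branch length {t}")
    if t == 0:
        return np.eye(Q.shape[0])
    return expm(Q * t)


class _Decomposed:
    """Eigendecomposition of a reversible Q for fast repeated P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2)
        self.w = w
        self.right = U / sqrt_pi[:, None] * 1.0
        self.left = (U * sqrt_pi[:, None]).T

    def probs(self, t: float) -> np.ndarray:
        P = (self.right * np.exp(self.w * t)) @ self.left
        np.clip(P, 0.0, 1.0, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def probs_many(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for a vector of times at once: (m, k, k)."""
        E = np.exp(np.outer(ts, self.w))              # (m, k)
        P = (self.right[None, :, :] * E[:, None, :]) @ self.left
        np.clip(P, 0.0, 1.0, out=P)
        return P / P.sum(axis=2, keepdims=True)


def discrete_gamma_rates(alpha: float, n: int = 4,
                         use_median: bool = False) -> np.ndarray:
    """Mean-one discrete-gamma rate multipliers (category means)."""
    return _discrete_gamma_rates_cached(float(alpha), int(n),
                                        bool(use_median)).copy()


from functools import lru_cache  # noqa: E402


@lru_cache(maxsize=512)
def _discrete_gamma_rates_cached(alpha, n, use_median):
    if alpha <= 0:
        raise LikelihoodError("gamma shape must be positive")
    if n < 1:
        raise LikelihoodError("need at least one category")
    if n == 1:
        return np.ones(1)
    if use_median:
        qs = (np.arange(n) + 0.5) / n
        rates = stats.gamma.ppf(qs, a=alpha, scale=1.0 / alpha)
        return rates / rates.mean()
    bounds = stats.gamma.ppf(np.arange(1, n) / n, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X | b_i < X < b_{i+1}] * n for mean-1 gamma: incomplete-gamma identity
    upper = stats.gamma.cdf(bounds[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = stats.gamma.cdf(bounds[:-1], a=alpha + 1, scale=1.0 / alpha)
    return n * (upper - lower)


# ---------------------------------------------------------------------------
# Pruning likelihood


@dataclass
class PartitionLikelihoodResult:
    """Per-site log-likelihoods, ascertainment corrections, and total."""

    site_log_likelihoods: np.ndarray
    correction: np.ndarray = None   # per-site log(1 - p_constant), <= 0
    weights: np.ndarray = None

    def __post_init__(self):
        n = len(self.site_log_likelihoods)
        if self.correction is None:
            self.correction = np.zeros(n)
        if self.weights is None:
            self.weights = np.ones(n)

    @property
    def total(self) -> float:
        return float(np.dot(self.weights,
                            self.site_log_likelihoods - self.correction))

    def to_tsv(self, path) -> None:
        """Diagnostic dump of per-character log-likelihoods."""
        import pandas as pd
        pd.DataFrame({
            "site": np.arange(len(self.site_log_likelihoods)),
            "log_likelihood": self.site_log_likelihoods,
            "ascertainment_correction": self.correction,
            "weight": self.weights,
        }).to_csv(path, sep="\t", index=False)


def _prune(tree: TimeTree, tip_partials: np.ndarray, P_by_node: dict,
           pi: np.ndarray):
    """One pruning pass; returns (root_partials, log_scale_per_pattern)."""
    n_pat = tip_partials.shape[1]
    partials = {}
    log_scale = np.zeros(n_pat)
    for node in tree.postorder():
        if node.is_leaf:
            partials[node] = tip_partials[node.index]
            continue
        prod = None
        for child in node.children:
            term = partials[child] @ P_by_node[child.index].T
            prod = term if prod is None else prod * term
        mx = prod.max(axis=1)
        mx[mx == 0] = 1.0
        log_scale += np.log(mx)
        partials[node] = prod / mx[:, None]
    root = partials[tree.root]
    return root, log_scale


def partition_log_likelihood(tree: TimeTree, tip_partials: np.ndarray,
                             model: SiteModel,
                             branch_lengths: np.ndarray,
                             weights: np.ndarray | None = None,
                             dec: "_Decomposed | None" = None
                             ) -> PartitionLikelihoodResult:
    """Pruning log-likelihood of one homogeneous data block.

    ``tip_partials`` has shape (n_tips, n_patterns, k): indicator (or
    partial ambiguity) vectors per tip and pattern; a missing cell is
    all ones.  ``branch_lengths`` gives the effective length (duration
    x rate) per node index.  Gamma categories and the invariant class
    are marginalized; with ``ascertainment="variable"`` each pattern's
    likelihood is divided by the probability of being variable.
    """
    k = model.k
    if tip_partials.shape[2] != k:
        raise LikelihoodError("tip partials do not match state count")
    n_pat = tip_partials.shape[1]
    missing_pattern = np.all(tip_partials == 1.0, axis=(0, 2))
    pi = model.stationary_freqs
    if dec is None:
        dec = _Decomposed(build_rate_matrix(model), pi)
    rates = (discrete_gamma_rates(model.gamma_shape, model.n_categories)
             if model.gamma_shape is not None else np.ones(1))

    bl = np.asarray(branch_lengths, dtype=float)
    n_cat = len(rates)
    # all (category, node) transition matrices in one shot; pruning is
    # batched over categories via stacked matmuls
    P_all = dec.probs_many(np.outer(rates, bl).ravel()).reshape(
        n_cat, len(bl), k, k)
    P_T = np.swapaxes(P_all, 2, 3)           # (cat, node, k, k) transposed
    partials = {}
    log_scale = np.zeros((n_cat, n_pat))
    for node in tree.postorder():
        if node.is_leaf:
            partials[node] = tip_partials[node.index]     # (pat, k)
            continue
        prod = None
        for child in node.children:
            term = partials[child] @ P_T[:, child.index]  # (cat, pat, k)
            prod = term if prod is None else prod * term
        mx = prod.max(axis=-1)
        mx[mx == 0] = 1.0
        log_scale += np.log(mx)
        partials[node] = prod / mx[..., None]
    root = partials[tree.root]
    if root.ndim == 2:                        # single-tip degenerate case
        root = np.broadcast_to(root, (n_cat, n_pat, k))
    rootpi = root @ pi                        # (cat, pat)
    log_offset = log_scale.max(axis=0)
    like = np.mean(rootpi * np.exp(log_scale - log_offset), axis=0)

    if model.p_invariant > 0:
        # invariant class: nonzero only for potentially constant patterns
        const_like = np.zeros(n_pat)
        for s in range(k):
            const_like += pi[s] * np.prod(tip_partials[:, :, s], axis=0)
        like = ((1 - model.p_invariant) * like
                + model.p_invariant * const_like * np.exp(-log_offset))

    with np.errstate(divide="ignore"):
        site_lnl = np.log(like) + log_offset

    correction = np.zeros(n_pat)
    if model.ascertainment == "variable":
        log_pc = constant_pattern_log_prob(tree, model, branch_lengths,
                                           dec=dec)
        one_minus = -np.expm1(log_pc)
        if one_minus <= 0:
            raise LikelihoodError(
                "variable-coding correction diverged: constant-pattern "
                f"probability {math.exp(log_pc):.6g} >= 1 (tree length "
                f"{float(np.sum(branch_lengths)):.3g})")
        correction[:] = math.log(one_minus)
    if np.any(missing_pattern):
        # an all-missing character carries no information: contributes 0
        site_lnl[missing_pattern] = 0.0
        correction[missing_pattern] = 0.0
    return PartitionLikelihoodResult(site_lnl, correction, weights)


def constant_pattern_log_prob(tree: TimeTree, model: SiteModel,
                              branch_lengths: np.ndarray,
                              dec: "_Decomposed | None" = None) -> float:
    """log sum over the k constant patterns of their probability
    (the ascertainment term of variable coding)."""
    k = model.k
    n_tips = tree.n_tips
    tip_partials = np.zeros((n_tips, k, k))
    for s in range(k):
        tip_partials[:, s, s] = 1.0
    sub = SiteModel(family=model.family, k=k, ordered=model.ordered,
                    exchangeabilities=model.exchangeabilities,
                    base_freqs=model.base_freqs,
                    gamma_shape=model.gamma_shape,
                    n_categories=model.n_categories,
                    p_invariant=model.p_invariant, ascertainment="none")
    res = partition_log_likelihood(tree, tip_partials, sub, branch_lengths,
                                   dec=dec)
    from scipy.special import logsumexp
    return float(logsumexp(res.site_log_likelihoods))


def variable_coding_correction(tree: TimeTree, model: SiteModel,
                               branch_lengths: np.ndarray) -> float:
    """Per-character log correction: log(1 - P(constant)).

    Subtracting this from a character's raw log-likelihood conditions
    it on being variable.  Raises when the correction argument is
    numerically non-positive (e.g. tree length approaching 0, where
    every pattern is constant).
    """
    log_pc = constant_pattern_log_prob(tree, model, branch_lengths)
    one_minus = -math.expm1(log_pc)
    if one_minus <= 0:
        raise LikelihoodError(
            "variable-coding correction diverged (all patterns constant); "
            f"log P(constant) = {log_pc:.6g}")
    return math.log(one_minus)


# ---------------------------------------------------------------------------
# Data-to-partials adapters


def morph_tip_partials(matrix: MorphMatrix, chars: np.ndarray,
                       tip_order: list[str], k: int) -> np.ndarray:
    """Indicator partials for a group of characters sharing state count
    ``k``, with tips in likelihood index order."""
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    out = np.zeros((len(tip_order), len(chars), k))
    for ti, name in enumerate(tip_order):
        if name not in row_of:
            out[ti] = 1.0
            continue
        row = matrix.cells[row_of[name]]
        for ci, j in enumerate(chars):
            cell = row[j]
            if cell in (MISSING, INAPPLICABLE):
                out[ti, ci] = 1.0
            else:
                for s in cell:
                    out[ti, ci, s] = 1.0
    return out


def morph_log_likelihood(tree: TimeTree, matrix: MorphMatrix,
                         branch_lengths: np.ndarray,
                         gamma_shape: float | None = None,
                         n_categories: int = 4,
                         ascertainment: str = "variable") -> float:
    """Log-likelihood of a whole morphological partition.

    Characters are grouped by (state count, ordering) since each group
    shares a rate matrix; the gamma shape is shared across the
    partition, matching a single-partition morphological model.
    """
    total = 0.0
    groups: dict[tuple[int, bool], list[int]] = {}
    for j in range(matrix.n_chars):
        key = (int(matrix.n_states[j]), bool(matrix.ordered[j]))
        groups.setdefault(key, []).append(j)
    for (k, ordered), chars in sorted(groups.items()):
        model = SiteModel(family="mk", k=k, ordered=ordered,
                          gamma_shape=gamma_shape,
                          n_categories=n_categories,
                          ascertainment=ascertainment)
        partials = morph_tip_partials(matrix, np.asarray(chars),
                                      tree.tip_names(), k)
        res = partition_log_likelihood(tree, partials, model, branch_lengths)
        total += res.total
    return total


def dna_tip_partials(sites: np.ndarray, taxa: list[str],
                     tip_order: list[str]):
    """Compressed site patterns -> (partials, weights)."""
    row_of = {t: i for i, t in enumerate(taxa)}
    n_sites = sites.shape[1]
    coded = np.full((len(tip_order), n_sites), 4, dtype=np.uint8)
    for ti, name in enumerate(tip_order):
        if name in row_of:
            coded[ti] = sites[row_of[name]]
    patterns, weights = np.unique(coded, axis=1, return_counts=True)
    n_pat = patterns.shape[1]
    out = np.zeros((len(tip_order), n_pat, 4))
    for s in range(4):
        out[:, :, s] = (patterns == s)
    out[patterns == 4] = 1.0
    return out, weights.astype(float)


def dna_log_likelihood(tree: TimeTree, sites: np.ndarray, taxa: list[str],
                       branch_lengths: np.ndarray,
                       model: SiteModel) -> float:
    partials, weights = dna_tip_partials(sites, taxa, tree.tip_names())
    res = partition_log_likelihood(tree, partials, model, branch_lengths,
                                   weights)
    return res.total
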