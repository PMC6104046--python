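"""Marginal ancestral-state reconstruction and biogeography.

Computes, for every internal node of a fixed dated tree (typically the
allcompat summary tree), the marginal posterior probability of each
character state under the same Mk machinery used for inference; calls
best states with the >10%-separation rule (single best state, or an
inclusively polymorphic set when runners-up are close); counts state
changes along branches; and treats the six biogeographic areas as one
unordered 6-state character, optionally integrating over a posterior
tree sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .characters import AREAS, MorphMatrix
from .models import SiteModel, _Decomposed, build_rate_matrix, \
    discrete_gamma_rates, morph_tip_partials, partition_log_likelihood
from .treemodel import TimeTree


class AsrError(ValueError):
    pass


def asr_marginal(tree: TimeTree, tip_partials: np.ndarray,
                 model: SiteModel, branch_lengths: np.ndarray) -> dict:
    """Marginal state probabilities at every internal node.

    ``tip_partials`` is (n_tips, n_chars, k) as in the likelihood;
    returns {node: (n_chars, k) array of probabilities summing to 1}.
    Characters with no data get uniform vectors.  Matches brute-force
    joint enumeration marginalized over the other nodes.
    """
    k = model.k
    pi = model.stationary_freqs
    Q = build_rate_matrix(model)
    dec = _Decomposed(Q, pi)
    rates = (discrete_gamma_rates(model.gamma_shape, model.n_categories)
             if model.gamma_shape is not None else np.ones(1))
    n_pat = tip_partials.shape[1]
    total = {n: np.zeros((n_pat, k)) for n in tree.postorder()
             if not n.is_leaf}
    for r in rates:
        P = {}
        for node in tree.postorder():
            if node.parent is not None:
                P[node] = dec.probs(branch_lengths[node.index] * r)
        # downward conditionals
        down = {}
        for node in tree.postorder():
            if node.is_leaf:
                down[node] = tip_partials[node.index]
                continue
            prod = np.ones((n_pat, k))
            for ch in node.children:
                prod = prod * (down[ch] @ P[ch].T)
            s = prod.sum(axis=1, keepdims=True)
            s[s == 0] = 1.0
            down[node] = prod / s
        # upward (outside) arrays
        up = {tree.root: np.tile(pi, (n_pat, 1))}
        for node in tree.preorder():
            if node.is_leaf:
                continue
            for ch in node.children:
                sib = np.ones((n_pat, k))
                for other in node.children:
                    if other is not ch:
                        sib = sib * (down[other] @ P[other].T)
                msg = up[node] * sib          # distribution over node state
                up[ch] = msg @ P[ch]
                s = up[ch].sum(axis=1, keepdims=True)
                s[s == 0] = 1.0
                up[ch] /= s
        for node in total:
            total[node] += down[node] * up[node]
    out = {}
    for node, arr in total.items():
        s = arr.sum(axis=1, keepdims=True)
        uniform = s[:, 0] == 0
        arr = arr / np.where(s == 0, 1.0, s)
        arr[uniform] = 1.0 / k
        out[node] = arr
    return out


@dataclass
class StateCall:
    """Best-state calls: per character a frozenset (singleton = single
    best state; larger = inclusively polymorphic)."""

    calls: list

    def __iter__(self):
        return iter(self.calls)

    def __getitem__(self, i):
        return self.calls[i]

    def __len__(self):
        return len(self.calls)


def call_best_states(probs: np.ndarray, margin: float = 0.10,
                     mode: str = "absolute") -> StateCall:
    """Apply the best-state calling rule to (n_chars, k) probabilities.

    "absolute" (default): the top state is called alone when it exceeds
    the runner-up by more than ``margin`` in absolute probability;
    otherwise the call is the inclusive set of states within ``margin``
    of the top.  "ratio": the runner-up disqualifies a single call when
    it exceeds ``margin`` x the top probability; the inclusive set then
    contains states above that fraction of the top.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    calls = []
    for p in probs:
        order = np.argsort(p)[::-1]
        top = p[order[0]]
        runner = p[order[1]] if len(p) > 1 else 0.0
        if mode == "absolute":
            single = (top - runner) > margin
            members = np.flatnonzero(p >= top - margin)
        elif mode == "ratio":
            single = runner <= margin * top
            members = np.flatnonzero(p > margin * top)
        else:
            raise AsrError(f"unknown calling mode {mode!r}")
        calls.append(frozenset([int(order[0])]) if single
                     else frozenset(int(i) for i in members))
    return StateCall(calls)


def count_branch_changes(parent_calls: StateCall, child_calls: StateCall,
                         characters=None) -> int:
    """Number of characters changing along a branch.

    A character counts one change event when the endpoint call sets are
    disjoint (a multi-step ordered jump is still one event); overlapping
    sets — including shared members of polymorphic calls — count zero.
    """
    idx = range(len(parent_calls)) if characters is None else characters
    changes = 0
    for j in idx:
        if not (parent_calls[j] & child_calls[j]):
            changes += 1
    return changes


def branch_change_count_steps(parent_calls, child_calls,
                              characters=None) -> int:
    """Alternative counting: minimum ordered step distance between the
    endpoint call sets, summed over characters."""
    idx = range(len(parent_calls)) if characters is None else characters
    steps = 0
    for j in idx:
        a, b = parent_calls[j], child_calls[j]
        if a & b:
            continue
        steps += min(abs(x - y) for x in a for y in b)
    return steps


def asr_morphology(tree: TimeTree, matrix: MorphMatrix,
                   branch_lengths: np.ndarray,
                   gamma_shape: float | None = None,
                   characters=None) -> dict:
    """ASR for (a subset of) a morphological matrix.

    Returns {node: {char_index: probability vector}} with nodes keyed by
    object; characters grouped by state count as in the likelihood.
    """
    chars = (np.arange(matrix.n_chars) if characters is None
             else np.asarray(list(characters)))
    groups: dict = {}
    for j in chars:
        key = (int(matrix.n_states[j]), bool(matrix.ordered[j]))
        groups.setdefault(key, []).append(int(j))
    out: dict = {}
    for (k, ordered), group in sorted(groups.items()):
        model = SiteModel(family="mk", k=k, ordered=ordered,
                          gamma_shape=gamma_shape)
        partials = morph_tip_partials(matrix, np.asarray(group),
                                      tree.tip_names(), k)
        node_probs = asr_marginal(tree, partials, model, branch_lengths)
        for node, arr in node_probs.items():
            out.setdefault(node, {})
            for row, j in enumerate(group):
                out[node][j] = arr[row]
    return out


def scored_characters(matrix: MorphMatrix, focal_taxa) -> np.ndarray:
    """Indices of characters scored (non-missing) for any focal taxon —
    the subset reconstructed along the focal branches."""
    from .characters import MISSING, INAPPLICABLE
    rows = [matrix.taxa.index(t) for t in focal_taxa]
    keep = []
    for j in range(matrix.n_chars):
        if any(matrix.cells[i][j] not in (MISSING, INAPPLICABLE)
               for i in rows):
            keep.append(j)
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# Biogeography


def area_tip_partials(tip_areas: dict, tip_order: list) -> np.ndarray:
    out = np.zeros((len(tip_order), 1, 6))
    for i, name in enumerate(tip_order):
        area = tip_areas.get(name)
        if area is None:
            out[i, 0, :] = 1.0
        elif area not in AREAS:
            raise AsrError(f"unknown area label {area!r}")
        else:
            out[i, 0, AREAS.index(area)] = 1.0
    return out


def _optimize_area_rate(tree, partials, branch_lengths):
    model = SiteModel(family="mk", k=6)

    def neg(log_rate):
        bl = branch_lengths * math.exp(log_rate)
        return -partition_log_likelihood(tree, partials, model, bl).total

    res = minimize_scalar(neg, bounds=(-12, 5), method="bounded")
    return math.exp(res.x)


def asr_biogeography(tree: TimeTree, tip_areas: dict,
                     rate: float | None = None) -> dict:
    """Marginal area probabilities at internal nodes under an unordered
    6-state Mk dispersal model on the dated tree.

    ``rate`` (dispersals/Ma) is maximum-likelihood optimized when not
    given.  Returns {clade frozenset: probability vector over AREAS}.
    """
    partials = area_tip_partials(tip_areas, tree.tip_names())
    durations = tree.durations()
    if rate is None:
        rate = _optimize_area_rate(tree, partials, durations)
    model = SiteModel(family="mk", k=6)
    node_probs = asr_marginal(tree, partials, model, durations * rate)
    return {tree.clade_names(node): arr[0]
            for node, arr in node_probs.items()}


def asr_biogeography_posterior(trees, tip_areas: dict,
                               rate: float | None = None) -> dict:
    """Biogeographic ASR integrated over a posterior tree sample.

    Per-clade area probabilities are averaged over the sampled trees
    that contain the clade."""
    sums: dict = {}
    counts: dict = {}
    for tree in trees:
        probs = asr_biogeography(tree, tip_areas, rate=rate)
        for clade, p in probs.items():
            sums[clade] = sums.get(clade, 0) + p
            counts[clade] = counts.get(clade, 0) + 1
    return {c: sums[c] / counts[c] for c in sums}


def areas_to_newick(tree: TimeTree, area_probs: dict) -> str:
    """Render a biogeographic reconstruction onto newick: internal
    nodes are labeled best-area=probability."""

    def fmt(node):
        if node.is_leaf:
            label = node.name
        else:
            label = "(" + ",".join(fmt(c) for c in node.children) + ")"
            clade = tree.clade_names(node)
            if clade in area_probs:
                p = area_probs[clade]
                best = int(np.argmax(p))
                area = AREAS[best].replace(" ", "_")
                label += f"'{area}={p[best]:.3f}'"
        if node.parent is not None:
            label += f":{node.parent.age - node.age:.6g}"
        return label

    return fmt(tree.root) + ";"


def asr_table(node_probs: dict, tree: TimeTree) -> pd.DataFrame:
    """Flatten {node: {char: probs}} to a tidy (node, char, state,
    probability) table keyed by clade size + smallest member."""
    rows = []
    for node, chars in node_probs.items():
        clade = tree.clade_names(node)
        label = f"{min(clade)}+{len(clade)}"
        for j, p in sorted(chars.items()):
            for s, prob in enumerate(p):
                rows.append({"node": label, "character": j, "state": s,
                             "probability": float(prob)})
    return pd.DataFrame(rows)
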