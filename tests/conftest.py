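import numpy as np
import pytest

from tipdating.treemodel import TimeTree


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def quartet_tree():
    """Asymmetric 4-taxon dated tree used by the brute-force oracles."""
    return TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def triplet_tree():
    return TimeTree.from_newick("((A:1,B:1):1,C:2);")


def brute_force_pattern_prob(tree, Q, branch_lengths, tip_states, pi=None):
    """Enumerate all internal-node state assignments (oracle for the
    pruning algorithm); tip_states maps tip name -> state index or a
    set of allowed states."""
    import itertools

    from scipy.linalg import expm

    k = Q.shape[0]
    if pi is None:
        pi = np.full(k, 1.0 / k)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    tips = {n.name: n for n in tree.tips}
    P = {n.index: expm(Q * branch_lengths[n.index]) for n in nodes
         if n.parent is not None}
    total = 0.0
    tip_sets = {name: ({s} if np.isscalar(s) else set(s))
                for name, s in tip_states.items()}
    for assign in itertools.product(range(k), repeat=len(internals)):
        tip_choices = [sorted(tip_sets[name]) for name in sorted(tips)]
        for leaf_assign in itertools.product(*tip_choices):
            st = {n: s for n, s in zip(internals, assign)}
            for name, s in zip(sorted(tips), leaf_assign):
                st[tips[name]] = s
            p = pi[st[tree.root]]
            for n in nodes:
                if n.parent is not None:
                    p *= P[n.index][st[n.parent], st[n]]
            total += p
    return total
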