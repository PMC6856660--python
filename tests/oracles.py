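"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) used by the package
implementation: UniFrac is computed edge by edge from explicit descendant
tip sets, and tree-topology nulls come from exhaustive enumeration of all
rooted binary labeled topologies.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def tree_edges(tree):
    """[(branch_length, frozenset of descendant tip names)] for every
    non-root node of a skbio TreeNode."""
    edges = []
    for node in tree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        edges.append((float(node.length), tips))
    return edges


def brute_unweighted_unifrac(set_a, set_b, tree):
    set_a, set_b = set(set_a), set(set_b)
    unique = shared = 0.0
    for length, tips in tree_edges(tree):
        in_a = bool(tips & set_a)
        in_b = bool(tips & set_b)
        if in_a and in_b:
            shared += length
        elif in_a or in_b:
            unique += length
    union = unique + shared
    return unique / union if union > 0 else 0.0


def brute_weighted_unifrac(counts_a, counts_b, tree, normalized=False):
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    num = den = 0.0
    for length, tips in tree_edges(tree):
        pa = sum(counts_a.get(t, 0) for t in tips) / tot_a
        pb = sum(counts_b.get(t, 0) for t in tips) / tot_b
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    if normalized:
        return num / den if den > 0 else 0.0
    return num


# ---- exhaustive rooted-topology enumeration ------------------------------

def _add_leaf_everywhere(tree, leaf):
    out = [(tree, leaf)]
    if isinstance(tree, tuple):
        left, right = tree
        out += [(nl, right) for nl in _add_leaf_everywhere(left, leaf)]
        out += [(left, nr) for nr in _add_leaf_everywhere(right, leaf)]
    return out


def all_rooted_topologies(labels):
    """Every rooted binary labeled topology over ``labels`` as nested tuples
    (1, 1, 3, 15, 105, ... trees for 1..5 labels)."""
    trees = [labels[0]]
    for leaf in labels[1:]:
        trees = [t2 for t in trees for t2 in _add_leaf_everywhere(t, leaf)]
    return trees


def topology_clades(tree):
    """Nontrivial clades (size >= 2, < n) of a nested-tuple topology."""
    clades = []

    def tips(t):
        if not isinstance(t, tuple):
            return frozenset([t])
        s = tips(t[0]) | tips(t[1])
        clades.append(s)
        return s

    all_tips = tips(tree)
    return {c for c in clades if 1 < len(c) < len(all_tips)}


def treenode_clades(tree):
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        c = frozenset(t.name for t in node.tips())
        if 1 < len(c) < len(all_tips):
            out.add(c)
    return out


def nrf_between_clade_sets(ca, cb):
    denom = len(ca) + len(cb)
    return len(ca ^ cb) / denom if denom else 0.0


def exact_nrf_null(reference_tree):
    """Exact distribution of nRF between every rooted topology and the
    reference, by exhaustive enumeration (practical for <= 6 tips)."""
    labels = sorted(t.name for t in reference_tree.tips())
    ref = treenode_clades(reference_tree)
    return np.array(
        [nrf_between_clade_sets(topology_clades(t), ref) for t in all_rooted_topologies(labels)]
    )


def exhaustive_two_group_anosim_p(dm_data, n_a):
    """Exact ANOSIM p over all equal-size two-group label assignments."""
    from scipy.stats import rankdata

    n = dm_data.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(dm_data[iu, ju])
    denom = len(ranks) / 2.0

    def r_of(group_a):
        in_a = np.zeros(n, bool)
        in_a[list(group_a)] = True
        within = in_a[iu] == in_a[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_of(range(n_a))
    stats = [r_of(c) for c in combinations(range(n), n_a)]
    return sum(1 for s in stats if s >= observed - 1e-12) / len(stats)


def exhaustive_t_test_p(x, y):
    """Exact two-sided permutation p for the pooled-variance t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = len(x)

    def t_of(idx_a):
        a = pooled[list(idx_a)]
        b = np.delete(pooled, list(idx_a))
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        if sp2 <= 0:
            return 0.0
        return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))

    observed = abs(t_of(range(nx)))
    stats = [abs(t_of(c)) for c in combinations(range(len(pooled)), nx)]
    return sum(1 for s in stats if s >= observed - 1e-12) / len(stats)
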