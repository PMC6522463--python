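"""Independent brute-force oracles for variation and tree operations.

Deliberately naive re-implementations used only to cross-check the
package: per-column set logic for alignment statistics, and split
enumeration by graph edge removal (networkx) for tree queries.  They share
no code path with the package beyond Newick parsing.
"""

from itertools import combinations

import networkx as nx

UNAMB = set("ACGT")


def oracle_column_classes(seqs):
    """Per column: (is_variable, is_informative, coverage)."""
    length = len(seqs[0])
    out = []
    for col in range(length):
        chars = [s[col] for s in seqs if s[col] in UNAMB]
        counts = {c: chars.count(c) for c in set(chars)}
        variable = len(counts) >= 2
        informative = sum(1 for v in counts.values() if v >= 2) >= 2
        out.append((variable, informative, len(chars)))
    return out


def oracle_pairwise(a, b):
    d = ov = 0
    for ca, cb in zip(a, b):
        if ca in UNAMB and cb in UNAMB:
            ov += 1
            if ca != cb:
                d += 1
    return d, ov


def oracle_synapomorphic_columns(g_seqs, h_seqs):
    """1-based columns where each group is uniform for different bases and
    every member covers (min_coverage_fraction = 1)."""
    cols = []
    for col in range(len(g_seqs[0])):
        g = [s[col] for s in g_seqs]
        h = [s[col] for s in h_seqs]
        if not all(c in UNAMB for c in g + h):
            continue
        if len(set(g)) == 1 and len(set(h)) == 1 and g[0] != h[0]:
            cols.append(col + 1)
    return cols


def oracle_group_stats(g_seqs, h_seqs):
    """(min, max, mean) of cross-pair distances; pairs with zero overlap
    excluded; None if no usable pair."""
    dists = []
    for a in g_seqs:
        for b in h_seqs:
            d, ov = oracle_pairwise(a, b)
            if ov:
                dists.append(d)
    if not dists:
        return None
    return min(dists), max(dists), sum(dists) / len(dists)


def tree_splits(gt):
    """All splits of a GeneTree as (frozenset side, support) via graph
    edge removal — independent of the package's traversal."""
    g = nx.Graph()
    supports = {}
    leaves = set()
    for node in gt.tree.preorder_node_iter():
        g.add_node(id(node))
        if node.is_leaf():
            leaves.add(node.taxon.label)
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node))
            supports[(id(node.parent_node), id(node))] = getattr(
                node, "support", None
            )
    label_of = {
        id(n): n.taxon.label
        for n in gt.tree.leaf_node_iter()
    }
    out = []
    for (u, v), sup in supports.items():
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, v)
        side = frozenset(label_of[n] for n in comp if n in label_of)
        out.append((side, sup, leaves - side))
    return out, leaves


def oracle_monophyletic(gt, G):
    """(is_monophyletic, support-of-isolating-split) under unrooted
    semantics; trivial whole-tree case is monophyletic with support None."""
    splits, leaves = tree_splits(gt)
    Gl = frozenset(G) & frozenset(leaves)
    if len(Gl) < 2:
        return "uninformative", None
    if Gl == leaves:
        return "monophyletic", None
    for side, sup, other in splits:
        if side == Gl or frozenset(other) == Gl:
            return "monophyletic", sup
    return "non_monophyletic", None


def oracle_contradicted(gt, G, tau):
    """Supported split incompatible with (G | rest): all four
    intersections non-empty."""
    splits, leaves = tree_splits(gt)
    Gl = frozenset(G) & frozenset(leaves)
    rest = leaves - Gl
    if len(Gl) < 2 or not rest:
        return False
    for side, sup, other in splits:
        if sup is None or sup < tau:
            continue
        if side & Gl and side & rest and (Gl - side) and (rest - side):
            return True
    return False
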