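"""Support-aware monophyly, exclusivity-contradiction and sister queries.

All queries use unrooted split semantics by default (Bayesian consensus
trees carry no meaningful root): a group is monophyletic iff some edge of
the tree induces the bipartition (group | rest).  Rooted refinements
(paraphyly vs polyphyly wording, sister extraction without an outgroup)
apply only when the tree is explicitly rooted or an outgroup is supplied.

A polytomy never certifies monophyly but never contradicts it either:
absence of resolution is absence of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy

from .datamodel import GeneTree, SisterUndefinedError, TreeFormatError

__all__ = [
    "MonophylyResult",
    "ContradictionResult",
    "DEFAULT_SUPPORT_THRESHOLD",
    "monophyly_status",
    "is_contradicted",
    "sister_group",
]

# Conventional posterior-probability cutoff for a clade to count as resolved.
DEFAULT_SUPPORT_THRESHOLD = 0.95


@dataclass
class MonophylyResult:
    """Outcome of a monophyly query for one group on one tree.

    ``support`` is the support of the minimal split isolating the group
    (``None`` for the trivial whole-tree split or when the tree carries no
    supports).
    """

    group: FrozenSet[str]
    tree: str  # locus name
    status: str  # monophyletic | non_monophyletic | paraphyletic | polyphyletic | uninformative
    support: Optional[float] = None

    def resolved(self, support_threshold: float = DEFAULT_SUPPORT_THRESHOLD) -> bool:
        """Monophyletic *and* supported (or supports absent on the tree)."""
        return self.status == "monophyletic" and (
            self.support is None or self.support >= support_threshold
        )


@dataclass
class ContradictionResult:
    """Whether any supported split is incompatible with the group's
    exclusivity, with the witnessing split(s)."""

    tree: str
    group: FrozenSet[str]
    contradicted: bool
    witness: Optional[Tuple[str, ...]] = None  # leaves of the witnessing clade
    witness_support: Optional[float] = None
    witnesses: List[Tuple[Tuple[str, ...], float]] = field(default_factory=list)


def _restricted_leaves(
    gt: GeneTree, restrict_to: Optional[Set[str]]
) -> Set[str]:
    leaves = set(gt.leaf_labels())
    if restrict_to is not None:
        leaves &= set(restrict_to)
    return leaves


def _splits(gt: GeneTree, leaves: Set[str]):
    """Yield (leafset_below & leaves, support, node) for every non-root node.

    Each tree edge induces one bipartition of the restricted leaf set;
    trivial (empty or full) restricted sides are still yielded and must be
    filtered by the caller.
    """
    below: Dict[int, Set[str]] = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            below[id(node)] = {lab} if lab in leaves else set()
        else:
            s: Set[str] = set()
            for ch in node.child_nodes():
                s |= below[id(ch)]
            below[id(node)] = s
        if node.parent_node is not None:
            yield below[id(node)], getattr(node, "support", None), node


def monophyly_status(
    gt: GeneTree,
    G: Set[str],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    restrict_to: Optional[Set[str]] = None,
) -> MonophylyResult:
    """Monophyly of ``G`` on one gene tree.

    ``restrict_to`` limits the query to a set of leaf labels (e.g. only
    specimens with candidate labels, ignoring published references).
    Returns ``uninformative`` when fewer than two members of ``G`` are in
    the tree; a group spanning every (restricted) leaf is monophyletic by
    the trivial split, with support absent.
    """
    if not gt.tree.leaf_nodes():
        raise TreeFormatError("empty tree")
    leaves = _restricted_leaves(gt, restrict_to)
    Gl = frozenset(set(G) & leaves)
    nonmembers = leaves - Gl
    if len(Gl) < 2:
        return MonophylyResult(Gl, gt.locus_name, "uninformative")
    if not nonmembers:
        return MonophylyResult(Gl, gt.locus_name, "monophyletic", None)

    if gt.rooted:
        return _rooted_status(gt, Gl, nonmembers, leaves)

    for side, support, _node in _splits(gt, leaves):
        if side == Gl or side == nonmembers:
            return MonophylyResult(Gl, gt.locus_name, "monophyletic", support)
    return MonophylyResult(Gl, gt.locus_name, "non_monophyletic")


def _rooted_status(
    gt: GeneTree, Gl: FrozenSet[str], nonmembers: Set[str], leaves: Set[str]
) -> MonophylyResult:
    """Rooted refinement: paraphyly vs polyphyly of a non-exclusive group.

    The minimal clade spanning ``Gl`` is located; if its intruding
    non-member leaves themselves form one clade the group is paraphyletic,
    otherwise polyphyletic.
    """
    gt.tree.is_rooted = True  # this branch only runs for rooted trees
    mrca = gt.tree.mrca(taxon_labels=sorted(Gl))
    clade = {
        lf.taxon.label
        for lf in mrca.leaf_iter()
        if lf.taxon.label in leaves
    }
    if clade == set(Gl):
        return MonophylyResult(
            Gl, gt.locus_name, "monophyletic", getattr(mrca, "support", None)
        )
    intruders = clade - Gl
    if len(intruders) == 1:
        return MonophylyResult(Gl, gt.locus_name, "paraphyletic")
    in_mrca = gt.tree.mrca(taxon_labels=sorted(intruders))
    in_clade = {
        lf.taxon.label
        for lf in in_mrca.leaf_iter()
        if lf.taxon.label in leaves
    }
    status = "paraphyletic" if in_clade == intruders else "polyphyletic"
    return MonophylyResult(Gl, gt.locus_name, status)


def is_contradicted(
    gt: GeneTree,
    G: Set[str],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    restrict_to: Optional[Set[str]] = None,
) -> ContradictionResult:
    """Whether a supported split is incompatible with ``G`` being exclusive.

    A split contradicts the group's genealogical exclusivity iff both of
    its sides contain members *and* non-members of ``G`` (standard split
    incompatibility with the bipartition G | rest).  Splits without
    support, or supported below ``support_threshold``, never contradict.
    """
    leaves = _restricted_leaves(gt, restrict_to)
    Gl = frozenset(set(G) & leaves)
    nonmembers = leaves - Gl
    result = ContradictionResult(gt.locus_name, Gl, contradicted=False)
    if len(Gl) < 2 or not nonmembers:
        return result
    for side, support, _node in _splits(gt, leaves):
        if support is None or support < support_threshold:
            continue
        g_in = side & Gl
        nm_in = side & nonmembers
        if g_in and nm_in and (Gl - g_in) and (nonmembers - nm_in):
            result.witnesses.append((tuple(sorted(side)), support))
    if result.witnesses:
        result.contradicted = True
        # strongest, then smallest, witness first for a stable report
        result.witnesses.sort(key=lambda w: (-w[1], len(w[0]), w[0]))
        result.witness, result.witness_support = result.witnesses[0]
    return result


def sister_group(
    gt: GeneTree,
    G: Set[str],
    outgroup: Optional[Set[str]] = None,
    restrict_to: Optional[Set[str]] = None,
) -> Set[str]:
    """Leaves of the clade adjacent to ``G``.

    The tree is rooted with ``outgroup`` when supplied, else taken as
    rooted as written.  Raises :class:`SisterUndefinedError` when ``G``
    does not form a clade; callers should then fall back to the nearest
    candidate by total SNP distance.
    """
    work = gt.clone()
    leaves = _restricted_leaves(work, restrict_to)
    Gl = set(G) & leaves
    if not Gl:
        raise SisterUndefinedError("group absent from tree")
    if outgroup:
        og = set(outgroup) & set(work.leaf_labels())
        if not og:
            raise SisterUndefinedError("outgroup absent from tree")
        if len(og) == 1:
            node = work.tree.find_node_with_taxon_label(next(iter(og)))
        else:
            node = work.tree.mrca(taxon_labels=sorted(og))
        work.tree.reroot_at_edge(node.edge, update_bipartitions=False)
    work.tree.is_rooted = True  # rooted as written / by the outgroup
    mrca = work.tree.mrca(taxon_labels=sorted(Gl))
    clade = {
        lf.taxon.label for lf in mrca.leaf_iter() if lf.taxon.label in leaves
    }
    if clade != Gl:
        raise SisterUndefinedError(
            f"group is not monophyletic on tree {gt.locus_name!r}; "
            "use nearest-neighbour fallback (min group distance)"
        )
    parent = mrca.parent_node
    if parent is None:
        raise SisterUndefinedError("group spans the whole tree")
    sister: Set[str] = set()
    for ch in parent.child_nodes():
        if ch is mrca:
            continue
        sister |= {
            lf.taxon.label for lf in ch.leaf_iter() if lf.taxon.label in leaves
        }
    if not sister:
        raise SisterUndefinedError("no sister leaves on the non-group side")
    return sister
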