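"""Gene-tree model and the clade/support primitives behind orthology calls.

A :class:`GeneTree` wraps a DendroPy tree and carries a support scale:
maximum-likelihood bootstrap percentages on [0, 100] or Bayesian posterior
probabilities on [0, 1]. All classification thresholds operate on the
bootstrap-percent scale, so posterior supports are normalized (x100) before
use. Supports conceptually live on edges (bipartitions); in Newick they are
attached to the child-side internal node, the common convention, and
rerooting re-attaches each support to the node subtending the same
bipartition — rooting never changes a bipartition's support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "GeneTree",
    "CladeResult",
    "read_newick",
    "write_newick",
    "normalize_support",
    "root_at_outgroup",
    "first_reference_ancestor",
    "is_monophyletic",
]

BOOTSTRAP_PERCENT = "bootstrap_percent"
POSTERIOR_UNIT = "posterior_unit"

_SCALE_RANGE = {BOOTSTRAP_PERCENT: 100.0, POSTERIOR_UNIT: 1.0}


class GeneTree:
    """A gene tree with leaf labels, branch lengths and node supports."""

    def __init__(self, tree: dendropy.Tree, support_scale: str = BOOTSTRAP_PERCENT):
        if support_scale not in _SCALE_RANGE:
            raise ValueError(f"unknown support scale: {support_scale!r}")
        self.tree = tree
        self.support_scale = support_scale
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {', '.join(dupes)}")

    # -- basic accessors -------------------------------------------------
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def find_leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise KeyError(f"leaf {label!r} not in tree")

    def __contains__(self, label: str) -> bool:
        return label in self.leaf_set()

    def copy(self) -> "GeneTree":
        return read_newick(write_newick(self), support_scale=self.support_scale)

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """All-pairs leaf-to-leaf path lengths (missing lengths count 0)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        out: dict[tuple[str, str], float] = {}
        taxa = [lf.taxon for lf in self.tree.leaf_node_iter()]
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1:]:
                d = pdm.patristic_distance(t1, t2)
                out[(t1.label, t2.label)] = d
                out[(t2.label, t1.label)] = d
        return out


@dataclass(frozen=True)
class CladeResult:
    """The clade returned by the first-reference-ancestor walk."""

    leaves: frozenset[str]
    subfamilies_present: frozenset[str]
    support: float | None

    @property
    def effective_support(self) -> float:
        """Absent support compares as 0 against any threshold."""
        return 0.0 if self.support is None else self.support


def _clade_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def read_newick(text: str, support_scale: str = BOOTSTRAP_PERCENT) -> GeneTree:
    """Parse single-tree Newick; numeric internal labels become supports."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"Newick parse error: {exc}") from exc
    for node in tree.preorder_node_iter():
        node.support = None
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
                node.label = None
            except ValueError:
                pass  # non-numeric internal label: keep as a plain label
    return GeneTree(tree, support_scale=support_scale)


def _fmt_length(x: float) -> str:
    return f"{x:.6g}"


def _fmt_support(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


def _node_newick(node: dendropy.Node) -> str:
    if node.is_leaf():
        out = node.taxon.label
    else:
        inner = ",".join(_node_newick(c) for c in node.child_nodes())
        label = ""
        if getattr(node, "support", None) is not None:
            label = _fmt_support(node.support)
        elif node.label:
            label = node.label
        out = f"({inner}){label}"
    if node.edge.length is not None:
        out += f":{_fmt_length(node.edge.length)}"
    return out


def write_newick(tree: GeneTree) -> str:
    """Serialize with supports as internal labels, 6-sig-digit lengths."""
    return _node_newick(tree.tree.seed_node) + ";"


def normalize_support(tree: GeneTree) -> GeneTree:
    """Return a copy with all supports on the bootstrap-percent scale."""
    limit = _SCALE_RANGE[tree.support_scale]
    out = tree.copy()
    factor = 100.0 / limit
    for node in out.tree.preorder_node_iter():
        s = getattr(node, "support", None)
        if s is None:
            continue
        if not (0.0 <= s <= limit):
            raise ValueError(
                f"support {s} outside [0, {limit}] for scale {tree.support_scale}"
            )
        node.support = s * factor
    out.support_scale = BOOTSTRAP_PERCENT
    return out


def _bipartition_key(
    side: frozenset[str], all_leaves: frozenset[str]
) -> tuple[str, ...]:
    comp = all_leaves - side
    return min(tuple(sorted(side)), tuple(sorted(comp)))


def root_at_outgroup(tree: GeneTree, outgroup_labels: Iterable[str]) -> GeneTree:
    """Root on the edge separating the outgroup from the rest.

    When the outgroup is not monophyletic in the unrooted tree, the root is
    placed on the edge maximizing the number of outgroup labels on the
    outgroup side (ties: smallest clade), with a warning. Supports are
    re-attached by bipartition, so rooting never changes the support
    associated with a split.
    """
    out = tree.copy()
    dt = out.tree
    all_leaves = out.leaf_set()
    og = frozenset(outgroup_labels) & all_leaves
    if not og:
        raise ValueError("no outgroup label present in tree")
    if og == all_leaves:
        raise ValueError("outgroup covers every leaf; rooting undefined")

    support_map: dict[tuple[str, ...], float] = {}
    for node in dt.preorder_node_iter():
        s = getattr(node, "support", None)
        if node is dt.seed_node or node.is_leaf() or s is None:
            continue
        support_map[_bipartition_key(_clade_leafset(node), all_leaves)] = s

    # Choose the rooting edge: examine both sides of every edge.
    best: tuple[int, int, tuple[str, ...]] | None = None
    best_node: dendropy.Node | None = None
    best_side: frozenset[str] | None = None
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        under = _clade_leafset(node)
        for side in (under, all_leaves - under):
            n_og = len(side & og)
            if n_og == 0 or not side:
                continue
            cand = (-n_og, len(side), tuple(sorted(side)))
            if best is None or cand < best:
                best = cand
                best_node = node
                best_side = side
    assert best_node is not None and best_side is not None
    if best_side != og:
        warnings.warn(
            "outgroup is not monophyletic; rooting at the edge with the most "
            "outgroup leaves on one side",
            stacklevel=2,
        )

    edge = best_node.edge
    if edge.length is not None:
        dt.reroot_at_edge(edge, length1=edge.length / 2.0, length2=edge.length / 2.0)
    else:
        dt.reroot_at_edge(edge)
    dt.seed_node.support = None
    dt.suppress_unifurcations()

    for node in dt.preorder_node_iter():
        if node is dt.seed_node or node.is_leaf():
            continue
        key = _bipartition_key(_clade_leafset(node), all_leaves)
        node.support = support_map.get(key)
    return out


def first_reference_ancestor(
    tree: GeneTree, query: str, reference_map: Mapping[str, str]
) -> CladeResult:
    """Walk from a query leaf toward the root to the first clade holding a
    reference leaf; report that clade's reference subfamilies and support.
    """
    leaf = tree.find_leaf(query)
    refs_in_tree = set(reference_map) & tree.leaf_set()
    if not refs_in_tree - {query}:
        raise ValueError("no reference leaf present in tree")
    node = leaf.parent_node
    while node is not None:
        clade = _clade_leafset(node)
        refs_here = (clade & refs_in_tree) - {query}
        if refs_here:
            return CladeResult(
                leaves=clade,
                subfamilies_present=frozenset(reference_map[r] for r in refs_here),
                support=getattr(node, "support", None),
            )
        node = node.parent_node
    raise AssertionError("unreachable: root contains all reference leaves")


def is_monophyletic(
    tree: GeneTree, leafset: Iterable[str]
) -> tuple[bool, float | None]:
    """Test whether a leaf set forms a clade (either side of a bipartition).

    Returns the supporting edge's value; singletons are trivially
    monophyletic with absent support.
    """
    target = frozenset(leafset)
    if not target:
        raise ValueError("empty leafset")
    all_leaves = tree.leaf_set()
    missing = target - all_leaves
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    if len(target) == 1:
        return True, None
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = _clade_leafset(node)
        if clade == target or (all_leaves - clade) == target:
            return True, getattr(node, "support", None)
    return False, None
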