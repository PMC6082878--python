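"""Newick tree I/O (dendropy-backed) and bipartition algebra.

Bipartitions (unrooted splits) are the currency of all support, conflict and
recovery analyses: each internal edge of a tree partitions the taxon set in
two, and agreement between trees is measured on these splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .errors import BipartitionDomainError, TooFewTaxaError


def read_newick(source: str, rooted: bool = False) -> dendropy.Tree:
    """Parse one Newick tree from a file path or a literal Newick string.

    Numeric internal-node labels are the usual support-value convention and
    are preserved as node labels, never as taxa.
    """
    data = source if source.strip().startswith("(") else open(source).read()
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        rooting="force-rooted" if rooted else "default-unrooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s.strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


@dataclass(frozen=True)
class Bipartition:
    """A canonical two-way split of a taxon set.

    The stored ``split`` is the side *not* containing the reference taxon
    (by default the lexicographically smallest label), which makes
    canonicalization idempotent and hashing orientation-free.
    """

    split: frozenset[str]
    complement: frozenset[str]

    @classmethod
    def of(cls, side_a, side_b, reference: str | None = None) -> "Bipartition":
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise BipartitionDomainError("both sides must be nonempty")
        if a & b:
            raise BipartitionDomainError(f"sides overlap: {sorted(a & b)}")
        ref = reference if reference is not None else min(a | b)
        if ref in a:
            a, b = b, a
        return cls(a, b)

    @property
    def taxa(self) -> frozenset[str]:
        return self.split | self.complement

    def sides(self) -> tuple[frozenset[str], frozenset[str]]:
        return self.split, self.complement

    def is_trivial(self) -> bool:
        return min(len(self.split), len(self.complement)) < 2

    def restrict(self, taxa) -> "Bipartition | None":
        """Induced split on a taxon subset; None if it degenerates to trivial."""
        t = frozenset(taxa)
        a, b = self.split & t, self.complement & t
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition.of(a, b)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            ",".join(sorted(self.split)) + " | " + ",".join(sorted(self.complement))
        )


def bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """All nontrivial unrooted splits induced by the tree's internal edges.

    For a rooted tree the root edge contributes no extra split (the two basal
    edges induce the same split and are deduplicated by the set).
    """
    leaves = leaf_labels(tree)
    if len(leaves) < 4:
        raise TooFewTaxaError(f"need >= 4 leaves, got {len(leaves)}")
    full = frozenset(leaves)
    out: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        above = full - below
        if len(below) >= 2 and len(above) >= 2:
            out.add(Bipartition.of(below, above))
    return out


def tree_splits_cached(tree: dendropy.Tree) -> set[Bipartition]:
    """bipartitions() memoized on the tree object (used in hot jackknife loops)."""
    cached = getattr(tree, "_hs_splits", None)
    if cached is None:
        cached = bipartitions(tree)
        tree._hs_splits = cached
    return cached


def are_compatible(b1: Bipartition, b2: Bipartition) -> bool:
    """True iff some tree on the common taxon set displays both splits.

    Splits on different taxon sets are first restricted to the intersection;
    disjoint taxon sets are a domain error. Two splits are compatible iff at
    least one of the four pairwise side intersections is empty.
    """
    t1, t2 = b1.taxa, b2.taxa
    if t1 != t2:
        common = t1 & t2
        if not common:
            raise BipartitionDomainError("bipartitions on disjoint taxon sets")
        r1, r2 = b1.restrict(common), b2.restrict(common)
        if r1 is None or r2 is None:
            return True  # a trivial restriction conflicts with nothing
        b1, b2 = r1, r2
    a1, c1 = b1.sides()
    a2, c2 = b2.sides()
    return not (a1 & a2) or not (a1 & c2) or not (c1 & a2) or not (c1 & c2)


def tree_from_splits(
    splits, taxa, edge_length: float | None = None
) -> dendropy.Tree:
    """Build a tree displaying a pairwise-compatible split collection.

    Roots at the reference taxon side: each split's ``split`` side (the side
    without the smallest label) is treated as a clade; compatibility makes
    these clades a laminar family, assembled largest-first.
    """
    taxa = sorted(set(taxa))
    ref = taxa[0] if taxa else None
    clades = sorted(
        {frozenset(s.split if ref not in s.split else s.complement) for s in splits},
        key=lambda c: (-len(c), tuple(sorted(c))),
    )
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    root_children: dict = {"_members": set(taxa), "_kids": []}

    def insert(node: dict, clade: frozenset) -> None:
        for kid in node["_kids"]:
            if clade <= kid["_members"]:
                insert(kid, clade)
                return
        node["_kids"].append({"_members": set(clade), "_kids": []})

    for clade in clades:
        insert(root_children, clade)

    def build(spec: dict, parent) -> None:
        covered: set[str] = set()
        for kid in spec["_kids"]:
            node = parent.new_child(edge_length=edge_length)
            build(kid, node)
            covered |= kid["_members"]
        for label in sorted(spec["_members"] - covered):
            leaf = parent.new_child(edge_length=edge_length)
            leaf.taxon = ns.get_taxon(label)

    build(root_children, tree.seed_node)
    tree.is_rooted = False
    return tree
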