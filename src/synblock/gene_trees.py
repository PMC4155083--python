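"""Reconciled gene forests: NHX parsing and pruning at the ancestor.

Gene families are defined phylogenetically: two extant genes are in the same
family if and only if they descend from the same gene of the last common
ancestor LCA(S_a, S_b) of the two compared species.  Given a reconciled gene
forest (rooted binary trees whose nodes carry a species label ``S=`` and a
duplication flag ``D=Y|N`` in NHX comments, TreeBest-style) and a species
tree, each gene tree is cut at the nodes that represent genes of the LCA:

* a speciation node whose species is the LCA roots one family;
* a duplication node whose species is the LCA represents a duplication
  *inside* the LCA genome, so each child roots its own family;
* leaves whose root path never passes through an LCA node are lineage
  specific (born after the LCA) and belong to no family.

Tree consumption only: reconciliation itself is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

from .core_model import FamilySet, ValidationError

__all__ = [
    "SpeciesTree",
    "GeneTreeNode",
    "parse_species_tree",
    "species_lca",
    "parse_gene_forest",
    "prune_forest_to_families",
]


class GeneForestParseError(ValueError):
    """Raised on malformed newick/NHX input."""


@dataclass
class GeneTreeNode:
    """Node of a reconciled gene tree (binary internal nodes, named leaves)."""

    species: str
    event: str  # "speciation" | "duplication" | "leaf"
    gene_name: str | None = None
    children: list["GeneTreeNode"] = field(default_factory=list)

    def leaves(self) -> list["GeneTreeNode"]:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


class SpeciesTree:
    """A rooted species tree with unique node labels (leaves and internals)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._by_label: dict[str, dendropy.Node] = {}
        for node in tree:
            label = node.taxon.label if node.taxon else node.label
            if label is None:
                continue
            if label in self._by_label:
                raise ValidationError(f"duplicate species label {label!r}")
            self._by_label[label] = node

    def node(self, species: str) -> dendropy.Node:
        try:
            return self._by_label[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in species tree") from None

    def lca(self, a: str, b: str) -> str:
        """Label of the deepest node ancestral to (or equal to) both."""
        na, nb = self.node(a), self.node(b)
        ancestors_a = []
        n = na
        while n is not None:
            ancestors_a.append(n)
            n = n.parent_node
        seen = set(id(x) for x in ancestors_a)
        n = nb
        while n is not None:
            if id(n) in seen:
                label = n.taxon.label if n.taxon else n.label
                return label
            n = n.parent_node
        raise ValidationError("species tree has no common root")  # pragma: no cover

    def is_ancestor_or_self(self, anc: str, desc: str) -> bool:
        """True if the node labelled ``anc`` lies on the root path of ``desc``."""
        target = self.node(anc)
        n = self.node(desc)
        while n is not None:
            if n is target:
                return True
            n = n.parent_node
        return False


def parse_species_tree(source) -> SpeciesTree:
    """Parse a newick species tree with labelled internal nodes.

    ``source`` is a path or a newick string.
    """
    data = _read_source(source)
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return SpeciesTree(tree)


def species_lca(tree: SpeciesTree, a: str, b: str) -> str:
    """Last common ancestor species of ``a`` and ``b``; lca(x, x) == x."""
    return tree.lca(a, b)


def _read_source(source) -> str:
    s = str(source)
    if "(" in s and ";" in s:
        return s
    with open(source, "r", encoding="utf-8") as fh:
        return fh.read()


_NHX_RE = re.compile(r"&&NHX:?(.*)", re.S)


def _nhx_tags(node: dendropy.Node) -> dict[str, str]:
    # dendropy interprets [&&NHX:k=v:...] comments as node annotations;
    # raw comments are kept as a fallback for dialects it leaves alone
    tags: dict[str, str] = {
        str(k): str(v) for k, v in node.annotations.values_as_dict().items()
    }
    for comment in node.comments:
        m = _NHX_RE.match(comment)
        if not m:
            continue
        for item in m.group(1).split(":"):
            if "=" in item:
                k, v = item.split("=", 1)
                tags[k] = v
    return tags


def _convert(node: dendropy.Node) -> GeneTreeNode:
    tags = _nhx_tags(node)
    children = node.child_nodes()
    # unwrap unary wrapper nodes (outer parentheses around the root);
    # inner NHX tags take precedence over the wrapper's
    while len(children) == 1:
        node = children[0]
        tags = {**tags, **_nhx_tags(node)}
        children = node.child_nodes()
    if not children:
        name = node.taxon.label if node.taxon else node.label
        if name is None:
            raise GeneForestParseError("leaf without a gene name")
        if "S" not in tags:
            raise GeneForestParseError(f"leaf {name!r} lacks an NHX S= tag")
        return GeneTreeNode(species=tags["S"], event="leaf", gene_name=name)
    if len(children) != 2:
        raise GeneForestParseError(
            f"non-binary internal node with {len(children)} children"
        )
    if "S" not in tags:
        raise GeneForestParseError("internal node lacks an NHX S= tag")
    event = "duplication" if tags.get("D") == "Y" else "speciation"
    return GeneTreeNode(
        species=tags["S"],
        event=event,
        children=[_convert(ch) for ch in children],
    )


def parse_gene_forest(source) -> list[GeneTreeNode]:
    """Parse an NHX newick forest (one tree per line or ';'-separated)."""
    data = _read_source(source)
    try:
        trees = dendropy.TreeList.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise GeneForestParseError(f"malformed newick forest: {exc}") from exc
    return [_convert(t.seed_node) for t in trees]


def prune_forest_to_families(
    forest: list[GeneTreeNode],
    species_tree: SpeciesTree,
    species_a: str,
    species_b: str,
    ancestor: str | None = None,
) -> FamilySet:
    """Cut each gene tree at the LCA to derive families.

    ``ancestor`` optionally names a species above the LCA at which to prune
    instead (more paralogy is then folded into each family).  Ancestral gene
    names are deterministic: ``fam<treeIndex>.<rootPath>`` where the root
    path is 'r' followed by the child indices leading to the family root.
    """
    lca = ancestor if ancestor is not None else species_tree.lca(
        species_a, species_b
    )
    if ancestor is not None and not species_tree.is_ancestor_or_self(
        ancestor, species_tree.lca(species_a, species_b)
    ):
        raise ValidationError(
            f"ancestor {ancestor!r} does not precede "
            f"LCA({species_a!r}, {species_b!r})"
        )
    keep = {species_a, species_b}
    families: dict[str, set[str]] = {}

    def emit(root: GeneTreeNode, name: str) -> None:
        members = {
            lf.gene_name
            for lf in root.leaves()
            if lf.species in keep and lf.gene_name
        }
        if members:
            families[name] = members

    def at_lca(node: GeneTreeNode, path: str, tree_idx: int) -> None:
        # A duplication in the LCA genome: each child is a distinct
        # ancestral gene; chained LCA duplications keep splitting.
        if node.event == "duplication" and node.species == lca:
            for i, ch in enumerate(node.children):
                at_lca(ch, f"{path}{i}", tree_idx)
        else:
            emit(node, f"fam{tree_idx}.{path}")

    def descend(node: GeneTreeNode, path: str, tree_idx: int) -> None:
        if node.species == lca:
            at_lca(node, path, tree_idx)
        elif node.species != lca and _strictly_above(
            species_tree, node.species, lca
        ):
            for i, ch in enumerate(node.children):
                descend(ch, f"{path}{i}", tree_idx)
        # else: the lineage skipped the LCA -> lineage-specific, no family

    for ti, tree in enumerate(forest):
        descend(tree, "r", ti)
    return FamilySet(families)


def _strictly_above(tree: SpeciesTree, species: str, lca: str) -> bool:
    try:
        return species != lca and tree.is_ancestor_or_self(species, lca)
    except KeyError:
        return False
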