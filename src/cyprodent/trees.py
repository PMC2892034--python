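"""Rooted-phylogeny I/O and validation, built on dendropy.

Trees are handled as rooted ``dendropy.Tree`` objects throughout the
package.  Tip labels are canonicalised to space-separated binomials so they
match the character table (standard Newick writes spaces as underscores).
Branch lengths may be unassigned: the packaged consensus topology ships
without lengths, and :func:`assign_branch_lengths` installs either unit
lengths or Grafen-style heights before any likelihood computation.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from dendropy.utility import error

__all__ = [
    "parse_newick",
    "read_newick",
    "write_newick",
    "assign_branch_lengths",
    "validate_monophyly",
    "prune_to_taxa",
    "tip_labels",
    "mrca_node",
    "node_signature",
    "packaged_tree_path",
    "packaged_clade_map",
    "load_fig5_tree",
    "load_clade_map",
    "CladeReport",
    "MonophylyError",
]


class MonophylyError(ValueError):
    """Raised when a clade map references taxa absent from the tree."""


def _canon(label: str) -> str:
    return label.replace("_", " ").strip()


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Polytomies and missing branch lengths are preserved; internal labels are
    kept.  Raises ``ValueError`` on malformed input or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=False,
            suppress_internal_node_taxa=True,
        )
    except error.DataParseError as exc:  # carries line/column position
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree from a file."""
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to Newick, preserving labels and assigned lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Canonical (space-separated) tip labels in tree order."""
    return [_canon(lf.taxon.label) for lf in tree.leaf_node_iter()]


def assign_branch_lengths(tree: dendropy.Tree, method: str = "unit") -> dendropy.Tree:
    """Install branch lengths on a topology in place (and return it).

    ``unit`` sets every branch to length 1.  ``grafen`` sets each node's
    height proportional to its clade size minus one, normalised so every
    root-to-tip path has length 1; the resulting tree is ultrametric.
    """
    if method == "unit":
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                edge.length = 1.0
        tree.seed_node.edge.length = None
        return tree
    if method == "grafen":
        sizes: dict[dendropy.Node, int] = {}
        for node in tree.postorder_node_iter():
            sizes[node] = 1 if node.is_leaf() else sum(sizes[c] for c in node.child_nodes())
        root_size = sizes[tree.seed_node]
        if root_size < 2:
            raise ValueError("grafen heights need at least two tips")
        denom = root_size - 1
        heights = {
            node: (0.0 if node.is_leaf() else (sizes[node] - 1) / denom)
            for node in tree.postorder_node_iter()
        }
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                node.edge.length = None
                continue
            node.edge.length = heights[node.parent_node] - heights[node]
        return tree
    raise ValueError(f"unknown branch-length method {method!r}; expected 'unit' or 'grafen'")


@dataclass
class CladeReport:
    """Monophyly verdicts per clade: clade -> (is_monophyletic, intruders)."""

    verdicts: dict[str, tuple[bool, set[str]]]

    @property
    def all_monophyletic(self) -> bool:
        return all(ok for ok, _ in self.verdicts.values())


def mrca_node(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor node of a set of tip labels."""
    wanted = {_canon(t) for t in taxa}
    leaves = [
        lf for lf in tree.leaf_node_iter() if _canon(lf.taxon.label) in wanted
    ]
    found = {_canon(lf.taxon.label) for lf in leaves}
    if found != wanted:
        raise MonophylyError(f"taxa not on tree: {sorted(wanted - found)}")
    if len(leaves) == 1:
        return leaves[0]
    node = tree.mrca(taxa=[lf.taxon for lf in leaves])
    if node is None:  # dendropy returns None only on pathological input
        raise MonophylyError(f"no common ancestor found for {sorted(wanted)}")
    return node


def validate_monophyly(
    tree: dendropy.Tree, clades: Mapping[str, Iterable[str]]
) -> CladeReport:
    """Check each named clade for monophyly on a rooted tree.

    A clade is monophyletic when the MRCA of its members subtends exactly
    those tips; otherwise the extra tips are reported as intruders.
    Raises :class:`MonophylyError` if a clade member is absent from the tree.
    """
    verdicts: dict[str, tuple[bool, set[str]]] = {}
    for name, members in clades.items():
        wanted = {_canon(t) for t in members}
        node = mrca_node(tree, wanted)
        subtended = {_canon(lf.taxon.label) for lf in node.leaf_iter()}
        intruders = subtended - wanted
        verdicts[name] = (not intruders, intruders)
    return CladeReport(verdicts=verdicts)


def prune_to_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Return a copy restricted to ``keep`` tips.

    Unary internal nodes produced by pruning are suppressed with their
    branch lengths summed, so patristic distances among kept tips are
    conserved.
    """
    wanted = {_canon(t) for t in keep}
    if not wanted:
        raise ValueError("refusing to prune to an empty taxon set")
    present = {_canon(lf.taxon.label) for lf in tree.leaf_node_iter()}
    absent = wanted - present
    if absent:
        raise ValueError(f"taxa not on tree: {sorted(absent)}")
    pruned = tree.clone(depth=1)
    keep_taxa = [
        lf.taxon
        for lf in pruned.leaf_node_iter()
        if _canon(lf.taxon.label) in wanted
    ]
    pruned.retain_taxa(keep_taxa)
    pruned.purge_taxon_namespace()
    return pruned


def node_signature(node: dendropy.Node) -> str:
    """Stable node address: '|'-joined sorted labels of subtended tips.

    Immune to child-order differences between otherwise identical trees.
    """
    return "|".join(sorted(_canon(lf.taxon.label) for lf in node.leaf_iter()))


def packaged_tree_path() -> Path:
    """Path of the packaged 46-tip consensus-topology fixture."""
    return Path(str(resources.files("cyprodent").joinpath("data", "fig5.nwk")))


def load_fig5_tree(branch_lengths: str | None = None) -> dendropy.Tree:
    """Load the packaged Cypriniformes consensus topology.

    ``branch_lengths`` may name an assignment method ('unit' or 'grafen');
    by default the topology is returned with lengths unassigned.
    """
    tree = read_newick(packaged_tree_path())
    if branch_lengths is not None:
        assign_branch_lengths(tree, branch_lengths)
    return tree


def packaged_clade_map() -> Path:
    return Path(str(resources.files("cyprodent").joinpath("data", "clades.tsv")))


def load_clade_map(path: str | Path | None = None) -> dict[str, set[str]]:
    """Read a clade->taxa TSV (columns: clade, taxon) into a mapping."""
    import csv

    if path is None:
        path = packaged_clade_map()
    clades: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            clades.setdefault(row["clade"], set()).add(row["taxon"])
    return clades
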