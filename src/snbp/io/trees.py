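"""Newick parsing via dendropy, with token-level error reporting."""

from __future__ import annotations

from pathlib import Path

import dendropy

from snbp.errors import TreeParseError


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree.

    Leaf labels are preserved verbatim (no underscore munging).
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed newick: {exc}") from exc
    if len(tree.leaf_nodes()) == 0:
        raise TreeParseError("tree has no leaves")
    return tree


def read_tree(path) -> dendropy.Tree:
    path = Path(path)
    text = path.read_text()
    try:
        return parse_tree(text)
    except TreeParseError as exc:
        raise TreeParseError(f"malformed newick: {exc}", path=path) from exc


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def node_id(node: dendropy.Node) -> str:
    """Stable node id: leaf label, or sorted clade leaf labels joined by '|'."""
    leaves = [lf.taxon.label for lf in node.leaf_iter()]
    if len(leaves) == 1:
        return leaves[0]
    return "|".join(sorted(leaves))


def find_node(tree: dendropy.Tree, ident: str) -> dendropy.Node | None:
    """Find a node by label or by its :func:`node_id`."""
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label == ident or node_id(node) == ident:
            return node
    return None


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )
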