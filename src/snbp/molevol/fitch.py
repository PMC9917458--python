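"""Parsimony ancestral states (Hartigan's generalization of Fitch).

Returns, per site, the set of states the focal node takes across all
most-parsimonious reconstructions; sites with more than one state are
masked and should be excluded from polarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from snbp.errors import MissingDataError
from snbp.io.trees import parse_tree


@dataclass
class AncestralSequence:
    states: list[frozenset[str]]
    sequence: str  # ambiguous sites rendered as 'N'
    mask: list[bool]  # True where ambiguous


def _node_key(node: dendropy.Node) -> str:
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return leaves[0] if len(leaves) == 1 else "|".join(leaves)


def _hartigan_site(tree, chars: dict[str, str]):
    """Per-node MPR state sets for a single character."""
    alphabet = sorted(set(chars.values()))
    vu: dict[int, frozenset] = {}
    vl: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vu[id(node)] = frozenset(chars[node.taxon.label])
            vl[id(node)] = frozenset()
            continue
        counts = {s: 0 for s in alphabet}
        for child in node.child_nodes():
            for s in vu[id(child)]:
                counts[s] += 1
        m = max(counts.values())
        vu[id(node)] = frozenset(s for s, c in counts.items() if c == m)
        vl[id(node)] = frozenset(s for s, c in counts.items() if c == m - 1)
    final: dict[int, frozenset] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            final[id(node)] = vu[id(node)]
            continue
        fu = final[id(node.parent_node)]
        if fu <= vu[id(node)]:
            final[id(node)] = fu
        else:
            final[id(node)] = vu[id(node)] | (fu & vl[id(node)])
    return final


def fitch_ancestral(tree, sequences: dict[str, str], focal: str) -> AncestralSequence:
    """Infer the parsimony state sets at ``focal`` for every site.

    Parameters
    ----------
    tree : dendropy.Tree or newick string; must have >= 3 leaves
    sequences : leaf label -> sequence (equal lengths); tree leaves must be
        a subset of the keys
    focal : node identifier: a leaf label, an internal node label, or the
        sorted leaf labels of the clade joined by "|"
    """
    if isinstance(tree, str):
        tree = parse_tree(tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("need >= 3 taxa")
    missing = set(leaves) - set(sequences)
    if missing:
        raise MissingDataError(f"tree leaves absent from alignment: {sorted(missing)}")
    lengths = {len(sequences[l]) for l in leaves}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal lengths")
    (length,) = lengths

    focal_node = None
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label == focal or _node_key(node) == focal:
            focal_node = node
            break
    if focal_node is None:
        raise MissingDataError(f"focal node {focal!r} not found in tree")

    states: list[frozenset[str]] = []
    for i in range(length):
        chars = {l: sequences[l][i] for l in leaves}
        final = _hartigan_site(tree, chars)
        states.append(final[id(focal_node)])
    mask = [len(s) != 1 for s in states]
    sequence = "".join("N" if m else next(iter(s)) for s, m in zip(states, mask))
    return AncestralSequence(states=states, sequence=sequence, mask=mask)
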