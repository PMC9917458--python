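"""Continuous-time codon evolution (HKY mutation x omega), Gillespie per branch.

The substitution process acts per codon site: single-base moves to sense
codons only (moves to stops have rate zero, so no rejection is ever needed
mid-simulation), transitions weighted by kappa, nonsynonymous moves by
omega. Rates are scaled so one unit of branch length equals roughly one
expected substitution per codon site at omega = kappa = 1.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from snbp.genetics import (
    CODON_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    codon_neighbors,
    is_transition,
)
from snbp.io.trees import parse_tree
from snbp.molevol.alignment import CodonAlignment
from snbp.simulate.rng import substream

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def _build_rate_table(omega: float, kappa: float):
    """(targets, rates, total) per sense codon, scaled to ~1 sub/site/unit."""
    targets: list[np.ndarray] = []
    rates: list[np.ndarray] = []
    for codon in SENSE_CODONS:
        aa = CODON_TABLE[codon]
        t_list, r_list = [], []
        for pos, base, new_codon in codon_neighbors(codon):
            if new_codon in STOP_CODONS:
                continue
            rate = kappa if is_transition(codon[pos], base) else 1.0
            if CODON_TABLE[new_codon] != aa:
                rate *= omega
            t_list.append(_CODON_INDEX[new_codon])
            r_list.append(rate)
        targets.append(np.array(t_list, dtype=np.int64))
        rates.append(np.array(r_list, dtype=np.float64))
    # scale so the mean leave-rate over a uniform sense-codon composition
    # at omega = kappa = 1 would be 1 per unit branch length
    neutral_total = 0.0
    for codon in SENSE_CODONS:
        neutral_total += sum(
            1.0
            for _, _, nc in codon_neighbors(codon)
            if nc not in STOP_CODONS
        )
    scale = neutral_total / len(SENSE_CODONS)
    rates = [r / scale for r in rates]
    totals = np.array([r.sum() for r in rates])
    return targets, rates, totals


def _evolve_site(codon_idx: int, t: float, tables, rng: np.random.Generator) -> int:
    targets, rates, totals = tables
    remaining = t
    cur = codon_idx
    while True:
        total = totals[cur]
        if total <= 0:
            return cur
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            return cur
        remaining -= wait
        r = rates[cur]
        cur = int(targets[cur][rng.choice(len(r), p=r / r.sum())])


def simulate_codon_alignment(
    tree,
    omega: float,
    kappa: float,
    n_codons: int,
    seed: int,
    root_codons: list[str] | None = None,
    stream: str = "codon",
) -> CodonAlignment:
    """Evolve a gap-free codon alignment down ``tree``.

    Parameters
    ----------
    tree : dendropy.Tree or newick str
    omega, kappa : selection and transition/transversion parameters (> 0)
    n_codons : alignment length in codons (>= 1)
    seed : master seed; this generator uses the ``stream`` substream
    root_codons : optional fixed root sequence (list of sense codons)
    stream : substream name, so callers can evolve several independent
        alignments from one master seed
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if isinstance(tree, str):
        tree = parse_tree(tree)
    rng = substream(seed, stream)
    tables = _build_rate_table(omega, kappa)

    total_length = sum(
        (e.length or 0.0) for e in tree.preorder_edge_iter() if e.head_node.parent_node
    )
    if total_length == 0.0:
        warnings.warn("all branch lengths are zero: no divergence will accumulate")

    if root_codons is None:
        root_idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    else:
        if len(root_codons) != n_codons:
            raise ValueError("root_codons length mismatch")
        root_idx = np.array([_CODON_INDEX[c] for c in root_codons])

    states: dict[int, np.ndarray] = {id(tree.seed_node): root_idx}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_state = states[id(node.parent_node)]
        blen = node.edge.length or 0.0
        child = parent_state.copy()
        if blen > 0:
            for i in range(n_codons):
                child[i] = _evolve_site(int(child[i]), blen, tables, rng)
        states[id(node)] = child

    sequences = {}
    for leaf in tree.leaf_node_iter():
        idx = states[id(leaf)]
        sequences[leaf.taxon.label] = "".join(SENSE_CODONS[i] for i in idx)
    return CodonAlignment(sequences)
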