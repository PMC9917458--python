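"""Shared-synteny verification of candidate loci."""

from __future__ import annotations

from snbp.errors import MissingDataError
from snbp.io.gff3 import GeneOrder


def check_synteny(
    locus: tuple[str, int, int],
    expected_neighbors: list[str],
    gene_order: GeneOrder,
    k: int = 5,
) -> tuple[bool, int]:
    """Is the locus within ``k`` genes of any expected neighbor's ortholog?

    ``locus`` is (contig, start, end) in the internal 0-based half-open
    convention. Both directions are scanned; a neighbor exactly ``k`` genes
    away counts. Returns (is_syntenic, number of expected neighbors found).
    """
    if not expected_neighbors:
        raise ValueError("expected_neighbors must be nonempty")
    contig, start, end = locus
    if end <= start:
        raise ValueError(f"bad locus span [{start}, {end})")
    try:
        genes = gene_order.genes_on(contig)
    except KeyError:
        raise MissingDataError(
            f"locus contig {contig!r} missing from gene order"
        ) from None

    mid = (start + end) / 2.0
    # insertion rank of the locus in the contig's gene order; genes whose
    # rank is within k of it (either side) form the syntenic window
    rank = sum(1 for g in genes if (g.start + g.end) / 2.0 < mid)
    window = [
        g
        for i, g in enumerate(genes)
        # gene at list index i occupies rank i (before) or i+1 (after the
        # locus); distance in genes is measured accordingly
        if (i < rank and rank - i <= k) or (i >= rank and i - rank + 1 <= k)
    ]
    expected = set(expected_neighbors)
    matched = sum(
        1
        for g in window
        if g.gene_id in expected and not (g.start < end and start < g.end)
    )
    return matched >= 1, matched
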