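"""Toy genome construction with conserved synteny and planted lesions.

Each species genome is a single contig carrying diverged homologs of a
configured gene order. Focal genes can be planted as pseudogenes (premature
in-frame stop) or deleted outright, giving labelled truth for end-to-end
homolog-calling tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from snbp.errors import SimulationError
from snbp.genetics import SENSE_CODONS, translate
from snbp.io.gff3 import GeneFeature, GeneOrder
from snbp.io.trees import parse_tree
from snbp.simulate.codon import simulate_codon_alignment
from snbp.simulate.rng import substream

_SPACER_LEN = 120
_MIN_DETECTABLE_IDENTITY = 0.20


@dataclass
class SyntenySpec:
    """Gene order on the (single) toy contig and which genes are focal."""

    gene_order: list[str]
    focal: list[str]
    n_codons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.focal) - set(self.gene_order)
        if unknown:
            raise ValueError(f"focal genes not in gene order: {sorted(unknown)}")
        for gene in self.focal:
            i = self.gene_order.index(gene)
            if i == 0 and i == len(self.gene_order) - 1:
                raise ValueError(f"focal gene {gene!r} has no flanking genes")

    def neighbors(self, gene: str) -> list[str]:
        """Expected flanking genes of a focal gene, nearest first."""
        i = self.gene_order.index(gene)
        out = []
        for offset in range(1, len(self.gene_order)):
            for j in (i - offset, i + offset):
                if 0 <= j < len(self.gene_order) and self.gene_order[j] != gene:
                    out.append(self.gene_order[j])
        return out


@dataclass
class ToyGenomes:
    """Per-species genomes plus the query set and planted truth."""

    genomes: dict[str, dict[str, str]]  # species -> {contig: sequence}
    gene_orders: dict[str, GeneOrder]  # species -> annotation
    queries: dict[str, str]  # gene -> root protein (the search query)
    query_cds: dict[str, str]  # gene -> root CDS
    truth: dict[tuple[str, str], str]  # (species, gene) -> planted status
    contig_name: str = "contig1"


def _random_root_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n)]


def _plant_stop(cds: str) -> str:
    """Replace the codon one quarter of the way in with TAA."""
    n = len(cds) // 3
    idx = max(1, n // 4)
    return cds[: 3 * idx] + "TAA" + cds[3 * idx + 3 :]


def simulate_toy_genomes(
    spec: SyntenySpec,
    tree,
    divergence: float,
    seed: int,
    pseudogenes: set[tuple[str, str]] = frozenset(),
    deletions: set[tuple[str, str]] = frozenset(),
) -> ToyGenomes:
    """Build per-species toy genomes from ``spec`` evolved along ``tree``.

    ``divergence`` scales all branch lengths. ``pseudogenes`` and
    ``deletions`` are sets of (species, gene) pairs; only focal genes may be
    planted. Raises SimulationError if divergence pushes any homolog below
    the detectability floor (20% protein identity to its query).
    """
    if isinstance(tree, str):
        tree = parse_tree(tree)
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    for sp, gene in set(pseudogenes) | set(deletions):
        if gene not in spec.focal:
            raise ValueError(f"can only plant lesions in focal genes, not {gene!r}")

    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    scaled = tree.clone(depth=1)
    for edge in scaled.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * divergence

    rng = substream(seed, "genomes")
    queries: dict[str, str] = {}
    query_cds: dict[str, str] = {}
    evolved: dict[str, dict[str, str]] = {}  # gene -> species -> cds
    for gene in spec.gene_order:
        n_codons = spec.n_codons.get(gene, 60)
        root = _random_root_codons(rng, n_codons)
        query_cds[gene] = "".join(root)
        queries[gene] = translate(query_cds[gene])
        aln = simulate_codon_alignment(
            scaled,
            omega=0.2,
            kappa=2.0,
            n_codons=n_codons,
            seed=seed,
            root_codons=root,
            stream=f"genomes-{gene}",
        )
        evolved[gene] = dict(aln.sequences)
        for sp in species:
            prot = translate(evolved[gene][sp])
            ident = sum(a == b for a, b in zip(prot, queries[gene])) / len(prot)
            if ident < _MIN_DETECTABLE_IDENTITY:
                raise SimulationError(
                    f"divergence too high: {gene} in {sp} fell to "
                    f"{ident:.0%} identity vs its query"
                )

    genomes: dict[str, dict[str, str]] = {}
    gene_orders: dict[str, GeneOrder] = {}
    truth: dict[tuple[str, str], str] = {}
    contig = "contig1"
    for sp in species:
        parts: list[str] = []
        features: list[GeneFeature] = []
        pos = 0

        def spacer():
            nonlocal pos
            s = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=_SPACER_LEN)
            )
            parts.append(s)
            pos += len(s)

        spacer()
        for gene in spec.gene_order:
            status = "ortholog_syntenic"
            if (sp, gene) in deletions:
                truth[(sp, gene)] = "absent"
                continue
            cds = evolved[gene][sp]
            if (sp, gene) in pseudogenes:
                cds = _plant_stop(cds)
                status = "pseudogene"
            start = pos
            parts.append(cds)
            pos += len(cds)
            features.append(
                GeneFeature(gene_id=gene, contig=contig, start=start, end=pos, strand="+")
            )
            spacer()
            if gene in spec.focal:
                truth[(sp, gene)] = status
        genomes[sp] = {contig: "".join(parts)}
        gene_orders[sp] = GeneOrder(features)

    return ToyGenomes(
        genomes=genomes,
        gene_orders=gene_orders,
        queries=queries,
        query_cds=query_cds,
        truth=truth,
        contig_name=contig,
    )
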