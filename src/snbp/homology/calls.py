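"""Per-species homolog calling: search, filter, RBH, synteny, pseudogene.

Status vocabulary: ortholog_syntenic, paralog_nonsyntenic, pseudogene,
absent. Chromosome class stays "unknown" until sex-linkage assignment
fills it in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from snbp.homology.filters import (
    CONFIRMED,
    filter_hits,
    reciprocal_best_hit,
)
from snbp.homology.pseudogene import PSEUDOGENE, detect_pseudogene
from snbp.homology.search import search_genome, search_protein_db
from snbp.homology.synteny import check_synteny
from snbp.io.gff3 import GeneOrder
from snbp.io.hits import HitRecord, sort_hits_best_first

STATUSES = ("ortholog_syntenic", "paralog_nonsyntenic", "pseudogene", "absent")
CHROMOSOME_CLASSES = ("A", "X", "Y", "sex_ambiguous", "unknown")

#: relaxed e-value for the confirmation re-scan of syntenic windows
LOW_THRESHOLD_E = 1.0


@dataclass
class HomologCall:
    query_gene: str
    species: str
    locus: tuple[str, int, int, str] | None  # (contig, start, end, strand)
    status: str
    chromosome_class: str = "unknown"
    supporting_hits: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.chromosome_class not in CHROMOSOME_CLASSES:
            raise ValueError(f"bad chromosome class {self.chromosome_class!r}")
        if (self.status == "absent") != (self.locus is None):
            raise ValueError("status is 'absent' iff locus is None")


def _extended_locus(hit: HitRecord, contig_seq: str, query_len_aa: int):
    """Project a hit onto the full expected ORF, in frame, on the hit strand.

    Returns (dna, start, end) where start/end are forward-strand contig
    coordinates of the extracted window.
    """
    length = len(contig_seq)
    if hit.strand == "+":
        start = hit.sstart - 3 * hit.qstart
        while start < 0:
            start += 3
        end = min(start + 3 * query_len_aa, length)
        return contig_seq[start:end], start, end
    rc = str(Seq(contig_seq).reverse_complement())
    # map hit span onto the reverse-complement coordinate system
    rc_start = (length - hit.send) - 3 * hit.qstart
    while rc_start < 0:
        rc_start += 3
    rc_end = min(rc_start + 3 * query_len_aa, length)
    dna = rc[rc_start:rc_end]
    return dna, length - rc_end, length - rc_start


def call_homologs(
    queries: dict[str, str],
    genome: dict[str, str],
    gene_order: GeneOrder,
    neighbors: dict[str, list[str]],
    species: str,
    proteome: dict[str, str] | None = None,
    k: int = 5,
    hits: list[HitRecord] | None = None,
) -> list[HomologCall]:
    """Call each query gene's locus and status in one species genome.

    ``proteome`` is the reverse-search database (defaults to ``queries``).
    Precomputed forward ``hits`` may be supplied to skip the built-in
    search backend.
    """
    proteome = proteome or queries
    calls: list[HomologCall] = []
    all_hits = hits if hits is not None else search_genome(queries, genome)
    for gene, qprot in queries.items():
        fwd = [h for h in all_hits if h.query == gene]
        kept = filter_hits(fwd)
        candidate = None
        relic_only = False
        if kept:
            candidate = sort_hits_best_first(kept)[0]
        else:
            # low-threshold confirmation pass: re-scan syntenic windows for
            # degenerate relics; can only confirm pseudogene vs absent
            relaxed = [
                h
                for h in fwd
                if h.evalue < LOW_THRESHOLD_E
                and (h.qend - h.qstart) >= 0.5 * len(qprot)
            ]
            syntenic_relaxed = []
            for h in relaxed:
                try:
                    ok, _ = check_synteny(
                        (h.subject, h.sstart, h.send), neighbors[gene], gene_order, k
                    )
                except Exception:
                    ok = False
                if ok:
                    syntenic_relaxed.append(h)
            if syntenic_relaxed:
                candidate = sort_hits_best_first(syntenic_relaxed)[0]
                relic_only = True
        if candidate is None:
            calls.append(
                HomologCall(query_gene=gene, species=species, locus=None, status="absent")
            )
            continue

        contig_seq = genome[candidate.subject]
        locus_dna, ext_start, ext_end = _extended_locus(
            candidate, contig_seq, len(qprot)
        )
        rev_hits = search_protein_db(f"{gene}_locus", locus_dna, proteome)
        rbh = reciprocal_best_hit(kept, rev_hits, gene)
        try:
            syntenic, _n = check_synteny(
                (candidate.subject, candidate.sstart, candidate.send),
                neighbors[gene],
                gene_order,
                k,
            )
        except Exception:
            syntenic = False
        try:
            pseudo = detect_pseudogene(locus_dna, qprot)
        except ValueError:
            pseudo = None

        if relic_only:
            if pseudo == PSEUDOGENE and rbh == CONFIRMED:
                status = "pseudogene"
            else:
                calls.append(
                    HomologCall(
                        query_gene=gene, species=species, locus=None, status="absent"
                    )
                )
                continue
        elif pseudo == PSEUDOGENE:
            status = "pseudogene"
        elif rbh == CONFIRMED and syntenic:
            status = "ortholog_syntenic"
        else:
            status = "paralog_nonsyntenic"
        calls.append(
            HomologCall(
                query_gene=gene,
                species=species,
                locus=(candidate.subject, ext_start, ext_end, candidate.strand),
                status=status,
                supporting_hits=[
                    f"{h.subject}:{h.sstart}-{h.send}({h.strand})" for h in (kept or [candidate])
                ],
            )
        )
    return calls
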