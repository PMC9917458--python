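"""Pseudogene calling by translate-and-scan.

The operational rule (a premature stop or frameshifting indel truncating
more than 20% of the expected ORF) is this artifact's own definition; the
upstream analyses never state one.
"""

from __future__ import annotations

from snbp.genetics import translate

INTACT = "intact"
PSEUDOGENE = "pseudogene"

MIN_LOCUS_NT = 30
MAX_TRUNCATION = 0.20


def detect_pseudogene(locus_dna: str, query_protein: str) -> str:
    """Classify an in-frame locus as intact or pseudogene.

    ``locus_dna`` must be anchored in frame 0 by the best alignment to the
    query. The effective ORF ends at the first internal stop (or at the
    end of the sequence, which a frameshifting indel pulls forward); a
    locus whose effective ORF is shorter than 80% of the query's length is
    a pseudogene.
    """
    locus_dna = locus_dna.upper().replace("-", "")
    if len(locus_dna) < MIN_LOCUS_NT:
        raise ValueError(
            f"locus too short ({len(locus_dna)} nt < {MIN_LOCUS_NT}) to classify"
        )
    if not query_protein:
        raise ValueError("empty query protein")
    expected = len(query_protein)
    protein = translate(locus_dna)
    stop_idx = protein.find("*")
    effective = len(protein) if stop_idx == -1 else stop_idx
    truncation = 1.0 - effective / expected
    return PSEUDOGENE if truncation > MAX_TRUNCATION else INTACT
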