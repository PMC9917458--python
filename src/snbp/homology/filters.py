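"""Hit filtering and reciprocal-best-hit confirmation.

Threshold comparisons are strict (<, >) exactly as used in the search
protocol this mirrors: e-value < e_max, identity > id_min, bit score >
score_min.
"""

from __future__ import annotations

from snbp.io.hits import HitRecord

CONFIRMED = "confirmed"
UNCONFIRMED = "unconfirmed"

DEFAULT_E_MAX = 1e-2
DEFAULT_ID_MIN = 20.0
DEFAULT_SCORE_MIN = 10.0


def filter_hits(
    hits: list[HitRecord],
    e_max: float = DEFAULT_E_MAX,
    id_min: float = DEFAULT_ID_MIN,
    score_min: float = DEFAULT_SCORE_MIN,
) -> list[HitRecord]:
    """Keep hits with e-value < e_max, identity > id_min and bit score >
    score_min. Order-preserving and idempotent; empty output is allowed.
    """
    for t in (e_max, id_min, score_min):
        if not (t == t and abs(t) != float("inf")):
            raise ValueError("thresholds must be finite")
    return [
        h
        for h in hits
        if h.evalue < e_max and h.identity > id_min and h.bitscore > score_min
    ]


def reciprocal_best_hit(
    forward_hits: list[HitRecord],
    reverse_hits: list[HitRecord],
    query_gene: str,
) -> str:
    """Confirm orthology if the best reverse hit is the original query.

    Best = lowest e-value, ties broken by highest bit score, then
    lexicographic subject id, so the verdict is invariant under permutation
    of the input list. No reverse hits is "unconfirmed", not an error.
    """
    del forward_hits  # part of the contract; the verdict rests on the reverse search
    if not reverse_hits:
        return UNCONFIRMED
    best = min(reverse_hits, key=lambda h: (h.evalue, -h.bitscore, h.subject))
    return CONFIRMED if best.subject == query_gene else UNCONFIRMED
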