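"""Genetic-code tables and small codon helpers used across modules."""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stop codons map to "*"
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
)
NUCLEOTIDES = ("A", "C", "G", "T")

#: transition partners (purine<->purine, pyrimidine<->pyrimidine)
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for ``codon``; ``*`` for stops, ``X`` otherwise."""
    return CODON_TABLE.get(codon.upper(), "X")


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string (trailing partial codon dropped)."""
    n = len(seq) - len(seq) % 3
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, n, 3))


def codon_neighbors(codon: str):
    """Yield (position, new_base, new_codon) for all 9 single-base changes."""
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base != codon[pos]:
                yield pos, base, codon[:pos] + base + codon[pos + 1 :]


def iter_codons(seq: str):
    """Iterate over consecutive codons of an in-frame sequence."""
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3]


def diff_positions(a: str, b: str) -> list[int]:
    return [i for i in range(len(a)) if a[i] != b[i]]


def substitution_pathways(c1: str, c2: str):
    """All orderings of the single-base steps converting ``c1`` into ``c2``.

    Each pathway is a list of (from_codon, to_codon) steps. Pathways passing
    through a stop codon are excluded, following the usual counting-method
    convention. Returns an empty list when every ordering is blocked.
    """
    positions = diff_positions(c1, c2)
    pathways = []
    for order in itertools.permutations(positions):
        steps = []
        cur = c1
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            pathways.append(steps)
    return pathways
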