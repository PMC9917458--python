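"""Counting-method dN/dS (Nei & Gojobori style) with Jukes-Cantor correction.

Sites are counted per codon by mutational fractions with mutations to stop
codons excluded; codons differing at several positions are averaged over
all unblocked minimal substitution pathways. The proportions are corrected
with d = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from snbp.errors import SaturationError
from snbp.genetics import (
    CODON_TABLE,
    STOP_CODONS,
    codon_neighbors,
    substitution_pathways,
)
from snbp.molevol.alignment import CodonAlignment, GAP


@dataclass(frozen=True)
class DnDsResult:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: float
    ds: float
    omega: float | None  # None when dS == 0 (flagged undefined)
    n_codons_compared: int


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one codon.

    Each position contributes the fraction of its possible mutations that
    are nonsynonymous; mutations creating stop codons are excluded from
    both numerator and denominator.
    """
    if codon in STOP_CODONS or len(codon) != 3:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TABLE[codon]
    by_pos: dict[int, list[bool]] = {0: [], 1: [], 2: []}
    for pos, _base, new_codon in codon_neighbors(codon):
        if new_codon in STOP_CODONS:
            continue
        by_pos[pos].append(CODON_TABLE[new_codon] != aa)
    n = s = 0.0
    for pos in range(3):
        muts = by_pos[pos]
        if not muts:
            continue
        frac_nonsyn = sum(muts) / len(muts)
        n += frac_nonsyn
        s += 1.0 - frac_nonsyn
    return n, s


def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences averaged over pathways.

    Pathways through stop codons are excluded. Raises ValueError when every
    pathway is blocked (the codon pair is then uncountable).
    """
    if c1 == c2:
        return 0.0, 0.0
    pathways = substitution_pathways(c1, c2)
    if not pathways:
        raise ValueError(f"all substitution pathways {c1}->{c2} pass through stops")
    nd_total = sd_total = 0.0
    for steps in pathways:
        for frm, to in steps:
            if CODON_TABLE[frm] != CODON_TABLE[to]:
                nd_total += 1.0
            else:
                sd_total += 1.0
    k = len(pathways)
    return nd_total / k, sd_total / k


def jukes_cantor(p: float) -> float:
    """JC distance for proportion ``p``; raises SaturationError at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: correction undefined")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _pairwise(codons1: list[str], codons2: list[str]) -> DnDsResult:
    n_sites = s_sites = 0.0
    nd = sd = 0.0
    compared = 0
    for c1, c2 in zip(codons1, codons2):
        if GAP in c1 or GAP in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        try:
            dnd, dsd = codon_pair_differences(c1, c2)
        except ValueError:
            continue  # fully blocked pathway pair: skip codon
        n1, s1 = codon_site_counts(c1)
        n2, s2 = codon_site_counts(c2)
        n_sites += (n1 + n2) / 2.0
        s_sites += (s1 + s2) / 2.0
        nd += dnd
        sd += dsd
        compared += 1
    if compared == 0:
        raise ValueError("no shared ungapped codons to compare")
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    dn = jukes_cantor(pn)
    ds = jukes_cantor(ps)
    omega = dn / ds if ds > 0 else None
    return DnDsResult(
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        dn=dn,
        ds=ds,
        omega=omega,
        n_codons_compared=compared,
    )


def ng86_dnds(alignment: CodonAlignment) -> DnDsResult:
    """dN/dS for an alignment: pairwise for 2 taxa, mean-pairwise otherwise.

    For >2 sequences, site and difference counts are averaged over all
    pairs before correction, and omega = mean dN / mean dS. Symmetric in
    sequence order.
    """
    taxa = alignment.taxa
    if len(taxa) < 2:
        raise ValueError("need >= 2 sequences")
    codons = {t: alignment.codons(t) for t in taxa}
    results = [
        _pairwise(codons[a], codons[b]) for a, b in combinations(sorted(taxa), 2)
    ]
    k = len(results)
    if k == 1:
        return results[0]
    dn = sum(r.dn for r in results) / k
    ds = sum(r.ds for r in results) / k
    return DnDsResult(
        n_sites=sum(r.n_sites for r in results) / k,
        s_sites=sum(r.s_sites for r in results) / k,
        nd=sum(r.nd for r in results) / k,
        sd=sum(r.sd for r in results) / k,
        pn=sum(r.pn for r in results) / k,
        ps=sum(r.ps for r in results) / k,
        dn=dn,
        ds=ds,
        omega=dn / ds if ds > 0 else None,
        n_codons_compared=min(r.n_codons_compared for r in results),
    )
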