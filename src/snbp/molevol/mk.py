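"""McDonald-Kreitman tables and tests.

Builds the four counts (Dn, Ds, Pn, Ps) from aligned ingroup alleles plus
an outgroup sequence, optionally polarized against an inferred ancestor,
with an optional rare-polymorphism filter. The test is a Pearson chi-square
(df = 1, no continuity correction) on the 2x2 table, falling back to
Fisher's exact test when any expected cell is below 5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from scipy import stats

from snbp.genetics import CODON_TABLE, STOP_CODONS
from snbp.io.tables import PolymorphismRecord
from snbp.molevol.alignment import GAP
from snbp.molevol.ng86 import codon_pair_differences


@dataclass
class MKTable:
    dn: float = 0.0
    ds: float = 0.0
    pn: int = 0
    ps: int = 0
    polarized: bool = False
    rare_threshold: float | None = None
    excluded_multiallelic: int = 0
    excluded_complex: int = 0
    excluded_ambiguous_ancestor: int = 0
    excluded_rare: int = 0
    records: list[PolymorphismRecord] = field(default_factory=list)

    @property
    def variant(self) -> str:
        pol = "polarized" if self.polarized else "unpolarized"
        rare = "rare-filtered" if self.rare_threshold is not None else "all SNPs"
        return f"{pol}, {rare}"


@dataclass(frozen=True)
class MKResult:
    dn: float
    ds: float
    pn: int
    ps: int
    alpha: float | None  # None when Dn = 0 or Ps = 0
    neutrality_index: float | None
    statistic: float | None
    p_value: float | None
    method: str  # "chi2" | "fisher" | "undefined"
    variant: str


def _codon_column(seqs: dict[str, str], i: int) -> dict[str, str]:
    return {name: seq[3 * i : 3 * i + 3] for name, seq in seqs.items()}


def mk_build(
    ingroup: dict[str, str],
    outgroup: str,
    ancestor: str | None = None,
    rare_threshold: float | None = None,
    polarized: bool = False,
    gene: str = "gene",
) -> MKTable:
    """Classify variable codon sites into the four MK counts.

    Parameters
    ----------
    ingroup : aligned CDS per allele (same length, in frame)
    outgroup : aligned outgroup CDS
    ancestor : aligned ancestral CDS (required when polarized)
    rare_threshold : drop polymorphisms with frequency below this value
        (derived-allele frequency when polarized, minor-allele otherwise)
    polarized : assign fixed differences to the ingroup lineage only when
        the ingroup state differs from the ancestor
    """
    if not ingroup:
        raise ValueError("no ingroup alleles")
    lengths = {len(s) for s in ingroup.values()} | {len(outgroup)}
    if polarized:
        if ancestor is None:
            raise ValueError("polarized mode requires an ancestor sequence")
        lengths.add(len(ancestor))
    if len(lengths) != 1:
        raise ValueError(f"sequences must be aligned to one length, got {lengths}")
    (length,) = lengths
    if length % 3:
        raise ValueError("alignment length must be divisible by 3")

    table = MKTable(polarized=polarized, rare_threshold=rare_threshold)
    n_alleles = len(ingroup)
    for i in range(length // 3):
        col = _codon_column(ingroup, i)
        out_codon = outgroup[3 * i : 3 * i + 3]
        codons = list(col.values())
        if any(GAP in c for c in codons) or GAP in out_codon:
            continue
        if any(c in STOP_CODONS for c in codons) or out_codon in STOP_CODONS:
            continue
        anc_codon = ancestor[3 * i : 3 * i + 3] if ancestor else None
        if anc_codon is not None and (GAP in anc_codon or "N" in anc_codon):
            table.excluded_ambiguous_ancestor += 1
            continue
        counts = Counter(codons)
        distinct = sorted(counts)
        if len(distinct) > 2:
            table.excluded_multiallelic += 1
            continue
        if len(distinct) == 2:
            a, b = distinct
            if sum(x != y for x, y in zip(a, b)) != 1:
                table.excluded_complex += 1
                continue
            if polarized:
                if anc_codon not in distinct:
                    table.excluded_ambiguous_ancestor += 1
                    continue
                derived = b if anc_codon == a else a
                freq = counts[derived] / n_alleles
            else:
                minor = min(distinct, key=lambda c: (counts[c], c))
                freq = counts[minor] / n_alleles
            if rare_threshold is not None and freq < rare_threshold:
                table.excluded_rare += 1
                continue
            syn = CODON_TABLE[a] == CODON_TABLE[b]
            if syn:
                table.ps += 1
            else:
                table.pn += 1
            table.records.append(
                PolymorphismRecord(
                    gene,
                    i,
                    "synonymous" if syn else "nonsynonymous",
                    "polymorphism",
                    frequency=min(max(freq, 1e-9), 1 - 1e-9),
                )
            )
        else:
            fixed = distinct[0]
            if polarized:
                if fixed == anc_codon:
                    continue  # change happened on the outgroup lineage
                reference = anc_codon
            else:
                reference = out_codon
            if fixed == reference:
                continue
            try:
                nd, sd = codon_pair_differences(reference, fixed)
            except ValueError:
                table.excluded_complex += 1
                continue
            table.dn += nd
            table.ds += sd
            if nd or sd:
                table.records.append(
                    PolymorphismRecord(
                        gene,
                        i,
                        "nonsynonymous" if nd >= sd else "synonymous",
                        "divergence",
                        lineage="ingroup" if polarized else None,
                    )
                )
    return table


def mk_test(table: MKTable) -> MKResult:
    """Alpha, neutrality index, and a 2x2 test on [[Dn, Ds], [Pn, Ps]]."""
    dn, ds, pn, ps = table.dn, table.ds, table.pn, table.ps
    if min(dn, ds, pn, ps) < 0:
        raise ValueError("counts must be non-negative")
    alpha = None
    ni = None
    if dn > 0 and ps > 0:
        alpha = 1.0 - (ds * pn) / (dn * ps)
        if ds > 0:
            ni = (pn * ds) / (ps * dn)
    stat, p, method = _test_2x2(dn, ds, pn, ps)
    return MKResult(
        dn=dn,
        ds=ds,
        pn=pn,
        ps=ps,
        alpha=alpha,
        neutrality_index=ni,
        statistic=stat,
        p_value=p,
        method=method,
        variant=table.variant,
    )


def _test_2x2(dn: float, ds: float, pn: float, ps: float):
    n = dn + ds + pn + ps
    row1, row2 = dn + ds, pn + ps
    col1, col2 = dn + pn, ds + ps
    if row1 == 0 or row2 == 0 or col1 == 0 or col2 == 0:
        return None, None, "undefined"
    expected = [
        row1 * col1 / n,
        row1 * col2 / n,
        row2 * col1 / n,
        row2 * col2 / n,
    ]
    if min(expected) < 5:
        observed = [[round(dn), round(ds)], [round(pn), round(ps)]]
        _, p = stats.fisher_exact(observed, alternative="two-sided")
        return None, float(p), "fisher"
    observed = [dn, ds, pn, ps]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, "chi2"


def pooled_mk_table(
    records: list[PolymorphismRecord], rare_threshold: float | None = None
) -> MKTable:
    """Pool per-site records (e.g. simulator output) into one MK table."""
    table = MKTable(rare_threshold=rare_threshold)
    for r in records:
        if r.kind == "divergence":
            if r.site_class == "nonsynonymous":
                table.dn += 1
            else:
                table.ds += 1
        else:
            if rare_threshold is not None and r.frequency < rare_threshold:
                table.excluded_rare += 1
                continue
            if r.site_class == "nonsynonymous":
                table.pn += 1
            else:
                table.ps += 1
    return table
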