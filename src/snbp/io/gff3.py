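"""Minimal GFF3 reader/writer for gene-order (synteny) work.

Only ``gene`` features are retained; gene order on a contig is defined by
sorting on (contig, start). File coordinates are 1-based inclusive and are
converted here, once, to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from snbp.errors import ParseError


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+', '-' or '.'

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad span [{self.start}, {self.end}) for {self.gene_id}")


class GeneOrder:
    """Genes per contig, ordered by start coordinate."""

    def __init__(self, genes: list[GeneFeature]):
        self._by_contig: dict[str, list[GeneFeature]] = {}
        self._by_id: dict[str, GeneFeature] = {}
        for g in genes:
            self._by_contig.setdefault(g.contig, []).append(g)
            self._by_id[g.gene_id] = g
        for contig in self._by_contig:
            self._by_contig[contig].sort(key=lambda g: (g.start, g.end, g.gene_id))

    @property
    def contigs(self) -> list[str]:
        return sorted(self._by_contig)

    def genes_on(self, contig: str) -> list[GeneFeature]:
        if contig not in self._by_contig:
            raise KeyError(f"contig {contig!r} not in gene order")
        return list(self._by_contig[contig])

    def get(self, gene_id: str) -> GeneFeature | None:
        return self._by_id.get(gene_id)

    def index_on_contig(self, gene_id: str) -> int:
        g = self._by_id[gene_id]
        return self._by_contig[g.contig].index(g)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path) -> GeneOrder:
    path = Path(path)
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            contig, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype != "gene":
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError:
                raise ParseError(
                    f"non-numeric coordinate {start_s!r}/{end_s!r}",
                    path=path,
                    line=lineno,
                ) from None
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"bad 1-based span {start1}..{end1}", path=path, line=lineno
                )
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise ParseError("gene feature without ID", path=path, line=lineno)
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    contig=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in "+-" else ".",
                )
            )
    return GeneOrder(genes)


def write_gff3(order: GeneOrder | list[GeneFeature], path, source: str = "snbp") -> None:
    genes = list(order)
    genes.sort(key=lambda g: (g.contig, g.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        source,
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
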