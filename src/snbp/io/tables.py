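"""Copy-number matrices and polymorphism tables (internal TSV dialects)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from snbp.errors import ParseError

#: valid genomic location classes for copy counts
LOCATION_CLASSES = ("A", "X", "Y", "X/Y", "U")


class CopyNumberMatrix:
    """gene x species x location-class -> non-negative copy count."""

    def __init__(self):
        self._counts: dict[tuple[str, str, str], int] = {}
        self._locus_groups: dict[tuple[str, str, str], str] = {}

    def set(self, gene: str, species: str, location: str, count: int,
            locus_group: str | None = None) -> None:
        if location not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {location!r}")
        if count < 0:
            raise ValueError(f"negative copy count {count}")
        self._counts[(gene, species, location)] = int(count)
        if locus_group is not None:
            self._locus_groups[(gene, species, location)] = locus_group

    def get(self, gene: str, species: str, location: str) -> int:
        return self._counts.get((gene, species, location), 0)

    def locus_group(self, gene: str, species: str, location: str) -> str | None:
        return self._locus_groups.get((gene, species, location))

    def total_copies(self, gene: str, species: str) -> int:
        return sum(
            c for (g, s, _), c in self._counts.items() if g == gene and s == species
        )

    @property
    def genes(self) -> list[str]:
        return sorted({g for g, _, _ in self._counts})

    @property
    def species(self) -> list[str]:
        return sorted({s for _, s, _ in self._counts})

    def items(self):
        return sorted(self._counts.items())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CopyNumberMatrix):
            return NotImplemented
        mine = {k: v for k, v in self._counts.items() if v > 0}
        theirs = {k: v for k, v in other._counts.items() if v > 0}
        return mine == theirs


def read_copy_table(path) -> CopyNumberMatrix:
    """Read TSV with header: gene, species, location, copies[, locus_group]."""
    path = Path(path)
    matrix = CopyNumberMatrix()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene", "species", "location", "copies"]
        if header[: len(required)] != required:
            raise ParseError(
                f"expected header {required}, got {header}", path=path, line=1
            )
        has_group = len(header) > 4 and header[4] == "locus_group"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"expected >= 4 columns, got {len(fields)}", path=path, line=lineno
                )
            gene, species, location = fields[0], fields[1], fields[2]
            try:
                copies = int(fields[3])
            except ValueError:
                raise ParseError(
                    f"non-numeric copy count {fields[3]!r}", path=path, line=lineno
                ) from None
            group = fields[4] if has_group and len(fields) > 4 and fields[4] else None
            try:
                matrix.set(gene, species, location, copies, locus_group=group)
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
    return matrix


def write_copy_table(matrix: CopyNumberMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tspecies\tlocation\tcopies\tlocus_group\n")
        for (gene, species, location), count in matrix.items():
            group = matrix.locus_group(gene, species, location) or ""
            fh.write(f"{gene}\t{species}\t{location}\t{count}\t{group}\n")


@dataclass(frozen=True)
class PolymorphismRecord:
    """One classified variable site of a gene.

    ``kind`` is "polymorphism" or "divergence"; ``site_class`` is
    "synonymous" or "nonsynonymous". Polymorphisms carry a derived-allele
    frequency in (0, 1); divergence records carry none.
    """

    gene: str
    site: int
    site_class: str
    kind: str
    frequency: float | None = None
    lineage: str | None = None

    def __post_init__(self):
        if self.site_class not in ("synonymous", "nonsynonymous"):
            raise ValueError(f"bad site class {self.site_class!r}")
        if self.kind not in ("polymorphism", "divergence"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind == "polymorphism":
            if self.frequency is None or not (0.0 < self.frequency < 1.0):
                raise ValueError(
                    f"polymorphism frequency must be in (0,1), got {self.frequency}"
                )
        elif self.frequency is not None:
            raise ValueError("divergence records carry no frequency")


def read_polymorphism_table(path) -> list[PolymorphismRecord]:
    path = Path(path)
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene", "site", "site_class", "kind", "frequency", "lineage"]
        if header != expected:
            raise ParseError(
                f"expected header {expected}, got {header}", path=path, line=1
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"expected 6 columns, got {len(fields)}", path=path, line=lineno
                )
            gene, site_s, site_class, kind, freq_s, lineage = fields
            try:
                site = int(site_s)
                freq = float(freq_s) if freq_s else None
            except ValueError:
                raise ParseError(
                    f"non-numeric field {site_s!r}/{freq_s!r}", path=path, line=lineno
                ) from None
            try:
                records.append(
                    PolymorphismRecord(
                        gene=gene,
                        site=site,
                        site_class=site_class,
                        kind=kind,
                        frequency=freq,
                        lineage=lineage or None,
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
    return records


def write_polymorphism_table(records: list[PolymorphismRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsite\tsite_class\tkind\tfrequency\tlineage\n")
        for r in records:
            freq = f"{r.frequency:.6g}" if r.frequency is not None else ""
            fh.write(
                f"{r.gene}\t{r.site}\t{r.site_class}\t{r.kind}\t{freq}\t{r.lineage or ''}\n"
            )
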