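"""Tabular homology-hit records (12-column BLAST-style dialect).

Columns, tab-separated, no header:
query, subject, pct_identity, length, mismatches, gap_opens,
qstart, qend, sstart, send, evalue, bitscore

Query/subject coordinates in the file are 1-based inclusive; subject start
may exceed subject end to encode a minus-strand hit. At parse time
coordinates are normalized to 0-based half-open with an explicit strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from snbp.errors import ParseError

N_COLUMNS = 12


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    identity: float  # percent, 0-100
    length: int
    mismatches: int
    gap_opens: int
    qstart: int  # 0-based half-open after normalization
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if self.qstart < 0 or self.qend <= self.qstart:
            raise ValueError(f"bad query span [{self.qstart}, {self.qend})")
        if self.sstart < 0 or self.send <= self.sstart:
            raise ValueError(f"bad subject span [{self.sstart}, {self.send})")


def _parse_line(fields: list[str], path, lineno: int) -> HitRecord:
    try:
        q, s = fields[0], fields[1]
        identity = float(fields[2])
        length = int(fields[3])
        mismatches = int(fields[4])
        gap_opens = int(fields[5])
        qstart1, qend1 = int(fields[6]), int(fields[7])
        sstart1, send1 = int(fields[8]), int(fields[9])
        evalue = float(fields[10])
        bitscore = float(fields[11])
    except ValueError as exc:
        raise ParseError(f"non-numeric field: {exc}", path=path, line=lineno) from None
    strand = "+"
    if sstart1 > send1:
        sstart1, send1 = send1, sstart1
        strand = "-"
    if qstart1 < 1 or sstart1 < 1:
        raise ParseError("coordinates must be positive", path=path, line=lineno)
    try:
        return HitRecord(
            query=q,
            subject=s,
            identity=identity,
            length=length,
            mismatches=mismatches,
            gap_opens=gap_opens,
            qstart=qstart1 - 1,
            qend=qend1,
            sstart=sstart1 - 1,
            send=send1,
            evalue=evalue,
            bitscore=bitscore,
            strand=strand,
        )
    except ValueError as exc:
        raise ParseError(str(exc), path=path, line=lineno) from None


def read_hits(path) -> list[HitRecord]:
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != N_COLUMNS:
                raise ParseError(
                    f"expected {N_COLUMNS} columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            hits.append(_parse_line(fields, path, lineno))
    return hits


def write_hits(hits: list[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "-":
                sstart1, send1 = h.send, h.sstart + 1
            else:
                sstart1, send1 = h.sstart + 1, h.send
            fh.write(
                "\t".join(
                    [
                        h.query,
                        h.subject,
                        f"{h.identity:.3f}",
                        str(h.length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.qstart + 1),
                        str(h.qend),
                        str(sstart1),
                        str(send1),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def sort_hits_best_first(hits: list[HitRecord]) -> list[HitRecord]:
    """Deterministic best-first order: e-value asc, bitscore desc, subject id."""
    return sorted(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject, h.sstart))
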