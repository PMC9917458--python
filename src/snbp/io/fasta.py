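"""FASTA round-trip helpers (thin wrapper over Bio.SeqIO)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from snbp.errors import DuplicateIdError, ParseError


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Raises
    ------
    DuplicateIdError
        if two records share an id.
    ParseError
        if the file is empty or not FASTA.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r}", path=path)
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ParseError("no FASTA records found", path=path)
    return records


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    path = Path(path)
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)
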