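"""In-frame codon alignments."""

from __future__ import annotations

from dataclasses import dataclass, field

from snbp.genetics import STOP_CODONS

GAP = "-"


@dataclass
class CodonAlignment:
    """Aligned coding sequences, length divisible by 3, no internal stops.

    ``taxa`` preserves input order; ``sequences`` maps taxon -> aligned CDS.
    """

    sequences: dict[str, str]
    genetic_code: int = 1
    taxa: list[str] = field(init=False)

    def __post_init__(self):
        self.taxa = list(self.sequences)
        if not self.sequences:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")
        for name, seq in self.sequences.items():
            seq = seq.upper()
            self.sequences[name] = seq
            n_codons = length // 3
            for i in range(n_codons):
                codon = seq[3 * i : 3 * i + 3]
                if GAP in codon:
                    continue
                # terminal stop codons are tolerated; internal ones are not
                if codon in STOP_CODONS and i < n_codons - 1:
                    raise ValueError(
                        f"internal stop codon {codon} at codon {i} in {name!r}"
                    )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codons(self, taxon: str) -> list[str]:
        seq = self.sequences[taxon]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        return CodonAlignment(
            {t: self.sequences[t] for t in taxa}, genetic_code=self.genetic_code
        )
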