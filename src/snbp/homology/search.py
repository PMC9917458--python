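"""Built-in six-frame translated Smith-Waterman search backend.

A pluggable stand-in for an external translated-BLAST engine at toy scale:
BLOSUM62, affine gaps 11/1, Karlin-Altschul e-values with standard gapped
constants. Any backend producing :class:`snbp.io.hits.HitRecord` lists can
replace it.
"""

from __future__ import annotations

import math

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from snbp.genetics import translate
from snbp.io.hits import HitRecord

# gapped Karlin-Altschul parameters for BLOSUM62 with 11/1 gap costs
_LAMBDA = 0.267
_K = 0.041


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0  # first gap residue: open 11 + extend 1
    aligner.extend_gap_score = -1.0
    return aligner


def bit_score(raw: float) -> float:
    return (_LAMBDA * raw - math.log(_K)) / math.log(2)


def e_value(raw: float, m: int, n: int) -> float:
    return _K * m * n * math.exp(-_LAMBDA * raw)


def _frames(dna: str):
    """Yield (strand, frame, protein, aa->nt mapping info) for all 6 frames."""
    rc = str(Seq(dna).reverse_complement())
    for strand, seq in (("+", dna), ("-", rc)):
        for frame in range(3):
            prot = translate(seq[frame:])
            if prot:
                yield strand, frame, prot


def _alignment_stats(alignment):
    """(matches, mismatches, gap_opens, n_columns, spans) of a local alignment."""
    blocks_t, blocks_q = alignment.aligned
    target, query = alignment.target, alignment.query
    matches = mismatches = 0
    aligned_len = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        for i in range(te - ts):
            if target[ts + i] == query[qs + i]:
                matches += 1
            else:
                mismatches += 1
        aligned_len += te - ts
    gap_opens = 0
    gap_len = 0
    for i in range(1, len(blocks_t)):
        gt = blocks_t[i][0] - blocks_t[i - 1][1]
        gq = blocks_q[i][0] - blocks_q[i - 1][1]
        if gt > 0:
            gap_opens += 1
            gap_len += gt
        if gq > 0:
            gap_opens += 1
            gap_len += gq
    t_span = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    q_span = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    return matches, mismatches, gap_opens, aligned_len + gap_len, t_span, q_span


def search_genome(
    queries: dict[str, str],
    genome: dict[str, str],
    e_max: float = 10.0,
) -> list[HitRecord]:
    """Search protein queries against a nucleotide genome (six frames).

    Returns the best local hit per (query, contig, strand, frame) with
    e-value below ``e_max``, subject coordinates in nucleotides.
    """
    aligner = _aligner()
    total_nt = sum(len(s) for s in genome.values())
    hits: list[HitRecord] = []
    for qname, qprot in queries.items():
        for contig, dna in genome.items():
            length = len(dna)
            for strand, frame, prot in _frames(dna):
                try:
                    alignments = aligner.align(prot, qprot)
                    best = alignments[0]
                except (ValueError, IndexError):
                    continue
                raw = float(best.score)
                if raw <= 0:
                    continue
                ev = e_value(raw, len(qprot), total_nt)
                if ev >= e_max:
                    continue
                m, mm, go, ncols, (ts, te), (qs, qe) = _alignment_stats(best)
                if ncols == 0:
                    continue
                # aa coords in this frame -> nt coords on the forward strand
                nt_start_fs = frame + 3 * ts
                nt_end_fs = frame + 3 * te
                if strand == "+":
                    sstart, send = nt_start_fs, nt_end_fs
                else:
                    sstart, send = length - nt_end_fs, length - nt_start_fs
                hits.append(
                    HitRecord(
                        query=qname,
                        subject=contig,
                        identity=100.0 * m / ncols,
                        length=ncols,
                        mismatches=mm,
                        gap_opens=go,
                        qstart=qs,
                        qend=qe,
                        sstart=sstart,
                        send=send,
                        evalue=ev,
                        bitscore=bit_score(raw),
                        strand=strand,
                    )
                )
    return hits


def search_protein_db(
    segment_id: str,
    dna: str,
    db: dict[str, str],
    e_max: float = 10.0,
) -> list[HitRecord]:
    """Search a nucleotide segment (six frames) against a protein set.

    The blastx-style reverse search used for reciprocal-best-hit checks;
    subject coordinates are protein (aa) positions.
    """
    aligner = _aligner()
    total_aa = sum(len(p) for p in db.values())
    hits: list[HitRecord] = []
    for strand, frame, prot in _frames(dna):
        for name, target_prot in db.items():
            try:
                alignments = aligner.align(target_prot, prot)
                best = alignments[0]
            except (ValueError, IndexError):
                continue
            raw = float(best.score)
            if raw <= 0:
                continue
            ev = e_value(raw, len(dna), total_aa)
            if ev >= e_max:
                continue
            m, mm, go, ncols, (ts, te), (qs, qe) = _alignment_stats(best)
            if ncols == 0:
                continue
            hits.append(
                HitRecord(
                    query=segment_id,
                    subject=name,
                    identity=100.0 * m / ncols,
                    length=ncols,
                    mismatches=mm,
                    gap_opens=go,
                    qstart=frame + 3 * qs,
                    qend=frame + 3 * qe,
                    sstart=ts,
                    send=te,
                    evalue=ev,
                    bitscore=bit_score(raw),
                    strand=strand,
                )
            )
    return hits
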