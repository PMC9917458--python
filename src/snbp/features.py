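"""Protein descriptors: isoelectric point, net charge, basic-residue
fraction, and position-weight-matrix motif scanning for HMG boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Bjellqvist pKa values (the ExPASy convention)
PKA_BJELLQVIST = {
    "n_term": 7.50,
    "c_term": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
}

# EMBOSS pKa values
PKA_EMBOSS = {
    "n_term": 8.60,
    "c_term": 3.60,
    "D": 3.90,
    "E": 4.10,
    "C": 8.50,
    "Y": 10.10,
    "H": 6.50,
    "K": 10.80,
    "R": 12.50,
}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


def _clean(sequence: str) -> str:
    sequence = sequence.upper().strip("*")
    if not sequence:
        raise ValueError("empty sequence")
    unknown = set(sequence) - set(AMINO_ACIDS)
    if unknown:
        warnings.warn(f"ignoring non-standard residues {sorted(unknown)}")
        sequence = "".join(c for c in sequence if c in AMINO_ACIDS)
    if not sequence:
        raise ValueError("no standard residues in sequence")
    return sequence


def net_charge(sequence: str, ph: float, pka: dict[str, float] = PKA_BJELLQVIST) -> float:
    """Henderson-Hasselbalch net charge over termini + D, E, C, Y, H, K, R."""
    sequence = _clean(sequence)
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for aa in _BASIC:
        charge += sequence.count(aa) / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        charge -= sequence.count(aa) / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str, pka: dict[str, float] = PKA_BJELLQVIST, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    sequence = _clean(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def basic_fraction(sequence: str) -> float:
    """Fraction of K + R residues."""
    sequence = _clean(sequence)
    return (sequence.count("K") + sequence.count("R")) / len(sequence)


@dataclass
class MotifProfile:
    """Log-odds position-weight matrix over the 20 standard residues."""

    matrix: list[dict[str, float]]  # one dict per position
    threshold: float  # minimum window score for a hit

    @property
    def length(self) -> int:
        return len(self.matrix)

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length mismatch")
        total = 0.0
        for pos, aa in enumerate(window):
            total += self.matrix[pos].get(aa, min(self.matrix[pos].values()))
        return total


def load_motif_profile(path=None) -> MotifProfile:
    """Load the packaged HMG-box PWM (or any PWM in the same TSV layout).

    Layout: first line ``#threshold <float>``, then a header
    ``pos<TAB>A<TAB>C...`` and one row of log-odds per position.
    """
    if path is None:
        path = Path(str(resources.files("snbp.data").joinpath("hmg_box_pwm.tsv")))
    lines = Path(path).read_text().splitlines()
    threshold = None
    rows = []
    header: list[str] | None = None
    for line in lines:
        if line.startswith("#threshold"):
            threshold = float(line.split()[1])
            continue
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if header is None:
            header = fields[1:]
            continue
        rows.append({aa: float(v) for aa, v in zip(header, fields[1:])})
    if threshold is None or not rows:
        raise ValueError(f"bad PWM file {path}")
    return MotifProfile(matrix=rows, threshold=threshold)


def hmg_box_scan(
    sequence: str, profile: MotifProfile | None = None
) -> tuple[int, list[tuple[int, int]]]:
    """Count non-overlapping motif hits above threshold, greedy best-first.

    Returns (count, [(start, end) spans]). Sequences shorter than the
    profile yield 0 hits.
    """
    if profile is None:
        profile = load_motif_profile()
    sequence = _clean(sequence)
    L = profile.length
    if len(sequence) < L:
        return 0, []
    scored = []
    for start in range(len(sequence) - L + 1):
        s = profile.score(sequence[start : start + L])
        if s >= profile.threshold:
            scored.append((s, start))
    scored.sort(key=lambda t: (-t[0], t[1]))
    spans: list[tuple[int, int]] = []
    for _score, start in scored:
        end = start + L
        if all(end <= s0 or start >= e0 for s0, e0 in spans):
            spans.append((start, end))
    spans.sort()
    return len(spans), spans


@dataclass(frozen=True)
class ProteinFeatures:
    id: str
    length: int
    pi_whole: float
    pi_domains: tuple[float, ...]
    net_charge_ph7: float
    fraction_basic: float
    hmg_box_count: int
    hmg_box_spans: tuple[tuple[int, int], ...]


def protein_features(
    name: str,
    sequence: str,
    profile: MotifProfile | None = None,
    pka: dict[str, float] = PKA_BJELLQVIST,
) -> ProteinFeatures:
    """All descriptors for one protein; domain pI computed per motif hit."""
    cleaned = _clean(sequence)
    count, spans = hmg_box_scan(cleaned, profile)
    domain_pis = tuple(isoelectric_point(cleaned[s:e], pka) for s, e in spans)
    return ProteinFeatures(
        id=name,
        length=len(cleaned),
        pi_whole=isoelectric_point(cleaned, pka),
        pi_domains=domain_pis,
        net_charge_ph7=net_charge(cleaned, 7.0, pka),
        fraction_basic=basic_fraction(cleaned),
        hmg_box_count=count,
        hmg_box_spans=tuple(spans),
    )
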