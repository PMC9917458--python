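"""Bimodal read-depth simulation for sex-linkage classification tests.

Per-base depth is negative-binomial around a class mean (variance
mu + dispersion * mu^2; dispersion = 0 degrades to Poisson). Males carry
one X and one Y dose against two autosomal doses; females carry two X
doses and no Y.
"""

from __future__ import annotations

import numpy as np

from snbp.io.depth import DepthTable
from snbp.simulate.config import CoverageParams
from snbp.simulate.rng import substream

# depth multipliers relative to haploid depth, per (sex, chromosome class)
_DOSE = {
    ("male", "A"): 2.0,
    ("male", "X"): 1.0,
    ("male", "Y"): 1.0,
    ("female", "A"): 2.0,
    ("female", "X"): 2.0,
    ("female", "Y"): 0.0,
}


def _draw(rng: np.random.Generator, mu: float, dispersion: float, n: int) -> np.ndarray:
    if mu <= 0:
        return np.zeros(n, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mu, size=n).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p, size=n).astype(np.int64)


def simulate_coverage(
    params: CoverageParams, seed: int
) -> tuple[DepthTable, DepthTable, dict[str, str]]:
    """Return (male depth, female depth, true class per contig)."""
    params.validate()
    if not params.contig_lengths:
        raise ValueError("no contigs configured")
    missing = set(params.contig_lengths) - set(params.contig_classes)
    if missing:
        raise ValueError(f"contigs without a class: {sorted(missing)}")
    rng_m = substream(seed, "coverage-male")
    rng_f = substream(seed, "coverage-female")
    male: dict[str, np.ndarray] = {}
    female: dict[str, np.ndarray] = {}
    truth: dict[str, str] = {}
    for contig in sorted(params.contig_lengths):
        length = params.contig_lengths[contig]
        cls = params.contig_classes[contig]
        truth[contig] = cls
        mu_m = params.haploid_depth * _DOSE[("male", cls)]
        mu_f = params.haploid_depth * _DOSE[("female", cls)]
        male[contig] = _draw(rng_m, mu_m, params.dispersion, length)
        female[contig] = _draw(rng_f, mu_f, params.dispersion, length)
    return DepthTable(male), DepthTable(female), truth
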