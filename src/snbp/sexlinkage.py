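"""Coverage-based sex-chromosome assignment of contigs.

Window medians of per-base depth, a two-peak kernel-density threshold,
female/male depth ratios to split X from Y, single-copy-ortholog majority
voting for Muller elements, and genetic-cross linkage classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from snbp.errors import UnimodalCoverageError
from snbp.io.depth import DepthTable

DEFAULT_WINDOW = 10_000
MIN_PARTIAL_FRACTION = 0.10

# female/male depth-ratio cutoffs; operational defaults, configurable
Y_RATIO_MAX = 0.25
X_RATIO_RANGE = (0.75, 1.5)

MULLER_MIN_ORTHOLOGS = 3
MULLER_MIN_AGREEMENT = 0.80


@dataclass
class CoverageProfile:
    contig: str
    window: int
    window_medians: np.ndarray
    contig_median: float


@dataclass
class ContigCall:
    contig: str
    klass: str  # autosomal | sex_linked | X | Y | ambiguous
    threshold: float
    peaks: tuple[float, float]
    evidence: str = "coverage"  # coverage | female_ratio | ortholog


def window_medians(
    table: DepthTable, window: int = DEFAULT_WINDOW
) -> dict[str, CoverageProfile]:
    """Median depth per half-open window of each contig.

    The trailing partial window is kept when it spans at least 10% of the
    window length, otherwise merged into the previous window. Empty contigs
    are skipped with a warning.
    """
    if window < 100:
        raise ValueError("window must be >= 100")
    profiles: dict[str, CoverageProfile] = {}
    for contig in table.contigs:
        depth = table.depth(contig)
        n = len(depth)
        if n == 0:
            warnings.warn(f"contig {contig!r} is empty; skipped")
            continue
        edges = list(range(0, n, window))
        spans = [(s, min(s + window, n)) for s in edges]
        if len(spans) > 1 and (spans[-1][1] - spans[-1][0]) < MIN_PARTIAL_FRACTION * window:
            last = spans.pop()
            prev = spans.pop()
            spans.append((prev[0], last[1]))
        medians = np.array([float(np.median(depth[s:e])) for s, e in spans])
        profiles[contig] = CoverageProfile(
            contig=contig,
            window=window,
            window_medians=medians,
            contig_median=float(np.median(depth)),
        )
    return profiles


def find_two_peaks(window_medians_all: np.ndarray) -> tuple[float, float]:
    """Two highest-density local maxima of the window-median distribution.

    Gaussian KDE with Silverman's bandwidth on a 512-point grid over
    [0, 99.5th percentile]. Raises UnimodalCoverageError with fewer than
    two maxima.
    """
    values = np.asarray(window_medians_all, dtype=float)
    if len(values) < 200:
        raise ValueError(f"need >= 200 window medians, got {len(values)}")
    kde = gaussian_kde(values, bw_method="silverman")
    hi = float(np.percentile(values, 99.5))
    grid = np.linspace(0.0, hi, 512)
    density = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    is_max = (density[interior] > density[interior - 1]) & (
        density[interior] >= density[interior + 1]
    )
    maxima = interior[is_max]
    if len(maxima) < 2:
        raise UnimodalCoverageError(
            "coverage density has fewer than two local maxima; "
            "supply a manual threshold"
        )
    top2 = maxima[np.argsort(density[maxima])[-2:]]
    peaks = sorted(float(grid[i]) for i in top2)
    return peaks[0], peaks[1]


def classify_contigs(
    profiles: dict[str, CoverageProfile], peaks: tuple[float, float]
) -> list[ContigCall]:
    """Split contigs at the midpoint of the two coverage peaks."""
    p1, p2 = peaks
    if not p1 < p2:
        raise ValueError(f"peaks must satisfy p1 < p2, got {peaks}")
    threshold = (p1 + p2) / 2.0
    calls = []
    for contig in sorted(profiles):
        prof = profiles[contig]
        klass = "sex_linked" if prof.contig_median < threshold else "autosomal"
        calls.append(
            ContigCall(
                contig=contig,
                klass=klass,
                threshold=threshold,
                peaks=(p1, p2),
                evidence="coverage",
            )
        )
    return calls


def split_x_y(
    male_profiles: dict[str, CoverageProfile],
    female_profiles: dict[str, CoverageProfile],
    sex_linked: list[str],
    y_ratio_max: float = Y_RATIO_MAX,
    x_ratio_range: tuple[float, float] = X_RATIO_RANGE,
) -> dict[str, str]:
    """Assign sex-linked contigs to X or Y from the female/male depth ratio.

    The ratio is female median over the male diploid-equivalent depth
    (2 x the contig's male median, since a sex-linked contig is haploid in
    males): ratio < y_ratio_max -> Y (females lack the Y); ratio within
    x_ratio_range -> X (females carry two X doses, matching the male
    autosomal level); anything else, or zero male depth, -> ambiguous.
    """
    out: dict[str, str] = {}
    for contig in sex_linked:
        if contig not in male_profiles or contig not in female_profiles:
            raise KeyError(f"both sexes' depth required for contig {contig!r}")
        male_med = male_profiles[contig].contig_median
        female_med = female_profiles[contig].contig_median
        if male_med == 0:
            out[contig] = "ambiguous"
            continue
        ratio = female_med / (2.0 * male_med)
        if ratio < y_ratio_max:
            out[contig] = "Y"
        elif x_ratio_range[0] <= ratio <= x_ratio_range[1]:
            out[contig] = "X"
        else:
            out[contig] = "ambiguous"
    return out


def assign_muller(
    contig_orthologs: list[str], ortholog_to_muller: dict[str, str]
) -> str | None:
    """Majority Muller element among a contig's single-copy orthologs.

    Requires >= 3 placed orthologs and >= 80% agreement, else None.
    """
    placed = [ortholog_to_muller[o] for o in contig_orthologs if o in ortholog_to_muller]
    if len(placed) < MULLER_MIN_ORTHOLOGS:
        return None
    counts: dict[str, int] = {}
    for m in placed:
        counts[m] = counts.get(m, 0) + 1
    best = max(sorted(counts), key=lambda m: counts[m])
    if counts[best] / len(placed) >= MULLER_MIN_AGREEMENT:
        return best
    return None


def cross_linkage(
    mother_genotype: tuple[str, str] | str,
    father_genotype: str,
    f1_male_genotypes: list[str],
) -> str:
    """Classify a marker from F1 male inheritance in a genetic cross.

    F1 males inherit their X only from the mother and their Y only from
    the father; autosomal markers show both parental alleles across F1
    males.
    """
    if not f1_male_genotypes:
        raise ValueError("no F1 males genotyped")
    maternal = set(mother_genotype) if isinstance(mother_genotype, tuple) else {mother_genotype}
    paternal = {father_genotype}
    if maternal == paternal:
        return "uninformative"
    observed = set(f1_male_genotypes)
    if observed <= maternal and not (observed & (paternal - maternal)):
        return "X_linked"
    if observed <= paternal - maternal:
        return "Y_linked"
    if observed & maternal and observed & (paternal - maternal):
        return "autosomal"
    return "uninformative"
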