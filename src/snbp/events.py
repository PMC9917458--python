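"""Amplification/loss event inference and enrichment statistics.

Amplification = five or more copies of one gene at one genomic location
(counts are never summed across locations). Losses are placed by Dollo
parsimony: the gene is gained once at its origin node and the minimum set
of branches explains all absent/pseudogene leaves. Event-location classes
are A (all autosomes combined), X, Y, X/Y (either sex chromosome) and U
(unknown); only X, Y and X/Y count as sex-linked.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import dendropy
from scipy import stats

from snbp.errors import MissingDataError, ParseError
from snbp.io.tables import CopyNumberMatrix, LOCATION_CLASSES
from snbp.io.trees import find_node, node_id, parse_tree

SEX_LINKED_CLASSES = frozenset({"X", "Y", "X/Y"})
AMPLIFICATION_MIN_COPIES = 5

LOST_STATES = frozenset({"absent", "pseudogene"})


@dataclass(frozen=True)
class AmplifiedLocus:
    gene: str
    species: str
    location: str
    copies: int
    locus_group: str | None = None


@dataclass(frozen=True)
class Event:
    gene: str
    clade: str  # node id of the branch (child node) carrying the event
    kind: str  # amplification | loss
    location: str
    copies: int = 0

    def __post_init__(self):
        if self.kind not in ("amplification", "loss"):
            raise ValueError(f"bad event kind {self.kind!r}")


EventSet = list  # list[Event]


def call_amplifications(
    matrix: CopyNumberMatrix, min_copies: int = AMPLIFICATION_MIN_COPIES
) -> list[AmplifiedLocus]:
    """Loci with >= min_copies copies at one specific location."""
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    out = []
    for (gene, species, location), count in matrix.items():
        if count >= min_copies:
            out.append(
                AmplifiedLocus(
                    gene=gene,
                    species=species,
                    location=location,
                    copies=count,
                    locus_group=matrix.locus_group(gene, species, location),
                )
            )
    return out


def _dollo_losses(
    tree: dendropy.Tree,
    origin: dendropy.Node,
    lost_species: set[str],
) -> list[str]:
    """Minimal branch set under ``origin`` explaining all lost leaves.

    A branch belongs to the set iff its subtree's (known) leaves are all
    lost and its parent's subtree is not all-lost (or it is the origin
    itself). Leaves without data are treated as retained, the conservative
    choice.
    """
    all_lost: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            all_lost[id(node)] = label in lost_species
        else:
            children = node.child_nodes()
            all_lost[id(node)] = all(all_lost[id(c)] for c in children)

    events: list[str] = []

    def walk(node, parent_all_lost: bool):
        if all_lost[id(node)]:
            if not parent_all_lost:
                events.append(node_id(node))
            return  # no further events possible below an all-lost branch
        for child in node.child_nodes():
            walk(child, False)

    walk(origin, False)
    return sorted(events)


def infer_events(
    amplified: list[AmplifiedLocus],
    presence: dict[tuple[str, str], str],
    tree,
    origins: dict[str, str],
) -> list[Event]:
    """Collapse amplified loci into independent events and infer Dollo losses.

    Amplified loci sharing a (gene, locus_group) across species collapse to
    a single event at the MRCA of the carrying species; loci without an
    asserted homology group yield one event per species. Loss events for
    each gene are the minimal Dollo branch set below its origin node.
    """
    if isinstance(tree, str):
        tree = parse_tree(tree)
    tree_species = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for (gene, species) in presence:
        if species not in tree_species:
            raise MissingDataError(f"species {species!r} missing from tree")

    events: list[Event] = []
    grouped: dict[tuple[str, str], list[AmplifiedLocus]] = {}
    for loc in amplified:
        if loc.species not in tree_species:
            raise MissingDataError(f"species {loc.species!r} missing from tree")
        if loc.locus_group is not None:
            grouped.setdefault((loc.gene, loc.locus_group), []).append(loc)
        else:
            events.append(
                Event(loc.gene, loc.species, "amplification", loc.location, loc.copies)
            )
    for (gene, _group), loci in sorted(grouped.items()):
        species = sorted({l.species for l in loci})
        if len(species) == 1:
            clade = species[0]
        else:
            taxa = [
                tree.taxon_namespace.get_taxon(s) for s in species
            ]
            mrca = tree.mrca(taxa=taxa)
            clade = node_id(mrca)
        location = loci[0].location
        copies = max(l.copies for l in loci)
        events.append(Event(gene, clade, "amplification", location, copies))

    genes = sorted({g for (g, _s) in presence})
    for gene in genes:
        origin_id = origins.get(gene)
        if origin_id is None:
            raise MissingDataError(f"no origin node provided for gene {gene!r}")
        origin = find_node(tree, origin_id)
        if origin is None:
            raise MissingDataError(f"origin node {origin_id!r} not found in tree")
        lost = {
            s for (g, s), status in presence.items()
            if g == gene and status in LOST_STATES
        }
        for clade in _dollo_losses(tree, origin, lost):
            events.append(Event(gene, clade, "loss", "U"))
    return events


def sex_linkage_enrichment(
    events: list[Event], null_p: float = 1.0 / 3.0, continuity_chi2: bool = False
) -> tuple[float, float]:
    """(proportion of sex-linked events, two-sided p against ``null_p``).

    Sex-linked means location class X, Y or X/Y; A and U count only in the
    denominator. Default test: exact binomial, two-sided by the
    minimum-likelihood rule; ``continuity_chi2`` switches to a chi-square
    with Yates correction.
    """
    if not events:
        raise ValueError("no events")
    n = len(events)
    k = sum(1 for e in events if e.location in SEX_LINKED_CLASSES)
    if continuity_chi2:
        expected_k = n * null_p
        expected_not = n * (1 - null_p)
        chi2 = (abs(k - expected_k) - 0.5) ** 2 / expected_k + (
            abs((n - k) - expected_not) - 0.5
        ) ** 2 / expected_not
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        p = float(stats.binomtest(k, n, null_p, alternative="two-sided").pvalue)
    return k / n, p


def fisher_exact_2x2(table: list[list[int]]) -> float:
    """Two-sided Fisher's exact p by exact hypergeometric enumeration.

    Sums the probabilities of all tables (with the observed margins) whose
    probability does not exceed the observed one, in exact integer
    arithmetic.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c
    # P(x) ~ C(r1, x) * C(n - r1, c1 - x); shared denominator cancels
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    weights = {
        x: math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)
    }
    observed = weights[a]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= observed)
    return tail / total


def retention_contingency(
    records: list[tuple[str, str]]
) -> tuple[list[list[int]], float]:
    """2x2 post-fusion fate table (rows: linkage, cols: fate) + Fisher p.

    Each record is (linkage in {sex, autosome},
    fate in {degenerated_or_relocated, retained}).
    """
    if not records:
        raise ValueError("no fate records")
    table = [[0, 0], [0, 0]]
    for linkage, fate in records:
        if linkage not in ("sex", "autosome"):
            raise ValueError(f"unknown linkage label {linkage!r}")
        if fate not in ("degenerated_or_relocated", "retained"):
            raise ValueError(f"unknown fate label {fate!r}")
        i = 0 if linkage == "sex" else 1
        j = 0 if fate == "degenerated_or_relocated" else 1
        table[i][j] += 1
    return table, fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# packaged fixtures (transcribed event tables; see the files' comments)

_AMP_TOKEN = re.compile(r"^(\d+)\s*(X/Y|A|X|Y|U)$")


def parse_amplification_entry(entry: str) -> dict[str, int]:
    """Parse an event-list entry like ``2A;1X;2Y;4X/Y;1U`` into counts."""
    entry = entry.strip()
    if entry in ("0", ""):
        return {}
    counts: dict[str, int] = {}
    for token in entry.split(";"):
        token = token.strip()
        m = _AMP_TOKEN.match(token)
        if not m:
            raise ParseError(f"bad amplification token {token!r}")
        count, location = int(m.group(1)), m.group(2)
        if location not in LOCATION_CLASSES:
            raise ParseError(f"unknown location class {location!r}")
        counts[location] = counts.get(location, 0) + count
    return counts


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("snbp.data").joinpath(name)))


def load_amplification_fixture(path=None) -> dict[str, dict[str, int]]:
    """gene -> location class -> number of independent amplification events."""
    path = Path(path) if path else _fixture_path("table2_amplifications.tsv")
    out: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene", "amplification_events"]:
            raise ParseError(f"unexpected header {header}", path=path, line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"expected 2 columns, got {len(fields)}", path=path, line=lineno
                )
            gene, entry = fields
            out[gene] = parse_amplification_entry(entry)
    return out


def amplification_event_list(fixture: dict[str, dict[str, int]]) -> list[Event]:
    """Flatten a fixture into one Event per independent amplification."""
    events = []
    for gene in sorted(fixture):
        for location in sorted(fixture[gene]):
            for i in range(fixture[gene][location]):
                events.append(
                    Event(gene, f"{gene}:{location}:{i + 1}", "amplification", location)
                )
    return events


def load_fusion_fates_fixture(path=None) -> list[tuple[str, str]]:
    """(linkage, fate) records for genes rearranged by chromosomal fusions."""
    path = Path(path) if path else _fixture_path("fig5_fusion_fates.tsv")
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["case", "linkage", "fate"]:
            raise ParseError(f"unexpected header {header}", path=path, line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 columns, got {len(fields)}", path=path, line=lineno
                )
            _case, linkage, fate = fields
            records.append((linkage, fate))
    return records


def load_montium_fixture(
    matrix_path=None, tree_path=None
) -> tuple[dict[tuple[str, str], str], dendropy.Tree, dict[str, str]]:
    """(presence matrix, species tree, per-gene origin nodes).

    The matrix marks each (gene, species) as present (1) or pseudogene (P);
    every gene predates the clade, so each origin is the tree root.
    """
    matrix_path = Path(matrix_path) if matrix_path else _fixture_path(
        "fig6_montium_matrix.tsv"
    )
    tree_path = Path(tree_path) if tree_path else _fixture_path("montium_tree.nwk")
    tree = parse_tree(tree_path.read_text())
    presence: dict[tuple[str, str], str] = {}
    with open(matrix_path) as fh:
        lines = [
            l.rstrip("\n")
            for l in fh
            if l.strip() and not l.startswith("#")
        ]
    header = lines[0].split("\t")
    if header[0] != "gene":
        raise ParseError(f"first column must be 'gene', got {header[0]!r}", path=matrix_path)
    species = header[1:]
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"ragged row {fields[0]!r}", path=matrix_path)
        gene = fields[0]
        for sp, value in zip(species, fields[1:]):
            if value == "1":
                presence[(gene, sp)] = "present"
            elif value in ("P", "0"):
                presence[(gene, sp)] = "pseudogene" if value == "P" else "absent"
            else:
                raise ParseError(f"bad cell {value!r} for {gene}/{sp}", path=matrix_path)
    root = node_id(tree.seed_node)
    origins = {gene: root for gene in {g for (g, _s) in presence}}
    return presence, tree, origins
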