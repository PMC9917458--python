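"""Gene gain/loss/amplification simulation on a species tree.

Events are Poisson along each branch. Gains create a new single-copy gene
in their chromosome class; losses remove a randomly chosen present gene
entirely (optionally leaving a pseudogene); amplifications add >= 2 copies
of a present gene at a location drawn with probability ``sex_bias`` on a
sex chromosome. Replaying the emitted event log down the tree reproduces
the copy-number matrix exactly.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy

from snbp.errors import ConfigError
from snbp.io.tables import CopyNumberMatrix
from snbp.io.trees import node_id, parse_tree
from snbp.simulate.config import SimulationConfig, CHROMOSOME_CLASSES
from snbp.simulate.rng import substream

PRESENT, PSEUDOGENE, ABSENT = "present", "pseudogene", "absent"


@dataclass(frozen=True)
class TrueEvent:
    branch: str  # id of the child node of the branch
    gene: str
    kind: str  # gain | loss | amplification
    location: str  # A | X | Y
    copies: int  # gain: 1; amplification: added copies >= 2; loss: 0
    locus_group: str | None = None
    pseudogene: bool = False  # for losses: leave a pseudogene relic

    def __post_init__(self):
        if self.kind not in ("gain", "loss", "amplification"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.kind == "amplification" and self.copies < 2:
            raise ValueError("amplification copy count must be >= 2")


@dataclass
class TrueEventLog:
    """Simulator ground truth against which inference stages are scored."""

    events: list[TrueEvent] = field(default_factory=list)
    true_omega: dict[str, float] = field(default_factory=dict)
    true_alpha: dict[str, float] = field(default_factory=dict)
    true_contig_class: dict[str, str] = field(default_factory=dict)
    origins: dict[str, str] = field(default_factory=dict)  # gene -> origin node id


def resolve_tree(tree_spec, seed: int) -> dendropy.Tree:
    """Resolve a newick string or (n_species, birth_rate) into a tree."""
    if isinstance(tree_spec, str):
        return parse_tree(tree_spec)
    if isinstance(tree_spec, (tuple, list)) and len(tree_spec) == 2:
        n_species, birth_rate = int(tree_spec[0]), float(tree_spec[1])
        if n_species < 2:
            raise ConfigError("tree must have >= 2 leaves")
        if birth_rate <= 0:
            raise ConfigError("birth rate must be > 0")
        from dendropy.simulate import treesim

        taxa = dendropy.TaxonNamespace(
            [f"sp{i:02d}" for i in range(1, n_species + 1)]
        )
        return treesim.birth_death_tree(
            birth_rate=birth_rate,
            death_rate=0.0,
            num_extant_tips=n_species,
            taxon_namespace=taxa,
            rng=_random.Random(seed),
        )
    raise ConfigError(f"bad tree_spec {tree_spec!r}")


class _GeneState:
    __slots__ = ("copies", "status")

    def __init__(self, copies: dict[str, int] | None = None, status: str = PRESENT):
        self.copies = dict(copies or {})
        self.status = status

    def clone(self) -> "_GeneState":
        return _GeneState(self.copies, self.status)

    @property
    def present(self) -> bool:
        return self.status == PRESENT and sum(self.copies.values()) > 0

    def main_location(self) -> str:
        if not self.copies:
            return "A"
        return max(sorted(self.copies), key=lambda c: self.copies[c])


def _apply_event(state: dict[str, _GeneState], ev: TrueEvent) -> None:
    if ev.kind == "gain":
        state[ev.gene] = _GeneState({ev.location: 1})
    elif ev.kind == "loss":
        gs = state[ev.gene]
        gs.copies = {}
        gs.status = PSEUDOGENE if ev.pseudogene else ABSENT
    else:  # amplification
        gs = state[ev.gene]
        gs.copies[ev.location] = gs.copies.get(ev.location, 0) + ev.copies


def simulate_gene_family_history(
    config: SimulationConfig,
) -> tuple[CopyNumberMatrix, dict[tuple[str, str], str], TrueEventLog]:
    """Simulate copy-number evolution; return (matrix, presence matrix, log).

    The presence matrix maps (gene, species) to present/pseudogene/absent.
    """
    config.validate()
    tree = resolve_tree(config.tree_spec, config.seed)
    if len(tree.leaf_nodes()) < 2:
        raise ConfigError("tree must have >= 2 leaves")
    rng = substream(config.seed, "history")

    root_state: dict[str, _GeneState] = {}
    log = TrueEventLog()
    root_id = node_id(tree.seed_node)
    for i in range(config.n_root_genes):
        gene = f"gene{i + 1:02d}"
        root_state[gene] = _GeneState({"A": 1})
        log.origins[gene] = root_id

    gain_counter = 0
    amp_counter = 0
    states: dict[int, dict[str, _GeneState]] = {
        id(tree.seed_node): root_state
    }

    loss_rate = sum(config.rates[c].loss for c in config.rates)
    amp_rate = sum(config.rates[c].amplification for c in config.rates)

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_state = states[id(node.parent_node)]
        state = {g: gs.clone() for g, gs in parent_state.items()}
        blen = node.edge.length or 0.0
        branch = node_id(node)
        if blen > 0:
            # gains are class-specific
            for cls in CHROMOSOME_CLASSES:
                n_gain = rng.poisson(config.rates[cls].gain * blen)
                for _ in range(n_gain):
                    gain_counter += 1
                    gene = f"novel{gain_counter:03d}"
                    ev = TrueEvent(branch, gene, "gain", cls, 1)
                    _apply_event(state, ev)
                    log.events.append(ev)
                    log.origins[gene] = branch
            # losses remove a random present gene outright
            n_loss = rng.poisson(loss_rate * blen)
            for _ in range(n_loss):
                present = sorted(g for g, gs in state.items() if gs.present)
                if not present:
                    break
                gene = present[rng.integers(0, len(present))]
                pseudo = bool(rng.random() < config.pseudogene_fraction)
                ev = TrueEvent(
                    branch,
                    gene,
                    "loss",
                    state[gene].main_location(),
                    0,
                    pseudogene=pseudo,
                )
                _apply_event(state, ev)
                log.events.append(ev)
            # amplifications land on a sex chromosome with prob sex_bias
            n_amp = rng.poisson(amp_rate * blen)
            for _ in range(n_amp):
                present = sorted(g for g, gs in state.items() if gs.present)
                if not present:
                    break
                gene = present[rng.integers(0, len(present))]
                if rng.random() < config.sex_bias:
                    location = "X" if rng.random() < 0.5 else "Y"
                else:
                    location = "A"
                copies = 2 + int(rng.poisson(4))
                amp_counter += 1
                ev = TrueEvent(
                    branch,
                    gene,
                    "amplification",
                    location,
                    copies,
                    locus_group=f"amp{amp_counter:03d}",
                )
                _apply_event(state, ev)
                log.events.append(ev)
        states[id(node)] = state

    matrix = CopyNumberMatrix()
    presence: dict[tuple[str, str], str] = {}
    all_genes = sorted(log.origins)
    for leaf in tree.leaf_node_iter():
        species = leaf.taxon.label
        state = states[id(leaf)]
        for gene in all_genes:
            gs = state.get(gene)
            if gs is None:
                presence[(gene, species)] = ABSENT
                continue
            presence[(gene, species)] = gs.status if not gs.present else PRESENT
            for cls, count in sorted(gs.copies.items()):
                if count > 0:
                    matrix.set(gene, species, cls, count)
    return matrix, presence, log


def replay_event_log(
    config: SimulationConfig, log: TrueEventLog
) -> CopyNumberMatrix:
    """Independently replay ``log`` down the tree to rebuild the matrix.

    Used as the oracle for the simulator's self-consistency invariant.
    """
    tree = resolve_tree(config.tree_spec, config.seed)
    by_branch: dict[str, list[TrueEvent]] = {}
    for ev in log.events:
        by_branch.setdefault(ev.branch, []).append(ev)

    root_state: dict[str, _GeneState] = {}
    root_id = node_id(tree.seed_node)
    for gene, origin in log.origins.items():
        if origin == root_id and gene.startswith("gene"):
            root_state[gene] = _GeneState({"A": 1})

    states = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        state = {g: gs.clone() for g, gs in states[id(node.parent_node)].items()}
        for ev in by_branch.get(node_id(node), []):
            _apply_event(state, ev)
        states[id(node)] = state

    matrix = CopyNumberMatrix()
    for leaf in tree.leaf_node_iter():
        species = leaf.taxon.label
        for gene, gs in states[id(leaf)].items():
            if gs.present:
                for cls, count in sorted(gs.copies.items()):
                    if count > 0:
                        matrix.set(gene, species, cls, count)
    return matrix
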