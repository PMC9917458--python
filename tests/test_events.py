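"""Event inference and enrichment statistics, with brute-force oracles."""

import itertools
import math
import random

import pytest
from scipy.stats import fisher_exact as scipy_fisher

from snbp.errors import MissingDataError, ParseError
from snbp.events import (
    AmplifiedLocus,
    Event,
    amplification_event_list,
    call_amplifications,
    fisher_exact_2x2,
    infer_events,
    load_amplification_fixture,
    load_fusion_fates_fixture,
    load_montium_fixture,
    parse_amplification_entry,
    retention_contingency,
    sex_linkage_enrichment,
)
from snbp.io.tables import CopyNumberMatrix
from snbp.io.trees import parse_tree

# ---------------------------------------------------------------------------
# brute-force minimal-cover oracle for Dollo losses


def dollo_oracle_min_events(newick: str, lost_leaves: set[str]) -> int:
    """Minimum number of branch cuts disconnecting exactly the lost leaves."""
    tree = parse_tree(newick)
    edges = [
        n for n in tree.preorder_node_iter() if n.parent_node is not None or True
    ]
    # an "event" on node n removes the whole clade under n
    nodes = list(tree.preorder_node_iter())
    leaf_sets = []
    for n in nodes:
        leaf_sets.append(frozenset(lf.taxon.label for lf in n.leaf_iter()))
    all_leaves = leaf_sets[0]
    target = frozenset(lost_leaves)
    if not target:
        return 0
    best = None
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(range(len(nodes)), r):
            covered = frozenset().union(*(leaf_sets[i] for i in combo))
            if covered == target:
                best = r
                break
        if best is not None:
            break
    return best


class TestCallAmplifications:
    def test_five_copies_amplified(self):
        m = CopyNumberMatrix()
        m.set("g", "sp", "X", 5)
        assert len(call_amplifications(m)) == 1

    def test_four_copies_not_amplified(self):
        m = CopyNumberMatrix()
        m.set("g", "sp", "X", 4)
        assert call_amplifications(m) == []

    def test_copies_not_summed_across_locations(self):
        m = CopyNumberMatrix()
        m.set("g", "sp", "X", 3)
        m.set("g", "sp", "A", 2)
        assert call_amplifications(m) == []

    def test_min_copies_floor(self):
        m = CopyNumberMatrix()
        with pytest.raises(ValueError):
            call_amplifications(m, min_copies=1)


class TestInferEvents:
    NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"

    def test_spec_example_two_losses(self):
        # gene gained at root, present only in A -> losses on B and mrca(C,D)
        presence = {
            ("g", "A"): "present",
            ("g", "B"): "absent",
            ("g", "C"): "absent",
            ("g", "D"): "pseudogene",
        }
        events = infer_events([], presence, self.NEWICK, {"g": "A|B|C|D"})
        losses = [e for e in events if e.kind == "loss"]
        assert len(losses) == 2
        assert {e.clade for e in losses} == {"B", "C|D"}

    def test_single_species_amplification_is_one_event(self):
        amp = [AmplifiedLocus("g", "A", "X", 6, locus_group=None)]
        events = infer_events(amp, {}, self.NEWICK, {})
        assert len(events) == 1
        assert events[0].kind == "amplification" and events[0].clade == "A"

    def test_shared_locus_group_collapses_to_mrca(self):
        amp = [
            AmplifiedLocus("g", "A", "X", 6, locus_group="grp1"),
            AmplifiedLocus("g", "B", "X", 8, locus_group="grp1"),
        ]
        events = infer_events(amp, {}, self.NEWICK, {})
        assert len(events) == 1
        assert events[0].clade == "A|B"

    def test_distinct_groups_stay_independent(self):
        amp = [
            AmplifiedLocus("g", "A", "X", 6, locus_group="grp1"),
            AmplifiedLocus("g", "B", "X", 8, locus_group="grp2"),
        ]
        events = infer_events(amp, {}, self.NEWICK, {})
        assert len(events) == 2

    def test_species_missing_from_tree_errors(self):
        presence = {("g", "NOPE"): "absent"}
        with pytest.raises(MissingDataError):
            infer_events([], presence, self.NEWICK, {"g": "A|B|C|D"})

    def test_losses_match_brute_force_on_random_patterns(self):
        newick = "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
        leaves = list("abcdefgh")
        rng = random.Random(7)
        for _ in range(30):
            lost = {l for l in leaves if rng.random() < 0.4}
            if len(lost) == len(leaves):
                lost.discard(rng.choice(leaves))
            presence = {
                ("x", l): ("absent" if l in lost else "present") for l in leaves
            }
            events = infer_events(
                [], presence, newick, {"x": "|".join(sorted(leaves))}
            )
            n_losses = sum(1 for e in events if e.kind == "loss")
            assert n_losses == dollo_oracle_min_events(newick, lost), lost


class TestSexLinkageEnrichment:
    @staticmethod
    def events(n_sex, n_auto, n_unknown=0):
        out = []
        for i in range(n_sex):
            out.append(Event("g", f"s{i}", "amplification", "X"))
        for i in range(n_auto):
            out.append(Event("g", f"a{i}", "amplification", "A"))
        for i in range(n_unknown):
            out.append(Event("g", f"u{i}", "amplification", "U"))
        return out

    def test_16_of_20_is_80_percent(self):
        # 14 X/Y/XY + 2 U + 4 A mimics the headline accounting shape
        evs = self.events(16, 2, 2)
        prop, _p = sex_linkage_enrichment(evs)
        assert prop == pytest.approx(0.80)

    def test_exact_binomial_p_matches_term_summation(self):
        evs = self.events(16, 4)
        _prop, p = sex_linkage_enrichment(evs)
        # independent term-by-term minimum-likelihood summation
        n, k, p0 = 20, 16, 1 / 3
        pmf = [
            math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)
        ]
        expected = sum(x for x in pmf if x <= pmf[k] * (1 + 1e-7))
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(2.5e-5, abs=5e-6)

    def test_all_autosomal_lower_tail(self):
        evs = self.events(0, 12)
        prop, p = sex_linkage_enrichment(evs)
        assert prop == 0.0
        assert 0 < p < 0.05

    def test_u_class_in_denominator_only(self):
        evs = self.events(3, 0, 3)
        prop, _ = sex_linkage_enrichment(evs)
        assert prop == pytest.approx(0.5)

    def test_permutation_invariance(self):
        evs = self.events(10, 5, 2)
        rng = random.Random(1)
        results = set()
        for _ in range(10):
            rng.shuffle(evs)
            results.add(sex_linkage_enrichment(list(evs)))
        assert len(results) == 1

    def test_zero_events_errors(self):
        with pytest.raises(ValueError):
            sex_linkage_enrichment([])

    def test_continuity_chi2_variant(self):
        evs = self.events(16, 4)
        _prop, p = sex_linkage_enrichment(evs, continuity_chi2=True)
        assert 1e-6 < p < 1e-3


class TestFisherExact:
    def test_retention_table(self):
        assert fisher_exact_2x2([[3, 5], [0, 16]]) == pytest.approx(
            0.02766798418972332, abs=1e-12
        )

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_five_full_enumeration(self):
        # only the two extreme tables have probability <= observed: 2/252
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_agrees_with_scipy_on_random_tables(self):
        rng = random.Random(3)
        for _ in range(300):
            cells = [rng.randint(0, 10) for _ in range(4)]
            if sum(cells) == 0 or sum(cells) > 30:
                continue
            table = [cells[:2], cells[2:]]
            if sum(table[0]) == 0 and sum(table[1]) == 0:
                continue
            mine = fisher_exact_2x2(table)
            _odds, ref = scipy_fisher(table, alternative="two-sided")
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12), table


class TestRetentionContingency:
    def test_fig5_counts(self):
        records = [("sex", "degenerated_or_relocated")] * 3 + [
            ("sex", "retained")
        ] * 5 + [("autosome", "retained")] * 16
        table, p = retention_contingency(records)
        assert table == [[3, 5], [0, 16]]
        assert round(p, 2) == 0.03

    def test_all_retained_p_one(self):
        records = [("sex", "retained")] * 4 + [("autosome", "retained")] * 4
        _table, p = retention_contingency(records)
        assert p == pytest.approx(1.0)

    def test_single_record_p_one(self):
        _table, p = retention_contingency([("sex", "retained")])
        assert p == pytest.approx(1.0)

    def test_unknown_fate_rejected(self):
        with pytest.raises(ValueError):
            retention_contingency([("sex", "exploded")])


class TestFixtures:
    def test_parse_amplification_entry(self):
        assert parse_amplification_entry("2A;1X;2Y;4X/Y;1U") == {
            "A": 2,
            "X": 1,
            "Y": 2,
            "X/Y": 4,
            "U": 1,
        }
        assert parse_amplification_entry("0") == {}
        with pytest.raises(ParseError):
            parse_amplification_entry("2Q")

    def test_table2_fixture_totals(self):
        fixture = load_amplification_fixture()
        events = amplification_event_list(fixture)
        assert len(events) == 20

    def test_fusion_fates_margins(self):
        records = load_fusion_fates_fixture()
        assert len(records) == 24

    def test_montium_fixture_consistency(self):
        presence, tree, origins = load_montium_fixture()
        genes = {g for (g, _s) in presence}
        assert genes == {"CG14835", "Mst33A", "tHMG", "Mst77F", "Prtl99C", "CG34269"}
        assert len(tree.leaf_nodes()) == 11
        assert set(origins) == genes
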