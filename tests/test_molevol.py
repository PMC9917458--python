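"""Molecular-evolution unit tests with independent oracles.

The NG86 expected values below were computed (and frozen) with the
brute-force pathway-enumeration oracle implemented in this file before the
package implementation was checked against it.
"""

import itertools
import math

import pytest
from Bio.Seq import Seq

from snbp.errors import SaturationError
from snbp.molevol import (
    CodonAlignment,
    MKTable,
    fitch_ancestral,
    jukes_cantor,
    mk_build,
    mk_test,
    ng86_dnds,
    percentile_rank,
    pooled_mk_table,
)
from snbp.simulate import simulate_mk_counts
from snbp.simulate.config import MKParams

# ---------------------------------------------------------------------------
# independent NG86 oracle (pathway enumeration via Biopython translation)

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> tuple[float, float]:
    n = s = 0.0
    for pos in range(3):
        total = nonsyn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOPS:
                continue
            total += 1
            if _aa(mut) != _aa(codon):
                nonsyn += 1
        if total:
            n += nonsyn / total
            s += 1 - nonsyn / total
    return n, s


def oracle_diffs(c1: str, c2: str):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    nds, sds = [], []
    for order in itertools.permutations(positions):
        cur, nd, sd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if _aa(cur) != _aa(nxt):
                nd += 1
            else:
                sd += 1
            cur = nxt
        if ok:
            nds.append(nd)
            sds.append(sd)
    if not nds:
        return None
    return sum(nds) / len(nds), sum(sds) / len(sds)


def oracle_dnds(s1: str, s2: str):
    n_sites = s_sites = nd = sd = 0.0
    for i in range(len(s1) // 3):
        c1, c2 = s1[3 * i : 3 * i + 3], s2[3 * i : 3 * i + 3]
        d = oracle_diffs(c1, c2)
        if d is None:
            continue
        n1, sx1 = oracle_sites(c1)
        n2, sx2 = oracle_sites(c2)
        n_sites += (n1 + n2) / 2
        s_sites += (sx1 + sx2) / 2
        nd += d[0]
        sd += d[1]
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return n_sites, s_sites, nd, sd, jc(nd / n_sites), jc(sd / s_sites)


# fixed 30-codon toy pair shipped as an inline fixture
PAIR_1 = (
    "ATGGCTAAGCGTTTACCGGAAGATCTGTGTTTTGGTCATATTAAAATGAACCCACAGAGATCT"
    "ACCGTTTGGTACGATGCTGAAGGTAAA"
)
PAIR_2 = (
    "ATGGCAAAACGTCTACCGGAGGATTTGTGTTATGGTCACATTAGAATGAATCCAGAGAGATCG"
    "ACCGTATGGTATGACGCAGAAGGTAGA"
)


class TestNG86:
    def test_identical_sequences(self):
        aln = CodonAlignment({"a": PAIR_1, "b": PAIR_1})
        r = ng86_dnds(aln)
        assert r.dn == 0.0 and r.ds == 0.0
        assert r.omega is None  # flagged undefined

    def test_symmetry_under_swap(self):
        r1 = ng86_dnds(CodonAlignment({"a": PAIR_1, "b": PAIR_2}))
        r2 = ng86_dnds(CodonAlignment({"a": PAIR_2, "b": PAIR_1}))
        assert r1 == r2

    def test_thirty_codon_fixture_matches_frozen_oracle_values(self):
        r = ng86_dnds(CodonAlignment({"a": PAIR_1, "b": PAIR_2}))
        # values frozen from the oracle above
        assert r.n_sites == pytest.approx(70.5)
        assert r.s_sites == pytest.approx(19.5)
        assert r.nd == pytest.approx(4.0)
        assert r.sd == pytest.approx(12.0)
        assert r.dn == pytest.approx(0.058998464295684144, abs=1e-12)
        assert r.ds == pytest.approx(1.28823862280575, abs=1e-10)
        assert r.omega == pytest.approx(0.04579777632127426, abs=1e-10)

    def test_matches_oracle_recomputed(self):
        r = ng86_dnds(CodonAlignment({"a": PAIR_1, "b": PAIR_2}))
        n, s, nd, sd, dn, ds = oracle_dnds(PAIR_1, PAIR_2)
        assert r.n_sites == pytest.approx(n)
        assert r.s_sites == pytest.approx(s)
        assert (r.nd, r.sd) == pytest.approx((nd, sd))
        assert (r.dn, r.ds) == pytest.approx((dn, ds), abs=1e-12)

    def test_saturation_flagged(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.8)

    def test_gapped_codons_skipped(self):
        aln = CodonAlignment({"a": "ATG---AAA", "b": "ATGCCCAAA"})
        r = ng86_dnds(aln)
        assert r.n_codons_compared == 2


class TestMKBuild:
    # four ingroup alleles over two codons + outgroup
    def test_no_variation_all_zero(self):
        ingroup = {f"a{i}": "ATGAAA" for i in range(4)}
        t = mk_build(ingroup, "ATGAAA")
        assert (t.dn, t.ds, t.pn, t.ps) == (0, 0, 0, 0)

    def test_fixed_nonsyn_plus_syn_polymorphism(self):
        # codon1 fixed difference ATG->TTG (M->L, nonsynonymous);
        # codon2 polymorphism AAA/AAG (K->K, synonymous) at frequency 0.5
        ingroup = {"a1": "ATGAAA", "a2": "ATGAAG", "a3": "ATGAAA", "a4": "ATGAAG"}
        t = mk_build(ingroup, "TTGAAA")
        assert (t.dn, t.ds, t.pn, t.ps) == (1, 0, 0, 1)

    def test_rare_polymorphism_removed_below_5_percent(self):
        # 40 alleles; one carries a derived nonsynonymous variant (freq 2.5%)
        ingroup = {f"a{i}": "ATGAAA" for i in range(39)}
        ingroup["a39"] = "ATGCAA"  # K -> Q at codon 2
        anc = "ATGAAA"
        kept = mk_build(ingroup, "ATGAAA", ancestor=anc, polarized=True)
        filtered = mk_build(
            ingroup, "ATGAAA", ancestor=anc, polarized=True, rare_threshold=0.05
        )
        assert kept.pn == 1
        assert filtered.pn == 0 and filtered.excluded_rare == 1

    def test_polarized_outgroup_lineage_changes_not_counted(self):
        # ingroup matches ancestor; outgroup differs -> no ingroup divergence
        ingroup = {f"a{i}": "ATGAAA" for i in range(4)}
        t = mk_build(ingroup, "ATGGAA", ancestor="ATGAAA", polarized=True)
        assert (t.dn, t.ds) == (0, 0)

    def test_multiallelic_site_excluded_and_counted(self):
        ingroup = {"a1": "AAA", "a2": "AAC", "a3": "AAG"}
        t = mk_build(ingroup, "AAA")
        assert (t.pn, t.ps) == (0, 0)
        assert t.excluded_multiallelic == 1


class TestMKTest:
    def test_alpha_formula(self):
        r = mk_test(MKTable(dn=20, ds=10, pn=5, ps=10))
        assert r.alpha == pytest.approx(0.75)

    def test_neutral_identity(self):
        r = mk_test(MKTable(dn=10, ds=10, pn=7, ps=7))
        assert r.alpha == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_chi2_hand_computed(self):
        # expected counts: 16.667, 13.333, 8.333, 6.667 -> chi2 = 4.5
        r = mk_test(MKTable(dn=20, ds=10, pn=5, ps=10))
        assert r.method == "chi2"
        assert r.statistic == pytest.approx(4.5)
        assert r.p_value == pytest.approx(0.0339, abs=5e-4)

    def test_p_matches_independent_chi2_cdf(self):
        # spec invariant: p equals an independent chi2 CDF evaluation to 1e-10
        r = mk_test(MKTable(dn=20, ds=10, pn=5, ps=10))
        independent = math.erfc(math.sqrt(r.statistic / 2))
        assert r.p_value == pytest.approx(independent, abs=1e-10)

    def test_fisher_fallback_on_small_expected(self):
        r = mk_test(MKTable(dn=2, ds=1, pn=1, ps=3))
        assert r.method == "fisher"

    def test_zero_margin_flagged(self):
        r = mk_test(MKTable(dn=0, ds=0, pn=3, ps=4))
        assert r.p_value is None and r.method == "undefined"

    def test_alpha_undefined_when_dn_zero(self):
        r = mk_test(MKTable(dn=0, ds=5, pn=3, ps=4))
        assert r.alpha is None

    def test_alpha_may_be_negative(self):
        r = mk_test(MKTable(dn=2, ds=10, pn=12, ps=10))
        assert r.alpha < 0


class TestRareFilterImprovesAlpha:
    def test_filtered_alpha_closer_to_truth(self):
        params = MKParams(
            alpha_true=0.5, mean_ds=10, mean_ps=10, rare_fraction=0.4, n_genes=500
        )
        records = simulate_mk_counts(params, seed=11)
        raw = mk_test(pooled_mk_table(records)).alpha
        filtered = mk_test(
            pooled_mk_table(records, rare_threshold=params.rare_freq_max)
        ).alpha
        assert abs(filtered - 0.5) < abs(raw - 0.5)
        assert raw < filtered


# ---------------------------------------------------------------------------
# Fitch/Hartigan ancestral states with a brute-force oracle


def _brute_force_states(newick: str, leaf_chars: dict[str, str], focal: str):
    """Enumerate all internal-state assignments; collect focal states over
    all minimum-change assignments."""
    import dendropy

    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True, rooting="force-rooted"
    )
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    alphabet = sorted(set(leaf_chars.values()))

    def key(node):
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        return leaves[0] if len(leaves) == 1 else "|".join(leaves)

    best_cost = None
    focal_states = set()
    for assignment in itertools.product(alphabet, repeat=len(internals)):
        states = {id(n): a for n, a in zip(internals, assignment)}
        for lf in tree.leaf_node_iter():
            states[id(lf)] = leaf_chars[lf.taxon.label]
        cost = sum(
            1
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
            and states[id(n)] != states[id(n.parent_node)]
        )
        node = next(n for n in tree.preorder_node_iter() if key(n) == focal)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            focal_states = {states[id(node)]}
        elif cost == best_cost:
            focal_states.add(states[id(node)])
    return frozenset(focal_states)


class TestFitchAncestral:
    def test_all_leaves_identical(self):
        tree = "((a,b),(c,d));"
        seqs = {l: "ACGT" for l in "abcd"}
        anc = fitch_ancestral(tree, seqs, "a|b|c|d")
        assert anc.sequence == "ACGT"
        assert not any(anc.mask)

    def test_single_derived_leaf_majority(self):
        tree = "((a,b),(c,d));"
        seqs = {"a": "T", "b": "A", "c": "A", "d": "A"}
        anc = fitch_ancestral(tree, seqs, "a|b|c|d")
        assert anc.sequence == "A"

    def test_random_six_leaf_matches_brute_force(self):
        import random

        tree = "(((a,b),c),((d,e),f));"
        rng = random.Random(42)
        for focal in ("a|b", "a|b|c", "d|e|f", "a|b|c|d|e|f"):
            for _ in range(25):
                chars = {l: rng.choice("ACGT") for l in "abcdef"}
                anc = fitch_ancestral(tree, {l: chars[l] for l in chars}, focal)
                assert anc.states[0] == _brute_force_states(tree, chars, focal), (
                    focal,
                    chars,
                )

    def test_missing_focal_node_errors(self):
        tree = "((a,b),(c,d));"
        seqs = {l: "A" for l in "abcd"}
        with pytest.raises(Exception, match="focal"):
            fitch_ancestral(tree, seqs, "nope")


class TestPercentileRank:
    def test_above_all(self):
        assert percentile_rank(10, [1, 2, 3]) == 100.0

    def test_tie_with_single_element(self):
        assert percentile_rank(5, [5]) == 50.0

    def test_direct_count_against_1_to_99(self):
        # strictly-below convention: 95 of 99 background values below 95.5
        assert percentile_rank(95.5, range(1, 100)) == pytest.approx(100 * 95 / 99)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank(1.0, [1.0, float("nan")])

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank(1.0, [])
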