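"""Pileup semantics, the three-condition het caller, repeat filtering,
allele-graph construction, Fisher pair testing against a hypergeometric
oracle, Bonferroni pruning, and haplotype assembly."""

import numpy as np
import pytest

from linkfrag.phasing_ref import (
    DELETION,
    AlleleGraph,
    HetVariant,
    PairTest,
    PileupColumn,
    allele_balance,
    assemble_haplotypes,
    bonferroni_prune,
    build_allele_graph,
    build_pileup,
    call_het_variants,
    compare_haplotypes,
    filter_repeat_regions,
    in_repeat_region,
)
from linkfrag.phasing_ref import test_pair_phase as pair_phase  # avoid test collection
from linkfrag.seqio import AlignmentRecord, CapabilityError, Genome

from conftest import fisher_two_sided_oracle


def _aln(read_id, start, bases, quals=None, ops=None):
    n = len(bases)
    return AlignmentRecord(
        read_id, "c", start, start + sum(l for o, l in (ops or [("M", n)]) if o in "M=XD"),
        0, n if ops is None else sum(l for o, l in ops if o in "M=XI"),
        ops=ops or [("M", n)], bases=bases,
        qualities=quals if quals is not None else [40] * n,
    )


class TestPileup:
    def test_uniform_column(self):
        ref = Genome({"c": "ACGT" * 5})
        alns = [_aln(f"r{i}", 0, "ACGTACGT") for i in range(10)]
        cols = build_pileup(alns, ref)
        col = cols[("c", 0)]
        assert col.counts == {"A": 10}
        assert col.n == 10

    def test_low_quality_base_counts_in_n_only(self):
        ref = Genome({"c": "AAAA"})
        alns = [_aln("hi", 0, "AAAA"), _aln("lo", 0, "AAAA", quals=[9, 40, 40, 40])]
        cols = build_pileup(alns, ref, quality_min=10)
        col = cols[("c", 0)]
        assert col.counts == {"A": 1}
        assert col.n == 2

    def test_deletion_distinct_allele(self):
        ref = Genome({"c": "ACGTACGT"})
        aln = _aln("r", 0, "ACGCGT", ops=[("M", 3), ("D", 2), ("M", 3)])
        cols = build_pileup([aln], ref)
        assert cols[("c", 3)].counts == {DELETION: 1}
        assert cols[("c", 4)].counts == {DELETION: 1}

    def test_insertion_keyed_at_anchor(self):
        ref = Genome({"c": "ACGTACGT"})
        aln = _aln("r", 0, "ACGTTTACGT", ops=[("M", 4), ("I", 2), ("M", 4)])
        cols = build_pileup([aln], ref)
        assert cols[("c", 3)].counts == {("INS", "TTT"): 1}

    def test_interval_only_records_rejected(self):
        rec = AlignmentRecord("r", "c", 0, 4, 0, 4)
        with pytest.raises(CapabilityError):
            build_pileup([rec], Genome({"c": "ACGT"}))


class TestHetCaller:
    def _col(self, n1, n2, n, a1="A", a2="C"):
        counts = {a1: n1, a2: n2}
        if n > n1 + n2:
            counts["G"] = 0  # filler allele with zero support
        return PileupColumn("c", 0, counts, n)

    @pytest.mark.parametrize(
        "n1,n2,n,called",
        [
            (6, 4, 12, True),   # all three conditions hold
            (7, 2, 9, False),   # balance: 7 > 2*2
            (5, 4, 30, False),  # coverage: 9 < 15
            (5, 5, 10, True),
            (4, 6, 12, True),   # order-agnostic
            (20, 10, 40, True),  # boundary n1 == 2*n2
            (21, 10, 40, False),
        ],
    )
    def test_three_conditions(self, n1, n2, n, called):
        out = call_het_variants([self._col(n1, n2, n)])
        assert bool(out) is called

    def test_exhaustive_grid_matches_direct_conditions(self):
        for n1 in range(0, 21):
            for n2 in range(0, n1 + 1):
                for n in (n1 + n2, n1 + n2 + 7, 2 * (n1 + n2) + 1, 60):
                    if n2 == 0:
                        continue
                    got = bool(call_het_variants([self._col(n1, n2, n)]))
                    expect = (
                        n1 + n2 >= 10
                        and (n1 + n2) >= n / 2
                        and n1 <= 2 * n2
                        and n2 <= 2 * n1
                    )
                    assert got is expect, (n1, n2, n)


class TestRepeatFilter:
    @pytest.mark.parametrize(
        "context,inside,expected",
        [
            ("AAAAA", 2, True),       # 5x 1-bp unit
            ("ATATATATAT", 4, True),  # 5x "AT"
            ("ATATATAT", 4, False),   # only 4 copies
            ("AAAA", 2, False),       # only 4 copies
            ("ACGTACGTAA", 5, False),
        ],
    )
    def test_unit_runs(self, context, inside, expected):
        pad = "GCGTC" * 8  # repeat-free padding
        ref = Genome({"c": pad + context + pad[::-1]})
        assert in_repeat_region(ref, "c", len(pad) + inside) is expected

    def test_filter_keeps_nonrepeat_variants(self):
        ref = Genome({"c": "GCGTC" * 4 + "AAAAA" + "GCGTC" * 4})
        vs = [HetVariant("c", 22, "A", 10, "T", 8), HetVariant("c", 3, "G", 10, "T", 8)]
        out = filter_repeat_regions(vs, ref)
        assert [v.position for v in out] == [3]


class TestAlleleGraph:
    def _variants(self):
        return [HetVariant("c", 10, "A", 12, "T", 10), HetVariant("c", 50, "C", 11, "G", 9)]

    def test_cooccurrence_weights(self):
        variants = self._variants()
        bases = ["A" if i == 10 else "C" if i == 50 else "G" for i in range(60)]
        alns = [_aln(f"r{i}", 0, "".join(bases)) for i in range(12)]
        g = build_allele_graph(variants, alns)
        assert g.w(("c", 10), 1, ("c", 50), 1) == 12
        assert g.w(("c", 10), 1, ("c", 50), 2) == 0

    def test_read_covering_one_site_adds_nothing(self):
        g = build_allele_graph(self._variants(), [_aln("r", 0, "A" * 20)])
        assert not g.weights

    def test_weights_match_brute_force_recount(self, rng):
        variants = self._variants()
        reads = []
        expected = {}
        for i in range(40):
            a = rng.choice(["A", "T", "G"])  # G = neither top allele
            b = rng.choice(["C", "G", "A"])
            bases = ["G"] * 60
            bases[10], bases[50] = a, b
            reads.append(_aln(f"r{i}", 0, "".join(bases)))
            sa = {"A": 1, "T": 2}.get(a)
            sb = {"C": 1, "G": 2}.get(b)
            if sa and sb:
                key = (sa, sb)
                expected[key] = expected.get(key, 0) + 1
        g = build_allele_graph(variants, reads)
        for (sa, sb), w in expected.items():
            assert g.w(("c", 10), sa, ("c", 50), sb) == w


class TestPairPhase:
    def _graph_with_table(self, table):
        variants = [HetVariant("c", 1, "A", 1, "T", 1), HetVariant("c", 2, "C", 1, "G", 1)]
        g = AlleleGraph(variants)
        for s in (1, 2):
            for t in (1, 2):
                for _ in range(table[s - 1][t - 1]):
                    g.add_cooccurrence(("c", 1), s, ("c", 2), t)
        return g

    def test_clear_cis(self):
        g = self._graph_with_table([[12, 0], [0, 9]])
        t = pair_phase(g, ("c", 1), ("c", 2))
        assert t.p_value < 0.05 and t.orientation == "cis"

    def test_clear_trans(self):
        g = self._graph_with_table([[0, 11], [10, 0]])
        t = pair_phase(g, ("c", 1), ("c", 2))
        assert t.p_value < 0.05 and t.orientation == "trans"

    def test_symmetric_table_none(self):
        g = self._graph_with_table([[5, 5], [5, 5]])
        t = pair_phase(g, ("c", 1), ("c", 2))
        assert t.p_value == pytest.approx(1.0)
        assert t.orientation == "none"

    def test_below_weight_threshold_untested(self):
        g = self._graph_with_table([[5, 4], [0, 0]])
        t = pair_phase(g, ("c", 1), ("c", 2))
        assert t.p_value is None and t.orientation == "none"

    def test_p_matches_hypergeometric_oracle_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            tab = [[int(x) for x in rng.integers(0, 8, 2)] for _ in range(2)]
            if sum(tab[0]) + sum(tab[1]) < 10:
                continue
            g = self._graph_with_table(tab)
            t = pair_phase(g, ("c", 1), ("c", 2))
            assert t.p_value == pytest.approx(fisher_two_sided_oracle(tab), abs=1e-9)


class TestBonferroniPrune:
    def _tests(self, pvals, site=("c", 1)):
        out = []
        for k, p in enumerate(pvals):
            out.append(PairTest(site, ("c", 100 + k), [[5, 0], [0, 5]], p, "cis"))
        return out

    def test_exactly_one_third_retained(self):
        retained, _ = bonferroni_prune(self._tests([0.001, 0.2, 0.3]))
        assert ("c", 1) in retained  # corrected 0.003; 1/3 significant retains

    def test_zero_significant_excluded(self):
        retained, excluded = bonferroni_prune(self._tests([0.2, 0.3, 0.4]))
        assert ("c", 1) not in retained
        assert ("c", 1) in excluded

    def test_single_significant_pair_retained(self):
        retained, _ = bonferroni_prune(self._tests([0.01]))
        assert ("c", 1) in retained

    def test_untested_site_excluded_with_reason(self):
        t = PairTest(("c", 1), ("c", 2), [[3, 0], [0, 2]], None, "none")
        retained, excluded = bonferroni_prune([t])
        assert not retained
        assert excluded[("c", 1)] == "untested"

    def test_monotone_lower_p_never_hurts(self, rng):
        for _ in range(50):
            pvals = list(rng.random(int(rng.integers(1, 6))))
            base_retained = ("c", 1) in bonferroni_prune(self._tests(pvals))[0]
            k = int(rng.integers(0, len(pvals)))
            lowered = list(pvals)
            lowered[k] = lowered[k] / 10
            if base_retained:
                assert ("c", 1) in bonferroni_prune(self._tests(lowered))[0]


class TestAssembleHaplotypes:
    def _test(self, i, j, orientation, w=20):
        tab = [[w, 0], [0, w]] if orientation == "cis" else [[0, w], [w, 0]]
        return PairTest(("c", i), ("c", j), tab, 0.001, orientation)

    def test_cis_trans_chain_parity(self):
        tests = [self._test(1, 2, "cis"), self._test(2, 3, "trans")]
        sites = {("c", 1), ("c", 2), ("c", 3)}
        pair = assemble_haplotypes(tests, sites)
        assert len(pair.blocks) == 1
        alleles = dict(pair.blocks[0])
        assert alleles[("c", 1)] == alleles[("c", 2)] != alleles[("c", 3)]

    def test_single_site_block(self):
        pair = assemble_haplotypes([], {("c", 5)})
        assert pair.blocks == [[(("c", 5), 1)]]

    def test_disconnected_components_are_separate_blocks(self):
        tests = [self._test(1, 2, "cis"), self._test(10, 11, "cis")]
        pair = assemble_haplotypes(tests, {("c", 1), ("c", 2), ("c", 10), ("c", 11)})
        assert len(pair.blocks) == 2

    def test_conflict_resolved_by_weight(self):
        tests = [
            self._test(1, 2, "cis", w=30),
            self._test(2, 3, "cis", w=30),
            self._test(1, 3, "trans", w=5),  # contradicts the chain; weaker
        ]
        pair = assemble_haplotypes(tests, {("c", 1), ("c", 2), ("c", 3)})
        assert pair.conflicts == 1
        alleles = dict(pair.blocks[0])
        assert alleles[("c", 1)] == alleles[("c", 3)]


class TestAlleleBalanceAndComparison:
    def test_published_anchor_value(self):
        assert allele_balance([HetVariant("c", 1, "A", 60, "T", 40)]) == pytest.approx(0.4)

    def test_balanced_sites(self):
        vs = [HetVariant("c", i, "A", 7, "T", 7) for i in range(5)]
        assert allele_balance(vs) == pytest.approx(0.5)

    def test_matches_brute_force_mean(self, rng):
        vs = []
        fs = []
        for i in range(30):
            n2 = int(rng.integers(1, 20))
            n1 = n2 + int(rng.integers(0, 20))
            vs.append(HetVariant("c", i, "A", n1, "T", n2))
            fs.append(n2 / (n1 + n2))
        assert allele_balance(vs) == pytest.approx(float(np.mean(fs)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            allele_balance([])

    def _pair_and_truth(self):
        from linkfrag.phasing_ref import HaplotypePair

        variants = [
            HetVariant("c", 1, "A", 10, "T", 9),
            HetVariant("c", 2, "C", 10, "G", 9),
            HetVariant("c", 3, "A", 10, "G", 9),
        ]
        pair = HaplotypePair(blocks=[[(("c", 1), 1), (("c", 2), 1), (("c", 3), 2)]])
        truth = {("c", 1): ("A", "T"), ("c", 2): ("C", "G"), ("c", 3): ("G", "A")}
        return pair, variants, truth

    def test_identical_haplotypes_full_match(self):
        pair, variants, truth = self._pair_and_truth()
        m = compare_haplotypes(pair, variants, truth)
        assert m["matching_sites"] == 3 and m["switch_errors"] == 0

    def test_global_swap_invariance(self):
        pair, variants, truth = self._pair_and_truth()
        swapped = {s: (b, a) for s, (a, b) in truth.items()}
        m = compare_haplotypes(pair, variants, swapped)
        assert m["matching_sites"] == 3 and m["switch_errors"] == 0

    def test_one_flipped_site_one_switch_pair(self):
        pair, variants, truth = self._pair_and_truth()
        truth[("c", 2)] = ("G", "C")  # flip middle site
        m = compare_haplotypes(pair, variants, truth)
        assert m["matching_sites"] == 2
        assert m["switch_errors"] == 2  # flanked on both sides
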