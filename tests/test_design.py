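"""Guide enumeration, filtering, linker pairing, DAG construction and panel
selection, checked against brute-force oracles where the spec of the
operation admits one."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkfrag.design import (
    DesignConfig,
    DesignError,
    GenomeIndex,
    GuideCandidate,
    LinkerCandidate,
    TargetRegion,
    build_linker_graph,
    design_panel,
    enumerate_guide_candidates,
    filter_gc,
    filter_offtarget,
    filter_unique,
    filter_variant_overlap,
    off_target_score,
    partition_subregions,
    propose_linkers,
    select_panel,
)
from linkfrag.seqio import Genome, VariantRecord, revcomp

from conftest import brute_guide_sites, random_dna


class TestPartitionSubregions:
    @pytest.mark.parametrize(
        "L,F,expected_n",
        [(15_000, 15_000, 3), (1, 15_000, 3), (45_001, 15_000, 6), (30_000, 15_000, 4)],
    )
    def test_subregion_count_formula(self, L, F, expected_n):
        region = TargetRegion("c", 100_000, 100_000 + L)
        subs = partition_subregions(region, DesignConfig(read_length=F))
        assert len(subs) == expected_n == math.ceil(L / F) + 2

    @given(st.integers(min_value=1, max_value=400_000))
    @settings(max_examples=100, deadline=None)
    def test_subregion_count_any_length(self, L):
        region = TargetRegion("c", 500_000, 500_000 + L)
        subs = partition_subregions(region, DesignConfig())
        assert len(subs) == math.ceil(L / 15_000) + 2

    def test_flanking_placement(self):
        region = TargetRegion("c", 60_000, 90_000)
        subs = partition_subregions(region, DesignConfig())
        assert subs[0].end == region.start  # s_1 flanks on the left
        assert subs[-1].start == region.end  # s_n starts after the region
        assert all(s.end - s.start == 15_000 for s in subs)
        assert all(a.start < b.start for a, b in zip(subs, subs[1:]))

    def test_invalid_read_length_rejected(self):
        with pytest.raises(DesignError):
            DesignConfig(read_length=0)


class TestEnumerateCandidates:
    def test_minimal_forward_site(self):
        g = Genome({"c": "ACGTACGTACGTACGTACGTAGG"})  # 20-mer + AGG
        cands = enumerate_guide_candidates(g, "c", 0, 23)
        fwd = [c for c in cands if c.strand == "+"]
        assert len(fwd) == 1
        c = fwd[0]
        assert c.protospacer == "ACGTACGTACGTACGTACGT"
        assert c.pam == "AGG"
        assert c.nick_pos == 17  # 3 bp 5' of the PAM

    def test_reverse_site_from_cc(self):
        fwd = "ACGTACGTACGTACGTACGTAGG"
        g = Genome({"c": revcomp(fwd)})
        cands = enumerate_guide_candidates(g, "c", 0, 23)
        rev = [c for c in cands if c.strand == "-"]
        assert len(rev) == 1
        assert rev[0].protospacer == "ACGTACGTACGTACGTACGT"
        assert rev[0].nick_pos == 6

    def test_window_shorter_than_23_is_empty(self, tiny_genome):
        assert enumerate_guide_candidates(tiny_genome, "chr1", 0, 22) == []

    def test_matches_brute_force_both_strands(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 200)
            g = Genome({"c": seq})
            got = {
                (c.start, c.strand) for c in enumerate_guide_candidates(g, "c", 0, len(seq))
            }
            assert got == brute_guide_sites(seq)

    def test_reverse_complement_mirror(self, rng):
        seq = random_dna(rng, 300)
        fwd = {
            (c.start, c.strand)
            for c in enumerate_guide_candidates(Genome({"c": seq}), "c", 0, 300)
        }
        rc = {
            (c.start, c.strand)
            for c in enumerate_guide_candidates(Genome({"c": revcomp(seq)}), "c", 0, 300)
        }
        flipped = {(300 - (s + 23), "-" if st == "+" else "+") for s, st in rc}
        assert fwd == flipped


def _mk_candidate(protospacer, pam="AGG", start=0, strand="+", contig="c"):
    return GuideCandidate(
        contig=contig,
        start=start,
        end=start + 23,
        strand=strand,
        protospacer=protospacer,
        pam=pam,
        nick_pos=start + 17,
        gc=(protospacer.count("G") + protospacer.count("C")) / 20,
    )


class TestGcFilter:
    @pytest.mark.parametrize(
        "gc_count,kept",
        [(8, True), (12, True), (7, False), (13, False)],  # 0.40/0.60 kept
    )
    def test_boundaries(self, gc_count, kept):
        proto = "G" * gc_count + "A" * (20 - gc_count)
        out = filter_gc([_mk_candidate(proto)], DesignConfig())
        assert bool(out) is kept


class TestUniquenessFilter:
    def test_duplicate_forward_removed_unique_kept(self, rng):
        seq = random_dna(rng, 800)
        site = "ACGTACGTACGTACGTACGTAGG"
        dup = "TTTTGGGGCCCCAAAATTTTCGG"
        genome = Genome({"c": seq + site + dup + random_dna(rng, 50) + dup})
        index = GenomeIndex(genome)
        cands = enumerate_guide_candidates(genome, "c", 0, genome.length("c"))
        kept = {c.seq23 for c in filter_unique(cands, index)}
        assert site in kept
        assert dup not in kept

    def test_reverse_complement_copy_counts(self, rng):
        site = "ACGTACGTACGTACGTACGTAGG"
        genome = Genome({"c": site + random_dna(rng, 100) + revcomp(site)})
        index = GenomeIndex(genome)
        assert index.occurrences(site) == 2
        cands = enumerate_guide_candidates(genome, "c", 0, genome.length("c"))
        assert site not in {c.seq23 for c in filter_unique(cands, index)}


class TestOffTargetScore:
    def test_weight_arithmetic_and_cutoff(self):
        cfg = DesignConfig()
        c = _mk_candidate("A" * 20)
        c.h1, c.h2 = 20, 0
        assert cfg.w1 * 20 + cfg.w2 * 0 == pytest.approx(19.9222, abs=1e-3)
        assert cfg.w1 * 20 + cfg.w2 * 0 <= cfg.offtarget_cutoff
        assert cfg.w1 * 20 + cfg.w2 * 257 > cfg.offtarget_cutoff

    def test_unique_guide_scores_zero(self, rng):
        seq = random_dna(rng, 2000)
        genome = Genome({"c": seq})
        index = GenomeIndex(genome)
        cands = enumerate_guide_candidates(genome, "c", 0, len(seq))
        # on a short random genome every 12-mer seed is almost surely unique
        zero = [c for c in cands if off_target_score(c, index, DesignConfig()) == 0]
        assert zero, "expected at least one seed-unique candidate"
        for c in zero:
            assert c.h1 == 0 and c.h2 == 0

    def test_h1_h2_count_seed_sharers(self, rng):
        base = random_dna(rng, 300)
        site = "ACGTACGTACGTACGTACGTAGG"
        # same PAM-proximal 12-mer, different distal 8-mer
        sharer12 = "TTTTTTTT" + site[8:20] + "TGG"
        # same proximal 8-mer only
        sharer8 = "TTTTTTTTTTTT" + site[12:20] + "TGG"
        genome = Genome({"c": base + site + "T" * 10 + sharer12 + "T" * 10 + sharer8})
        index = GenomeIndex(genome)
        cand = next(
            c
            for c in enumerate_guide_candidates(genome, "c", 0, genome.length("c"))
            if c.seq23 == site
        )
        off_target_score(cand, index, DesignConfig())
        assert cand.h1 == 1
        assert cand.h2 == 1
        assert cand.score == pytest.approx(256 / 257 + 1 / 257)

    def test_score_monotone_in_counts(self):
        cfg = DesignConfig()
        scores = [cfg.w1 * h1 + cfg.w2 * h2 for h1 in range(5) for h2 in range(5)]
        for h1 in range(4):
            for h2 in range(4):
                assert cfg.w1 * (h1 + 1) + cfg.w2 * h2 >= cfg.w1 * h1 + cfg.w2 * h2
                assert cfg.w1 * h1 + cfg.w2 * (h2 + 1) >= cfg.w1 * h1 + cfg.w2 * h2
        assert min(scores) == 0


class TestVariantOverlapFilter:
    def test_snv_inside_protospacer_removed(self):
        c = _mk_candidate("A" * 20, start=100)
        v = VariantRecord("c", 105, "A", "T")
        assert filter_variant_overlap([c], [v]) == []

    def test_snv_past_pam_kept(self):
        c = _mk_candidate("A" * 20, start=100)  # site [100, 123)
        v = VariantRecord("c", 123, "A", "T")
        assert filter_variant_overlap([c], [v]) == [c]

    def test_deletion_spanning_pam_boundary_removed(self):
        c = _mk_candidate("A" * 20, start=100)
        v = VariantRecord("c", 121, "AAAA", "A")  # ref span [121, 125)
        assert filter_variant_overlap([c], [v]) == []


class TestProposeLinkers:
    def _genome_with_pair(self, rng, gap):
        """Forward guide then reverse guide `gap` bp downstream, embedded in a
        PAM-free (GG/CC-free) background so they are the only sites."""
        fwd_site = "ACGTACGTACGTACGTACGTAGG"
        rev_site = revcomp("TGCATGCATGCATGCATGCAAGG")
        left = "AT" * 50
        middle = "AT" * (gap // 2)
        seq = left + fwd_site + middle + rev_site + "AT" * 50
        return Genome({"c": seq}), len(left)

    def test_valid_pair_with_het(self, rng):
        genome, off = self._genome_with_pair(rng, 368)  # linker length == 400
        index = GenomeIndex(genome)
        cands = enumerate_guide_candidates(genome, "c", 0, genome.length("c"))
        var = VariantRecord("c", off + 100, "A", "T", "het")
        cfg = DesignConfig()
        out = propose_linkers(cands, (0, genome.length("c")), index, [var], cfg)
        assert len(out) == 1
        lk = out[0]
        assert cfg.linker_min <= lk.length <= cfg.linker_max
        assert lk.guide_up.strand != lk.guide_down.strand
        assert lk.het_variants

    def test_no_het_rejected_when_required(self, rng):
        genome, _ = self._genome_with_pair(rng, 354)
        index = GenomeIndex(genome)
        cands = enumerate_guide_candidates(genome, "c", 0, genome.length("c"))
        out = propose_linkers(cands, (0, genome.length("c")), index, [], DesignConfig())
        assert out == []

    def test_out_of_window_rejected(self, rng):
        genome, off = self._genome_with_pair(rng, 600)
        index = GenomeIndex(genome)
        cands = enumerate_guide_candidates(genome, "c", 0, genome.length("c"))
        var = VariantRecord("c", off + 100, "A", "T", "het")
        out = propose_linkers(cands, (0, genome.length("c")), index, [var], DesignConfig())
        assert out == []


def _mk_linker(start, end, contig="c"):
    up = _mk_candidate("A" * 20, start=start + 3, strand="+", contig=contig)
    down = _mk_candidate("C" * 20, start=end - 26, strand="-", contig=contig)
    return LinkerCandidate(contig=contig, start=start, end=end, guide_up=up, guide_down=down)


class TestLinkerGraph:
    @pytest.mark.parametrize(
        "gap,has_edge",
        [(11_000, True), (9_999, False), (10_000, True), (20_000, True), (20_001, False)],
    )
    def test_gap_window_boundaries(self, gap, has_edge):
        a = _mk_linker(0, 400)
        b = _mk_linker(400 + gap, 800 + gap)
        g = build_linker_graph([a, b], DesignConfig())
        assert g.has_edge(a.linker_id, b.linker_id) is has_edge

    def test_graph_is_acyclic(self):
        linkers = [_mk_linker(i * 12_000, i * 12_000 + 400) for i in range(6)]
        import networkx as nx

        g = build_linker_graph(linkers, DesignConfig())
        assert nx.is_directed_acyclic_graph(g)
        assert all(
            g.nodes[u]["linker"].start < g.nodes[v]["linker"].start for u, v in g.edges
        )


class TestSelectPanel:
    def _panel_from_chain(self, spacing, genome_len=70_000, n_linkers=4, F=15_000):
        genome = Genome({"c": "A" * genome_len})
        linkers = [
            _mk_linker(5_000 + i * spacing, 5_400 + i * spacing) for i in range(n_linkers)
        ]
        cfg = DesignConfig(read_length=F)
        graph = build_linker_graph(linkers, cfg)
        region = TargetRegion("c", linkers[0].end + 1, linkers[-1].start - 1, "r")
        subs = partition_subregions(region, cfg)
        # widen s_1/s_n to the linkers for this synthetic chain
        subs[0].start, subs[0].end = 0, linkers[0].end + 2
        subs[0].lsa_start, subs[0].lsa_end = 0, linkers[0].end + 2
        subs[-1].start, subs[-1].end = linkers[-1].start - 2, genome_len
        subs[-1].lsa_start, subs[-1].lsa_end = linkers[-1].start - 2, genome_len
        return select_panel([(region, subs, graph)], genome, cfg), linkers

    def test_single_chain_selected_with_terminal_fragments(self):
        panel, linkers = self._panel_from_chain(15_000)
        rd = panel.regions[0]
        assert [lk.linker_id for lk in rd.linkers] == [lk.linker_id for lk in linkers]
        assert len(rd.fragments) == len(linkers) + 1
        assert rd.fragments[0].left_linker is None
        assert rd.fragments[-1].right_linker is None
        interior = rd.fragments[1:-1]
        assert all(f.left_linker and f.right_linker for f in interior)

    def test_balanced_path_beats_unbalanced(self):
        """Two s_1->s_n paths with fragment sets {15k,15k} vs {11k,19k}:
        the balanced one wins the |fragment - F| objective."""
        cfg = DesignConfig()
        genome = Genome({"c": "A" * 80_000})
        a = _mk_linker(1_000, 1_400)
        mid_even = _mk_linker(15_600, 16_000)  # fragments 15000 / 15000
        mid_skew = _mk_linker(11_600, 12_000)  # fragments 11000 / 19000
        z = _mk_linker(30_200, 30_600)
        graph = build_linker_graph([a, mid_even, mid_skew, z], cfg)
        region = TargetRegion("c", 2_000, 30_000, "r")
        subs = partition_subregions(region, cfg)
        subs[0].start = subs[0].lsa_start = 0
        subs[0].end = subs[0].lsa_end = 2_000
        subs[-1].start = subs[-1].lsa_start = 30_000
        subs[-1].end = subs[-1].lsa_end = 40_000
        panel = select_panel([(region, subs, graph)], genome, cfg)
        chosen = [lk.linker_id for lk in panel.regions[0].linkers]
        assert chosen == [a.linker_id, mid_even.linker_id, z.linker_id]

    def test_no_path_is_design_failure(self):
        cfg = DesignConfig()
        genome = Genome({"c": "A" * 50_000})
        a = _mk_linker(1_000, 1_400)
        b = _mk_linker(40_000, 40_400)  # unreachable: gap >> gap_max
        graph = build_linker_graph([a, b], cfg)
        region = TargetRegion("c", 2_000, 39_000, "r")
        subs = partition_subregions(region, cfg)
        subs[0].start = subs[0].lsa_start = 0
        subs[0].end = subs[0].lsa_end = 2_000
        subs[-1].start = subs[-1].lsa_start = 39_000
        subs[-1].end = subs[-1].lsa_end = 50_000
        with pytest.raises(DesignError):
            select_panel([(region, subs, graph)], genome, cfg)


class TestEndToEndDesign:
    def test_panel_on_synthetic_diploid_contains_planted_hets(self, rng):
        from linkfrag.simulator import SimConfig, make_diploid_genome

        sim = SimConfig(genome_length=60_000, snv_rate=1.5e-3, indel_rate=1e-4, seed=3)
        dip = make_diploid_genome(sim)
        cfg = DesignConfig(read_length=8_000, gap_min=5_000, gap_max=11_000)
        region = TargetRegion("sim", 15_000, 45_000, "t")
        panel = design_panel(dip.reference, [region], dip.variants, cfg)
        rd = panel.regions[0]
        assert rd.linkers, "design should select at least one linker"
        for lk in rd.linkers:
            assert lk.het_variants, "every selected linker must contain a het variant"
            assert cfg.linker_min <= lk.length <= cfg.linker_max
        # interior gaps respect the window
        for x, y in zip(rd.linkers, rd.linkers[1:]):
            assert cfg.gap_min <= y.start - x.end <= cfg.gap_max
        # outermost linkers flank the region
        assert rd.linkers[0].start < region.start
        assert rd.linkers[-1].end > region.end
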