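"""Reference-free phasing via guide matching, per-linker read grouping,
consensus building, and the shared allele-graph machinery.

Designed guides (protospacer + PAM, 23-mers) are searched for in the first
and last 500 bp of every read at bounded edit distance (≤ 4), in both
orientations.  Reads matching either guide of a linker form that linker's
group; the parts of the grouped reads around the match are aligned and
voted column-by-column into a consensus, positions with fewer than 30 reads
behind the two most frequent alleles being masked.  Reads are then realigned
to the consensus and phased exactly as in the reference-based pipeline.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .design import DesignPanel, LinkerCandidate
from .phasing_ref import (
    DELETION,
    AlleleGraph,
    HaplotypePair,
    HetVariant,
    assemble_haplotypes,
    bonferroni_prune,
    build_pileup,
    call_het_variants,
    filter_repeat_regions,
    test_pair_phase,
)
from .seqio import Genome, Read, overlap_align, revcomp

__all__ = [
    "GuideMatch",
    "LinkerReadGroup",
    "ConsensusSequence",
    "match_guides_in_read",
    "group_reads_by_linker",
    "consensus_from_group",
    "phase_denovo",
]


@dataclass
class GuideMatch:
    read_id: str
    guide_id: str
    terminus: str  # {"first", "last"}
    orientation: str  # {"as-is", "revcomp"}
    distance: int
    read_start: int  # on the read as stored
    read_end: int


@dataclass
class LinkerReadGroup:
    linker: LinkerCandidate
    read_ids: list[str] = field(default_factory=list)
    parts: list[Read] = field(default_factory=list)  # genome-forward oriented


@dataclass
class ConsensusSequence:
    linker_id: str
    bases: str
    support: list[int]  # top-two allele support per emitted column
    masked: set[int]  # emitted-column indices with support below threshold

    def unmasked_length(self) -> int:
        return len(self.bases) - len(self.masked)


def _window_matches(
    query: str, window: str, offset: int, max_edit: int
) -> Optional[tuple[int, int, int]]:
    res = edlib.align(query, window, mode="HW", task="locations", k=max_edit)
    d = res["editDistance"]
    if d == -1:
        return None
    start = min(loc[0] for loc in res["locations"])
    end = min(loc[1] for loc in res["locations"] if loc[0] == start) + 1
    return d, offset + start, offset + end


def match_guides_in_read(
    read: Read,
    guides: Sequence,
    max_edit: int = 4,
    terminus_window: int = 500,
) -> list[GuideMatch]:
    """Best bounded-edit-distance occurrence of each guide 23-mer (either
    orientation) within the first and last ``terminus_window`` bp of a read
    (the whole read when shorter); infix matching with free end gaps on the
    read side."""
    out: list[GuideMatch] = []
    n = len(read.bases)
    windows = [("first", 0, read.bases[: min(terminus_window, n)])]
    if n > terminus_window:
        windows.append(("last", n - terminus_window, read.bases[-terminus_window:]))
    for g in guides:
        seq = g.seq23 if hasattr(g, "seq23") else str(g)
        gid = g.guide_id if hasattr(g, "guide_id") else str(g)
        for terminus, offset, window in windows:
            best = None
            for orient, q in (("as-is", seq), ("revcomp", revcomp(seq))):
                hit = _window_matches(q, window, offset, max_edit)
                if hit and (best is None or hit[0] < best[0][0]):
                    best = (hit, orient)
            if best:
                (d, s, e), orient = best
                out.append(
                    GuideMatch(
                        read_id=read.id,
                        guide_id=gid,
                        terminus=terminus,
                        orientation=orient,
                        distance=d,
                        read_start=s,
                        read_end=e,
                    )
                )
    return out


def group_reads_by_linker(
    reads: Sequence[Read],
    panel: DesignPanel,
    max_edit: int = 4,
    terminus_window: int = 500,
    margin: int = 200,
) -> tuple[list[LinkerReadGroup], list[str]]:
    """One group per designed linker: reads matching either of its guides,
    with the read part around the match (expected linker extent + margin)
    extracted and oriented genome-forward.  Returns the groups and the ids
    of reads that matched no guide."""
    groups = {lk.linker_id: LinkerReadGroup(linker=lk) for lk in panel.linkers}
    guide_to_linkers: dict[str, list[LinkerCandidate]] = defaultdict(list)
    all_guides: dict[str, object] = {}
    for lk in panel.linkers:
        for g in (lk.guide_up, lk.guide_down):
            guide_to_linkers[g.guide_id].append(lk)
            all_guides[g.guide_id] = g
    unmatched = []
    guide_list = list(all_guides.values())
    for read in reads:
        matches = match_guides_in_read(read, guide_list, max_edit, terminus_window)
        if not matches:
            unmatched.append(read.id)
            continue
        assigned: set[str] = set()
        for m in matches:
            g = all_guides[m.guide_id]
            for lk in guide_to_linkers[m.guide_id]:
                if lk.linker_id in assigned:
                    continue
                part = _extract_part(read, m, g, lk, margin)
                if part is None:
                    continue
                assigned.add(lk.linker_id)
                grp = groups[lk.linker_id]
                grp.read_ids.append(read.id)
                grp.parts.append(part)
    return list(groups.values()), unmatched


def _extract_part(
    read: Read, match: GuideMatch, guide, linker: LinkerCandidate, margin: int
) -> Optional[Read]:
    """Slice the read segment expected to overlap the linker and orient it to
    the genome forward strand."""
    extent = linker.length + margin
    a = max(0, match.read_start - extent)
    b = min(len(read.bases), match.read_end + extent)
    bases = read.bases[a:b]
    quals = read.qualities[a:b] if read.qualities is not None else None
    # Orientation: the stored guide sequence is 5'->3' on its own strand; its
    # forward-genome image is seq23 for '+' guides and revcomp(seq23) for '-'.
    # The part is genome-forward iff the matched orientation corresponds.
    genome_forward_hit = (
        match.orientation == "as-is"
        if getattr(guide, "strand", "+") == "+"
        else match.orientation == "revcomp"
    )
    if not genome_forward_hit:
        bases = revcomp(bases)
        quals = quals[::-1] if quals is not None else None
    return Read(f"{read.id}", bases, quals)


def consensus_from_group(
    group: LinkerReadGroup, min_support: int = 30
) -> ConsensusSequence:
    """Column-majority consensus of the group's read parts.

    Parts are aligned to the longest part (center-star); each center column
    is voted by majority (ties broken lexicographically, gap last); columns
    whose two most frequent alleles are supported by fewer than
    ``min_support`` reads in total are masked; gap-majority columns are
    dropped; majority insertions are spliced in after their anchor.
    """
    if not group.parts:
        raise ValueError(f"linker {group.linker.linker_id}: empty read group")
    center = max(group.parts, key=lambda r: len(r.bases))
    center_genome = Genome({"center": center.bases})
    # overlap alignment: parts cover ragged extents around the linker, so
    # only their genuine overlap with the center contributes columns
    alns = [
        overlap_align(part.bases, center.bases, contig="center", read_id=part.id)
        for part in group.parts
    ]
    columns = build_pileup(alns, center_genome, quality_min=0)
    out_bases: list[str] = []
    support: list[int] = []
    masked: set[int] = set()
    for pos in range(len(center.bases)):
        col = columns.get(("center", pos))
        if col is None or not col.counts:
            continue
        ranked = sorted(
            col.counts.items(),
            key=lambda kv: (-kv[1], _allele_rank(kv[0])),
        )
        top_allele, _ = ranked[0]
        top2 = sum(cnt for _, cnt in ranked[:2])
        if top_allele == DELETION:
            continue  # gap-majority column drops out of the consensus
        if isinstance(top_allele, tuple) and top_allele[0] == "INS":
            emitted = top_allele[1]  # anchor base + inserted sequence
        else:
            emitted = str(top_allele)
        for ch in emitted:
            out_bases.append(ch)
            support.append(top2)
            if top2 < min_support:
                masked.add(len(out_bases) - 1)
    return ConsensusSequence(
        linker_id=group.linker.linker_id,
        bases="".join(out_bases),
        support=support,
        masked=masked,
    )


def _allele_rank(allele) -> str:
    # lexicographic tie-break A < C < G < T < gap < insertion
    if allele == DELETION:
        return "ZZ0"
    if isinstance(allele, tuple):
        return "ZZ1" + allele[1]
    return str(allele)


def phase_denovo(
    groups: Sequence[LinkerReadGroup],
    consensuses: dict[str, ConsensusSequence],
    quality_min: int = 10,
    min_pair_weight: int = 10,
    alpha: float = 0.05,
    min_consensus_length: int = 50,
) -> tuple[HaplotypePair, list[HetVariant], AlleleGraph]:
    """Phase heterozygous sites on the linker consensuses.

    Read parts are realigned to their linker's consensus; het variants are
    called and the allele co-occurrence graph built with the same thresholds
    as the reference-based pipeline (sites live on consensus coordinates,
    contig name = linker id).  Parts from the same read share a read id, so
    reads touching two linkers phase them together.
    """
    consensus_genome: dict[str, str] = {}
    alignments = []
    skipped: dict = {}
    for group in groups:
        cons = consensuses.get(group.linker.linker_id)
        if cons is None:
            continue
        if cons.unmasked_length() < min_consensus_length:
            skipped[(group.linker.linker_id, -1)] = "consensus too short"
            continue
        consensus_genome[group.linker.linker_id] = cons.bases
        for part in group.parts:
            aln = overlap_align(
                part.bases,
                cons.bases,
                contig=group.linker.linker_id,
                read_id=part.id,
            )
            aln.qualities = part.qualities
            alignments.append(aln)
    genome = Genome(consensus_genome)
    columns = build_pileup(alignments, genome, quality_min)
    variants = call_het_variants(columns)
    # exclude masked consensus columns from calling
    variants = [
        v
        for v in variants
        if v.position not in consensuses[v.contig].masked
    ]
    variants = filter_repeat_regions(variants, genome)
    graph = _allele_graph_by_read(variants, alignments, quality_min)
    tests = [
        test_pair_phase(graph, i, j, min_pair_weight, alpha)
        for i, j in graph.tested_pairs(min_pair_weight)
    ]
    retained, excluded = bonferroni_prune(tests, alpha)
    pair = assemble_haplotypes(tests, retained)
    pair.excluded.update(excluded)
    pair.excluded.update(skipped)
    return pair, variants, graph


def _allele_graph_by_read(
    variants: Sequence[HetVariant],
    alignments,
    quality_min: int,
) -> AlleleGraph:
    """Allele co-occurrence where the unit of evidence is the source read:
    parts of one read aligned to different linker consensuses count as one
    read carrying alleles at both linkers."""
    from .phasing_ref import iter_read_alleles

    graph = AlleleGraph(variants)
    sites = graph.variants
    per_read: dict[str, dict] = defaultdict(dict)
    for aln in alignments:
        for site, allele, _q in iter_read_alleles(aln, quality_min):
            v = sites.get(site)
            if v is None or allele is None:
                continue
            if allele == v.allele1:
                per_read[aln.read_id][site] = 1
            elif allele == v.allele2:
                per_read[aln.read_id][site] = 2
    for carried in per_read.values():
        items = sorted(carried.items())
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                (i, s), (j, t) = items[a], items[b]
                graph.add_cooccurrence(i, s, j, t)
    return graph
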