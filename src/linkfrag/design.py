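"""Joint sgRNA / linker panel design for linked-fragment sequencing.

A target region is tiled with fixed-length sub-regions; inside each
sub-region's linker-search area (LSA) candidate 20-mer+NGG guide sites are
enumerated on both strands and filtered (genome uniqueness, GC content,
seed-based off-target score, known-variant overlap).  Opposite-strand guide
pairs whose implied linker passes length / uniqueness / heterozygous-variant
checks become linker candidates; linkers are connected into a DAG whose edges
are fragment-length-compatible gaps, and a shortest-path pass (fragment
lengths as close as possible to the target read length, with a reuse discount
for guides already selected for another region) picks the panel.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .seqio import Genome, VariantRecord, revcomp

__all__ = [
    "DesignConfig",
    "TargetRegion",
    "SubRegion",
    "GuideCandidate",
    "LinkerCandidate",
    "DesignPanel",
    "GenomeIndex",
    "DesignError",
    "partition_subregions",
    "enumerate_guide_candidates",
    "filter_unique",
    "filter_gc",
    "off_target_score",
    "filter_offtarget",
    "filter_variant_overlap",
    "propose_linkers",
    "build_linker_graph",
    "select_panel",
    "design_panel",
]


class DesignError(RuntimeError):
    """Design is infeasible under the given configuration."""


@dataclass
class DesignConfig:
    """Tunable parameters of the design algorithm.

    Defaults target ~15 kbp nanopore reads on a human-scale genome; the
    :meth:`model_genome` preset narrows linker lengths and caps fragment
    length for small model genomes such as a phage chromosome.
    """

    read_length: int = 15_000  # target read / fragment length F, bp
    linker_min: int = 300
    linker_max: int = 500
    gap_min: int = 10_000  # fragment gap window, bp, inclusive
    gap_max: int = 20_000
    gc_min: float = 0.40
    gc_max: float = 0.60
    w1: float = 256 / 257  # weight of 12-mer-seed off-target hits
    w2: float = 1 / 257  # weight of 8-mer-only-seed hits
    offtarget_cutoff: float = 20.0  # remove candidates with score > cutoff
    require_het_in_linker: bool = True
    max_fragment_length: Optional[int] = None
    lsa_length: Optional[int] = None  # None = LSA spans the full sub-region
    max_linkers_per_lsa: int = 50
    reuse_discount: float = 0.5  # per reused guide, in fragment-length units

    @classmethod
    def model_genome(cls, **overrides) -> "DesignConfig":
        """Preset for small linear model genomes (e.g. a 48.5-kbp phage)."""
        params = dict(
            read_length=7_000,
            linker_min=50,
            linker_max=250,
            gap_min=5_000,
            gap_max=10_000,
            max_fragment_length=25_000,
            require_het_in_linker=False,
        )
        params.update(overrides)
        return cls(**params)

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise DesignError("target read length must be positive")
        if self.linker_min > self.linker_max or self.gap_min > self.gap_max:
            raise DesignError("empty linker-length or gap window")


@dataclass
class TargetRegion:
    contig: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"region {self.name or self.contig}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SubRegion:
    index: int  # 1-based, s_1 .. s_n
    start: int
    end: int
    lsa_start: int
    lsa_end: int


@dataclass
class GuideCandidate:
    """A 20-mer protospacer + NGG PAM occurrence.

    ``protospacer``/``pam`` are given 5'→3' on the guide's strand;
    ``start``/``end`` is the forward-strand interval of the full 23-bp site
    (protospacer + PAM) and ``nick_pos`` the forward-strand coordinate of the
    nick boundary, 3 bp 5' of the PAM (between protospacer positions 17/18).
    """

    contig: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    nick_pos: int
    gc: float
    h1: int = 0
    h2: int = 0
    score: float = 0.0

    @property
    def seq23(self) -> str:
        return self.protospacer + self.pam

    @property
    def guide_id(self) -> str:
        return f"{self.contig}:{self.start}{self.strand}"


@dataclass
class LinkerCandidate:
    """An opposite-strand guide pair and the duplicated segment it defines."""

    contig: str
    start: int
    end: int
    guide_up: GuideCandidate  # smaller forward-strand coordinate
    guide_down: GuideCandidate
    unique: bool = True
    het_variants: list[VariantRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def linker_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


@dataclass
class PanelFragment:
    fragment_id: str
    contig: str
    start: int
    end: int
    left_linker: Optional[str]  # linker id, None for a terminal fragment end
    right_linker: Optional[str]


@dataclass
class RegionDesign:
    region: TargetRegion
    subregions: list[SubRegion]
    linkers: list[LinkerCandidate]
    fragments: list[PanelFragment]


@dataclass
class DesignPanel:
    regions: list[RegionDesign]

    @property
    def linkers(self) -> list[LinkerCandidate]:
        return [lk for rd in self.regions for lk in rd.linkers]

    @property
    def fragments(self) -> list[PanelFragment]:
        return [fr for rd in self.regions for fr in rd.fragments]

    def guides(self) -> list[GuideCandidate]:
        seen: dict[str, GuideCandidate] = {}
        for lk in self.linkers:
            for g in (lk.guide_up, lk.guide_down):
                seen.setdefault(g.guide_id, g)
        return list(seen.values())


# ---------------------------------------------------------------------------
# Sub-region partitioning
# ---------------------------------------------------------------------------

def partition_subregions(region: TargetRegion, config: DesignConfig) -> list[SubRegion]:
    """Tile a region with ``ceil(L/F) + 2`` fixed-length sub-regions.

    ``s_1`` ends at the region start (flanking it on the left), ``s_n`` starts
    at the region end; interior sub-regions tile the region at even stride.
    """
    F = config.read_length
    L = region.length
    n = math.ceil(L / F) + 2
    starts = [region.start - F]
    m = n - 2
    if m == 1:
        starts.append(region.start)
    else:
        span = L - F  # > 0 whenever m >= 2
        for i in range(m):
            starts.append(region.start + round(i * span / (m - 1)))
    starts.append(region.end)
    subs = []
    for i, s in enumerate(starts, start=1):
        lsa_s, lsa_e = s, s + F
        if config.lsa_length is not None and config.lsa_length < F:
            pad = (F - config.lsa_length) // 2
            lsa_s, lsa_e = s + pad, s + pad + config.lsa_length
        subs.append(SubRegion(index=i, start=s, end=s + F, lsa_start=lsa_s, lsa_end=lsa_e))
    return subs


# ---------------------------------------------------------------------------
# Genome k-mer index
# ---------------------------------------------------------------------------

class GenomeIndex:
    """23-mer occurrence counts and PAM-proximal seed counts over a genome.

    All counts consider both strands.  Seeds are the PAM-proximal 12-mer and
    8-mer of the protospacer of every 20-mer+NGG site in the genome (the NGG
    itself is shared by construction).
    """

    def __init__(self, genome: Genome):
        self.genome = genome
        self.kmer23: Counter[str] = Counter()
        self.seed12: Counter[str] = Counter()
        self.seed8: Counter[str] = Counter()
        self._unique23_prefix: dict[str, np.ndarray] = {}
        for contig in genome.contigs():
            seq = genome.sequences[contig]
            for i in range(len(seq) - 22):
                self.kmer23[seq[i : i + 23]] += 1
            for cand in enumerate_guide_candidates(genome, contig, 0, len(seq)):
                self.seed12[cand.protospacer[8:20]] += 1
                self.seed8[cand.protospacer[12:20]] += 1
        for contig in genome.contigs():
            seq = genome.sequences[contig]
            uniq = np.zeros(max(len(seq) - 22, 0) + 1, dtype=np.int64)
            for i in range(len(seq) - 22):
                km = seq[i : i + 23]
                uniq[i + 1] = uniq[i] + (1 if self.occurrences(km) == 1 else 0)
            self._unique23_prefix[contig] = uniq

    def occurrences(self, kmer23: str) -> int:
        # an odd-length k-mer can never equal its own reverse complement
        return self.kmer23[kmer23] + self.kmer23[revcomp(kmer23)]

    def interval_is_unique(self, contig: str, start: int, end: int) -> bool:
        """True if the genome substring [start, end) occurs exactly once
        (both strands).  A segment containing a genome-unique 23-mer is
        itself unique; otherwise fall back to direct counting."""
        if end - start < 23:
            return self.occurrences(self.genome.fetch(contig, start, end)) == 1 \
                if end - start > 0 else False
        pre = self._unique23_prefix[contig]
        lo = max(start, 0)
        hi = min(end - 22, len(pre) - 1)
        if hi > lo and pre[hi] - pre[lo] > 0:
            return True
        seg = self.genome.fetch(contig, start, end)
        count = 0
        for cseq in self.genome.sequences.values():
            count += cseq.count(seg) + cseq.count(revcomp(seg))
        return count == 1


# ---------------------------------------------------------------------------
# Candidate enumeration and filters
# ---------------------------------------------------------------------------

def enumerate_guide_candidates(
    genome: Genome, contig: str, start: int, end: int
) -> list[GuideCandidate]:
    """All 20-mer+NGG sites on both strands whose 23-bp footprint lies within
    ``[start, end)`` (clipped to the contig)."""
    seq = genome.sequences[contig]
    start = max(start, 0)
    end = min(end, len(seq))
    out: list[GuideCandidate] = []
    window = seq[start:end]
    for i in range(len(window) - 22):
        # forward: protospacer [i, i+20), PAM NGG at [i+20, i+23)
        if window[i + 21 : i + 23] == "GG":
            proto = window[i : i + 20]
            if _acgt_only(proto):
                g = start + i
                out.append(
                    GuideCandidate(
                        contig=contig,
                        start=g,
                        end=g + 23,
                        strand="+",
                        protospacer=proto,
                        pam=window[i + 20 : i + 23],
                        nick_pos=g + 17,
                        gc=_gc(proto),
                    )
                )
        # reverse: PAM CCN at [i, i+3), protospacer [i+3, i+23) (revcomp)
        if window[i : i + 2] == "CC":
            proto_fwd = window[i + 3 : i + 23]
            if len(proto_fwd) == 20 and _acgt_only(proto_fwd):
                g = start + i
                out.append(
                    GuideCandidate(
                        contig=contig,
                        start=g,
                        end=g + 23,
                        strand="-",
                        protospacer=revcomp(proto_fwd),
                        pam=revcomp(window[i : i + 3]),
                        nick_pos=g + 6,
                        gc=_gc(proto_fwd),
                    )
                )
    out.sort(key=lambda c: (c.start, c.strand))
    return out


def _acgt_only(s: str) -> bool:
    return all(c in "ACGT" for c in s)


def _gc(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


def filter_unique(
    candidates: Sequence[GuideCandidate], index: GenomeIndex
) -> list[GuideCandidate]:
    """Keep candidates whose 23-mer (protospacer+PAM) occurs exactly once in
    the genome, counting both strands."""
    return [c for c in candidates if index.occurrences(c.seq23) == 1]


def filter_gc(
    candidates: Sequence[GuideCandidate], config: DesignConfig
) -> list[GuideCandidate]:
    """Remove extreme-GC candidates; window boundaries are kept (the removal
    rule is strictly below/above the window)."""
    return [c for c in candidates if config.gc_min <= c.gc <= config.gc_max]


def off_target_score(
    candidate: GuideCandidate, index: GenomeIndex, config: DesignConfig
) -> float:
    """Seed-sharing off-target score ``w1*h1 + w2*h2``.

    h1 = number of *other* 20-mer+NGG sites sharing the PAM-proximal 12-mer;
    h2 = number sharing the PAM-proximal 8-mer but not the 12-mer.  The
    candidate's own locus is excluded from both counts.
    """
    c12 = index.seed12[candidate.protospacer[8:20]]
    c8 = index.seed8[candidate.protospacer[12:20]]
    candidate.h1 = c12 - 1
    candidate.h2 = c8 - c12
    candidate.score = config.w1 * candidate.h1 + config.w2 * candidate.h2
    return candidate.score


def filter_offtarget(
    candidates: Sequence[GuideCandidate], index: GenomeIndex, config: DesignConfig
) -> list[GuideCandidate]:
    """Remove candidates with off-target score above the cutoff."""
    return [
        c for c in candidates if off_target_score(c, index, config) <= config.offtarget_cutoff
    ]


def filter_variant_overlap(
    candidates: Sequence[GuideCandidate], variants: Sequence[VariantRecord]
) -> list[GuideCandidate]:
    """Remove candidates whose 23-bp site intersects any variant's reference
    span (SNVs span 1 bp; deletions span their reference allele)."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append((v.position, v.ref_end))
    for spans in by_contig.values():
        spans.sort()
    out = []
    for c in candidates:
        spans = by_contig.get(c.contig, [])
        starts = [s for s, _ in spans]
        i = bisect_right(starts, c.end - 1)
        hit = any(e > c.start for s, e in spans[max(0, i - 40) : i] if s < c.end)
        if not hit:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Linker proposal and graph
# ---------------------------------------------------------------------------

def _linker_interval(a: GuideCandidate, b: GuideCandidate) -> tuple[int, int]:
    """Forward-strand linker interval for an opposite-strand pair: from 3 bp
    outside the upstream guide's protospacer start to 3 bp outside the
    downstream guide's PAM end."""
    up, down = (a, b) if a.start <= b.start else (b, a)
    if up.strand == "+":
        start = up.start - 3  # protospacer starts at site start on '+'
    else:
        start = up.start + 3 - 3  # '-' protospacer starts after the CCN PAM
    if down.strand == "+":
        end = down.end + 3  # PAM ends at site end on '+'
    else:
        end = down.start + 3 + 3  # '-' PAM occupies the first 3 bp of the site
    return start, end


def propose_linkers(
    candidates: Sequence[GuideCandidate],
    lsa: tuple[int, int],
    index: GenomeIndex,
    variants: Sequence[VariantRecord],
    config: DesignConfig,
) -> list[LinkerCandidate]:
    """All valid opposite-strand guide pairs in the LSA whose linker interval
    has an in-window length, is unique in the genome, and (when required)
    contains at least one heterozygous variant."""
    lsa_s, lsa_e = lsa
    cands = sorted(
        (c for c in candidates if c.start >= lsa_s and c.end <= lsa_e),
        key=lambda c: c.start,
    )
    het_pos = sorted(
        v.position for v in variants if v.zygosity == "het"
    )
    out: list[LinkerCandidate] = []
    starts = [c.start for c in cands]
    for i, a in enumerate(cands):
        # partner site must start close enough for the linker window
        j_hi = bisect_right(starts, a.start + config.linker_max)
        for b in cands[i + 1 : j_hi]:
            if b.strand == a.strand:
                continue
            s, e = _linker_interval(a, b)
            if not (config.linker_min <= e - s <= config.linker_max):
                continue
            if s < 0 or e > index.genome.length(a.contig):
                continue
            hets = []
            if config.require_het_in_linker:
                lo = bisect_left(het_pos, s)
                hi = bisect_left(het_pos, e)
                if lo == hi:
                    continue
                hets = [
                    v
                    for v in variants
                    if v.zygosity == "het" and s <= v.position < e
                ]
            if not index.interval_is_unique(a.contig, s, e):
                continue
            out.append(
                LinkerCandidate(
                    contig=a.contig,
                    start=s,
                    end=e,
                    guide_up=a if a.start <= b.start else b,
                    guide_down=b if a.start <= b.start else a,
                    unique=True,
                    het_variants=hets,
                )
            )
    out.sort(key=lambda lk: (lk.start, lk.end))
    return out


def build_linker_graph(
    linkers: Sequence[LinkerCandidate], config: DesignConfig
) -> nx.DiGraph:
    """DAG over linkers: edge X→Y iff ``start(Y) - end(X)`` lies in the
    inclusive gap window (and the implied fragment respects any maximum
    fragment length)."""
    g = nx.DiGraph()
    linkers = sorted(linkers, key=lambda lk: (lk.start, lk.end))
    for lk in linkers:
        g.add_node(lk.linker_id, linker=lk)
    starts = [lk.start for lk in linkers]
    for x in linkers:
        lo = bisect_left(starts, x.end + config.gap_min)
        hi = bisect_right(starts, x.end + config.gap_max)
        for y in linkers[lo:hi]:
            frag_len = y.end - x.start
            if config.max_fragment_length and frag_len > config.max_fragment_length:
                continue
            g.add_edge(x.linker_id, y.linker_id, gap=y.start - x.end)
    return g


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------

def _cap_linkers_per_lsa(
    linkers: Sequence[LinkerCandidate],
    subregions: Sequence[SubRegion],
    config: DesignConfig,
) -> list[LinkerCandidate]:
    """Keep at most ``max_linkers_per_lsa`` linkers per LSA, preferring the
    lowest combined guide off-target score, then the leftmost start."""
    kept: list[LinkerCandidate] = []
    for sr in subregions:
        in_lsa = [lk for lk in linkers if sr.lsa_start <= lk.start and lk.end <= sr.lsa_end]
        in_lsa.sort(key=lambda lk: (lk.guide_up.score + lk.guide_down.score, lk.start, lk.end))
        kept.extend(in_lsa[: config.max_linkers_per_lsa])
    uniq = {lk.linker_id: lk for lk in kept}
    return sorted(uniq.values(), key=lambda lk: (lk.start, lk.end))


def _shortest_path(
    graph: nx.DiGraph,
    source_ids: list[str],
    sink_ids: list[str],
    config: DesignConfig,
    selected_guides: set[str],
) -> list[LinkerCandidate]:
    """Min-cost s_1→s_n path; cost = Σ|fragment − F| over interior fragments
    minus a discount for reusing already-selected guides; ties broken by the
    lexicographically smallest sequence of linker starts."""
    F = config.read_length
    discount = config.reuse_discount * F

    def node_bonus(lid: str) -> float:
        lk = graph.nodes[lid]["linker"]
        return -discount * sum(
            g.seq23 in selected_guides for g in (lk.guide_up, lk.guide_down)
        )

    order = sorted(graph.nodes, key=lambda lid: graph.nodes[lid]["linker"].start)
    INF = float("inf")
    best: dict[str, tuple[float, tuple[int, ...], Optional[str]]] = {}
    source_set = set(source_ids)
    for lid in order:
        lk = graph.nodes[lid]["linker"]
        if lid in source_set:
            cand = (node_bonus(lid), (lk.start,), None)
            if lid not in best or cand[:2] < best[lid][:2]:
                best[lid] = cand
        if lid not in best:
            continue
        cost, starts, _ = best[lid]
        for succ in graph.successors(lid):
            sl = graph.nodes[succ]["linker"]
            frag = sl.end - lk.start
            c2 = cost + abs(frag - F) + node_bonus(succ)
            cand = (c2, starts + (sl.start,), lid)
            if succ not in best or cand[:2] < best[succ][:2]:
                best[succ] = cand
    reach = [(best[lid][0], best[lid][1], lid) for lid in sink_ids if lid in best]
    if not reach:
        raise DesignError("no valid linker path from the first to the last sub-region")
    _, _, end_id = min(reach, key=lambda t: (t[0], t[1]))
    path = []
    cur: Optional[str] = end_id
    while cur is not None:
        path.append(graph.nodes[cur]["linker"])
        cur = best[cur][2]
    path.reverse()
    return path


def _fragments_for_path(
    region: TargetRegion,
    path: Sequence[LinkerCandidate],
    genome: Genome,
    config: DesignConfig,
) -> list[PanelFragment]:
    """Fragments implied by a linker path, linkers included; the terminal
    fragments extend outward past the region boundary (clipped to the
    contig / sub-region context)."""
    contig_len = genome.length(region.contig)
    left = max(0, region.start - config.read_length)
    right = min(contig_len, region.end + config.read_length)
    frags = []
    bounds: list[tuple[int, Optional[str]]] = [(left, None)]
    for lk in path:
        bounds.append((lk.start, lk.linker_id))
    prev_start, prev_id = bounds[0]
    for i, lk in enumerate(path):
        frags.append(
            PanelFragment(
                fragment_id=f"{region.name or region.contig}:frag{i}",
                contig=region.contig,
                start=prev_start,
                end=lk.end,
                left_linker=prev_id,
                right_linker=lk.linker_id,
            )
        )
        prev_start, prev_id = lk.start, lk.linker_id
    frags.append(
        PanelFragment(
            fragment_id=f"{region.name or region.contig}:frag{len(path)}",
            contig=region.contig,
            start=prev_start,
            end=right,
            left_linker=prev_id,
            right_linker=None,
        )
    )
    return frags


def select_panel(
    region_inputs: Sequence[tuple[TargetRegion, list[SubRegion], nx.DiGraph]],
    genome: Genome,
    config: DesignConfig,
) -> DesignPanel:
    """Joint panel selection: regions processed longest-first, each picking
    its min-cost path with a discount for guides already selected."""
    ordered = sorted(region_inputs, key=lambda t: -t[0].length)
    selected_guides: set[str] = set()
    designs: dict[str, RegionDesign] = {}
    for region, subs, graph in ordered:
        s1, sn = subs[0], subs[-1]
        src = [
            lid
            for lid in graph.nodes
            if s1.start <= graph.nodes[lid]["linker"].start
            and graph.nodes[lid]["linker"].end <= s1.end
        ]
        snk = [
            lid
            for lid in graph.nodes
            if sn.start <= graph.nodes[lid]["linker"].start
            and graph.nodes[lid]["linker"].end <= sn.end
        ]
        if not src:
            raise DesignError(
                f"region {region.name or region.contig}: no linker candidate in s_1"
            )
        if not snk:
            raise DesignError(
                f"region {region.name or region.contig}: no linker candidate in s_{len(subs)}"
            )
        path = _shortest_path(graph, src, snk, config, selected_guides)
        for lk in path:
            selected_guides.add(lk.guide_up.seq23)
            selected_guides.add(lk.guide_down.seq23)
        designs[region.name or region.contig] = RegionDesign(
            region=region,
            subregions=list(subs),
            linkers=list(path),
            fragments=_fragments_for_path(region, path, genome, config),
        )
    # restore the caller's region order
    out = [designs[r.name or r.contig] for r, _, _ in region_inputs]
    return DesignPanel(regions=out)


def design_panel(
    genome: Genome,
    regions: Sequence[TargetRegion],
    variants: Sequence[VariantRecord] = (),
    config: Optional[DesignConfig] = None,
    index: Optional[GenomeIndex] = None,
) -> DesignPanel:
    """End-to-end design: partition, enumerate, filter, pair, select."""
    config = config or DesignConfig()
    index = index or GenomeIndex(genome)
    inputs = []
    for region in regions:
        subs = partition_subregions(region, config)
        linkers: list[LinkerCandidate] = []
        for sr in subs:
            cands = enumerate_guide_candidates(genome, region.contig, sr.lsa_start, sr.lsa_end)
            cands = filter_unique(cands, index)
            cands = filter_gc(cands, config)
            cands = filter_offtarget(cands, index, config)
            cands = filter_variant_overlap(cands, variants)
            linkers.extend(
                propose_linkers(cands, (sr.lsa_start, sr.lsa_end), index, variants, config)
            )
        uniq = {lk.linker_id: lk for lk in linkers}
        linkers = _cap_linkers_per_lsa(list(uniq.values()), subs, config)
        graph = build_linker_graph(linkers, config)
        inputs.append((region, subs, graph))
    return select_panel(inputs, genome, config)
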