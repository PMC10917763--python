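"""Reference-based heterozygous variant calling and read-backed phasing.

Variants are called from a quality-filtered pileup with a three-condition
heuristic on the two most frequent alleles (minimum combined support, a
majority-of-coverage guard, and an allele-balance guard).  Reads then vote
for allele co-occurrence in a weighted graph; each site pair with total edge
weight >= 10 is tested with a two-sided Fisher's exact test; Bonferroni-style
per-site pruning drops unreliably connected sites, and the surviving
cis/trans constraints are 2-colored into a haplotype pair.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .seqio import AlignmentRecord, CapabilityError, Genome

__all__ = [
    "PileupColumn",
    "HetVariant",
    "AlleleGraph",
    "PairTest",
    "HaplotypePair",
    "build_pileup",
    "call_het_variants",
    "filter_repeat_regions",
    "build_allele_graph",
    "fisher_two_sided",
    "test_pair_phase",
    "bonferroni_prune",
    "assemble_haplotypes",
    "allele_balance",
    "compare_haplotypes",
    "phase_alignments",
]

# Allele encodings in a pileup column: a base string "A".."T", a deletion
# marker, or ("INS", inserted-sequence) keyed at the anchor base.
DELETION = "<del>"

Site = Hashable  # (contig, position) in this module


@dataclass
class PileupColumn:
    contig: str
    position: int
    counts: dict
    n: int  # total aligned reads covering the column (quality-blind)

    def top_two(self) -> list[tuple[object, int]]:
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        return items[:2]


@dataclass
class HetVariant:
    contig: str
    position: int
    allele1: object  # most frequent
    n1: int
    allele2: object
    n2: int

    @property
    def site(self) -> Site:
        return (self.contig, self.position)

    def allele(self, idx: int) -> object:
        return self.allele1 if idx == 1 else self.allele2


def build_pileup(
    alignments: Sequence[AlignmentRecord],
    reference: Genome,
    quality_min: int = 10,
    region: Optional[tuple[str, int, int]] = None,
) -> dict[Site, PileupColumn]:
    """Per-site allele counts from aligned reads.

    Bases below ``quality_min`` are excluded from allele counts but still
    count toward the column total ``n`` (so low-quality piles cannot fake a
    confident call).  Insertions are keyed at their anchor (preceding) base
    together with the inserted sequence; deletions are a distinct allele at
    each deleted position.
    """
    counts: dict[Site, dict] = defaultdict(lambda: defaultdict(int))
    totals: dict[Site, int] = defaultdict(int)
    for aln in alignments:
        if not aln.has_base_level():
            raise CapabilityError(
                f"{aln.read_id}: pileup requires per-base operations and bases"
            )
        if region and aln.contig != region[0]:
            continue
        for site, allele, qual in iter_read_alleles(aln, quality_min):
            if region and not (region[1] <= site[1] < region[2]):
                continue
            totals[site] += 1
            if allele is not None:
                counts[site][allele] += 1
    out = {}
    for site, n in totals.items():
        out[site] = PileupColumn(site[0], site[1], dict(counts.get(site, {})), n)
    return out


def iter_read_alleles(aln: AlignmentRecord, quality_min: int = 10):
    """Yield (site, allele_or_None, quality) for every reference position a
    read covers; ``None`` marks a quality-failing base (counts toward n
    only).  Insertion alleles replace the anchor-base allele."""
    quals = aln.qualities
    bases = aln.bases
    emitted: dict[int, tuple] = {}
    for op, n, rpos, qpos in aln.walk():
        if op in ("M", "=", "X"):
            for k in range(n):
                q = quals[qpos + k] if quals is not None else 60
                allele = bases[qpos + k] if q >= quality_min else None
                emitted[rpos + k] = (allele, q)
        elif op == "D":
            for k in range(n):
                emitted[rpos + k] = (DELETION, 60)
        elif op == "I":
            ins = bases[qpos : qpos + n]
            q = min(quals[qpos : qpos + n]) if quals is not None else 60
            anchor = rpos - 1
            if anchor in emitted and emitted[anchor][0] is not None:
                base = emitted[anchor][0]
                if base != DELETION and q >= quality_min:
                    emitted[anchor] = (("INS", str(base) + ins), min(emitted[anchor][1], q))
    for rpos in sorted(emitted):
        allele, q = emitted[rpos]
        yield (aln.contig, rpos), allele, q


def call_het_variants(
    columns: Mapping[Site, PileupColumn] | Iterable[PileupColumn],
    min_support: int = 10,
) -> list[HetVariant]:
    """Heuristic heterozygous call: with top-two allele counts n1 >= n2 and
    column total n, a site is het iff (i) n1+n2 >= 10, (ii) n1+n2 >= n/2,
    and (iii) n1 <= 2*n2 and n2 <= 2*n1."""
    if isinstance(columns, Mapping):
        columns = columns.values()
    out = []
    for col in columns:
        top = col.top_two()
        if len(top) < 2:
            continue
        (a1, n1), (a2, n2) = top
        if n1 + n2 < min_support:
            continue
        if n1 + n2 < col.n / 2:
            continue
        if n1 > 2 * n2 or n2 > 2 * n1:
            continue
        out.append(HetVariant(col.contig, col.position, a1, n1, a2, n2))
    out.sort(key=lambda v: (v.contig, v.position))
    return out


def in_repeat_region(reference: Genome, contig: str, position: int, min_copies: int = 5) -> bool:
    """True if ``position`` lies inside a run of >= min_copies consecutive
    copies of any 1-bp or 2-bp unit (e.g. AAAAA or ATATATATAT)."""
    seq = reference.sequences[contig]
    for unit in (1, 2):
        need = unit * min_copies
        lo = max(0, position - need + 1)
        hi = min(len(seq), position + need)
        window = seq[lo:hi]
        for s in range(len(window)):
            u = window[s : s + unit]
            if len(u) < unit:
                break
            if unit == 2 and u[0] == u[1]:
                continue  # a doubled base is a 1-bp unit
            e = s + unit
            while window[e : e + unit] == u:
                e += unit
            if e - s >= need and s <= position - lo < e:
                return True
    return False


def filter_repeat_regions(
    variants: Sequence[HetVariant], reference: Genome, min_copies: int = 5
) -> list[HetVariant]:
    """Drop variants inside short tandem repeat runs (>= 5 copies of a 1-bp
    or 2-bp unit), where base calling and alignment are unreliable."""
    return [
        v
        for v in variants
        if not in_repeat_region(reference, v.contig, v.position, min_copies)
    ]


class AlleleGraph:
    """Undirected weighted graph over (site, allele-index) nodes; the weight
    of an edge is the number of reads carrying both alleles."""

    def __init__(self, variants: Sequence[HetVariant]):
        self.variants: dict[Site, HetVariant] = {v.site: v for v in variants}
        self.weights: dict[tuple, int] = defaultdict(int)
        self.pair_totals: dict[tuple[Site, Site], int] = defaultdict(int)

    def _edge(self, i: Site, s: int, j: Site, t: int) -> tuple:
        if (j, t) < (i, s):
            (i, s), (j, t) = (j, t), (i, s)
        return (i, s, j, t)

    def add_cooccurrence(self, i: Site, s: int, j: Site, t: int) -> None:
        if i == j:
            return
        self.weights[self._edge(i, s, j, t)] += 1
        key = (i, j) if i <= j else (j, i)
        self.pair_totals[key] += 1

    def w(self, i: Site, s: int, j: Site, t: int) -> int:
        return self.weights.get(self._edge(i, s, j, t), 0)

    def table(self, i: Site, j: Site) -> list[list[int]]:
        return [
            [self.w(i, 1, j, 1), self.w(i, 1, j, 2)],
            [self.w(i, 2, j, 1), self.w(i, 2, j, 2)],
        ]

    def tested_pairs(self, min_total: int = 10) -> list[tuple[Site, Site]]:
        return sorted(k for k, tot in self.pair_totals.items() if tot >= min_total)


def build_allele_graph(
    variants: Sequence[HetVariant],
    alignments: Sequence[AlignmentRecord],
    quality_min: int = 10,
) -> AlleleGraph:
    """Assign each read to the alleles it carries at the called sites and
    count pairwise co-occurrences; a read carrying neither top allele at a
    site contributes nothing there."""
    graph = AlleleGraph(variants)
    sites = graph.variants
    for aln in alignments:
        carried: list[tuple[Site, int]] = []
        for site, allele, _q in iter_read_alleles(aln, quality_min):
            v = sites.get(site)
            if v is None or allele is None:
                continue
            if allele == v.allele1:
                carried.append((site, 1))
            elif allele == v.allele2:
                carried.append((site, 2))
        for a in range(len(carried)):
            for b in range(a + 1, len(carried)):
                (i, s), (j, t) = carried[a], carried[b]
                graph.add_cooccurrence(i, s, j, t)
    return graph


@dataclass
class PairTest:
    site_i: Site
    site_j: Site
    table: list[list[int]]
    p_value: Optional[float]
    orientation: str  # {"cis", "trans", "none"}

    @property
    def total_weight(self) -> int:
        return sum(self.table[0]) + sum(self.table[1])


def fisher_two_sided(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table."""
    _, p = fisher_exact(table, alternative="two-sided")
    return float(p)


def test_pair_phase(
    graph: AlleleGraph, i: Site, j: Site, min_total: int = 10, alpha: float = 0.05
) -> PairTest:
    """Fisher's exact test (two-sided) on the 2x2 allele co-occurrence table.

    Pairs with total weight < 10 are untested (orientation "none", no p).
    Significant pairs are cis (allele 1 of i travels with allele 1 of j)
    when w11 > w12, trans when w11 < w12; a tie yields no assignment.
    """
    table = graph.table(i, j)
    total = sum(table[0]) + sum(table[1])
    if total < min_total:
        return PairTest(i, j, table, None, "none")
    p = fisher_two_sided(table)
    orientation = "none"
    if p < alpha:
        w11, w12 = table[0]
        if w11 > w12:
            orientation = "cis"
        elif w11 < w12:
            orientation = "trans"
    return PairTest(i, j, table, float(p), orientation)


def bonferroni_prune(
    tests: Sequence[PairTest], alpha: float = 0.05
) -> tuple[set[Site], dict[Site, str]]:
    """Per-site pruning of unreliably connected sites.

    For each site, its pair p-values are Bonferroni-corrected within the
    site's own family (multiplied by the number of tests involving the site,
    capped at 1).  The site is excluded iff fewer than one-third of the
    corrected p-values are significant; exactly one-third retains.  Sites
    with no tested pair are excluded with reason "untested".
    """
    per_site: dict[Site, list[float]] = defaultdict(list)
    sites: set[Site] = set()
    for t in tests:
        sites.add(t.site_i)
        sites.add(t.site_j)
        if t.p_value is not None:
            per_site[t.site_i].append(t.p_value)
            per_site[t.site_j].append(t.p_value)
    retained: set[Site] = set()
    excluded: dict[Site, str] = {}
    for site in sites:
        pvals = per_site.get(site, [])
        if not pvals:
            excluded[site] = "untested"
            continue
        m = len(pvals)
        sig = sum(1 for p in pvals if min(1.0, p * m) < alpha)
        if 3 * sig >= m:
            retained.add(site)
        else:
            excluded[site] = f"unreliable ({sig}/{m} significant after correction)"
    return retained, excluded


@dataclass
class HaplotypePair:
    """Phased blocks: per block a list of (site, allele-index-on-haplotype-1),
    sites ordered by genomic position; haplotype 2 takes the other allele.
    Unique up to a global swap within each block."""

    blocks: list[list[tuple[Site, int]]]
    excluded: dict[Site, str] = field(default_factory=dict)
    conflicts: int = 0

    def phased_sites(self) -> dict[Site, tuple[int, int]]:
        out = {}
        for bi, block in enumerate(self.blocks):
            for site, idx in block:
                out[site] = (bi, idx)
        return out


class _ParityUnionFind:
    def __init__(self):
        self.parent: dict = {}
        self.parity: dict = {}

    def add(self, x) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.parity[x] = 0

    def union(self, x, y, rel: int) -> bool:
        """Join with x ~ y at relative parity ``rel`` (0 same, 1 opposite).
        Returns False on conflict."""
        rx, px = self._find(x)
        ry, py = self._find(y)
        if rx == ry:
            return (px ^ py) == rel
        self.parent[ry] = rx
        self.parity[ry] = px ^ py ^ rel
        return True

    def _find(self, x):
        path = []
        while self.parent[x] != x:
            path.append(x)
            x = self.parent[x]
        root = x
        acc = 0
        for node in reversed(path):
            acc ^= self.parity[node]
        # second pass to set compressed parities
        run = 0
        for node in reversed(path):
            run ^= self.parity[node]
            self.parity[node] = run
            self.parent[node] = root
        return root, acc


def assemble_haplotypes(
    tests: Sequence[PairTest],
    retained: set[Site],
) -> HaplotypePair:
    """2-color the significant cis/trans constraints among retained sites.

    Constraints are applied in decreasing total-weight order so that a
    conflicting (weaker) constraint loses; conflicts are counted.  Each
    connected component becomes a phase block, sites ordered left to right,
    canonicalized so the leftmost site carries its allele 1 on haplotype 1.
    """
    uf = _ParityUnionFind()
    for site in retained:
        uf.add(site)
    constraints = [
        t for t in tests if t.orientation in ("cis", "trans")
        and t.site_i in retained and t.site_j in retained
    ]
    constraints.sort(key=lambda t: (-t.total_weight, str(t.site_i), str(t.site_j)))
    conflicts = 0
    for t in constraints:
        rel = 0 if t.orientation == "cis" else 1
        if not uf.union(t.site_i, t.site_j, rel):
            conflicts += 1
    comps: dict[Site, list[tuple[Site, int]]] = defaultdict(list)
    for site in retained:
        root, parity = uf._find(site)
        comps[root].append((site, parity))
    blocks = []
    for members in comps.values():
        members.sort(key=lambda sp: sp[0])
        base = members[0][1]
        block = [(site, 1 + (parity ^ base)) for site, parity in members]
        blocks.append(block)
    blocks.sort(key=lambda b: b[0][0])
    return HaplotypePair(blocks=blocks, conflicts=conflicts)


def allele_balance(variants: Sequence[HetVariant]) -> float:
    """Mean frequency of the second most frequent allele, n2/(n1+n2)."""
    if not variants:
        raise ValueError("no variants")
    return float(np.mean([v.n2 / (v.n1 + v.n2) for v in variants]))


def compare_haplotypes(
    predicted: HaplotypePair,
    variants: Mapping[Site, HetVariant] | Sequence[HetVariant],
    truth: Mapping[Site, tuple[object, object]],
) -> dict:
    """Concordance of predicted phasing with truth (hap1 allele, hap2 allele)
    per site, under the best global swap per block; also counts switch
    errors (adjacent shared-site pairs whose relative orientation flips)."""
    if not isinstance(variants, Mapping):
        variants = {v.site: v for v in variants}
    n_phased = sum(len(b) for b in predicted.blocks)
    shared = 0
    matches = 0
    switches = 0
    for block in predicted.blocks:
        flags = []  # 0: predicted hap1 allele == truth hap1 allele; 1: flipped
        for site, idx in block:
            if site not in truth or site not in variants:
                continue
            v = variants[site]
            pred_h1 = v.allele(idx)
            t1, t2 = truth[site]
            if pred_h1 == t1:
                flags.append(0)
            elif pred_h1 == t2:
                flags.append(1)
            # alleles not matching truth at all are ignored here
        if not flags:
            continue
        shared += len(flags)
        d = sum(flags)
        matches += max(d, len(flags) - d)
        switches += sum(1 for a, b in zip(flags, flags[1:]) if a != b)
    if shared == 0:
        raise ValueError("no sites shared between prediction and truth")
    return {
        "phased_sites": n_phased,
        "shared_sites": shared,
        "matching_sites": matches,
        "switch_errors": switches,
    }


def phase_alignments(
    alignments: Sequence[AlignmentRecord],
    reference: Genome,
    quality_min: int = 10,
    min_pair_weight: int = 10,
    alpha: float = 0.05,
    repeat_filter: bool = True,
    region: Optional[tuple[str, int, int]] = None,
) -> tuple[HaplotypePair, list[HetVariant], AlleleGraph]:
    """Full reference-based pipeline: pileup → het calls → repeat filter →
    allele graph → pair tests → pruning → haplotype assembly."""
    columns = build_pileup(alignments, reference, quality_min, region)
    variants = call_het_variants(columns)
    if repeat_filter:
        variants = filter_repeat_regions(variants, reference)
    graph = build_allele_graph(variants, alignments, quality_min)
    tests = [
        test_pair_phase(graph, i, j, min_pair_weight, alpha)
        for i, j in graph.tested_pairs(min_pair_weight)
    ]
    retained, excluded = bonferroni_prune(tests, alpha)
    pair = assemble_haplotypes(tests, retained)
    pair.excluded.update(excluded)
    return pair, variants, graph
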