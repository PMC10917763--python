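"""Fragmentation-efficiency and target-enrichment analysis.

A read whose alignment terminates at a designed linker boundary witnesses a
formed linker; a read whose alignment crosses the whole linker contiguously
witnesses a failed one.  The per-linker formation ratio
``r = with / (with + spanning)`` then composes into per-fragment
fragmentation efficiencies: a terminal fragment forms whenever its single
flanking linker forms (efficiency ``100·r``), an interior fragment needs
linker generation on both ends (``100·r_left·r_right``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .design import DesignPanel, PanelFragment
from .seqio import AlignmentRecord, Genome

__all__ = [
    "LinkerObservation",
    "EfficiencyReport",
    "EnrichmentProfile",
    "classify_reads_at_linker",
    "linker_formation_ratio",
    "fragment_efficiency",
    "efficiency_report",
    "enrichment_profile",
]


@dataclass
class LinkerObservation:
    linker_id: str
    reads_with_linker: int
    reads_spanning: int

    def __post_init__(self) -> None:
        if self.reads_with_linker < 0 or self.reads_spanning < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EfficiencyReport:
    """Per-linker counts/ratios and per-fragment efficiencies (percent)."""

    observations: dict[str, LinkerObservation]
    ratios: dict[str, float]
    fragment_percent: dict[str, float]
    fragments: list[PanelFragment]

    def to_rows(self) -> list[dict]:
        rows = []
        for frag in self.fragments:
            row: dict = {
                "fragment_id": frag.fragment_id,
                "contig": frag.contig,
                "start": frag.start,
                "end": frag.end,
                "length": frag.end - frag.start,
                "left_linker": frag.left_linker or "",
                "right_linker": frag.right_linker or "",
                "efficiency_percent": round(self.fragment_percent[frag.fragment_id], 1),
            }
            rows.append(row)
        return rows


def classify_reads_at_linker(
    alignments: Sequence[AlignmentRecord],
    linker_id: str,
    linker_interval: tuple[str, int, int],
    tolerance: int = 50,
) -> LinkerObservation:
    """Count reads terminating at a linker versus reads crossing it.

    With-linker: one read end within ±tolerance of the matching linker
    boundary and the read covering at least ``linker length − tolerance`` of
    the linker.  Spanning: the alignment contiguously covers
    ``[start − tolerance, end + tolerance]``.  Each read is counted at most
    once per linker.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    contig, start, end = linker_interval
    length = end - start
    seen: set[str] = set()
    n_with = n_span = 0
    for aln in alignments:
        if aln.contig != contig or aln.read_id in seen:
            continue
        overlap = min(aln.ref_end, end) - max(aln.ref_start, start)
        if overlap < min(length - tolerance, length):
            continue
        ends_at = (
            abs(aln.ref_end - end) <= tolerance or abs(aln.ref_start - start) <= tolerance
        )
        spans = aln.ref_start <= start - tolerance and aln.ref_end >= end + tolerance
        if ends_at and not spans:
            n_with += 1
            seen.add(aln.read_id)
        elif spans:
            n_span += 1
            seen.add(aln.read_id)
    return LinkerObservation(linker_id, n_with, n_span)


def linker_formation_ratio(observation: LinkerObservation) -> float:
    """Fraction of linker-bearing reads among all reads informative at the
    linker: ``r = with / (with + spanning)``."""
    total = observation.reads_with_linker + observation.reads_spanning
    if total == 0:
        raise ZeroDivisionError(
            f"linker {observation.linker_id}: no informative reads (with + spanning = 0)"
        )
    return observation.reads_with_linker / total


def fragment_efficiency(
    fragment: PanelFragment, ratios: Mapping[str, float]
) -> float:
    """Fragmentation efficiency of a fragment, in percent.

    Interior fragments require linker generation on both ends
    (product of the flanking formation ratios); terminal fragments form with
    their single flanking linker.
    """
    r = 1.0
    flanks = [l for l in (fragment.left_linker, fragment.right_linker) if l is not None]
    if not flanks:
        raise ValueError(f"fragment {fragment.fragment_id} has no flanking linker")
    for lid in flanks:
        if lid not in ratios:
            raise KeyError(f"no formation ratio available for linker {lid}")
        r *= ratios[lid]
    return 100.0 * r


def efficiency_report(
    alignments: Sequence[AlignmentRecord],
    panel: DesignPanel,
    tolerance: int = 50,
) -> EfficiencyReport:
    """Per-linker counts and per-fragment efficiencies for a whole panel."""
    observations: dict[str, LinkerObservation] = {}
    ratios: dict[str, float] = {}
    for lk in panel.linkers:
        obs = classify_reads_at_linker(
            alignments, lk.linker_id, (lk.contig, lk.start, lk.end), tolerance
        )
        observations[lk.linker_id] = obs
        if obs.reads_with_linker + obs.reads_spanning > 0:
            ratios[lk.linker_id] = linker_formation_ratio(obs)
    percents = {
        frag.fragment_id: fragment_efficiency(frag, ratios) for frag in panel.fragments
    }
    return EfficiencyReport(
        observations=observations,
        ratios=ratios,
        fragment_percent=percents,
        fragments=list(panel.fragments),
    )


@dataclass
class EnrichmentProfile:
    """Mean depth across 100 scaled bins of each flank and of the body,
    averaged over regions, plus the genome-wide baseline and fold enrichment
    (mean target-body depth over genome-wide mean depth)."""

    left_flank: np.ndarray  # 100 bins
    body: np.ndarray  # 100 bins
    right_flank: np.ndarray  # 100 bins
    target_mean: float
    baseline: float

    @property
    def fold(self) -> float:
        return self.target_mean / self.baseline if self.baseline > 0 else float("inf")


def _depth_arrays(
    alignments: Sequence[AlignmentRecord], genome: Genome
) -> dict[str, np.ndarray]:
    depth = {c: np.zeros(genome.length(c) + 1, dtype=np.int64) for c in genome.contigs()}
    for aln in alignments:
        if aln.contig in depth:
            d = depth[aln.contig]
            d[max(aln.ref_start, 0)] += 1
            d[min(aln.ref_end, len(d) - 1)] -= 1
    return {c: np.cumsum(d)[:-1] for c, d in depth.items()}


def _binned_means(depth: np.ndarray, start: int, end: int, nbins: int = 100) -> np.ndarray:
    """Mean depth in ``nbins`` equal-sized sub-intervals of [start, end),
    clipped to the array; fractional bin widths use rounded edges."""
    start = max(start, 0)
    end = min(end, len(depth))
    if end <= start:
        return np.zeros(nbins)
    edges = np.linspace(start, end, nbins + 1)
    out = np.empty(nbins)
    for i in range(nbins):
        lo, hi = int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))
        out[i] = depth[lo:hi].mean() if hi > lo else 0.0
    return out


def enrichment_profile(
    alignments: Sequence[AlignmentRecord],
    regions: Sequence[tuple[str, int, int]],
    genome: Genome,
    flank: int = 20_000,
    nbins: int = 100,
) -> EnrichmentProfile:
    """Scaled depth profile over region bodies and their flanks.

    Each region body and each ``flank``-bp flank is split into ``nbins``
    equal bins; bin means are averaged across regions.  Fold enrichment is
    the mean per-base depth over the region bodies divided by the
    genome-wide mean depth.
    """
    depth = _depth_arrays(alignments, genome)
    left = np.zeros(nbins)
    body = np.zeros(nbins)
    right = np.zeros(nbins)
    target_total = 0.0
    target_len = 0
    for contig, start, end in regions:
        d = depth[contig]
        left += _binned_means(d, start - flank, start, nbins)
        body += _binned_means(d, start, end, nbins)
        right += _binned_means(d, end, end + flank, nbins)
        target_total += float(d[start:end].sum())
        target_len += end - start
    k = len(regions)
    genome_bases = sum(genome.length(c) for c in genome.contigs())
    baseline = sum(float(d.sum()) for d in depth.values()) / genome_bases
    return EnrichmentProfile(
        left_flank=left / k,
        body=body / k,
        right_flank=right / k,
        target_mean=target_total / target_len,
        baseline=baseline,
    )
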