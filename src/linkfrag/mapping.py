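"""Desk-scale read-to-reference mapping.

A thin seed-and-extend wrapper around the semiglobal aligner: an exact
k-mer from the read locates a candidate window on the reference (both
orientations are tried), and the read is aligned semiglobally inside the
window.  This is intended for simulated libraries and other small loci
(windows are capped at 200 kbp); genome-scale alignment is expected to be
ingested as SAM/PAF from a production aligner instead.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .seqio import AlignmentRecord, Genome, Read, alignment_cost, revcomp, semiglobal_align

__all__ = ["align_read", "align_reads"]


def _seed_window(
    bases: str, seq: str, k: int, offsets: Sequence[int], margin: int
) -> Optional[tuple[int, int]]:
    for off in offsets:
        if off + k > len(bases):
            break
        kmer = bases[off : off + k]
        pos = seq.find(kmer)
        if pos < 0 or seq.find(kmer, pos + 1) >= 0:
            continue  # absent or ambiguous seed
        start = max(0, pos - off - margin)
        end = min(len(seq), pos - off + len(bases) + margin)
        return start, end
    return None


def align_read(
    read: Read,
    genome: Genome,
    contig: Optional[str] = None,
    k: int = 24,
    margin: int = 300,
) -> Optional[AlignmentRecord]:
    """Align one read to a contig, trying both orientations; returns the
    lower-cost alignment, or None if no seed anchors the read anywhere."""
    contig = contig or genome.contigs()[0]
    seq = genome.sequences[contig]
    offsets = list(range(0, max(len(read.bases) - k, 1), max(len(read.bases) // 8, 200)))
    best: Optional[AlignmentRecord] = None
    best_strand = "+"
    for strand, bases, quals in (
        ("+", read.bases, read.qualities),
        ("-", revcomp(read.bases), read.qualities[::-1] if read.qualities else None),
    ):
        win = _seed_window(bases, seq, k, offsets, margin)
        if win is None:
            continue
        aln = semiglobal_align(
            bases, seq[win[0] : win[1]], contig=contig, window_offset=win[0], read_id=read.id
        )
        aln.qualities = quals
        aln.strand = strand
        if best is None or alignment_cost(aln) < alignment_cost(best):
            best = aln
            best_strand = strand
    if best is not None:
        best.strand = best_strand
    return best


def align_reads(
    reads: Sequence[Read],
    genome: Genome,
    contig: Optional[str] = None,
    k: int = 24,
    margin: int = 300,
) -> list[AlignmentRecord]:
    """Align a batch of reads, silently dropping reads that fail to seed
    (mirroring an aligner's unmapped fraction)."""
    out = []
    for read in reads:
        aln = align_read(read, genome, contig, k, margin)
        if aln is not None:
            out.append(aln)
    return out
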