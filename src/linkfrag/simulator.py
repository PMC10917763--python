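"""Synthetic linked-fragment library generator with full truth tracking.

The generator emulates the library that paired-nickase linker chemistry
produces from a diploid locus: molecules drawn from either haplotype, each
designed linker independently forming (and when it forms, depositing a full
tandem copy of the linker on BOTH resulting fragments), non-formed linkers
leaving the molecule contiguous, background reads from off-target sequence
at a suppressed rate, and nanopore-like substitution/indel errors.

Linker formation is parameterized by the *observable* read-space formation
ratio ``e``: a formed linker yields two linker-terminated reads while an
unformed one yields a single spanning read, so a molecule-level firing
probability ``p = e/(2-e)`` makes the with/(with+spanning) estimator of the
efficiency module converge to the configured ``e``.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import DesignPanel
from .seqio import Genome, Read, VariantRecord, revcomp

__all__ = [
    "SimConfig",
    "DiploidGenome",
    "SimTruth",
    "make_diploid_genome",
    "simulate_linked_fragments",
    "simulate_background",
    "add_read_errors",
    "simulate_library",
    "write_truth",
    "read_truth",
    "firing_probability",
    "expected_enrichment_fold",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for a synthetic library.

    Rates are per base; ``linker_efficiency`` is the read-space formation
    ratio each linker should exhibit (per-linker dict or a global float).
    """

    genome_length: int = 200_000
    snv_rate: float = 1e-3
    indel_rate: float = 1e-4
    gc: float = 0.5
    linker_efficiency: float | dict[str, float] = 0.9
    depth: float = 50.0
    background_rate: float = 0.0  # reads per kbp of off-target genome
    background_median_length: int = 8_000
    background_sigma: float = 0.5  # log-normal shape
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    end_jitter_sd: float = 0.0  # bp, truncation jitter of fragment ends
    terminal_margin: int = 2_000  # molecule overhang beyond the outermost linkers
    base_quality: int = 30
    error_quality: int = 5
    seed: int = 0

    def efficiency_of(self, linker_id: str) -> float:
        if isinstance(self.linker_efficiency, dict):
            return self.linker_efficiency[linker_id]
        return float(self.linker_efficiency)


def firing_probability(e: float) -> float:
    """Molecule-level firing probability giving read-space formation ratio e."""
    if not 0.0 <= e <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    return e / (2.0 - e)


@dataclass
class SimTruth:
    read_id: str
    haplotype: int  # 1 or 2; 0 for background convention-free reads
    molecule: int
    fragment_index: int
    left_linker: Optional[str]
    right_linker: Optional[str]
    is_background: bool = False


@dataclass
class DiploidGenome:
    """A reference contig plus two haplotypes differing at phased variants."""

    reference: Genome
    contig: str
    haplotypes: tuple[str, str]
    variants: list[VariantRecord]
    # ref->haplotype coordinate maps: sorted ref breakpoints and offsets
    _breaks: tuple[list[int], list[int]] = field(default=([], []))
    _offsets: tuple[list[int], list[int]] = field(default=([], []))

    def ref_to_hap(self, pos: int, hap: int) -> int:
        br = self._breaks[hap - 1]
        off = self._offsets[hap - 1]
        i = bisect_right(br, pos)
        return pos + (off[i - 1] if i > 0 else 0)

    def hap_fetch(self, ref_start: int, ref_end: int, hap: int) -> str:
        a = self.ref_to_hap(ref_start, hap)
        b = self.ref_to_hap(ref_end, hap)
        return self.haplotypes[hap - 1][a:b]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def make_diploid_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None, contig: str = "sim"
) -> DiploidGenome:
    """Random reference with phased heterozygous SNVs/indels planted at the
    configured rates (alt allele on haplotype 1 or 2 by fair coin)."""
    rng = rng or np.random.default_rng(config.seed)
    L = config.genome_length
    ref = _random_sequence(rng, L, config.gc)
    n_snv = rng.binomial(L, config.snv_rate)
    n_indel = rng.binomial(L, config.indel_rate)
    margin = 30
    positions = rng.choice(
        np.arange(margin, L - margin), size=n_snv + n_indel, replace=False
    )
    positions.sort()
    # drop variants closer than 12 bp so alleles never overlap
    keep = [0] if len(positions) else []
    for i in range(1, len(positions)):
        if positions[i] - positions[keep[-1]] >= 12:
            keep.append(i)
    positions = positions[keep]
    kinds = rng.permutation(
        np.array(["snv"] * n_snv + ["indel"] * n_indel)[: len(positions)]
    )
    variants: list[VariantRecord] = []
    for pos, kind in zip(positions, kinds):
        pos = int(pos)
        if kind == "snv":
            refb = ref[pos]
            alt = _BASES[rng.integers(0, 4)].tobytes().decode()
            while alt == refb:
                alt = _BASES[rng.integers(0, 4)].tobytes().decode()
            v = VariantRecord(contig, pos, refb, alt, "het", int(rng.integers(1, 3)))
        else:
            ln = int(rng.integers(1, 6))
            if rng.random() < 0.5:  # insertion after the anchor base
                ins = _random_sequence(rng, ln, config.gc)
                v = VariantRecord(contig, pos, ref[pos], ref[pos] + ins, "het", int(rng.integers(1, 3)))
            else:  # deletion of ln bases after the anchor
                v = VariantRecord(
                    contig, pos, ref[pos : pos + ln + 1], ref[pos], "het", int(rng.integers(1, 3))
                )
        variants.append(v)
    haps = []
    breaks: list[list[int]] = []
    offsets: list[list[int]] = []
    for hap in (1, 2):
        parts = []
        cur = 0
        br: list[int] = []
        off: list[int] = []
        delta = 0
        for v in variants:
            if v.phase != hap:
                continue
            parts.append(ref[cur : v.position])
            parts.append(v.alt)
            cur = v.ref_end
            delta += len(v.alt) - len(v.ref)
            br.append(v.ref_end)
            off.append(delta)
        parts.append(ref[cur:])
        haps.append("".join(parts))
        breaks.append(br)
        offsets.append(off)
    return DiploidGenome(
        reference=Genome({contig: ref}),
        contig=contig,
        haplotypes=(haps[0], haps[1]),
        variants=variants,
        _breaks=(breaks[0], breaks[1]),
        _offsets=(offsets[0], offsets[1]),
    )


def simulate_linked_fragments(
    diploid: DiploidGenome,
    panel: DesignPanel,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Read], list[SimTruth]]:
    """Emit one read per fragment of each simulated target molecule.

    A molecule spans the panel's fragment context; each selected linker fires
    independently (probability ``e/(2-e)``); fired linkers cut the molecule
    with the full linker duplicated onto both flanking fragments.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    reads: list[Read] = []
    truths: list[SimTruth] = []
    mol = 0
    for rd in panel.regions:
        if rd.region.contig != diploid.contig:
            raise ValueError(
                f"panel region {rd.region.name} is on {rd.region.contig}, "
                f"not the simulated contig {diploid.contig}"
            )
        contig_len = diploid.reference.length(diploid.contig)
        span_start = max(0, rd.fragments[0].start - config.terminal_margin)
        span_end = min(contig_len, rd.fragments[-1].end + config.terminal_margin)
        n_molecules = int(round(config.depth))
        linkers = rd.linkers
        for _ in range(n_molecules):
            mol += 1
            hap = int(rng.integers(1, 3))
            fired = [
                lk
                for lk in linkers
                if rng.random() < firing_probability(config.efficiency_of(lk.linker_id))
            ]
            cuts: list[tuple[int, int, Optional[str]]] = (
                [(span_start, span_start, None)]
                + [(lk.start, lk.end, lk.linker_id) for lk in fired]
                + [(span_end, span_end, None)]
            )
            for fi in range(len(cuts) - 1):
                left_start, _, left_id = cuts[fi]
                _, right_end, right_id = cuts[fi + 1]
                a, b = left_start, right_end
                if config.end_jitter_sd > 0:
                    a += int(round(rng.normal(0, config.end_jitter_sd)))
                    b += int(round(rng.normal(0, config.end_jitter_sd)))
                    a = max(span_start, min(a, b - 50))
                    b = min(span_end, max(b, a + 50))
                seq = diploid.hap_fetch(a, b, hap)
                rid = f"mol{mol}_frag{fi}"
                read = Read(rid, seq, [config.base_quality] * len(seq))
                if rng.random() < 0.5:
                    read = Read(rid, revcomp(seq), read.qualities[::-1])
                reads.append(read)
                truths.append(
                    SimTruth(
                        read_id=rid,
                        haplotype=hap,
                        molecule=mol,
                        fragment_index=fi,
                        left_linker=left_id,
                        right_linker=right_id,
                        is_background=False,
                    )
                )
    return reads, truths


def _offtarget_intervals(
    diploid: DiploidGenome, panel: DesignPanel, margin: int = 0
) -> list[tuple[int, int]]:
    L = diploid.reference.length(diploid.contig)
    spans = sorted(
        (max(0, rd.fragments[0].start - margin), min(L, rd.fragments[-1].end + margin))
        for rd in panel.regions
    )
    out = []
    cur = 0
    for s, e in spans:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < L:
        out.append((cur, L))
    return out


def simulate_background(
    diploid: DiploidGenome,
    panel: DesignPanel,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Read], list[SimTruth]]:
    """Residual off-target reads (Poisson count at ``background_rate`` reads
    per kbp of off-target genome; log-normal lengths, clipped to stay inside
    their off-target interval)."""
    rng = rng or np.random.default_rng(config.seed + 2)
    intervals = _offtarget_intervals(diploid, panel, config.terminal_margin)
    off_bp = sum(e - s for s, e in intervals)
    n = rng.poisson(config.background_rate * off_bp / 1000.0)
    reads: list[Read] = []
    truths: list[SimTruth] = []
    if not intervals or n == 0:
        return reads, truths
    weights = np.array([e - s for s, e in intervals], dtype=float)
    weights /= weights.sum()
    mu = math.log(config.background_median_length)
    for i in range(n):
        s, e = intervals[rng.choice(len(intervals), p=weights)]
        length = int(rng.lognormal(mu, config.background_sigma))
        length = max(200, length)
        start = int(rng.integers(s, e))
        end = min(start + length, e)
        hap = int(rng.integers(1, 3))
        seq = diploid.hap_fetch(start, end, hap)
        rid = f"bg{i}"
        read = Read(rid, seq, [config.base_quality] * len(seq))
        if rng.random() < 0.5:
            read = Read(rid, revcomp(seq), read.qualities[::-1])
        reads.append(read)
        truths.append(SimTruth(rid, hap, -1, -1, None, None, is_background=True))
    return reads, truths


def add_read_errors(
    reads: Sequence[Read], config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[Read]:
    """Apply iid per-base substitution/insertion/deletion errors; error bases
    receive ``error_quality`` so quality-aware consumers can suppress them."""
    rng = rng or np.random.default_rng(config.seed + 3)
    if config.sub_rate == config.ins_rate == config.del_rate == 0:
        return list(reads)
    out = []
    for read in reads:
        arr = np.frombuffer(read.bases.encode(), dtype=np.uint8)
        quals = np.asarray(
            read.qualities if read.qualities is not None else [config.base_quality] * len(arr),
            dtype=np.int16,
        ).copy()
        u = rng.random(len(arr))
        subs = u < config.sub_rate
        dels = (u >= config.sub_rate) & (u < config.sub_rate + config.del_rate)
        ins = (u >= config.sub_rate + config.del_rate) & (
            u < config.sub_rate + config.del_rate + config.ins_rate
        )
        if subs.any():
            shift = rng.integers(1, 4, size=int(subs.sum()))
            idx = np.flatnonzero(subs)
            base_idx = np.searchsorted(_BASES, 0)  # placeholder
            lut = np.full(256, 0, dtype=np.uint8)
            for k, b in enumerate(_BASES):
                lut[b] = k
            arr = arr.copy()
            arr[idx] = _BASES[(lut[arr[idx]] + shift) % 4]
            quals[idx] = config.error_quality
        if dels.any() or ins.any():
            pieces = []
            qpieces = []
            prev = 0
            events = sorted(
                [(int(i), "D") for i in np.flatnonzero(dels)]
                + [(int(i), "I") for i in np.flatnonzero(ins)]
            )
            for pos, kind in events:
                pieces.append(arr[prev:pos])
                qpieces.append(quals[prev:pos])
                if kind == "I":
                    pieces.append(arr[pos : pos + 1])
                    qpieces.append(quals[pos : pos + 1])
                    pieces.append(_BASES[rng.integers(0, 4, size=1)])
                    qpieces.append(np.array([config.error_quality], dtype=np.int16))
                prev = pos + 1 if kind == "D" else pos + 1
            pieces.append(arr[prev:])
            qpieces.append(quals[prev:])
            arr = np.concatenate(pieces)
            quals = np.concatenate(qpieces)
        out.append(Read(read.id, arr.tobytes().decode(), [int(q) for q in quals]))
    return out


def simulate_library(
    diploid: DiploidGenome,
    panel: DesignPanel,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Read], list[SimTruth]]:
    """Target molecules + background, with errors applied; one call, one seed."""
    rng = rng or np.random.default_rng(config.seed)
    reads, truths = simulate_linked_fragments(diploid, panel, config, rng)
    bg_reads, bg_truths = simulate_background(diploid, panel, config, rng)
    reads = add_read_errors(reads + bg_reads, config, rng)
    return reads, truths + bg_truths


def expected_enrichment_fold(
    diploid: DiploidGenome, panel: DesignPanel, config: SimConfig
) -> float:
    """Analytic fold enrichment implied by the study conditions.

    Region bodies see one full pass per molecule, so the expected body depth
    is the molecule count; the genome-wide baseline adds the on-target bases
    (including the extra linker copy each fired linker duplicates) and the
    expected background bases (log-normal mean length; end clipping at
    off-target interval boundaries is ignored, a ≲3% effect).
    """
    L = sum(diploid.reference.length(c) for c in diploid.reference.contigs())
    n_mol = int(round(config.depth))
    on_bases = 0.0
    for rd in panel.regions:
        contig_len = diploid.reference.length(rd.region.contig)
        span_start = max(0, rd.fragments[0].start - config.terminal_margin)
        span_end = min(contig_len, rd.fragments[-1].end + config.terminal_margin)
        extra = sum(
            firing_probability(config.efficiency_of(lk.linker_id)) * lk.length
            for lk in rd.linkers
        )
        on_bases += n_mol * (span_end - span_start + extra)
    bg_bases = 0.0
    for s, e in _offtarget_intervals(diploid, panel, config.terminal_margin):
        M = e - s
        n_reads = config.background_rate * M / 1000.0
        bg_bases += n_reads * _expected_clipped_length(
            M, config.background_median_length, config.background_sigma
        )
    baseline = (on_bases + bg_bases) / L
    return n_mol / baseline


def _expected_clipped_length(M: int, median: int, sigma: float, floor: int = 200) -> float:
    """E[min(X, e - start)] for a log-normal read length X (floored) whose
    start is uniform in an off-target interval of length M."""
    from scipy.stats import lognorm

    dist = lognorm(s=sigma, scale=median)
    t = np.linspace(0, M, 2048)
    surv = np.where(t < floor, 1.0, dist.sf(np.maximum(t, 1e-9)))
    G = np.concatenate([[0.0], np.cumsum((surv[1:] + surv[:-1]) / 2 * np.diff(t))])
    return float(np.trapezoid(G, t) / M)


def write_truth(truths: Sequence[SimTruth], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "haplotype": t.haplotype,
                "molecule": t.molecule,
                "fragment_index": t.fragment_index,
                "left_linker": t.left_linker if t.left_linker is not None else ".",
                "right_linker": t.right_linker if t.right_linker is not None else ".",
                "is_background": int(t.is_background),
            }
            for t in truths
        ],
        columns=[
            "read_id",
            "haplotype",
            "molecule",
            "fragment_index",
            "left_linker",
            "right_linker",
            "is_background",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[SimTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"left_linker": str, "right_linker": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SimTruth(
                read_id=str(row.read_id),
                haplotype=int(row.haplotype),
                molecule=int(row.molecule),
                fragment_index=int(row.fragment_index),
                left_linker=None if row.left_linker == "." else row.left_linker,
                right_linker=None if row.right_linker == "." else row.right_linker,
                is_background=bool(row.is_background),
            )
        )
    return out
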