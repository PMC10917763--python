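"""Self-contained synthetic studies exercising the whole pipeline.

Two canned experiments mirror the validation settings the package targets:

* :func:`lambda_style_design` — a six-linker panel on a 48.5-kbp random
  linear molecule (the geometry of a phage-genome model system), yielding
  seven linked fragments.
* :func:`roundtrip_study` — design → simulate → align → analyze on a
  200-kbp synthetic diploid locus at 50x depth with 0.5% read errors:
  per-linker formation-ratio recovery, reference-based and de novo phasing
  against planted truth, and enrichment-fold recovery.

Both are deterministic given their seed and run on a single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design import DesignConfig, DesignPanel, TargetRegion, design_panel
from .efficiency import efficiency_report, enrichment_profile
from .mapping import align_reads
from .phasing_denovo import consensus_from_group, group_reads_by_linker, phase_denovo
from .phasing_ref import DELETION, allele_balance, compare_haplotypes, phase_alignments
from .seqio import Genome, semiglobal_align
from .simulator import (
    DiploidGenome,
    SimConfig,
    expected_enrichment_fold,
    make_diploid_genome,
    simulate_library,
)

__all__ = ["lambda_style_design", "roundtrip_study", "RoundtripResult"]


def _random_linear_genome(seed: int, length: int = 48_502) -> Genome:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, length)]
    return Genome({"model": bases.tobytes().decode()})


def lambda_style_design(seed: int = 0) -> DesignPanel:
    """Design a six-linker panel on a 48.5-kbp random linear molecule.

    Short linkers (50-250 bp) and a ~9.3-kbp fragment target tile the
    molecule with exactly five interior hops, i.e. six linkers and seven
    linked fragments including the two terminal ones.
    """
    genome = _random_linear_genome(seed)
    config = DesignConfig.model_genome(
        read_length=9_300, gap_min=8_200, gap_max=10_600
    )
    region = TargetRegion("model", 1_500, 47_000, "molecule")
    return design_panel(genome, [region], [], config)


@dataclass
class RoundtripResult:
    """Everything the round-trip study measures, with the planted truth."""

    config: SimConfig
    panel: DesignPanel
    n_reads: int
    n_aligned: int
    linker_ratios: list[dict]  # per linker: id, with, spanning, r, planted e, z
    ref_phasing: dict
    denovo_phasing: dict
    allele_balance: float
    fold_measured: float
    fold_expected: float

    @property
    def max_abs_z(self) -> float:
        return max(abs(row["z"]) for row in self.linker_ratios)


def _truth_alleles(diploid: DiploidGenome) -> dict:
    """Planted (haplotype-1 allele, haplotype-2 allele) per pileup site,
    using the pileup's allele encodings (base, deletion, insertion)."""
    truth: dict = {}
    contig = diploid.contig
    for v in diploid.variants:
        if len(v.ref) == 1 and len(v.alt) == 1:  # SNV
            alleles = (v.alt, v.ref) if v.phase == 1 else (v.ref, v.alt)
            truth[(contig, v.position)] = alleles
        elif len(v.alt) > len(v.ref):  # insertion, keyed at the anchor base
            ins = ("INS", v.alt)
            alleles = (ins, v.ref) if v.phase == 1 else (v.ref, ins)
            truth[(contig, v.position)] = alleles
        else:  # deletion: each deleted base is a deletion-allele site
            for k in range(1, len(v.ref)):
                base = v.ref[k]
                alleles = (DELETION, base) if v.phase == 1 else (base, DELETION)
                truth[(contig, v.position + k)] = alleles
    return truth


def _project_denovo_truth(
    diploid: DiploidGenome,
    panel: DesignPanel,
    consensuses: dict,
    variants,
) -> dict:
    """Map de novo sites (linker id, consensus position) onto planted truth
    by aligning each consensus back to its linker's reference context."""
    ref = diploid.reference.sequences[diploid.contig]
    ref_truth = _truth_alleles(diploid)
    linker_by_id = {lk.linker_id: lk for lk in panel.linkers}
    projections: dict[str, dict[int, int]] = {}
    truth: dict = {}
    for v in variants:
        lid, cpos = v.site
        if lid not in projections:
            lk = linker_by_id[lid]
            pad = len(consensuses[lid].bases) + 300
            lo = max(0, lk.start - pad)
            hi = min(len(ref), lk.end + pad)
            aln = semiglobal_align(consensuses[lid].bases, ref[lo:hi], window_offset=lo)
            colmap: dict[int, int] = {}
            for op, n, rpos, qpos in aln.walk():
                if op in ("M", "=", "X"):
                    for k in range(n):
                        colmap[qpos + k] = rpos + k
            projections[lid] = colmap
        rpos = projections[lid].get(cpos)
        if rpos is None:
            continue
        site_truth = ref_truth.get((diploid.contig, rpos))
        if site_truth is not None:
            truth[v.site] = site_truth
    return truth


def roundtrip_study(
    seed: int,
    genome_length: int = 200_000,
    region_bounds: tuple[int, int] = (45_000, 155_000),
    depth: float = 50.0,
    linker_efficiency: float = 0.9,
    error_rate: float = 0.005,
    background_rate: float = 1.0,
    design_config: Optional[DesignConfig] = None,
) -> RoundtripResult:
    """Run the full design → simulate → align → analyze loop.

    The defaults are the package's reference validation conditions: a
    200-kbp diploid locus (het SNVs at 1e-3/bp, indels at 1e-4/bp), a
    110-kbp target region designed at the default 15-kbp fragment scale,
    50x molecule depth, 90% per-linker formation ratio, 0.5% read errors
    and one background read per kbp of off-target sequence.
    """
    sim = SimConfig(
        genome_length=genome_length,
        snv_rate=1e-3,
        indel_rate=1e-4,
        seed=seed,
        linker_efficiency=linker_efficiency,
        depth=depth,
        background_rate=background_rate,
        sub_rate=error_rate / 2,
        ins_rate=error_rate / 4,
        del_rate=error_rate / 4,
        end_jitter_sd=10.0,
    )
    diploid = make_diploid_genome(sim)
    region = TargetRegion(diploid.contig, *region_bounds, "target")
    panel = design_panel(
        diploid.reference, [region], diploid.variants, design_config or DesignConfig()
    )
    reads, truths = simulate_library(diploid, panel, sim)
    alignments = align_reads(reads, diploid.reference)

    # --- fragmentation efficiency recovery --------------------------------
    report = efficiency_report(alignments, panel)
    linker_rows = []
    for lk in panel.linkers:
        obs = report.observations[lk.linker_id]
        n = obs.reads_with_linker + obs.reads_spanning
        e = sim.efficiency_of(lk.linker_id)
        r = report.ratios[lk.linker_id]
        sigma = float(np.sqrt(e * (1 - e) / n))
        linker_rows.append(
            {
                "linker_id": lk.linker_id,
                "with": obs.reads_with_linker,
                "spanning": obs.reads_spanning,
                "r": r,
                "e": e,
                "z": (r - e) / sigma,
            }
        )

    # --- enrichment recovery ----------------------------------------------
    profile = enrichment_profile(
        alignments, [(region.contig, region.start, region.end)], diploid.reference
    )
    fold_expected = expected_enrichment_fold(diploid, panel, sim)

    # --- reference-based phasing vs planted truth -------------------------
    pair, variants, _ = phase_alignments(alignments, diploid.reference)
    truth = _truth_alleles(diploid)
    ref_metrics = compare_haplotypes(pair, variants, truth)
    balance = allele_balance(variants)

    # --- de novo phasing vs planted truth ---------------------------------
    groups, _ = group_reads_by_linker(reads, panel)
    consensuses = {
        g.linker.linker_id: consensus_from_group(g) for g in groups if g.parts
    }
    dn_pair, dn_variants, _ = phase_denovo(groups, consensuses)
    dn_truth = _project_denovo_truth(diploid, panel, consensuses, dn_variants)
    dn_metrics = compare_haplotypes(dn_pair, dn_variants, dn_truth)

    return RoundtripResult(
        config=sim,
        panel=panel,
        n_reads=len(reads),
        n_aligned=len(alignments),
        linker_ratios=linker_rows,
        ref_phasing=ref_metrics,
        denovo_phasing=dn_metrics,
        allele_balance=balance,
        fold_measured=profile.fold,
        fold_expected=fold_expected,
    )
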