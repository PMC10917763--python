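"""Simulate a linked-fragment library on a synthetic diploid locus.

Plants phased heterozygous SNVs/indels on a random 60-kbp genome, designs a
panel on it, then emits reads in which each designed linker forms with the
configured probability (formed linkers appear tandem-duplicated on both
flanking fragment reads) plus nanopore-like errors.
"""

from linkfrag.design import DesignConfig, TargetRegion, design_panel
from linkfrag.simulator import SimConfig, make_diploid_genome, simulate_library

config = SimConfig(
    genome_length=60_000,
    snv_rate=1.5e-3,
    indel_rate=1e-4,
    seed=11,
    linker_efficiency=0.9,   # read-space formation ratio per linker
    depth=40,                # molecules per target locus
    sub_rate=0.0025, ins_rate=0.00125, del_rate=0.00125,
    end_jitter_sd=10,
)
diploid = make_diploid_genome(config)
print(f"reference: {config.genome_length} bp, {len(diploid.variants)} planted het variants")

panel = design_panel(
    diploid.reference,
    [TargetRegion("sim", 15_000, 45_000, "target")],
    diploid.variants,
    DesignConfig(read_length=8_000, gap_min=5_000, gap_max=11_000),
)
print(f"panel: {len(panel.linkers)} linkers, {len(panel.fragments)} fragments")

reads, truths = simulate_library(diploid, panel, config)
n_bg = sum(t.is_background for t in truths)
n_linked = sum(t.left_linker is not None or t.right_linker is not None for t in truths)
print(f"\n{len(reads)} reads: {n_linked} linker-bearing, "
      f"{len(reads) - n_linked - n_bg} unfragmented/interior, {n_bg} background")
lens = sorted(len(r.bases) for r in reads)
print(f"read lengths: median {lens[len(lens) // 2]} bp, max {lens[-1]} bp")
# Every read carries a truth record (source haplotype, molecule, fragment
# index, flanking linkers) so downstream analyses can be scored exactly.
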