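"""Reference-free phasing: guide matching, consensus linkers, allele graph.

Finds the designed guides in read termini at edit distance <= 4, groups
reads per linker, votes a consensus for every linker region, realigns the
read parts, and phases heterozygous consensus sites exactly as the
reference-based engine does — without ever touching the reference.
"""

from linkfrag.design import DesignConfig, TargetRegion, design_panel
from linkfrag.phasing_denovo import consensus_from_group, group_reads_by_linker, phase_denovo
from linkfrag.simulator import SimConfig, make_diploid_genome, simulate_library

config = SimConfig(
    genome_length=60_000, snv_rate=2e-3, indel_rate=0, seed=31,
    linker_efficiency=0.9, depth=60,
    sub_rate=0.0025, ins_rate=0.00125, del_rate=0.00125, end_jitter_sd=5,
)
diploid = make_diploid_genome(config)
panel = design_panel(
    diploid.reference, [TargetRegion("sim", 15_000, 45_000, "t")], diploid.variants,
    DesignConfig(read_length=8_000, gap_min=5_000, gap_max=11_000),
)
reads, _ = simulate_library(diploid, panel, config)

groups, unmatched = group_reads_by_linker(reads, panel)
print(f"{len(reads)} reads -> {len(unmatched)} with no terminal guide match")
consensuses = {}
for g in groups:
    if g.parts:
        cons = consensus_from_group(g)
        consensuses[g.linker.linker_id] = cons
        print(f"  {g.linker.linker_id:<22} {len(g.parts):>3} parts, "
              f"consensus {len(cons.bases)} bp ({len(cons.masked)} masked columns)")

pair, variants, _ = phase_denovo(groups, consensuses)
print(f"\n{len(variants)} het sites on linker consensuses; "
      f"{sum(len(b) for b in pair.blocks)} phased in {len(pair.blocks)} block(s)")
for bi, block in enumerate(pair.blocks):
    sites = ", ".join(f"{lid.split(':')[1]}@{pos}" for (lid, pos), _ in block[:4])
    more = "" if len(block) <= 4 else f" (+{len(block) - 4} more)"
    print(f"  block {bi}: {sites}{more}")
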