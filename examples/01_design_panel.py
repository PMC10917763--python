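"""Design a six-linker panel on a 48.5-kbp random linear molecule.

Builds a model-genome-scale design (short 50-250 bp linkers, ~9.3-kbp
fragments) and prints the selected guides, linkers and implied fragments.
"""

from linkfrag.study import lambda_style_design

panel = lambda_style_design(seed=1)
rd = panel.regions[0]

print(f"selected {len(rd.linkers)} linkers -> {len(rd.fragments)} linked fragments")
print(f"{len(panel.guides())} guides (two per linker, opposite strands)\n")

print("guide      position  strand  protospacer+PAM")
for g in panel.guides():
    print(f"{g.guide_id:<12}{g.start + 1:>8}  {g.strand:^6}  {g.seq23}")

print("\nfragment                interval          length")
for fr in rd.fragments:
    kind = "terminal" if None in (fr.left_linker, fr.right_linker) else "interior"
    print(f"{fr.fragment_id:<22}{fr.start:>8}-{fr.end:<10}{fr.end - fr.start:>6}  {kind}")

# Each interior fragment sits between two linkers whose duplicated sequence
# it shares with its neighbours; the two terminal fragments run from the
# molecule ends to the outermost linkers.
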