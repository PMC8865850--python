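"""Design pegRNAs over a PBS x RT grid and list secondary nick options.

For a demo amplicon whose intended edit restores the canonical splice donor,
prints the pegRNA extension (RT template then PBS, 5'->3') for each length
combination, and every complementary-strand protospacer whose nick falls
within 120 nt of the primary nick.
"""

import pearkit as pk

amp = pk.make_demo_amplicon(seed=21)
print(f"amplicon {amp.name}: {len(amp.ref_seq)} nt, nick at {amp.cut_site}, "
      f"edit {amp.edit.kind} {amp.edit.ref_allele or '-'}>"
      f"{amp.edit.alt_allele or '-'} at {amp.edit.position}")
print(f"donor context edited to: "
      f"{pk.splice_state('GGTAAGT')} canonical GGTAAGT\n")

print("pbs_len\trt_len\textension (RT+PBS, 5'->3')")
for pbs_len in (10, 13, 16):
    for rt_len in (16, 24, 33):
        peg = pk.design_pegrna(amp, pbs_len, rt_len)
        print(f"{pbs_len}\t{rt_len}\t{peg.extension}")

print("\nsecondary nick candidates (offset along the targeted strand):")
for nick in pk.enumerate_nicks(amp, search_range=120):
    print(f"  offset {nick.offset:+d}\tspacer {nick.spacer}")
# Positive offsets are 3' of the primary nick on the targeted strand; a
# nick around +17 to +112 typically boosts editing in PE3 designs.
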