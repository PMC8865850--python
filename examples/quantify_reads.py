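"""Simulate an amplicon sequencing library and quantify prime editing.

Builds a 240-nt amplicon carrying a disabled splice donor (G-AC-AAGT), draws
10,000 reads in which 30% carry the intended AC->GT correction, 5% carry a
1-nt deletion at the nick, and every base has a 0.1% error rate, then runs
the classifier and prints the sample summary.
"""

import pearkit as pk

amp = pk.make_demo_amplicon(seed=11)
byproduct = pk.EditSpec(
    "deletion", amp.cut_site - 1, amp.ref_seq[amp.cut_site - 1], ""
)
params = pk.ReadSimParams(
    amplicon=amp, n_reads=10_000, frac_intended=0.30,
    byproduct_indels=[(byproduct, 0.05)], per_base_error=0.001,
    read_len=180, seed=1,
)
records, truth = pk.simulate_reads(params)
classes = pk.classify_reads([seq for _, seq, _ in records], amp)
q = pk.quantify_sample(classes)

print(f"reads: {q.n_total}  (filtered: {q.n_filtered})")
print(f"editing:     {q.editing_pct:6.2f} %   (simulated at 30%)")
print(f"indel:       {q.indel_pct:6.2f} %   (simulated at 5%)")
print(f"specificity: {q.specificity:6.2f}     (editing% / indel%, 0.05% floor)")
# The editing and indel rates recover the simulation mixture to within
# binomial noise; specificity ~6 means intended edits outnumber byproduct
# indels six-fold in this library.
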