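"""Enrichment of edited cells by reporter gating, with statistics.

Simulates 100,000 cells where half are transfected, 40% of transfected cells
edit the reporter plasmid, and genomic editing is far likelier in
reporter-edited cells (60%) than in merely transfected ones (10%).  Prints
editing under the three sorter gates and compares triplicate editing
measurements across gates with the assumption-driven decision tree.
"""

import numpy as np

import pearkit as pk

params = pk.PopulationParams(
    n_cells=100_000, p_transfect=0.5,
    p_plasmid_edit_given_transfect=0.4,
    p_genomic_given_plasmid_edit=0.6,
    p_genomic_given_transfect_only=0.1,
    seed=7,
)
cells = pk.simulate_population(params)
gates = pk.gated_editing_rates(cells)
for g in gates.values():
    print(f"{g.gate:>12}: {g.n_cells:6d} cells  "
          f"editing {g.editing_pct:5.2f}%  fold {g.fold_vs_none:4.2f}x")
# Sorting on the reporter (GFP) roughly quadruples the edited fraction
# versus no enrichment; the transfection marker (BFP) only doubles it.

groups = []
for seed in range(3):
    reps = []
    for rep in range(3):
        sub = pk.simulate_population(
            pk.PopulationParams(
                n_cells=3000, p_transfect=0.5,
                p_plasmid_edit_given_transfect=0.4,
                p_genomic_given_plasmid_edit=0.6,
                p_genomic_given_transfect_only=0.1,
                seed=100 * seed + rep,
            )
        )
        gate = ("none", "transfection", "pear")[seed]
        reps.append(pk.gated_editing_rates(sub)[gate].editing_pct)
    groups.append(reps)

res = pk.compare_groups(groups)
print(f"\ncomparison path: {res.path_taken}  omnibus p = {res.omnibus_p:.2e}")
for (i, j), p in res.pairwise:
    names = ("none", "transfection", "pear")
    print(f"  {names[i]} vs {names[j]}: adjusted p = {p:.3g}")
# With homoscedastic, normal replicates the tree lands on ANOVA + Tukey and
# every pairwise gate difference is significant.
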