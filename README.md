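# pearkit

Analysis toolkit for fluorescent prime-editing reporter assays.

Prime editors (PE) — a Cas9 nickase fused to a reverse transcriptase,
programmed by a prime-editing guide RNA (pegRNA) — install substitutions and
small insertions/deletions without double-strand breaks, but typical editing
rates of 10–30% make edited cells hard to find. A splice-site reporter turns
editing into fluorescence: a split fluorescent protein is interrupted by an
intron whose 5′ splice donor is disabled (e.g. G‑**AC**‑AAGT); a prime edit
restoring the canonical donor (G‑**GT**‑AAGT) restores splicing, and
fluorescence marks the edited cell. Sorting on the reporter enriches cells
whose genomic target was co-edited. `pearkit` implements the computational
layer of that workflow:

* **Amplicon geometry** (`pearkit.amplicon`) — protospacer/PAM location, the
  SpCas9 nick between protospacer positions 17/18, and edit application, all
  in 0-based forward-strand coordinates with inter-base nick positions.
* **Read classification** (`pearkit.align`) — semi-global alignment (global
  in the read, free reference end gaps; match +1, mismatch −1, gap open −4,
  extend −1), the 75%-of-first-20-bp anchor filter, byproduct indel calls
  within ±2 bp of the nick (any length), and intended-edit detection
  (substitutions require an indel-free read; programmed indels must match the
  left-normalised alignment gap exactly).
* **Quantification** (`pearkit.quantify`) — per-sample
  editing% = 100·n_intended/n_total, indel% = 100·n_indel/n_total, and
  specificity = editing% / max(indel%, 0.05%), the floor guarding against
  spuriously high ratios below the resolution of amplicon sequencing.
* **GUIDE-seq tag counting** (`pearkit.guideseq`) — exact counting of the
  34-nt dsODN and its 15-nt centre fragment
  (`GTTGTCATATGTTAA`/`TTAACATATGACAAC`) in either orientation, and off-target
  retention (≤7 spacer mismatches, absent from background controls).
* **pegRNA and reporter design** (`pearkit.design`) — splice-donor activity
  as a registry lookup over 7-nt contexts; PBS/RT construction (PBS = reverse
  complement of the bases 5′ of the nick on the protospacer strand, RT =
  reverse complement of the edited sequence 3′ of the nick, as RNA); and
  complementary-strand nick enumeration with signed nick-to-nick offsets.
* **Enrichment statistics** (`pearkit.stats`) — editing under the three
  sorter gates (all cells / transfection marker BFP⁺ / reporter GFP⁺), fold
  changes, Pearson correlation, and an assumption-driven comparison tree:
  Brown–Forsythe and D'Agostino–Pearson K² pretests, one-way ANOVA + Tukey
  when they pass, a Box–Cox rescue (λ ∈ [−2, 2] by maximum likelihood) when
  only normality fails, Kruskal–Wallis + Dunn (Bonferroni) otherwise.
* **Synthetic data** (`pearkit.simulate`) — seedable generators for amplicon
  reads (mixtures of edited/byproduct/unedited templates with per-base
  errors) and cell populations (hierarchical Bernoulli model of transfection
  → plasmid editing → genomic editing with fluorescence detection noise).

## Worked example

`examples/quantify_reads.py` simulates a 10,000-read library at 30% intended
editing, 5% byproduct indels and 0.1%/base error, then classifies and
quantifies it:

```
reads: 10000  (filtered: 0)
editing:      29.82 %   (simulated at 30%)
indel:         4.84 %   (simulated at 5%)
specificity:   6.16     (editing% / indel%, 0.05% floor)
```

The classifier recovers the simulated mixture to within binomial noise.
`examples/enrichment_gates.py` runs the cell-population model
(transfection 0.5, plasmid-edit|transfected 0.4, genomic|plasmid-edited 0.6,
genomic|transfected-only 0.1):

```
        none: 100000 cells  editing 14.98%  fold 1.00x
transfection:  49844 cells  editing 30.06%  fold 2.01x
        pear:  19985 cells  editing 60.03%  fold 4.01x
```

Gating on the reporter quadruples the edited fraction while the transfection
marker only doubles it — the law-of-total-probability expectations are
exactly 15%, 30% and 60%. The other examples cover pegRNA design
(`design_pegrna.py`) and dsODN tag counting (`guideseq_tags.py`).

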