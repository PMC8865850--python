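# Methods

## Coordinate frame and target geometry

All positions are 0-based, half-open, on the forward strand of the reference
amplicon. Nick ("cut") sites are inter-base integers: the index of the first
base 3′ of the nick on the forward strand, so the nick lies between indices
`cut-1` and `cut`. The SpCas9 nick is fixed between protospacer positions 17
and 18 (1-based on the protospacer strand), 3 nt 5′ of the NGG PAM; every
relative offset in the package (indel window, secondary-nick offsets, RT/PBS
spans) presupposes this primary nick. The PAM pattern is strictly NGG and
input sequences are restricted to uppercase A/C/G/T; degenerate bases are
rejected rather than pattern-matched. pegRNA spacers are written as
protospacer-strand sequence (the sgRNA sequence is the same string as RNA);
this convention is asserted throughout and documented here because both
conventions circulate in the field.

## Alignment

`align_semi_global` is global in the read with free end gaps in the
reference: every read base must be explained, unaligned reference flanks are
free, and read overhangs beyond the reference ends are scored as ordinary
insertions. Scores are match +1, mismatch −1, gap open −4 (the first gapped
base), gap extend −1 per additional base. The engine is
`Bio.Align.PairwiseAligner` (C implementation) configured for exactly these
semantics; its first reported alignment is deterministic for a fixed
Biopython version. Two numerical choices remove the remaining placement
ambiguity:

* every extracted indel is left-normalised (VCF-style: shifted to the
  lowest-coordinate equivalent position) before any positional comparison,
  so homopolymer/repeat indels have one canonical position;
* a gapless fast path handles reads whose best gapless placement has at most
  two mismatches. This is provably score-optimal: an alignment containing an
  interior gap scores at least 4 below its match count, so it can at best tie
  a gapless alignment with two mismatches, and ties are resolved in favour of
  mismatches over gaps. The fast path covers the overwhelming majority of
  reads at realistic error rates and keeps 10,000-read samples at a few
  seconds on one CPU.

The test suite validates the engine against a two-tier independent oracle:
a pure-Python three-state affine-gap dynamic program (score plus the complete
set of optimal operation multisets), itself validated against true exhaustive
enumeration of every alignment path on tiny instances.

## Read classification

A read is **filtered** when fewer than 75% of the first 20 reference bases
are aligned to an identical read base (gaps and uncovered positions count as
non-matches), or when the alignment covers fewer than 20 reference bases at
all (reported separately as `filter_reason="short"`). The anchor rule is the
only read-quality filter; base qualities are ignored.

For substitution edits a read is **intended** only if the alternate allele
is present at the edit position and the alignment contains no indel anywhere
— mismatches elsewhere are tolerated subject to the anchor rule. The phrase
"indels without mismatches" in this literature is ambiguous; here it is
interpreted as: the indel call itself must be a clean gap in the optimal
alignment, while point errors elsewhere in the read do not veto calls. For
programmed insertions/deletions a read is intended if the alignment contains
an indel exactly matching the edit (kind, left-normalised position, length
and inserted sequence); additional indels elsewhere do not revoke the label,
matching the convention that intended-indel quantification counts all reads
with the programmed modification.

Otherwise, if an indel lies within ±2 bp of the nick it is an
**indel_byproduct**; else the read is **unedited**. The window test keys on
the insertion point or the nearest deletion boundary (distance 0 if the nick
falls inside the deleted interval); `window_mode="overlap"` switches to
interval-overlap semantics, since the literature does not specify which the
original pipelines used. Any indel length is accepted.

## Quantification

editing% and indel% use the total read count (including filtered reads) as
denominator, matching the "number of total reads" convention;
`denominator="passing"` excludes filtered reads for sensitivity analyses.
Specificity is editing%/max(indel%, 0.05%); the 0.05% floor is the
conventional resolution limit of amplicon NGS and is a configurable constant,
not a derived quantity. Percentages are serialised to 2 decimals; full
precision is kept internally.

## dsODN tags and off-targets

Tag counting is exact substring matching (no mismatches) of the full 34-nt
dsODN and its 15-nt centre fragment in either orientation, at most one count
per read per category. Off-target candidates are retained when the
protospacer portion has at most 7 position-wise mismatches against the target
spacer — the PAM is excluded from the count, per GUIDE-seq convention — and
the site is absent from background controls; retained sites are ordered by
mismatch count then read support. Counts are per read; molecule
consolidation/UMI logic belongs to genome-scale discovery pipelines and is
out of scope.

## Reporter and pegRNA design

Splice-donor activity is a pure lookup over 7-nt contexts (last exonic base
plus first six intronic bases). The registry is seeded with the canonical
`GGTAAGT` only; additional empirically active variants are configuration
data supplied by the user, because donor activity beyond the canonical
context is an empirical property, not a sequence rule this package should
hard-code.

PBS = reverse complement (as RNA) of the `pbs_len` reference bases
immediately 5′ of the nick on the protospacer strand; RT template = reverse
complement (as RNA) of the first `rt_len` bases of the *edited* sequence 3′
of the nick on that strand; the 3′ extension is RT then PBS, 5′→3′. RT
coverage of the edit is validated constructively: pasting the RT-encoded
sequence over the nick must reproduce the edited amplicon, which catches all
partial-coverage cases for all three edit kinds. The guide scaffold is not
modelled. Secondary nicks are enumerated as complementary-strand
protospacers with NGG PAMs; offsets are nick-to-nick, measured along the
targeted strand (the strand the spacer anneals to) with positive = its 3′
direction.

## Synthetic data

The read generator draws each read's template from the mixture
(intended / byproduct indels / unedited), truncates to `read_len` from the
amplicon 5′ end (single-end, 5′-anchored — the anchor rule presupposes this
orientation), and applies i.i.d. substitution errors. Sequencing indel
errors are off by default so that the ±2 bp window's false-positive
behaviour stays interpretable; an optional indel-error rate exists for
stress tests. Quality strings are constant high quality because the
classification rules apply no quality filtering. Output is byte-identical
for a fixed seed.

The population generator is a hierarchical Bernoulli model: transfection,
then plasmid (reporter) editing given transfection, then genomic editing
with probability conditional on reporter status — the constraint
P(genomic | reporter-edited) ≥ P(genomic | transfected-only) encodes the
enrichment premise and is validated at construction. Observed BFP/GFP flags
are the latent states flipped with false-positive/false-negative rates
(default 0); gating operates on observed flags only. Default study
conditions used by the tests and the acceptance script: 10,000 reads at 30%
intended editing, 5% byproduct indels, 0.1%/base error, 180-nt reads on a
240-nt amplicon; populations of 100,000 cells at
(0.5, 0.4, 0.6, 0.1, 0.0) for the five probabilities above, giving exact
gate expectations of 15%/30%/60%. These sizes keep the full suite under a
minute per stage while leaving binomial noise far below the effects checked.

What the generators deliberately do not model: PCR duplicates and chimeras,
paired-end reads, position-dependent error profiles, continuous fluorescence
intensities, and spectral spillover. Passing tests therefore demonstrate the
correctness of the counting and decision rules under a clean generative
model, not robustness to those real-data artefacts.

## Statistics

The group-comparison tree: Brown–Forsythe (median-centred Levene) for
homogeneity and D'Agostino–Pearson K² on pooled ANOVA residuals for
normality, both at a fixed pretest α of 0.05. Residual normality is tested
on pooled residuals rather than per group because triplicate designs give
per-group tests no power; with fewer than 8 residuals (where K² is
undefined) Shapiro–Wilk substitutes. If both pretests pass: one-way ANOVA
with Tukey's HSD. If homogeneity passes but normality fails and the data are
positive: Box–Cox with λ chosen by maximum likelihood over [−2, 2], then the
pretests re-run on the transformed data. Any other outcome — including
heteroscedasticity, which a power transform of already-symmetric data rarely
repairs — routes to Kruskal–Wallis with Dunn's post hoc test. Dunn's z
statistics use pooled-rank means with the tie correction and Bonferroni
adjustment; the adjustment scheme is a documented default since the
literature usually names Dunn's test without one. Under a Gaussian null
(3 groups × 3 replicates, 1000 replicates) the tree's measured type-I error
is close to the nominal 0.05 (the acceptance suite asserts [0.03, 0.07]).

Degenerate inputs: identical constant groups return an explicit
`no_variance` outcome with NaN p-values; zero-variance vectors make the
Pearson correlation undefined and raise.

## Known limitations

* The aligner's tie-breaking among equally optimal alignments follows the
  engine's deterministic internal order; only indel positions (via
  left-normalisation) are guaranteed canonical.
* Off-target filtering assumes length-matched, pre-aligned candidate sites;
  bulged (gapped) off-targets are not scored.
* The splice-activity model is binary; partial donor activity is not
  represented.
* Enrichment gating is single-threshold boolean; no compensation or
  intensity modelling.
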