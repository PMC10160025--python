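# Methods

## Scope and data model

The package analyses per-isolate somatic substitution calls from
mutation-accumulation experiments in yeast. Read alignment and variant
calling are upstream concerns: ingest starts from a called table
(`chrom, pos, ref, alt, isolate`, 1-based positions, or a single-sample
VCF) and a reference FASTA. Every record's reference allele is checked
against the genome; mismatches — the signature of a genome-build mix-up —
are rejected into an explicit report rather than silently dropped.
Mitochondrial records are excluded by a configurable chromosome-name set
(default `chrM`, `chrMito`, `mitochondrion`, `chrmt`, `MT`); the nuclear
and mitochondrial mutational processes are distinct and all downstream
statistics are nuclear. Interval annotations (genes as BED6, origins as
TSV/BED midpoints) are 0-based half-open; conversions happen only in the
I/O layer.

Runs of adjacent substituted positions within one isolate are merged before
spectrum building: exactly two adjacent positions become a *tandem*
(doublet) record, three or more a *multi* record. Multi records are
excluded from both spectra — they are rare, their generating process is
unclear, and neither the single nor the doublet class space represents
them — but they are counted so nothing disappears silently. Merging
conserves the multiset of covered genomic positions.

How clonal (shared ancestral) mutations across isolates should be handled
depends on how the isolates were derived, so ingest exposes an optional
same-site-same-allele cross-isolate deduplication flag, off by default and
surfaced in the ingest report when used.

## Spectra

Single-base substitutions are strand-collapsed onto the pyrimidine: a
purine-reference record has its substitution and trinucleotide context
reverse-complemented, giving the standard 96 channels (6 substitutions × 16
contexts, labelled `T[C>T]A` style). Tandems are collapsed over reverse
complement into 78 classes using the conventional priority set of reference
dinucleotides (AC, AT, CC, CG, CT, GC, TA, TC, TG, TT); for palindromic
references the lexicographically smaller of the alt and its reverse
complement is canonical. This priority-set convention (rather than plain
lexicographic minimisation of the whole label) is what makes the familiar
category names — AC>TT, CC>TT, CT>TA — the canonical representatives.

Per-class summaries are the mean and sample (n−1) SD across isolates.
Burden fold change is the ratio of group medians. Spectrum comparison is a
2×K contingency χ² on pooled class totals without continuity correction;
classes empty in both groups are dropped and classes whose smaller expected
count is below 5 are pooled into a single "other" class so the asymptotic
test stays valid (the paper trail for such comparisons never states a
pooling rule; this is the package's choice, verified to hold the type-I
error near 5% in simulation). Whether singles and tandems are pooled into
one table or tested separately is the caller's choice; separate testing is
the default used throughout the examples. Concordance between spectra is
Pearson correlation on raw per-class counts (matching mutation-count axes,
not frequencies).

Mann–Whitney comparisons are exact for groups of up to 8 per side — all
C(n₁+n₂, n₁) rank assignments enumerated with midranks for ties and no
continuity correction, so complete separation at 6 vs 6 gives exactly
2/924 ≈ 0.0022 — and use the tie-corrected normal approximation above that.
The two regimes agree to ~0.01 at the boundary.

## Transcriptional asymmetry

NTS is the gene's coding (mRNA-like) strand, TS the template. A genic
mutation is assigned NTS when its collapsed pyrimidine lies on the coding
strand; tandems are assigned by the strand carrying their canonical
orientation at the 5′ position, with palindromic-reference tandems
ambiguous. Regions covered by more than one annotated gene are masked from
both the assignment and the denominator (strand is undefined there;
assignment treats any multi-gene overlap as ambiguous regardless of the
strands involved).

The two strands of a gene set differ in trinucleotide composition, so a raw
NTS/TS imbalance is not evidence of asymmetric damage or repair. The
expected NTS fraction of a class is taken from the per-strand context
frequencies over all (unmasked) gene bodies: NTS counts are k-mer counts on
coding-strand sequence, TS counts those of the reverse-complement k-mer.
Each class with at least `min_count` genic mutations (default 30) is tested
with a 1-df goodness-of-fit χ² against that expectation; p-values are
Bonferroni-corrected with family size equal to the number of tested classes
in the dataset. The reported normalized ratio `(n_NTS/e_NTS)/(n_TS/e_TS)`
is exactly 1 whenever the observed split matches the composition-derived
expectation — this is the package's reading of a "normalized NTS:TS ratio",
recorded here because the quantity is often plotted without a formula.
Context frequencies are computed over gene bodies only (not flanks), since
the assignment itself is restricted to gene bodies.

## Replicative asymmetry

The pyrimidine collapse destroys exactly the information replicative
asymmetry lives in, so here substitutions keep their orientation as read on
the reference top strand, and complementary pairs (C>T vs G>A, T>A vs A>T,
T>C vs A>G, C>A vs G>T, and the two symmetric pairs) are profiled
separately. Each mutation between two flanking origins gets a fractional
coordinate (pos − left)/(right − left); fractional position rather than raw
distance normalizes variable inter-origin spacing. Mutations outside the
outermost origins of a chromosome, or on chromosomes with fewer than two
origins, are excluded; a mutation exactly at the midpoint belongs to
neither fork direction.

The axis is cut into equal bins (default 10) and each member's share of the
pair's per-bin total is fit against the bin midpoint by unweighted least
squares, empty bins omitted. Because the two members' fractions sum to one
in every occupied bin, the two lines form the "cross" and the member-2
slope is the negative of member-1's. Slope uncertainty is a seeded
percentile bootstrap (default 1,000 draws) resampling mutations via the
multinomial over (bin, member) cells; no analytic uncertainty is attempted
because bin occupancy varies. Simulation shows ~95% coverage of the true
slope at these defaults. An optional stratification by the transcription
strand of the surrounding gene is deliberately not applied by default: it
interacts with the transcriptional analysis and is an analysis choice, not
a default.

## Reversion and CAN1 assays

Reversion frequency is revertants divided by viable cells plated; viable
counts come from a serial-dilution series as colonies/dilution averaged
over countable plates (30–300 colonies, a standard plate-counting window;
if nothing is countable all non-zero plates are used), assuming equal
plated volumes. With zero revertants among N plated cells the *maximum
estimated reversion frequency* 1/N is reported and flagged: it is an upper
bound (the MLE is 0) and shrinks monotonically with N. Fold changes between
groups use the median (mean available behind a flag); when either group's
median rests on an upper estimate the fold is reported as a bound
(`at_least` / `at_most`), never as an exact number. The CAN1
forward-mutation frequency is
(Can^R colonies × SC dilution)/(SC colonies × canavanine dilution); zero
Can^R colonies give 0 with a flag, since no upper-estimate convention
applies to that assay. Plain frequencies, not Luria–Delbrück rates per
division, are computed throughout.

## Synthetic data generator

The generator emulates the statistical structure the analyses measure and
nothing mechanistic: no dose–response, lesion chemistry or polymerase
model. A config seed fully determines all outputs.

* **Genome**: i.i.d. bases at a set GC content (default 0.38, yeast-like),
  several chromosomes of 150 kb by default — large enough that every
  context occurs thousands of times, small enough that index construction
  is instant.
* **Genes**: fixed-length, non-overlapping, random strand; placement
  distributes the free space between genes multinomially, so packing is
  uniform and fails only when the genes genuinely do not fit (a config
  error). Defaults (60 genes × 1.2 kb per 150 kb chromosome) give the
  ~50% genic fraction typical of a compact genome.
* **Origins**: evenly spaced with ±20% jitter, several per chromosome,
  giving inter-origin intervals in the tens of kb as in yeast.
* **Mutations**: per isolate, a Poisson (default mean 600 — hundreds of
  substitutions per genome, the scale of a serial-UV-exposure experiment
  with tens of isolates, 46 by default) number of events drawn from the
  configured class simplex. The default single-base simplex is UV-like
  (C>T at 5′-pyrimidine contexts dominant, minor T>C/T>A/C>A, low floor),
  and the default tandem mix is CC>TT-dominant with CT>TA and AC>TT at a
  6% tandem fraction. Sites are chosen among genomic occurrences of the
  class's context. Inside genes the strand orientation of the mutated
  pyrimidine is chosen with the configured NTS:TS odds (default 1, i.e. no
  bias), which makes the genic NTS fraction exactly odds/(1+odds) in
  expectation regardless of composition noise. A configured replicative
  slope is applied by rejection so the pyrimidine-on-top member's
  probability is 0.5 + slope·(fraction − 0.5) between origins. Tandems are
  emitted as two adjacent single-base rows so the tandem-merging code path
  is exercised, not bypassed. Within an isolate a site and its immediate
  neighbours are never reused, so no unintended runs arise — a consequence
  is that piling many thousands of draws into a single isolate on a toy
  genome depletes the densest class's sites; validation spreads draws
  across isolates, as real data do.
* **Reversion counts**: revertants ~ Poisson(frequency × survivors);
  binomial sampling would be indistinguishable at assay frequencies.

What passing on synthetic data does *not* show: robustness to alignment
artefacts, clonal structure among isolates, expression-dependent repair
variation across genes, replication-timing heterogeneity, or context
composition of a real genome. Those belong to the upstream pipeline and to
interpretation, not to this package's arithmetic.

## Numerical choices and degenerate inputs

* χ² tests are asymptotic with no continuity correction (matching the
  hand-computable 2×2 value of 128 for 90/10 vs 10/90); below two retained
  classes the spectrum test is undefined and raises.
* Pearson correlation on a zero-variance vector raises rather than
  returning NaN.
* `median_density_fold` raises when the denominator median is 0; fold
  bounds from zero-revertant groups are flagged, not raised.
* Trinucleotide context is unavailable at chromosome edges and at N bases;
  such records are excluded from context spectra and counted.
* Bootstrap draws with empty bins drop those bins from the fit; a bootstrap
  replicate with fewer than two occupied bins contributes no slope.
* The exact Mann–Whitney enumerator uses a 1e-9 tolerance on rank-distance
  comparisons to keep midrank arithmetic stable.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on generated data:
cohorts of up to 50 isolates at ~600 mutations each for burden and spectrum
statistics, 10,000-record classification sweeps, 5 × 2,000 mutations for
asymmetry recovery, 1,000 replicates for family-wise error control and 500
replicates (400 bootstrap draws each) for slope-CI calibration. These sizes
were chosen so each estimate's Monte-Carlo error is small against the
tolerance being checked while the whole suite stays interactive.
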