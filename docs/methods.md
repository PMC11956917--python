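# Methods

This note records the models, conventions and numerical choices behind
`mutsig`, in the order data flows through the package.

## Coordinates, normalization, filters

Positions in mutation records are 1-based (VCF convention); all internal
interval arithmetic is 0-based half-open, with converters at each format
boundary (GFF3 1-based → internal; BED passes through).  Every substitution
is reported in *pyrimidine space*: purine-centred calls and their local
contexts are reverse complemented so that C and T are always the mutated
bases.  "Cumulative" class counts (e.g. C→G) therefore always mean C→G plus
G→C.

Ingestion applies a variant-allele-frequency filter (default ≥ 0.90 —
isolates are clonal expansions, so true somatic calls are near-homozygous).
Records without a VAF pass the filter and are logged, since upstream
pipelines may omit it.  Parental (matched-normal) variants are subtracted by
(chrom, pos, ref, alt) identity; optionally a variant shared by more than
one isolate is treated as pre-existing and removed everywhere.  Records
with N in the reference base or the ±20 nt context are kept in the catalog
but excluded from context-dependent statistics, so denominators never
shrink silently.

## Sub-telomeric classification and strand-aware spectra

The telomere distance of a record is `min(pos − 1, L − pos)` (multi-base
records use their first reference base); a call is sub-telomeric when the
distance is ≤ 30 000 bp, the distance resection-derived ssDNA extends from
yeast telomere ends.  The boundary is inclusive and the arm tie at the
exact chromosome midpoint goes left — both arbitrary, both tested.

The strand-aware spectrum deliberately does *not* collapse to pyrimidines:
reciprocal left/right-arm asymmetry (top-strand C→N excess on left arms
mirrored by G→N on right arms) is the observable signature of lesions on
the resected bottom strand, and collapsing would erase it.

Mutation densities are reported per isolate per bp of ssDNA territory.
The territory denominator is not uniquely defined by the experiment; the
package's declared convention is two arms × 30 kb × number of chromosomes,
capped at the chromosome length, and it is overridable.  Densities computed
under a different convention scale by the territory ratio.

## Context enrichment (TriMS-style statistic)

For motif *m* with one uppercase mutated pyrimidine and substitution class
*s*:

* `mutations_total` = SBS of class *s* (pyrimidine space, N-free context);
* `mutations_motif` = those whose pyrimidine-normalized trinucleotide
  matches *m* (lowercase positions fixed, `n` matches any base);
* for each such mutation the ±20 nt top-strand window contributes
  occurrences of the mutated base in pyrimidine space (top-strand C or G
  for a C motif) to `context_ref` and occurrences of the motif pattern or
  its reverse complement to `context_motif`.

Windows are **summed per mutation, not unioned** — overlapping windows
count repeatedly.  This matches the per-mutation ±20 nt definition and
keeps the statistic local: each mutation is compared against its own
opportunity.  Occurrences are counted as substrings fully inside the
(truncated) window.

The enrichment is `(mutations_motif × context_ref) / (mutations_total ×
context_motif)`; `context_motif = 0` yields an explicitly undefined result
rather than an infinite one, and no load is computed.  Significance is a
one-sided Fisher's exact test (hypergeometric upper tail) on the 2×2 table
of motif/non-motif counts in mutations versus contexts; fully degenerate
tables give p = 1.  Bonferroni is the default correction: pooled results
over the motif family, per-sample results over the number of samples tested
for that motif.  Benjamini-Hochberg is available where a false-discovery
framing fits (e.g. many cohorts).  The minimum mutation load
`mutations_motif × (E − 1)/E` is reported only when E > 1 and the corrected
p ≤ α; the printed condition in some descriptions of this procedure
(corrected p ≥ α) would reward non-significance and is treated as a typo.

## Flank logos

Foreground = one substitution class; background = all other substitutions
of the same reference pyrimidine (not genomic composition — the contrast
asks what distinguishes this class from other mutations of the same base).
Each flank position in −k..+k (k = 2 by default, a pentanucleotide) and
each base is scored with an exact binomial test of the foreground count
against the background proportion; two one-sided tails are computed and the
smaller taken, the signed height is −log10 of the Bonferroni-corrected p
(family = 2k × 4), positive for over-representation.

The background proportion is treated as *fixed*.  This is the standard
probability-logo simplification and is accurate when the background is much
larger than the foreground (the usual case: all other substitutions of the
base); when n_bg is comparable to n_fg the plug-in ignores background
sampling noise and the test becomes anticonservative.  The type-I test in
the suite therefore runs in the n_bg ≫ n_fg regime, and results on small
backgrounds should be read qualitatively.

## Templated slippage

Deterministic rules formalise the slippage judgements:

* **Insertion** (anchor-style records): templated `dup_downstream` if the
  inserted tract equals the reference tract immediately after the insertion
  point, `dup_upstream` if it equals the tract ending at the anchor;
  downstream wins ties (+1 copying is the mechanistic expectation).
  Because VCF left-aligns indels, the maximally right-shifted placement is
  also tested and either match counts.  Partial matches of multi-base
  insertions are untemplated (conservative).
* **Deletion**: `run_deletion` if the deleted tract is a single letter C or
  G inside a maximal run of length ≥ 3.
* **DBS/MBS**: `donor_templated` if the alt tract occurs verbatim on the
  top strand within ±10 bp with the donor disjoint from the mutated
  positions; smallest |offset| wins, downstream on ties.  Donors are
  searched on the top strand only (no hairpin/reverse-complement donors).

Untemplated events can still match a donor by chance; the expected
background rate depends on local composition (≈ 1 − (1 − 4^−L)^(2(w−L+1))
for tract length L in window w), so summaries report the observed templated
fraction rather than hiding it.

## Transcriptional strand bias

Gene territory is the per-strand union of intervals.  A mutation whose
pyrimidine lies on strand *s* inside territory of a gene on strand *g* is
non-transcribed if *s = g*, transcribed otherwise; positions covered on
both strands (bidirectional) or on neither (intergenic) are excluded —
the deterministic reading of interval intersection.  The counts are tested
with a chi-square goodness of fit (1 df) against 50:50 by default; an
"opportunity" model sets the expectation proportional to motif occurrence
counts per strand inside unambiguous territory, a stricter control when
motif density differs by strand.  BH correction applies across cohorts.

## Synthetic cohorts

The generator's defaults are the study conditions, fixed once: a
16-chromosome, 750 kb/chromosome, GC = 0.38 genome (budding-yeast-like
composition and scale); 114 isolates with 761 total SBS; sub-telomeric
fraction 0.91; strand asymmetry 0.95 (near-complete reciprocal asymmetry,
allowing occasional double-strand-region events); class weights putting
C→G/C→A/C→T at 0.42/0.27/0.25 (the observed density ranking) with 6% T
mutations; 78 INDELs split 45/33 insertion/deletion, templated-insertion
fraction 0.9, C/G-anchor fraction 33/45, run-deletion fraction 0.4; 21 DBS
and 5 MBS with templated fractions 0.9 and 0.8 (4 of 5).  The planted
motif enrichment defaults to 4.0 — strong but attainable under the summed
±20 nt window convention (see below); the experiment's own enrichment
value is not printed anywhere, so this is the package's choice.

Enrichment planting works by exact site enumeration.  Every reference-base
position is classified by (region, arm, top-strand base, motif match) and
its window statistics (ref-base count `r_i`, motif occurrence count `m_i`)
are precomputed by sliding sums.  Events pick a motif site with probability
q, where q solves

    q (q·r̄_M + (1−q)·r̄_N) = E* (q·m̄_M + (1−q)·m̄_N)

so the *estimator's* expectation equals the target E*.  The naive choice
q = E* × (motif fraction) under-recovers because a mutation's own window
always contains its central motif occurrence; the quadratic accounts for
that.  The same inflation bounds the attainable estimate: on a GC = 0.38
genome the ±20 nt convention saturates near Ê ≈ 10.7, and the generator
raises an error for unattainable targets rather than silently clipping.
Sites are sampled without replacement (no collisions, exact counts); one
RNG stream per stage is derived from the master seed, so adding stages
never perturbs earlier draws.

What the generator does *not* emulate: real chromosome-length variation,
chromatin or replication-timing covariates, sequencing error, reporter-gene
selection bias toward one chromosome arm, and clustering of mutations
within single resection tracts.  Passing tests therefore demonstrate the
statistics' correctness and calibration under the planted structure, not
robustness to those real-data features.

## Problem sizes and numerical choices

The test suite and acceptance script run the default cohort at full scale
(12 Mb genome, 761 SBS) and scale the heavier property checks to sizes
that preserve their guarantees: enrichment recovery uses 1 400–8 000
mutations per target so every run has ≥ 500 motif events; null calibration
uses 200 samples × 40 mutations; the Fisher cross-check enumerates all
635 376 tables with total ≤ 60 exactly.  Floating-point output is formatted
to 6 significant digits for reproducible diffs; p-values are floored at the
smallest positive double before taking logs; Bonferroni values are clamped
to 1.
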