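# Methods

This note documents the models, parameters, and numerical choices behind
`eccatlas`, and what the synthetic cohort does and does not emulate.

## Coordinate frame and inputs

All internal coordinates are 0-based half-open (BED convention).  GTF input
(1-based inclusive) is converted on read, so a GTF feature and a BED record
describing the same bases yield identical internal intervals.  The genome
layout table (chromosome lengths, centromere intervals, excluded
chromosomes) is the placement frame for every operation; excluded
chromosomes (e.g. chrY in a mixed-sex cohort) are retained by the readers
and dropped at analysis time.  "Functional transcript" is a configurable
predicate on GTF attributes, defaulting to `transcript_type ==
"protein_coding"` (falling back to `gene_type`, and accepting everything
when the annotation carries neither), because annotation tagging schemes
vary across releases.

## Random-interval null

For every real circle, one random circle of identical length is placed
uniformly at random: a chromosome is drawn with probability proportional to
its length, a start uniformly over valid positions, and the draw is
rejected and repeated whenever the interval would cross a centromere or a
chromosome end (default 1000 attempts, then a hard error naming the
circle).  Per-tumor circle counts and exact length multisets are therefore
invariant by construction.  Random circles may overlap one another and real
circles; no GC or mappability matching is attempted.  The scrambled control
permutes the nucleotides of each breakpoint window independently
(per-window, not concatenated), preserving composition and window identity
while destroying order.

## Hotspot commonality

Circles are binned into non-overlapping 1 kb bins (configurable); a bin
scores 1 for a tumor when ≥1 of that tumor's circles overlaps it by ≥1 bp,
so a tumor contributes at most 1 per bin regardless of its circle count.
Real and null per-bin tumor counts are compared with an asymptotic
two-sample Kolmogorov–Smirnov test, sample excess kurtosis (Fisher
definition, bias-corrected; reported for both tracks because the heavier
real tail is the signal), and 0–100th-percentile QQ points; per-chromosome
KS is also available.  The hotspot threshold is the maximum bin count of
the supplied null track — a property of the null, recomputed per run, never
a constant — and hotspot bins whose gap is ≤ the merge distance (default
1 kb) are reported as one region with its maximum count.  Note that raising
the threshold shrinks hotspot territory monotonically but can split one
merged region into two, so region counts alone are not monotone in the
threshold.

## Gene content and expression

A transcript is inside a circle iff `circle.start ≤ t.start` and
`t.end ≤ circle.end` (strand ignored; equality allowed).  Transcripts
crossing a breakpoint stay genomic.  Gene-to-circle assignment is per gene
per tumor and existential over the tumor's circles.  Per tumor, a gene is
expressed when FPKM > 0; the circle/genome × expressed/not 2×2 table gets a
two-sided Fisher's exact test; per-tumor p-values combine by Fisher's
method (`−2Σ ln p` against χ² with 2k df); per-cancer-type contrasts use
paired two-tailed t-tests over tumors.  Tumors with no circle genes report
NaN fields rather than fabricated zeros; tumors missing from the expression
matrix are skipped with a warning.

The per-tumor "highly expressed circle genes" list is computed by applying
the SD threshold (mean + 1·SD, sample SD) to the tumor's expressed genes
genome-wide and intersecting with the tumor's circle-associated genes.
Computing the threshold over all expressed genes (rather than over circle
genes only) makes the list sensitive to a genuine expression boost of
circle genes and reduces to the same null behaviour when no boost exists;
this was a genuinely open design choice and is recorded here as ours.
Cross-tumor commonality ranks each gene by the number of tumors in which it
is both circle-associated and expressed, thresholded at mean + 2·SD.

Gene-set enrichment is a Fisher's exact test on the in-list × in-set table
over a universe (default: annotated genes with measured expression).  The
default "ease" mode decrements the observed overlap by one (floor 0) before
the test — the conservative jackknifed variant of the EASE/DAVID tradition —
with the standard one-sided test available as `mode="standard"`.  Raw
p-values are filtered at α = 0.05 for the cross-tumor tally; no FDR
correction is applied by default, matching the tally's descriptive role.
Exact-test p-values are discrete and conservative: under a true null they
are super-uniform (P(p ≤ α) ≤ α), not uniform, and the tests check exactly
that.

## Breakpoint self-homology

For a circle `[s, e)` the query window is `[s − f, s + f)` and the subject
window `[e − f, e + f)`, with `f = 500` (homology) or `f = 100`
(microhomology); circles not longer than `2f` are filtered so the windows
cannot overlap inside the circle.  The aligner seeds on exact shared words
(28 bp homology, 4 bp microhomology; words containing N never match),
clusters seed diagonals within a 16-diagonal pad, and extends each cluster
with a banded affine-gap Smith–Waterman (match +2, mismatch −3, gap open 5,
gap extend 2; a length-k gap costs `5 + 2k`).  With word size 1 and the
band covering all diagonals this reduces exactly to full Smith–Waterman,
which is how the aligner is validated against an independent
dynamic-programming oracle.  Hits overlapping a better hit in both query
and subject are dropped; within one diagonal cluster only the best
alignment is reported, which is sufficient because all downstream
statistics use the best hit per circle (lowest E, ties to longer length,
then leftmost start).  Both subject orientations are searched by default
(switchable), with subject coordinates reported in the original frame.

Significance is the Karlin–Altschul E-value `E = K·m·n·e^(−λS)` with the
published constants for this scoring scheme (λ = 0.625, K = 0.41) and the
raw window lengths as `m`, `n`; no effective-length correction is applied,
and both λ and K are configurable (an ungapped-λ solver for arbitrary
background composition is provided).  `E < 1` is significant.  Because the
search-space model under a 4 bp word is permissive by construction,
absolute microhomology percentages are sensitive to λ, K, and the
threshold; the analyses therefore rest on within-run group contrasts
(real vs random vs scrambled under the identical procedure), which is also
how the tests are framed.

Group summaries report the percentage of eligible circles with a
significant hit and the mean best-hit length over circles with a hit.  The
omnibus test is a one-way ANOVA on per-tumor hit percentages (and on
per-circle best-hit lengths) with Tukey HSD pairwise comparisons; the
degenerate all-equal-means case is reported as F = 0, p = 1 rather than
NaN.  The position trace marks, for each circle with a hit, every
query-window position covered by the best hit on a −f..+f number line
centred on the breakpoint and sums over circles; using the query window
only keeps the trace mass equal to the summed best-hit lengths.

## Motif scanning

A PFM becomes a log₂-odds PWM via
`p = (count + pseudocount·q) / (total + pseudocount)` against background
`q` (default uniform, pseudocount 1).  A hit is any position, either
strand, whose summed log-odds reaches the score threshold, default 80 % of
the maximal achievable score (the classic PWM-scanning convention; the
threshold is recorded in output metadata because enrichment is
threshold-dependent).  Windows are ±250 bp around each breakpoint of
circles > 500 bp; offsets are reported relative to the breakpoint (window
midpoint), minus-strand hits at their plus-strand start.  Per tumor and
motif, enrichment is a one-sided Fisher's exact test of windows-with-≥1-hit,
real vs matched random-control breakpoint windows — a background that
controls composition and genomic context simultaneously, replacing the
affinity-based background correction of lognormal-background scanners with
an exactly testable count statistic (a deliberate methodological
substitution).  α = 0.001; a motif is enriched in a group when significant
in ≥50 % of the group's tumors; common/unique sets are formed between
circles with and without genes.

## Synthetic cohort

Defaults (all configurable, one integer seed driving named substreams):
2 chromosomes × 300 kb with i.i.d. uniform base composition; a centered
centromere spanning 10 % of each chromosome; 300 non-overlapping genes of
400–1500 bp placed uniformly outside centromeres; 20 tumors; per-tumor
circle counts normal around 50 (CV 0.15); circle lengths log-uniform on
[300, 30 000] bp so the >200, >500 and >1000 bp eligibility filters all see
traffic on both sides; 5 hotspot loci of 5 kb, each receiving an
identically-placed circle in 90 % of tumors; baseline expression Bernoulli
(p = 0.52) × lognormal(μ = 1, σ = 1), with circle-resident genes boosted
×2 in FPKM and +0.15 in expressed probability — a deliberately scaled-down
cohort (tens of tumors, ~50 circles each) relative to the hundreds of
tumors and ~500 circles per tumor of real pan-cancer call sets.

Planting edits the genome itself (not extracted windows), so homology and
motif scans read one coherent FASTA: flank homology copies the sequence
straddling the start breakpoint onto the end breakpoint (optionally with
per-base mismatches), motif planting writes the PFM consensus at
breakpoint + offset, and a span registry skips any plant whose source or
destination would collide with an earlier edit, keeping the recorded truth
exact.  Plants are restricted to background (non-hotspot) circles because
hotspot circles share coordinates across tumors.  The gene-set collection
contains one planted set — the genes inside hotspot loci, hence
circle-resident in most tumors — plus random sets of comparable size.

What the generator does not emulate: real human repeat structure (the
Alu-driven homology background of real genomes), GC heterogeneity,
chromatin signal, and realistic circle-length tails up to tens of
megabases.  Passing recovery tests therefore demonstrates that the
pipeline detects the stated structures at the stated effect sizes under a
clean background; they say nothing about repeat-induced false-positive
rates on a real genome, where the matched random and scrambled controls
carry that burden.

For hotspot-recovery testing the scenario uses shorter circles
(log-uniform [300, 3000] bp) so that background bin penetrance stays low
relative to the planted 90 % penetrance — the regime in which a
null-maximum threshold is informative.  Problem sizes throughout the test
suite (hundreds of circles, tens of tumors, 2 000 null motif pairs,
exhaustive alignment oracles up to length 5 plus thousands of sampled pairs
up to length 12) were chosen to exercise every code path at desk scale.

## Known limitations

* The aligner reports one alignment per seeded diagonal cluster; two
  disjoint optima sharing a cluster collapse to the better one.
* E-values use raw window lengths without effective-length correction;
  absolute significance rates under the 4 bp word size are
  parameter-sensitive (group contrasts are not).
* The EASE-style "modified" Fisher's test is one convention among several;
  the standard test is exposed alongside it.
* Expression analysis cannot distinguish circle-derived from chromosomal
  transcripts; "circle-associated" is a positional statement only.
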