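# eccatlas

Cohort-scale analysis of extrachromosomal circular DNA (eccDNA) calls.

Tumor genomes shed double-stranded circular DNAs — from tens of base pairs
to megabases — whose origins are thought to involve homologous
recombination (HR) and microhomology-mediated end joining (MMEJ/MHMR).
Given per-tumor circle calls (BED intervals), `eccatlas` asks the questions
a circle-biogenesis study asks of such a cohort:

* **Do circles come from common loci?**  Each 1 kb genome bin gets a
  binarized tumor count `c_b = Σ_t 1[tumor t has ≥1 circle overlapping b]`;
  the real distribution of `c_b` is compared against a size/count-matched
  random-interval null (two-sample Kolmogorov–Smirnov, excess kurtosis, QQ
  points), and hotspots are bins with `c_b > max(null)`, merged within 1 kb.
* **Do circles carry genes, and are those genes expressed?**  A circle
  "has genes" when a complete functional transcript lies fully inside it;
  per tumor, circle vs genome gene classes are compared on percent
  expressed (FPKM > 0) and mean FPKM (Fisher's exact per tumor, Fisher's
  method `X² = −2Σ ln pᵢ` across tumors, paired t-tests per cancer type),
  and SD-thresholded gene lists (`x > μ + k·σ`, k = 1 per tumor, k = 2 for
  cross-tumor commonality) feed Fisher's-exact gene-set enrichment (EASE-style
  overlap−1 by default) over GMT collections.
* **Are breakpoints self-homologous?**  For each circle the ±500 bp windows
  straddling its two breakpoints are aligned with an internal seed-and-extend
  local aligner (exact-word seeding, banded affine-gap Smith–Waterman
  extension) and Karlin–Altschul significance
  `E = K·m·n·e^(−λS)`, threshold `E < 1`.  Homology mode uses a 28 bp
  minimum seed word on circles > 1 kb; microhomology mode uses a 4 bp word
  on ±100 bp windows of circles > 200 bp.  Identical scans run on matched
  random circles and on nucleotide-permuted (scrambled) windows; groups are
  compared by one-way ANOVA with Tukey HSD, and per-offset indicator traces
  localize homology relative to the breakpoint.
* **Are DNA-binding motifs enriched at breakpoints?**  JASPAR PFMs become
  log₂-odds PWMs (pseudocounted, hit threshold 80 % of the maximum score);
  ±250 bp breakpoint windows of circles > 500 bp are scanned on both
  strands, per-tumor enrichment is a one-sided Fisher's exact test of
  windows-with-hit against matched random-control windows (α = 0.001), and
  motifs significant in ≥50 % of tumors are tallied and partitioned into
  common/unique sets between circles with and without genes.

A synthetic-cohort generator plants all of this structure — recurrent
hotspot loci, homologous and microhomologous breakpoint flanks, motif
consensus sites, expression boosts for circle-resident genes — with a
recorded ground truth, so the whole pipeline is testable end-to-end with no
downloads.

## Worked example

Build a synthetic cohort in which half of the eligible circles carry an
exact 100 bp homologous flank pair, then run the three-group homology scan:

```python
from eccatlas import breakpoint_homology as bh, null_controls as nc, synthetic_cohort as sc
from eccatlas.io_formats import ReferenceSequence, read_circles_bed, read_genome_layout

cfg = sc.SyntheticConfig(seed=3, homology_plant_fraction=0.5)
files = sc.build_cohort(cfg, "demo")
cohort = read_circles_bed(files.circles_bed)
layout = read_genome_layout(files.layout_tsv)
ref = ReferenceSequence(files.fasta)
rand = nc.generate_random_circles(cohort, layout, nc.RandomizationSpec(seed=4))
results = {
    "real": bh.scan_cohort(cohort, ref, "homology"),
    "random_control": bh.scan_cohort(rand, ref, "homology"),
    "scrambled": bh.scan_windows(
        bh.scramble_window_pairs(bh.collect_window_pairs(cohort, ref, 500), 5),
        bh.AlignerParams.homology()),
}
comp = bh.summarize_groups(results)
print(comp.summary_frame().to_string(index=False))
print(f"ANOVA on per-tumor percentages: F={comp.anova_pct[0]:.1f}, p={comp.anova_pct[1]:.3g}")
```

which prints:

```
         group  n_circles  pct_with_hit  mean_hit_length
          real        736     38.994565       100.773519
random_control        734      5.177112        95.131579
     scrambled        736      0.000000              NaN
ANOVA on per-tumor percentages: F=316.3, p=1.39e-31
```

Real circles recover the planted homology (≈39 % of eligible circles, mean
best-hit length ≈ the planted 100 bp); random circles pick up only the
copies they happen to land on; scrambling the windows abolishes homology
entirely — the real > random > scrambled ordering that motivates an
HR/MHMR reading of breakpoint structure.

The same analyses run from the shell:

```bash
eccatlas simulate --outdir run --seed 3
eccatlas all      --outdir run --seed 3   # nulls, hotspots, classify,
                                          # expression, homology,
                                          # microhomology, motifs
```

Each stage writes tab-delimited tables, BED files, position traces, and a
`manifest_<stage>.json` (config echo, seed, outputs); identical config and
seed give byte-identical outputs.

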