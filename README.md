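# chipforge

Design and validation computations for SNP genotyping arrays, with seeded
synthetic-data generators providing ground truth for every stage.

Building a SNP chip for a non-model organism — the motivating case is a
fragmented mosquito genome assembled into thousands of supercontigs — means
turning noisy discovery variant calls into a set of markers that behave like
honest, single-copy, biallelic, Mendelian loci. `chipforge` implements that
pipeline end to end for people who design or audit such arrays:

1. **Probe design** — filter discovery variants (RNA-seq track: depth ≥ 7×,
   minor-allele frequency ≥ 0.2, fraction of reads carrying the two called
   alleles ≥ 0.85; RAD-seq track: depth ≥ 7×, variant phred quality ≥ 25,
   missingness ≤ 20%), require 35 bp of invariant flanking sequence on each
   side of the SNP (the hybridization probe spans the 71-mer), pool tracks,
   rank by a pluggable scoring hook, and measure marker spacing (Pearson *r*
   of inter-SNP distance against supercontig length detects positional bias).
2. **Marker QC** — classify every genotyped marker into exactly one class:
   `AllGenotypes`, `NoMinorHom`, `Monomorphic`, `MultiAllele` (off-target
   variant / duplication detected from channel-intensity clusters),
   `LowCallRate` (call rate < 95%), or `LowQuality`. Only the first two
   classes are retained.
3. **Mendelian screen** — for F1 cohorts from single-pair matings, test each
   *informative* locus (heterozygous in exactly one parent, so offspring are
   expected 1:1 in two genotype classes) with a χ² goodness-of-fit per
   cohort, combine cohorts with Fisher's method
   (X = −2 Σ ln pᵢ ~ χ²₂ₖ), and apply sequential Bonferroni–Holm across
   loci. Impossible offspring genotypes are flagged `incompatible` rather
   than folded into the statistic.
4. **Population characterization** — pairwise genotypic LD as the squared
   Pearson correlation of allele-dosage vectors (composite r², with the
   small-sample floor E[r²] ≈ 1/n for unlinked pairs), exact conditional
   Hardy–Weinberg tests with Holm correction, relatedness via the unadjusted
   Ajk estimator

   A_jk = (1/N) Σᵢ (x_ij − 2pᵢ)(x_ik − 2pᵢ) / (2pᵢ(1−pᵢ)),   j ≠ k,

   and PCA of column-standardized dosages with seeded balanced subsampling.

The `synthdata` module generates every input with known truth: fragmented
references with variant positions, Balding–Nichols structured populations,
F1 cross cohorts with controllable segregation distortion and genotyping
error, haplotype pools with distance-dependent LD, read-count tables for the
probe filters, and genotype matrices with injected QC defects.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/03_mendelian_screen.py` simulates three F1 cohorts
(32/31/32 offspring) over 5,000 loci of which 200 carry strong transmission
distortion (the heterozygous parent transmits one allele 90% of the time),
then screens them:

```
loci testable in >= 1 cohort: 4299
deviant after Holm:           133
incompatible genotypes:       0
untestable:                   701
retained markers:             4867
of 133 flagged loci, 133 are truly distorted (false flags: 0)
```

About 14% of loci are uninformative in every cohort (both parents
homozygous or both heterozygous everywhere) and cannot be tested; of the
testable loci, Holm-corrected Fisher-combined p values flag 133 — all of
them genuinely distorted, none of the 4,000+ fairly segregating loci — and
the flagged loci are dropped from the validated marker set.

`python examples/05_full_pipeline.py` chains all stages on a synthetic study
and prints the marker counts at every stage boundary from the run manifest;
`chipforge run --seed 11 --out-dir out/` does the same from the shell.

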