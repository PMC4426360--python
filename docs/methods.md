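# Methods

This note documents the models, statistics and numerical choices behind
`chipforge`, and what its synthetic-data generators do and do not emulate.

## Probe design filters

Two discovery tracks are modelled, reflecting the two ways array candidates
are typically mined:

* **RNA-seq track** (`filter_rna_track`): site retained iff read depth ≥ 7,
  minor-allele frequency ≥ 0.2, and (ref reads + alt reads) / total depth
  ≥ 0.85. The last rule screens out multiallelic or repeat-collapsed sites
  whose reads are not dominated by the two called alleles; the denominator
  is total site depth, including "other" (third-allele) reads. A zero-depth
  site is excluded with reason `no_coverage` rather than raising.
* **RAD-seq track** (`filter_rad_track`): depth ≥ 7, variant phred
  quality ≥ 25, fraction of missing genotype calls ≤ 0.20. A site carrying
  no genotypes at all counts as fully missing.

All thresholds are inclusive at the printed boundary. Filters are pure
conjunctions, so they commute; each excluded site records the first failing
rule in the documented order as its primary reason plus the full pass/fail
vector, which the tests rely on for order-independence checks.

MAF is computed from called genotypes when per-sample calls exist, otherwise
from the alt/(ref+alt) read fraction (pooled-sample discovery data carries
no per-sample calls); both are folded into [0, 0.5].

**Flank invariance.** A candidate passes iff no other known variant lies
within ±35 bp and both flanks fit inside the contig (positions are 1-based
inclusive everywhere user-visible; internal slices are half-open and noted
in code). The 71-mer centred on the SNP is the probe template, so the check
is against the *complete* variant index, not just filtered survivors.

**Pooling and ranking.** Candidates are unioned on (contig, pos, ref, alt)
with per-track provenance kept. Tracks calling different alternate alleles
at one position are a multiallelic conflict and every candidate at that
position is dropped. The commercial array-design scorer (hybridization
thermodynamics, self-hybridization, copy number) is not reproducible; the
ranking hook is pluggable and the default — GC content of the 71-mer
closest to 0.5, ties preserving input order via stable sort — is an
explicitly labelled stand-in.

**Spacing statistics.** Inter-marker distances are adjacent-pair gaps
between consecutive markers within a contig (an `all_pairs` switch provides
the alternative reading); each gap is paired with its contig's length, and
Pearson's r of gap vs length measures positional bias. With no contig
holding two markers the correlation is reported as not-computable (None),
never as zero.

## Marker QC classes

Each marker receives exactly one class with precedence
`LowQuality` → `LowCallRate` → `MultiAllele` → biological classes.
Data-quality failures are deliberately ranked before biological classes so
that, e.g., a low-call-rate monomorphic marker is accounted once as
`LowCallRate` and the class counts partition the marker set. Biological
classes from the observed genotype set: all three genotypes →
`AllGenotypes`; major homozygote + heterozygote only → `NoMinorHom`;
exactly one homozygous genotype → `Monomorphic`; residual shapes (both
homozygotes with no hets, or hets only) violate the biallelic cluster model
and land in the `LowQuality` catch-all.

The off-target (third allele / duplicated locus) detector mirrors
intensity-cluster logic: among samples in the heterozygote contrast region
(|log₂(signal_A/signal_B)| < 1), the signal magnitudes are split into two
groups by a 1-D two-means search; the marker is flagged when the group
means differ by ≥ 2× (both clusters ≥ 2 samples). Markers without
intensities are "not evaluable" and return False with a note; in
intensity-free operation `MultiAllele` and `LowQuality` can be driven by
externally supplied flags and scores instead. The 2× ratio and the
contrast cutoff are configurable; defaults were chosen so that a clean
heterozygote cluster (single magnitude mode) sits far below the flagging
ratio while a displaced cluster at a quarter of the normal magnitude is
flagged essentially always.

Retention: `AllGenotypes` ∪ `NoMinorHom`. `QCLedger.from_counts` supports
ledger arithmetic on externally supplied class counts (e.g. auditing a
published QC table).

## Mendelian screen

Only loci heterozygous in exactly one parent and homozygous in the other
are informative — the expectation is 1:1 over two genotype classes, giving
the test its power at cohort sizes near 32. Per cohort, the χ² statistic is
computed over categories with positive expected probability (df =
categories − 1); an observation in an expected-zero category (e.g. a BB
offspring of AB × AA) returns an `incompatible` flag instead of a
statistic, separating parental-genotyping-error signals from segregation
distortion. No-calls are removed per locus before testing. Cohort p values
are combined with Fisher's method when ≥ 2 cohorts are testable (a single
cohort's p is used directly); combined p values are Holm-corrected across
all testable loci and a locus is deviant iff its adjusted p ≤ α (default
0.05). The retained set excludes deviant and incompatible loci.

Cross selection (`select_crosses`) maximizes the union of informative loci:
greedy maximum-coverage with ties broken by cross id, switching to an
exhaustive subset search for ≤ 15 candidates (where it is provably
optimal; the tests compare greedy against brute force on small instances).

Numerical notes: a p value of exactly 0 entering Fisher's method propagates
to a combined p of 0 with a warning (log singularity). Holm adjustment uses
the cumulative-max step-down form, capped at 1, and agrees with
`statsmodels.stats.multitest.multipletests(method="holm")` on random input.

## Population statistics

* **LD**: composite (genotypic) r² — the squared Pearson correlation of
  B-allele dosage vectors over jointly called samples. It is phase-free,
  symmetric, invariant to allele relabeling (x → 2−x), and approaches the
  gamete (haplotype) r² as n grows; the agreement is asymptotic, not exact
  in finite samples, because cross-gamete covariance terms only vanish in
  expectation. For unlinked markers the estimator has a small-sample floor
  E[r²] ≈ 1/(n−1), which the cross-contig summaries make visible at n = 40.
  `ld_scan` computes all pairs with no distance or r² filter and reports:
  global / same-contig / cross-contig means, a 2-D histogram over half-open
  200-bp distance bins × r² bins, LOWESS curves (statsmodels, smoothing
  fraction 2/3, fixed) for all same-contig pairs and for pairs with
  r² ≥ 0.2, and the median distance among same-contig pairs in perfect LD
  (NaN when none). An EM-haplotype-frequency r² is not implemented; dosage
  mode is the single, documented definition used throughout.
* **HWE**: exact conditional test by default — conditioning on the observed
  allele counts, the p value sums the probabilities of all heterozygote
  counts (same parity, within the allele-count bounds) whose conditional
  probability does not exceed the observed table's. Distributions are
  cached per (n, allele count), making 10⁵ loci cheap. Monomorphic markers
  return p = 1. A 1-df χ² mode is available. Family-wise control uses Holm
  (Bonferroni available).
* **Relatedness**: the unadjusted Ajk estimator, with the distinct diagonal
  formula A_jj = 1 + (1/N) Σᵢ (x² − (1+2pᵢ)x + 2pᵢ²)/(2pᵢ(1−pᵢ)). Markers
  fixed in the sample are excluded (standardization undefined) and counted.
  Missing calls are handled pairwise-complete. By default pᵢ is the sample
  frequency, matching the behaviour of the upstream tools this estimator
  comes from; that convention centres unrelated off-diagonals at −1/(n−1),
  not 0, so an optional `allele_freqs` argument accepts external reference
  frequencies when the zero-expectation form is wanted. Both behaviours are
  tested.
* **PCA**: dosages are mean-imputed per marker (missing calls),
  zero-variance markers dropped, columns centred and scaled to unit
  variance, and scores taken from an SVD (scikit-learn, full solver, so
  results are deterministic up to component sign). Balanced subsampling — a
  seeded uniform draw without replacement down to a per-population target —
  is applied before the decomposition to keep an oversampled population
  from dominating the axes.

## Synthetic-data generators

All randomness flows through `numpy.random.default_rng(seed)`; every
generator is byte-reproducible under a fixed seed.

* **Reference** (`simulate_reference`): i.i.d. ACGT sequences; each base
  carries a variant independently with the configured density (per-contig
  counts are Binomial(L, density)); forced placements supported for
  boundary tests.
* **Populations** (`simulate_population`): Balding–Nichols — each
  population's allele frequency is a Beta(p(1−F)/F, (1−p)(1−F)/F) draw
  around the ancestral p with F = F_ST (F_ST = 0 short-circuits to the
  no-drift limit). Genotypes are HWE draws, optionally with within-
  population inbreeding F. The Weir–Cockerham estimator recovers the
  drift parameter within Monte-Carlo error in the tests.
* **Crosses** (`simulate_cross`): gametes follow the transmission model
  (hom parents transmit their allele; a het parent transmits B with
  probability d, default 0.5 = fair), offspring counts are multinomial.
  Genotyping error is a symmetric single-step miscall (hom → het; het →
  either hom with probability e/2 each); no-calls are removed per call at
  the configured rate. Distortion d = 0.9 is the "strong distortion"
  condition used in the power checks.
* **Linked genotypes** (`simulate_linked_genotypes`): copying-with-
  recombination over a fixed haplotype pool — each gamete is a mosaic of
  pool haplotypes, switching template between adjacent sites with
  probability 1 − exp(−ρ·d). Association decays exponentially with
  distance in expectation; contigs are independent, so cross-contig pairs
  recombine freely. This is deliberately simpler than a coalescent: it
  provides controllable decay shape, not population-genetic realism.
* **Defect injection** (`inject_marker_defects`): overwrites disjoint
  random marker subsets with truth-labelled defects (monomorphic, no minor
  homozygote, exact rounded low call rate, off-target intensity split at a
  quarter magnitude, sub-floor quality score) and synthesizes clean
  two-channel intensities for everything else. Segregation distortion is
  exercised through `simulate_cross`, where a pedigree exists for it to act
  on, rather than through the defect plan.

What the generators do **not** emulate: real allele-frequency spectra or
ascertainment bias, linked selection, genotype-intensity physics beyond the
two-cluster caricature, batch effects, or the fragmented-assembly length
distribution of any particular genome. Passing tests therefore demonstrate
the correctness and calibration of the *computations* under controlled
conditions, not the behaviour of any particular real dataset.

## Problem sizes and calibration experiments

The test-suite calibration experiments use: 50 replicates of 3 cohorts
(32/31/32) × 5,000 loci for the Mendelian family-wise false-deviant rate;
one 5,000-locus run at distortion 0.9 for power; 200 replicates of 40
diploids × 1,000 loci for HWE type-I control (also what
`scripts/acceptance.py` recomputes); 20 seeds of 4 × 25 markers at n = 40
for the cross-contig r² floor; and 10 seeds of 500-marker matrices with
250 injected defects for QC class recovery. These sizes keep the whole
suite near ten seconds while leaving Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The commercial genotype-calling and probe-scoring steps are consumed as
  inputs or replaced by labelled stand-ins, never reproduced.
* `MultiAllele` detection is a heuristic on summarized intensities; real
  off-target-variant callers fit full cluster models to raw intensities.
* The exact HWE test enumerates heterozygote counts, which is fast at
  array-study sample sizes (tens to hundreds) but the cache grows with
  distinct (n, allele-count) pairs.
* `mendel_screen` assumes autosomal biallelic inheritance; sex-linked and
  multiallelic models are out of scope, as are linkage-aware joint tests.
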