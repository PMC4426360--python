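"""Screen markers for Mendelian inheritance across three F1 cohorts.

Simulates three single-pair crosses (cohort sizes 32, 31, 32) over 5,000
loci.  Most loci segregate fairly; 200 carry strong transmission distortion
(the heterozygous parent transmits one allele 90% of the time).  Each locus
is chi-square-tested in every cohort where one parent is heterozygous and
the other homozygous, p values are Fisher-combined across cohorts, and
Holm-corrected combined p values below 0.05 flag a locus as deviant.
"""

import numpy as np

from chipforge import mendel
from chipforge import synthdata as sd

rng = np.random.default_rng(2024)
n_loci, n_distorted = 5_000, 200
distortion = np.full(n_loci, 0.5)
distortion[:n_distorted] = 0.9

cohorts = []
for ci, size in enumerate((32, 31, 32)):
    spec = sd.CrossSpec(
        maternal=rng.choice([0, 1, 2], n_loci, p=[0.3, 0.4, 0.3]),
        paternal=rng.choice([0, 1, 2], n_loci, p=[0.3, 0.4, 0.3]),
        n_offspring=size,
        distortion=distortion,
    )
    cohorts.append(sd.simulate_cross(spec, seed=100 + ci, cross_id=f"cross{ci + 1}"))

result, summary = mendel.mendel_screen(cohorts, alpha=0.05)
print(f"loci testable in >= 1 cohort: {summary.testable}")
print(f"deviant after Holm:           {summary.deviant}")
print(f"incompatible genotypes:       {summary.incompatible}")
print(f"untestable:                   {summary.untestable}")
print(f"retained markers:             {len(summary.retained_loci)}")

flagged = result.table[result.table.verdict == "deviant"].index
truly_distorted = set(cohorts[0].locus_ids[:n_distorted])
true_hits = sum(1 for locus in flagged if locus in truly_distorted)
print(f"of {len(flagged)} flagged loci, {true_hits} are truly distorted "
      f"(false flags: {len(flagged) - true_hits})")
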