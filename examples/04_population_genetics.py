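"""Characterize validated markers: LD decay, HWE, relatedness, PCA.

Simulates 40 diploids from a recombining haplotype pool on four supercontigs
(so same-contig marker pairs carry distance-dependent LD while cross-contig
pairs recombine freely), then runs the four population analyses.
"""

import numpy as np

from chipforge import popgen
from chipforge import synthdata as sd

pool = sd.random_haplotype_pool(n_contigs=4, sites_per_contig=40,
                                contig_length=200_000, n_haplotypes=8,
                                rho=5e-5, seed=1)
matrix = sd.simulate_linked_genotypes(pool, n_individuals=40, seed=2)

scan = popgen.ld_scan(matrix)
print(f"marker pairs:          {len(scan.pairs)}")
print(f"global mean r2:        {scan.mean_r2:.4f}")
print(f"same-contig mean r2:   {scan.same_contig_mean:.4f}")
print(f"cross-contig mean r2:  {scan.cross_contig_mean:.4f}  (~1/n = {1 / 40:.4f} for unlinked pairs)")
if not np.isnan(scan.median_perfect_ld_distance):
    print(f"median distance of perfect-LD pairs: {scan.median_perfect_ld_distance:.0f} bp")

hwe = popgen.hwe_screen(matrix, alpha=0.05, mode="exact", method="holm")
print(f"HWE-deviant markers after Holm: {hwe.n_deviant} of {len(hwe.table)}")

kin = popgen.ajk_relatedness(matrix)
off = kin.values[np.triu_indices(kin.values.shape[0], k=1)]
print(f"Ajk off-diagonal mean: {off.mean():+.4f} (unrelated; sample-frequency "
      f"standardization centres at -1/(n-1) = {-1 / 39:.4f})")

pca = popgen.pca_genotypes(matrix, seed=3)
print("variance explained by first 3 PCs:",
      ", ".join(f"{v:.3f}" for v in pca.explained_variance_ratio[:3]))
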