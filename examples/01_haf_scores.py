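"""HAF vectors and ℓ-HAF scores on a tiny hand-built sample.

Each derived allele (1) in a haplotype is replaced by its derived count in
the sample; the ℓ-HAF score sums the ℓ-th powers of those counts.  The mean
score links exactly to the site frequency spectrum.
"""

import numpy as np

import hafscore as hs

matrix = hs.HaplotypeMatrix(
    data=[[1, 1, 0], [1, 0, 1], [1, 0, 0], [0, 0, 0]],
    positions=[120.0, 5_000.0, 43_000.0],
)

print("haplotype matrix (rows = haplotypes):")
print(matrix.data)
print("derived counts per site:", matrix.derived_counts())

print("\nHAF vectors (derived entries -> sample counts):")
print(hs.haf_vectors(matrix).haf_vectors)

for ell in (1, 2):
    print(f"{ell}-HAF scores:", hs.ell_haf(matrix, ell))

spectrum = hs.sfs(matrix)
print("\nsite frequency spectrum xi_w:", spectrum.counts)
print("mean 1-HAF via SFS identity:", hs.mean_ell_haf_via_sfs(spectrum, 1),
      "= mean of direct scores:", hs.ell_haf(matrix, 1).mean())
# The identity (1/n) sum_w xi_w w^(l+1) holds exactly for any sample.
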