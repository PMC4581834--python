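"""Simulated neutral samples agree with the closed-form expectations.

A few hundred coalescent replicates are enough to see the means line up;
the genealogy of each non-recombining replicate is recorded, so the epoch
decomposition (mutation counts x clade sizes) can be checked against the
matrix-based scores exactly.
"""

import numpy as np

import hafscore as hs

params = hs.DemographyParams(theta=48, n=200, N=20_000)
reps = 500

means = np.array([
    hs.ell_haf(s.matrix).mean()
    for s in hs.simulate_neutral(params, reps, seed=7, record_genealogy=False)
])
se = means.std() / np.sqrt(reps)
print(f"mean 1-HAF over {reps} constant-size samples: "
      f"{means.mean():.0f} +- {se:.0f} (theory {hs.expected_ell_haf_constant(params):.0f})")

growth = hs.DemographyParams(theta=48, n=200, alpha=80, N=20_000)
gmeans = np.array([
    hs.ell_haf(s.matrix).mean()
    for s in hs.simulate_exponential_growth(growth, reps, seed=8)
])
print(f"mean 1-HAF over {reps} growth samples:        "
      f"{gmeans.mean():.1f} +- {gmeans.std() / np.sqrt(reps):.1f} "
      f"(theory {hs.expected_ell_haf_exponential(growth):.1f})")

sample = next(iter(hs.simulate_neutral(hs.DemographyParams(theta=20, n=12), 1, seed=9)))
print("\nepoch decomposition reproduces the direct scores exactly:",
      np.array_equal(hs.reconstruct_scores(sample.genealogy, 2),
                     hs.ell_haf(sample.matrix, 2)))
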