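"""Expected 1-HAF under three demographies, at the canonical parameters.

Constant size gives theta*(n-1)/2; exponential growth compresses the
genealogy near the root and shrinks the expectation ~40-fold at alpha=80;
mid-sweep carriers climb toward a peak near theta*n.
"""

import hafscore as hs

const = hs.DemographyParams(theta=48, n=200, N=20_000)
print("neutral constant size:",
      hs.expected_ell_haf_constant(const, ell=1))          # 4776.0
print("  (2-HAF:", hs.expected_ell_haf_constant(const, ell=2), ")")

growth = hs.DemographyParams(theta=48, n=200, alpha=80, N=20_000)
print("exponential growth (alpha=80):",
      round(hs.expected_ell_haf_exponential(growth, ell=1), 1))   # 126.9

print("\ncarrier / non-carrier expectations during a hard sweep (s=0.05):")
for nu in (0.1, 0.3, 0.5, 0.7, 0.9):
    state = hs.SweepState(nu=nu, s=0.05, params=const)
    print(f"  nu={nu:.1f}  carrier {hs.expected_haf_carrier(state):8.0f}"
          f"  non-carrier {hs.expected_haf_noncarrier(state):8.0f}")

print("peak carrier expectation:", round(hs.haf_peak(const), 1),
      f"~ theta*n = {48 * 200}")
# The carrier curve rises with the carrier fraction nu while non-carriers
# stay near the neutral mean; the peak is independent of s.
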