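"""Compute a normalized weighted rich-club curve for one connectome.

Builds a synthetic 68-node fiber-density network with a planted heavy core,
computes phi_w(k) and its normalization against 100 degree-preserving random
networks, and prints the curve.  phi_n > 1 over a k range is the rich-club
signature: the high-degree core concentrates more connection weight than a
degree-matched random network would.
"""

import numpy as np

import richclub as rc

fd, fa, md = rc.generate_base_connectome(rc.default_spec(seed=7))
curve = rc.rich_club_curve(fd, k_max=30, n_random=100, seed=1)

print("k   phi_w   null_mean   phi_n")
for k, pw, prm, pn in zip(curve.k_values, curve.phi_w, curve.phi_rand_mean,
                          curve.phi_norm):
    if np.isnan(pn):
        print(f"{k:2d}  (undefined: no edges among nodes with degree > {k})")
    else:
        print(f"{k:2d}  {pw:.4f}  {prm:.4f}      {pn:.3f}")

above = curve.k_values[curve.phi_norm > 1]
print(f"\nrich-club regime (phi_n > 1): k = {above.min()}..{above.max()}")
print("phi_n rises with k because the planted 26-node core holds the")
print("strongest edges; a degree-matched null spreads them evenly.")
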