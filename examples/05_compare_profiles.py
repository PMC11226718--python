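"""Dose-comparison metrics between two depth-dose profiles.

Scores a perturbed profile against a reference on a unified fine grid
(monotone cubic Hermite regridding): the percentage of voxels within
1% and 2% relative deviation (eps1/eps2), the mean absolute deviation,
and a Kolmogorov-Smirnov equivalence check on the cumulative curves.
"""

import numpy as np

import bfpdose as bd

rng = np.random.default_rng(2024)
depth = np.linspace(0.0, 30.0, 120)
reference = np.exp(-((depth - 3.0) / 14.0) ** 2) + 0.15

for sigma in (0.005, 0.03):
    perturbed = reference * (1.0 + sigma * rng.standard_normal(depth.size))
    c = bd.compare(depth, perturbed, depth, reference)
    print(f"multiplicative noise {100 * sigma:.1f}%:")
    print(f"  eps1 = {c.eps1:5.1f}%   eps2 = {c.eps2:5.1f}%   "
          f"mean |eps_r| = {c.eps_bar:.3f}%")
    print(f"  KS D = {c.ks_statistic:.4f}, p = {c.ks_pvalue:.3f} -> "
          f"equivalence {'rejected' if c.ks_reject() else 'not rejected'}"
          " at the 0.02 level")

print()
print("Half-percent noise keeps every voxel inside the 2% criterion;")
print("3% noise breaks eps1/eps2 but the KS test, which sees only the")
print("cumulative shape, is far less sensitive to uncorrelated noise.")
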