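"""Heterogeneous thorax phantom: tissue | bone | lung | tissue.

The slab stack uses the standard thickness fractions (13/7/22/58 % of a
total sized to 1.2x the beam range); the dose exhibits the density
jumps at the bone and lung interfaces.
"""

import numpy as np

import bfpdose as bd

bench = bd.build_benchmark("thorax", 100.0)
print("thorax benchmark at 100 MeV")
for name, t in zip(bench.materials, bench.thicknesses_cm()):
    rho = bd.get_material(name).density
    print(f"  {name:8s} {t:6.2f} cm  (rho = {rho:.2f} g/cm3)")

problem = bd.make_problem(bench, G=60, voxels=80, N=8, M=1)
solution = bd.solve(problem)
depth, dose = bd.dose_profile(solution)

edges = np.cumsum(bench.thicknesses_cm())
print("\ndepth [cm]  material  dose [MeV/g]")
for i in range(0, 80, 6):
    mat = bench.materials[np.searchsorted(edges, depth[i])]
    print(f"{depth[i]:9.2f}  {mat:8s}  {dose[i]:8.4f}")

audit = bd.energy_audit(solution)
print(f"\nenergy closure: {100 * audit['closure']:.2f} % of incident")
print("Dose per gram rises in the low-density lung (more track length")
print("per gram) and the beam still stops inside the distal tissue.")
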