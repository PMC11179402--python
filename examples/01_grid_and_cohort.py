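"""Tour of the 24-2 grid and the synthetic cohort generator.

Builds the 52-point perimetry grid, shows its symmetry permutations, then
draws a small synthetic cohort and summarizes the planted ground truth.

Run:  python examples/01_grid_and_cohort.py
"""

import dataclasses

import numpy as np

from sfmap import SyntheticCohortConfig, generate_cohort
from sfmap.vf_grid import (
    build_grid,
    default_normative,
    hemifield_masks,
    vertical_mirror_permutation,
)

# --- the grid -------------------------------------------------------------
grid = build_grid()
sup, inf = hemifield_masks()
print(f"24-2 grid: {len(grid)} points "
      f"({sup.sum()} superior, {inf.sum()} inferior)")
print(f"first point: index {grid[0].index} at "
      f"({grid[0].x_deg:+.0f}, {grid[0].y_deg:+.0f}) deg, "
      f"{grid[0].hemifield} hemifield")

perm = vertical_mirror_permutation()
print(f"vertical mirror is a true permutation: "
      f"{np.array_equal(perm[perm], np.arange(52))}")

# --- the cohort -----------------------------------------------------------
config = dataclasses.replace(SyntheticCohortConfig(), n_eyes=12, seed=42)
norm = default_normative()
eyes, mapping = generate_cohort(config, norm)

print(f"\ncohort of {len(eyes)} eyes on a {mapping.grid_shape} en-face "
      f"patch grid")
for severity in ("healthy", "early", "moderate_advanced"):
    n = sum(e.severity_class == severity for e in eyes)
    print(f"  {severity:18s} {n:2d} eyes")

eye = next(e for e in eyes if e.severity_class == "moderate_advanced")
print(f"\nexample eye {eye.eye_id}: {eye.laterality}, "
      f"{eye.defect_pattern} defect, truth MD {eye.truth_md:.1f} dB, "
      f"{len(eye.vf_series)} VF visits, "
      f"volume {eye.raw_scans[0].intensity.shape}")

pt = 5
print(f"\nplanted mapping for VF point {pt} "
      f"({grid[pt].x_deg:+.0f}, {grid[pt].y_deg:+.0f}) deg: "
      f"en-face patches {mapping.regions[pt].tolist()} "
      f"(effect {mapping.effect[pt]:.1f} dB per unit damage)")
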