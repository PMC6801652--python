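"""Sampling design: grid the study area, size and draw the audit sample.

The study area is divided into 100 m x 100 m cells; a simple random
sample of cells is sized with the finite-population (Cochran) formula at
95% confidence, margin 0.05, expected proportion 0.5.
"""

import flcoder as flc

city = flc.generate_city(flc.CitySpec(seed=1))
grid = city.grid(cell_size_m=100.0)
print(f"study frame: {len(grid)} cells of 100 m (grid {grid.n_cols} x {grid.n_rows})")

spec = flc.sample_size_finite(N=len(grid), p=0.5, e=0.05, conf=0.95)
print(f"sample size at {spec.conf:.0%} confidence, e={spec.e}: "
      f"n = {spec.n} cells ({spec.n / spec.N:.0%} of the frame)")

cells = flc.draw_sample(grid, spec.n, seed=42)
print(f"first sampled cells: {cells[:5]} ...")
# The auditors walk exactly these cells and record every food facility.
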