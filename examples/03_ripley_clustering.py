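"""Spatial clustering of puncta with Ripley's H statistic.

Compares a uniform-random (CSR), a Thomas-clustered and a jittered-lattice
point pattern on the same 10 x 10 µm window.  H(r) = 0 marks spatial
randomness; positive H marks clustering, negative H dispersion.
"""

import numpy as np

from patchstoich import (PatternSpec, PointPattern, RectRegion,
                         clustering_gradient, nearest_neighbor_distance,
                         ripley_h, simulate_point_pattern)

region = RectRegion(10_000.0, 10_000.0)
r_grid = np.arange(0.0, 2000.0, 20.0)

specs = {
    "uniform (CSR)": PatternSpec("csr", (10_000.0, 10_000.0),
                                 intensity_per_um2=2.0),
    "Thomas clusters": PatternSpec("clustered", (10_000.0, 10_000.0),
                                   parent_per_um2=0.08, mean_offspring=60.0,
                                   offspring_sd_nm=1200.0),
    "jittered lattice": PatternSpec("lattice_jitter", (10_000.0, 10_000.0),
                                    spacing_nm=500.0),
}

for name, spec in specs.items():
    points, _ = simulate_point_pattern(spec, seed=3)
    curve = ripley_h(PointPattern(points, region), r_grid)
    grad = clustering_gradient(curve)
    nn = nearest_neighbor_distance(curve)
    peak_H = curve.H_um.max()
    nn_txt = f"{nn:.0f} nm" if nn is not None else "n/a"
    print(f"{name:16s}: n={len(points):4d}  max H = {peak_H:+.3f} um  "
          f"modal dH/dr = {grad:+.3f}  r_nn = {nn_txt}")
# CSR hovers near H = 0 with a near-zero gradient; clusters push H (and its
# gradient) positive at the cluster scale; the lattice starts negative and
# its initial H minimum estimates the nearest-neighbour spacing.
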